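# alkylbind

A desk-scale, fully tested re-implementation of the computational analysis
used to characterize **asymmetric alkylphenol anesthetic binding to the
subunit interfaces of a heteropentameric GABA_A receptor**. Propofol-like
ligands bind the transmembrane interfaces of the receptor with very
different affinities, and the selectivity tracks the probability that the
ligand's hydroxyl forms a hydrogen bond with cavity residues. The package
reproduces every quantitative step of that argument with a toy host-guest
simulator and synthetic proteomics/pharmacology generators standing in for
the atomistic MD engine and the mass spectrometer:

1. **Alchemical decoupling free energies.** A Metropolis Monte Carlo
   sampler moves a rigid C-O-H ligand in a box with a Gaussian-well
   binding site scaled by a coupling parameter λ. Per-window work samples
   are turned into a free energy with the Zwanzig identity
   ΔG = −RT ln⟨exp(−ΔU/RT)⟩, corrected by the standard-state volume term
   −RT ln(V_site/V₀) with V₀ = 10²⁷/N_A ≈ 1660 Å³, giving
   K_D = exp(ΔG⁰/RT)·1 M and the ±δ uncertainty band
   (K_D e^{−δ/RT}, K_D e^{+δ/RT}), δ = 1 kcal/mol by default.
2. **Hydrogen-bond occupancy.** Geometric criterion (donor-acceptor
   distance ≤ 3.3 Å, deviation angle ≤ 40°), burn-in exclusion, and the
   per-site bond probability P_hb with >0.8 / <0.3 classification.
3. **Selectivity regression.** Closed-form OLS of pK_D = a·P_hb + b with
   standard errors, r², and a 95% mean-response confidence band.
4. **Quantitative ABPP.** TMT-style enrichment factors
   (mean UV+/UV− replicate ratio), the high-capture gate (EF > 10) and
   ligand-specificity rule (>50% protection and ΔEF ≥ 5).
5. **Pharmacology fits.** Variable-slope Hill dose-response with EC50
   CIs, the Cheng-Prusoff correction K_D = IC50/(1+[probe]/K_D^probe),
   and single-exponential photolysis decay with t½ = ln2/k.

Every generator serializes its ground truth, and every sampled quantity
has a deterministic oracle (3-D quadrature of the configuration
integrals, closed-form Gaussian identities, or exhaustive enumeration)
that the test suite checks against.

## Worked example

The packaged demo study runs the full chain — simulator → free-energy
engine → H-bond occupancy → selectivity regression — on four engineered
interface sites, two with hydrogen-bond geometry aligned to the bound
ligand and two with the polar partners offset from the binding position:

```bash
alkylbind demo --seed 1 --out demo_out
```

prints

```
affinity ranking: alpha+/beta- > beta+/alpha- > alpha+/gamma- > gamma+/beta-
report written to demo_out/demo_report.json
```

and the report contains (seed 1):

| site          | P_hb  | class | K_D (µM) | δ-band (µM) | ΔG⁰ (kcal/mol) |
|---------------|-------|-------|----------|-------------|----------------|
| alpha+/beta-  | 0.991 | high  | 1.6      | 0.3–9       | −7.96          |
| beta+/alpha-  | 0.991 | high  | 50       | 9–300       | −5.91          |
| alpha+/gamma- | 0.000 | low   | 4100     | 800–20000   | −3.27          |
| gamma+/beta-  | 0.000 | low   | 18000    | 3000–100000 | −2.39          |

The two hydrogen-bond-aligned sites bind 2–4 orders of magnitude tighter
than the misaligned ones and the K_D ranking follows the engineered well
depths exactly; the pooled pK_D-vs-P_hb line fits with a = 3.0 ± 0.8,
b = 2.1 ± 0.6, r² = 0.87. That is the qualitative selectivity pattern the
pipeline exists to detect: hydrogen bonding is the recognition element
that separates high- from low-affinity interfaces.

Other entry points: `alkylbind simulate/fep/hbond/selectivity/abpp/fit/synth`
(see `--help` on each; file formats are documented in `docs/FORMATS.md`,
the model in `docs/methods.md`).

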