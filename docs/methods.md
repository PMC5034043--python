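# Methods

## The toy host-guest model

The simulator replaces an all-atom membrane-receptor system with the
smallest model that still exercises the full free-energy/occupancy
analysis chain. A rigid three-atom ligand (C-O-H; bond lengths 1.4 and
1.0 Å, C-O-H angle 108.5°, typical covalent values) moves in a
hard-walled box (default 20×20×20 Å, centered on the origin). The binding
site is a sum of attractive isotropic Gaussian wells,

    U_site(r) = − Σ_i ε_i exp(−|r − c_i|² / 2w_i²),   ε_i ≥ 0,

evaluated at the hydroxyl-oxygen position, and the alchemical coupling is
linear: U_λ = λ·U_site. Because Gaussian wells are bounded there is no
endpoint singularity, so no soft-core scheme is needed.

Two deliberate simplifications keep the reference state analytic:

* Only the oxygen (the interaction center) is confined by the hard wall;
  the C and H atoms are rigid decorations that may protrude. At λ = 0 the
  oxygen is therefore *exactly* uniform over V_box, and every ensemble
  average is a 3-D integral over the box.
* There is no solvent, no protein degrees of freedom, and no periodic
  wrap. "Solvation" enters the free-energy assembly only as an injectable
  constant ΔG_solv (default 0 for the toy).

Hydrogen-bond partners are fixed site atoms. Each declared pair places an
acceptor atom and a donor atom (with its hydrogen 1.0 Å from the donor,
pointing at the acceptor). Engineered high-affinity sites put the pair
diametrically across the well center at 2.9 Å reach, so a bound ligand
oxygen sits right on the donor's H-bond axis; low-affinity sites use the
same construction displaced 5 Å from the well, mimicking a cavity whose
polar residues are engaged elsewhere (e.g. by a stable water cluster) and
unavailable to the ligand.

### Sampling

The Markov chain mixes three proposal kinds, all applied to the oxygen:

* local translations, a 50/50 mixture of a coarse step (default 2.0 Å)
  and a fine step (coarse/8) — the coarse step mixes across the box, the
  fine step resolves narrow well interiors;
* independence "hops" (probability 0.25) drawn from a fixed mixture
  density, half uniform over the box and half equal-weight Gaussians at
  the well centers (σ = well width), accepted with the exact
  Metropolis-Hastings ratio. These keep well↔bulk exchange efficient even
  when a thermal escape from a deep well is essentially forbidden;
* a small random-axis rigid rotation, proposed jointly with the
  translation. Orientation carries no energy, so it simply rides along
  with the translational accept/reject decision.

A single seeded generator drives each run; the seed, λ, and acceptance
rate are recorded in the trajectory metadata, and identical inputs give
bit-identical output. Chain samples are serially correlated; tests that
apply i.i.d. statistics (the λ = 0 uniformity chi-square) thin the chain
first, and Monte Carlo error bars elsewhere use batch means.

## Free-energy assembly

Decoupling runs over a λ schedule from 1 to 0 (default 24 uniform
windows; 10⁴ samples and 10³ equilibration steps per window, warm-started
window to window). Per window the forward work samples are
ΔU = (λ_{k+1}−λ_k)·U_site on λ_k-equilibrated states, and the Zwanzig
estimate is computed with a max-shifted log-mean-exp so it is finite for
any finite inputs. The same pass stores ΔU evaluated on the λ_{k+1}-side
samples; the resulting reverse estimate and the forward/reverse gap are
reported per window purely as an overlap diagnostic (the forward
exponential average is always the estimator of record). The standard
binding free energy is assembled as

    ΔG⁰ = −(ΔG_decouple + ΔG_solv) − RT ln(V_site / V₀),

with V₀ = 10²⁷/N_A ≈ 1660.5 Å³ and V_site = (4/3)πR_s³ from the
flat-bottom site region (default R_s = 4 Å — a model choice, since the
bound-region volume of a real protein site is not sharply defined).
The sign convention is negative-favorable, K_D = exp(ΔG⁰/RT)·1 M. (The
equivalent convention that writes K_D = exp(−ΔG⁰/RT) treats ΔG⁰ as the
positive unbinding free energy; only the negative-favorable form is
consistent with micromolar K_D values, so it is used throughout.)
Temperature defaults to 300 K with R = 1.9872×10⁻³ kcal/(mol·K).

Uncertainty bands multiply K_D by e^{±δ/RT} with δ = 1 kcal/mol by
default; printed forms round half-away-from-zero to 1 significant figure
(raw values are always retained). Note that bands computed from a
*rounded* K_D can differ in their last digit from bands computed from the
unrounded value — e.g. a true K_D of 0.13 µM prints as 0.1 µM while its
band prints as 0.02–0.7 µM, which is not the band of 0.1 µM exactly. Only
bands recomputed from the same printed value are expected to reproduce
digit-for-digit.

### Oracles

For any toy system the configurational integrals are low-dimensional:
Z(λ) = ∫_box exp(−λU/RT) dr. Two independent deterministic routes are
provided: Simpson quadrature on a regular grid (accurate for wells with
ε/RT up to ~10 at the default 161 points/axis) and, for isolated wells of
any depth, a 1-D radial decomposition Z = V_box + Σ_i 4π∫r²(e^{λε_i
g_i(r)/RT}−1)dr evaluated adaptively. The Monte Carlo pipeline is
validated against these: on the packaged single-well (ε = 5, w = 1.2 Å)
and three-well (ε = 4/3/2) systems the 24×10⁴-sample estimate agrees with
quadrature to well under 0.1 kcal/mol (typical |error| ≈ 0.01–0.02, seed
SD ≈ 0.01). For Gaussian work distributions the closed form
ΔG = µ − σ²/2RT is used.

## Hydrogen-bond occupancy

A donor-H···acceptor triple is bonded when d(D,A) ≤ 3.3 Å **and** the
deviation angle ≤ 40°, ties counting as bonded. The default deviation
convention is the angle at the donor between D→H and D→A (the criterion
of the common trajectory-analysis tooling); the alternative 180°−∠(D-H-A)
convention is selectable via the criterion's `convention` tag. Both
directions are scanned per frame: ligand hydroxyl as donor to site
acceptors, and site donors to the ligand oxygen (a hydroxyl oxygen plays
both parts). P_hb is the fraction of frames with at least one bond after
discarding the first `burn_in_fraction` of frames (default 0.25,
mirroring the usual practice of dropping the first quarter of a
production run as equilibration; toy time units are arbitrary, so the
burn-in is a fraction rather than an absolute time). Sites classify as
high (P_hb > 0.8), low (P_hb < 0.3) or intermediate — strict
inequalities.

## Selectivity regression

pK_D = −log₁₀(K_D/1 M) is regressed on P_hb by unweighted closed-form
OLS (a weight option exists for sensitivity analysis only). Standard
errors come from the residual variance at n−2 degrees of freedom, and the
95% band is the *mean-response* confidence band with the t-quantile —
with n = 4 interfaces the t-quantile at 2 degrees of freedom is large and
the band is correspondingly wide, which is deliberate honesty about a
four-point fit. The real-system fitted coefficients (a ≈ 3.4, b ≈ 3.4)
cannot be regenerated from printed data because the underlying per-site
(P_hb, pK_D) coordinates are not published; the packaged tests therefore
check exact recovery on constructed lines and qualitative agreement on
the demo study instead.

## ABPP quantification

Protein-level channel tables are the entry point (spectral search, FDR
and peptide-level rollup are upstream concerns). Enrichment factors are
the arithmetic mean of per-replicate channel ratios — matching the
"mean ratio" definition; the pooled-intensity alternative is available as
an option. Protection is defined against the same protein's capture EF,
protection% = 100·(EF_capture − EF_protected)/EF_capture. Decision rules:
high capture iff EF > 10 (strict); ligand-specific iff protection% > 50
and EF decrease ≥ 5, evaluated only for high-capture proteins. Replicates
with a zero UV(−) denominator make the record undefined; such records are
flagged and excluded rather than imputed with pseudo-counts, which would
silently reorder EF ranks.

The synthetic TMT generator draws background true EFs from a tight
log-normal around 1 (log2 SD 0.1, so the capture gate is genuinely
exercised rather than trivially passed), applies multiplicative
log-normal replicate noise specified as a log2-scale SD (default 0.28,
the scale at which replicate spread is conventionally reported), and
spikes in targets with prescribed (EF, protection%). It does not emulate
isotopic impurity, missing values, or abundance-dependent variance; a
perfect recall/precision result on it demonstrates the decision rules and
noise tolerance at realistic spread, not performance on real MS data.

## Pharmacology fits

The four-parameter logistic is response = bottom +
(top−bottom)/(1+(EC50/c)^h); h < 0 gives a decreasing curve in the same
parameterization, so displacement data fit without a separate inverted
branch. EC50 is optimized on a log10 scale, with a deterministic log-grid
start (40 points spanning min dose/10 to max dose×10) so repeated fits
are identical. CIs are asymptotic t-intervals from the local curvature by
default (EC50 intervals formed on the log scale and exponentiated); a
seeded case-resampling bootstrap is available because the CI method
behind published tables is typically unstated commercial software.
Measured calibration at the packaged generating conditions (EC50 6.1 µM,
slope 3, σ = 0.05, 8 doses × 4): ~95% empirical coverage for both
parameters. Exponential decay fits A(t) = A₀e^{−kt} (optional floor) with
t½ = ln2/k; the t½ interval is the monotone image of the k interval, and
flat or rising data is flagged (`no-decay-trend`, `rate-at-zero-boundary`)
rather than silently fitted.

## Demo study sizes and determinism

The packaged four-site study uses 24 windows × 2 500 samples for the
free-energy leg and 4 000 frames (25% burn-in) for occupancy — sizes
chosen so the whole study runs in seconds while keeping the Monte Carlo
error (~0.1 kcal/mol per site) far smaller than the engineered 1–2
kcal/mol gaps between sites. Engineered well depths are 16/14/11/10
kcal/mol (width 0.8 Å); deeper-equals-tighter is a design identity, so
the ranking check is a pipeline test, not a physics discovery. All stages
derive their seeds from the single run seed; a fixed seed gives a
byte-identical report.

## Known limitations

* The toy potential acts on a point; no ligand conformational entropy,
  no explicit water, no protein flexibility. Quantitative K_D values are
  properties of the toy, not predictions for any receptor.
* Forward exponential averaging is the only production estimator (no
  BAR/MBAR); the reverse estimate is diagnostic only.
* Donor/acceptor roles are explicit inputs — there is no chemical
  perception, and no water-cluster analysis behind the "hydrated cavity"
  narrative of the misaligned demo sites.
* Replicate-noise recovery and spike-in classification are validated on
  the generator's own noise model (log-normal, homoscedastic in log
  space), which understates the messiness of real reporter-ion data.
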