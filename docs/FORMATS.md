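# File formats

All text files are UTF-8; CSV is comma-separated with a header row and
`.` decimal; coordinates are Cartesian angstroms with no periodic wrap.

## Trajectory: XYZ + roles sidecar

`*.xyz` — standard multi-frame XYZ. Per frame: atom-count line, then a
comment line `lambda=<float> frame=<int>`, then `ELEMENT x y z` lines.

`*.roles.json` (written next to the XYZ unless another path is given):

```json
{
 "atoms": [{"id": "lig_O", "element": "O", "role": "donor",
            "group": "ligand", "parent": null}, ...],
 "frame_interval": 1.0,
 "metadata": {"seed": 0, "lambda": 1.0, "system": "...",
              "acceptance": 0.41, "u_site": [...]}
}
```

`role` ∈ {donor, hydrogen, acceptor, other}; every `hydrogen` names its
covalent donor in `parent`. `group` separates `ligand` from `site`.
`u_site` is the per-frame site energy (kcal/mol).

## Window samples CSV (`fep`)

Long format, one row per sample:

| column                | meaning                                   |
|-----------------------|-------------------------------------------|
| `lambda_from`         | window start coupling                     |
| `lambda_to`           | window end coupling                       |
| `delta_u_kcal_mol`    | ΔU = U(λ_to) − U(λ_from) on λ_from states |
| `delta_u_rev_kcal_mol`| optional; same ΔU on λ_to states          |

## System YAML (`simulate --config`)

```yaml
label: single-well
box_lengths: [20.0, 20.0, 20.0]
wells:
- {center: [0.0, 0.0, 0.0], depth: 5.0, width: 1.2}
site_region: {center: [0.0, 0.0, 0.0], radius: 4.0}
hb_sites:
- {acceptor: [0.0, 0.0, -2.9], donor: [0.0, 0.0, 2.9]}
```

Depths in kcal/mol, widths/radii/positions in angstroms.

## Selectivity records CSV

Columns `site_id`, `kd_molar`, `phb`. K_D in mol/L.

## ABPP quant CSV

One row per protein × replicate: `protein_id`, `replicate`, `uv_plus`,
`uv_minus`, `protected` (non-negative reporter intensities). The
classification output CSV adds `ef_capture`, `ef_protected`,
`protection_pct`, `delta_ef`, `high_capture`, `ligand_specific`,
`flagged`, `flag_reason`.

## Curve-fit CSVs

Hill: columns `concentration` (mol/L), `response`. Decay: columns
`time`, `value` (value > 0).

## JSON reports

`fep` writes the assembled free-energy result (per-window table
included); `selectivity` the fit + ranking; `hbond` the occupancy result;
`demo` the full study report. `synth` writes `truth.json` with the
generating parameters and seed next to every dataset.
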