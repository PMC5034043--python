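"""Quantitative ABPP classification from TMT reporter-channel tables.

Three reporter channels per replicate quantify each protein: ``uv_plus``
(photo-crosslinked capture), ``uv_minus`` (no-irradiation background) and
``protected`` (capture in the presence of excess competing ligand). The
decision rules:

* enrichment factor EF = arithmetic mean over replicates of the
  per-replicate UV+/UV- channel ratio (likewise protected/UV-);
* a protein is *high capture* when EF_capture > 10 (strict);
* a high-capture protein is *ligand specific* when
  protection% = 100 * (EF_capture - EF_protected) / EF_capture exceeds 50
  and the enrichment-factor decrease EF_capture - EF_protected is >= 5.

Replicates with a zero UV- denominator make the record undefined; such
records are flagged and excluded from classification rather than patched
with pseudo-counts, which would silently reorder enrichment ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProteinQuant",
    "EnrichmentRecord",
    "enrichment_factor",
    "classify_capture",
    "classify_protection",
    "classify_proteome",
    "summarize_proteome",
    "quant_from_csv",
    "records_to_frame",
]

QUANT_COLUMNS = ("protein_id", "replicate", "uv_plus", "uv_minus", "protected")


@dataclass
class ProteinQuant:
    """Per-protein channel intensities, one row per replicate."""

    protein_id: str
    uv_plus: np.ndarray
    uv_minus: np.ndarray
    protected: np.ndarray
    channel_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.uv_plus = np.asarray(self.uv_plus, dtype=float)
        self.uv_minus = np.asarray(self.uv_minus, dtype=float)
        self.protected = np.asarray(self.protected, dtype=float)
        sizes = {self.uv_plus.size, self.uv_minus.size, self.protected.size}
        if len(sizes) != 1 or self.uv_plus.size < 1:
            raise ValueError(f"{self.protein_id}: replicate channel arrays must match, >= 1")
        for name, arr in (("uv_plus", self.uv_plus), ("uv_minus", self.uv_minus),
                          ("protected", self.protected)):
            if (arr < 0).any() or not np.isfinite(arr).all():
                raise ValueError(f"{self.protein_id}: invalid {name} intensities")

    @property
    def n_replicates(self) -> int:
        return int(self.uv_plus.size)


@dataclass
class EnrichmentRecord:
    protein_id: str
    ef_capture: float | None
    ef_protected: float | None
    protection_pct: float | None
    delta_ef: float | None
    high_capture: bool
    ligand_specific: bool
    flagged: bool = False
    flag_reason: str | None = None
    log2_capture_ratios: np.ndarray | None = None
    log2_protected_ratios: np.ndarray | None = None


def enrichment_factor(quant: ProteinQuant) -> tuple[float | None, float | None]:
    """(EF_capture, EF_protected) or (None, None) for a zero UV- replicate."""
    if (quant.uv_minus == 0).any():
        return None, None
    return (
        float(np.mean(quant.uv_plus / quant.uv_minus)),
        float(np.mean(quant.protected / quant.uv_minus)),
    )


def classify_capture(ef_capture: float, threshold: float = 10.0) -> bool:
    """High-capture call: EF strictly greater than the threshold."""
    if ef_capture is None or not math.isfinite(ef_capture):
        raise ValueError("EF must be defined to classify capture")
    return ef_capture > threshold


def classify_protection(
    ef_capture: float,
    ef_protected: float,
    pct_threshold: float = 50.0,
    delta_threshold: float = 5.0,
) -> bool:
    """Ligand-specific call for a high-capture protein.

    True iff protection% > pct_threshold (strict) and the enrichment-factor
    decrease is >= delta_threshold.
    """
    if not (ef_capture > 0):
        raise ValueError("EF_capture must be positive to evaluate protection")
    protection_pct = 100.0 * (ef_capture - ef_protected) / ef_capture
    delta_ef = ef_capture - ef_protected
    return protection_pct > pct_threshold and delta_ef >= delta_threshold


def classify_proteome(
    quants: list[ProteinQuant],
    ef_threshold: float = 10.0,
    pct_threshold: float = 50.0,
    delta_threshold: float = 5.0,
) -> list[EnrichmentRecord]:
    """Apply the full capture/protection rule set to a quant table.

    Protection is only evaluated for proteins that pass the capture gate;
    undefined-EF records come back flagged with ``high_capture`` and
    ``ligand_specific`` both False.
    """
    records = []
    for q in quants:
        ef_cap, ef_prot = enrichment_factor(q)
        if ef_cap is None:
            records.append(
                EnrichmentRecord(
                    protein_id=q.protein_id,
                    ef_capture=None,
                    ef_protected=None,
                    protection_pct=None,
                    delta_ef=None,
                    high_capture=False,
                    ligand_specific=False,
                    flagged=True,
                    flag_reason="zero UV(-) intensity in at least one replicate",
                )
            )
            continue
        high = classify_capture(ef_cap, ef_threshold)
        protection_pct = (
            100.0 * (ef_cap - ef_prot) / ef_cap if ef_cap > 0 else None
        )
        specific = high and classify_protection(ef_cap, ef_prot, pct_threshold, delta_threshold)
        with np.errstate(divide="ignore"):
            l2c = np.log2(q.uv_plus / q.uv_minus)
            l2p = np.log2(q.protected / q.uv_minus)
        records.append(
            EnrichmentRecord(
                protein_id=q.protein_id,
                ef_capture=ef_cap,
                ef_protected=ef_prot,
                protection_pct=protection_pct,
                delta_ef=ef_cap - ef_prot,
                high_capture=high,
                ligand_specific=specific,
                log2_capture_ratios=l2c,
                log2_protected_ratios=l2p,
            )
        )
    return records


def _pooled_sd(ratio_sets: list[np.ndarray]) -> float | None:
    """Pooled within-protein SD of log2 ratios across replicates."""
    num = 0.0
    dof = 0
    for r in ratio_sets:
        r = r[np.isfinite(r)]
        if r.size >= 2:
            num += float(np.var(r, ddof=1)) * (r.size - 1)
            dof += r.size - 1
    return math.sqrt(num / dof) if dof > 0 else None


def summarize_proteome(
    records: list[EnrichmentRecord], bins: int = 40, log_base: float = 2.0
) -> dict:
    """Distribution summary of a classified proteome.

    Includes the log2 EF histogram, the pooled replicate-agreement SD in
    log2 space for capture and protected ratios, per-class counts, and the
    fraction of the input proteome passing the capture gate.
    """
    defined = [r for r in records if r.ef_capture is not None and r.ef_capture > 0]
    if not defined:
        raise ValueError("no records with defined EF")
    log_ef = np.log(np.array([r.ef_capture for r in defined])) / np.log(log_base)
    hist, edges = np.histogram(log_ef, bins=bins)
    n = len(records)
    n_high = sum(r.high_capture for r in defined)
    n_specific = sum(r.ligand_specific for r in defined)
    return {
        "n_proteins": n,
        "n_defined": len(defined),
        "n_flagged": n - len(defined),
        "n_high_capture": int(n_high),
        "n_ligand_specific": int(n_specific),
        "fraction_high_capture": n_high / n,
        "log_ef_hist_counts": hist.tolist(),
        "log_ef_hist_edges": edges.tolist(),
        "log2_sd_capture": _pooled_sd(
            [r.log2_capture_ratios for r in defined if r.log2_capture_ratios is not None]
        ),
        "log2_sd_protected": _pooled_sd(
            [r.log2_protected_ratios for r in defined if r.log2_protected_ratios is not None]
        ),
    }


def quant_from_csv(path: str | Path) -> list[ProteinQuant]:
    """Read a long-format quant CSV (protein_id, replicate, 3 channels)."""
    df = pd.read_csv(path)
    if not set(QUANT_COLUMNS).issubset(df.columns):
        raise ValueError(f"quant CSV must have columns {list(QUANT_COLUMNS)}")
    out = []
    for pid, g in df.groupby("protein_id", sort=False):
        g = g.sort_values("replicate")
        out.append(
            ProteinQuant(
                protein_id=str(pid),
                uv_plus=g["uv_plus"].to_numpy(),
                uv_minus=g["uv_minus"].to_numpy(),
                protected=g["protected"].to_numpy(),
            )
        )
    return out


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "ef_capture": [r.ef_capture for r in records],
            "ef_protected": [r.ef_protected for r in records],
            "protection_pct": [r.protection_pct for r in records],
            "delta_ef": [r.delta_ef for r in records],
            "high_capture": [r.high_capture for r in records],
            "ligand_specific": [r.ligand_specific for r in records],
            "flagged": [r.flagged for r in records],
            "flag_reason": [r.flag_reason for r in records],
        }
    )
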