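"""Interface affinity records and the pK_D-vs-P_hb selectivity line.

Per subunit interface the pipeline produces a dissociation constant K_D
and a hydrogen-bond probability P_hb; the selectivity analysis fits the
unweighted ordinary-least-squares line

    pK_D = a * P_hb + b,    pK_D = -log10(K_D / 1 M)

with closed-form coefficients, standard errors from the residual
variance at n-2 degrees of freedom, r^2, and a 95% mean-response
confidence band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InterfaceAffinity",
    "RegressionFit",
    "pkd",
    "fit_pkd_vs_phb",
    "rank_interfaces",
    "records_to_csv",
    "records_from_csv",
    "plot_fit",
]


def pkd(kd_molar: float) -> float:
    """pK_D = -log10(K_D / 1 M)."""
    if not (kd_molar > 0):
        raise ValueError(f"K_D must be positive, got {kd_molar}")
    return -math.log10(kd_molar)


@dataclass(frozen=True)
class InterfaceAffinity:
    """One (site, K_D, P_hb) record; pK_D derived on construction."""

    site_id: str
    kd_molar: float
    p_hb: float

    def __post_init__(self) -> None:
        if not (self.kd_molar > 0):
            raise ValueError(f"K_D must be positive, got {self.kd_molar}")
        if not (0.0 <= self.p_hb <= 1.0):
            raise ValueError(f"P_hb must be in [0, 1], got {self.p_hb}")

    @property
    def pkd(self) -> float:
        return pkd(self.kd_molar)


@dataclass
class RegressionFit:
    """OLS line pK_D = a * P_hb + b with uncertainties and a 95% band."""

    a: float
    b: float
    se_a: float
    se_b: float
    r2: float
    n: int
    residual_sd: float
    x_mean: float
    sxx: float

    def predict(self, p_hb) -> np.ndarray:
        return self.a * np.asarray(p_hb, dtype=float) + self.b

    def confidence_band(self, p_hb, level: float = 0.95):
        """Mean-response band half-width and (lo, hi) at the given P_hb."""
        x = np.asarray(p_hb, dtype=float)
        dof = self.n - 2
        if dof < 1:
            raise ValueError("confidence band needs n >= 3")
        t = stats.t.ppf(0.5 + level / 2.0, dof)
        half = t * self.residual_sd * np.sqrt(1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx)
        y = self.predict(x)
        return y - half, y + half

    def to_dict(self) -> dict:
        return {
            "slope_a": self.a,
            "intercept_b": self.b,
            "se_a": self.se_a,
            "se_b": self.se_b,
            "r2": self.r2,
            "n": self.n,
            "residual_sd": self.residual_sd,
        }


def fit_pkd_vs_phb(
    records: list[InterfaceAffinity], weights: np.ndarray | None = None
) -> RegressionFit:
    """Closed-form (optionally weighted) least squares of pK_D on P_hb.

    Unweighted by default; a weight vector is accepted for sensitivity
    analysis only.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    x = np.array([r.p_hb for r in records], dtype=float)
    y = np.array([r.pkd for r in records], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all P_hb identical")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    sw = w.sum()
    xb = (w * x).sum() / sw
    yb = (w * y).sum() / sw
    sxx = (w * (x - xb) ** 2).sum()
    sxy = (w * (x - xb) * (y - yb)).sum()
    a = sxy / sxx
    b = yb - a * xb
    resid = y - (a * x + b)
    rss = float((w * resid**2).sum())
    tss = float((w * (y - yb) ** 2).sum())
    n = len(records)
    dof = n - 2
    s2 = rss / dof if dof > 0 else 0.0
    s = math.sqrt(max(s2, 0.0))
    se_a = s / math.sqrt(sxx)
    se_b = s * math.sqrt(1.0 / sw + xb**2 / sxx)
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    return RegressionFit(
        a=float(a),
        b=float(b),
        se_a=float(se_a),
        se_b=float(se_b),
        r2=float(min(max(r2, 0.0), 1.0)),
        n=n,
        residual_sd=s,
        x_mean=float(xb),
        sxx=float(sxx),
    )


def rank_interfaces(records: list[InterfaceAffinity]) -> dict:
    """Order interfaces by affinity (ascending K_D) with fold differences.

    Returns the ordered site ids, the pairwise K_D ratio table (row / col),
    and the log10 gap between the tightest and weakest site.
    """
    if not records:
        raise ValueError("need at least 1 record")
    ordered = sorted(records, key=lambda r: r.kd_molar)
    ids = [r.site_id for r in ordered]
    kds = np.array([r.kd_molar for r in ordered])
    ratios = pd.DataFrame(kds[:, None] / kds[None, :], index=ids, columns=ids)
    return {
        "order": ids,
        "kd_molar": dict(zip(ids, kds.tolist())),
        "pairwise_kd_ratio": ratios,
        "log10_span": float(math.log10(kds[-1] / kds[0])),
    }


def records_to_csv(records: list[InterfaceAffinity], path: str | Path) -> None:
    pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "kd_molar": [r.kd_molar for r in records],
            "phb": [r.p_hb for r in records],
        }
    ).to_csv(path, index=False)


def records_from_csv(path: str | Path) -> list[InterfaceAffinity]:
    df = pd.read_csv(path)
    required = {"site_id", "kd_molar", "phb"}
    if not required.issubset(df.columns):
        raise ValueError(f"records CSV must have columns {sorted(required)}")
    return [
        InterfaceAffinity(str(r.site_id), float(r.kd_molar), float(r.phb))
        for r in df.itertuples()
    ]


def plot_fit(
    records: list[InterfaceAffinity], fit: RegressionFit, path: str | Path
) -> None:
    """Scatter of (P_hb, pK_D) with the fitted line and 95% band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([r.p_hb for r in records])
    y = np.array([r.pkd for r in records])
    grid = np.linspace(0.0, 1.0, 200)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    if fit.n > 2:
        lo, hi = fit.confidence_band(grid)
        ax.fill_between(grid, lo, hi, color="0.85", label="95% CI (mean)")
    ax.plot(grid, fit.predict(grid), "k-", lw=1,
            label=f"pK$_D$ = {fit.a:.2f} P$_{{hb}}$ + {fit.b:.2f}")
    ax.plot(x, y, "o", color="tab:blue")
    for r in records:
        ax.annotate(r.site_id, (r.p_hb, r.pkd), fontsize=7,
                    textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("P$_{hb}$")
    ax.set_ylabel("pK$_D$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
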