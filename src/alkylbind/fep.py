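"""Free-energy engine: Zwanzig exponential averaging, standard-state
correction, dissociation constants, and uncertainty bands.

The Zwanzig identity gives the exact free-energy difference between two
Hamiltonians from samples of the reference state:

    dG = -RT ln < exp(-dU / RT) >_ref

Summing it over a schedule of small coupling windows yields the decoupling
free energy dG_decouple (work to switch the site-ligand interaction off).
The standard binding free energy then assembles as

    dG0 = -(dG_decouple + dG_solv) + dG_volume,

with dG_volume = -RT ln(V_site / V0) the entropic cost of confining the
ligand from the standard-state volume per molecule V0 = 1660.5 A^3 to the
bound-site volume, and dG_solv an externally supplied ligand solvation
term (zero for the toy, whose "solvent" is an empty box). The convention
is negative-favorable: K_D = exp(dG0 / RT) * 1 mol/L, so a dG0 of
-7.85 kcal/mol at 300 K corresponds to K_D ~ 2 uM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .thermo import ThermoState, standard_state_volume_A3

__all__ = [
    "WindowSamples",
    "FreeEnergyResult",
    "KdBand",
    "zwanzig_window",
    "accumulate_decoupling",
    "standard_state_correction",
    "kd_from_delta_g",
    "delta_g_from_kd",
    "kd_uncertainty_band",
    "assemble_binding_free_energy",
    "round_sig",
    "windows_to_csv",
    "windows_from_csv",
]


@dataclass
class WindowSamples:
    """Energy-difference samples for one coupling window.

    ``delta_u`` holds dU = U(lam_to) - U(lam_from) evaluated on equilibrium
    samples of the lam_from state (kcal/mol). ``delta_u_reverse``, if
    present, holds the same dU evaluated on lam_to-side samples and feeds
    the forward/reverse overlap diagnostic only.
    """

    lam_from: float
    lam_to: float
    delta_u: np.ndarray
    delta_u_reverse: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta_u = np.asarray(self.delta_u, dtype=float)
        if self.delta_u.size < 1:
            raise ValueError("window needs at least one dU sample")
        if not np.isfinite(self.delta_u).all():
            raise ValueError("non-finite dU samples")
        if self.delta_u_reverse is not None:
            self.delta_u_reverse = np.asarray(self.delta_u_reverse, dtype=float)

    @property
    def n(self) -> int:
        return int(self.delta_u.size)


def zwanzig_window(samples: WindowSamples | np.ndarray, thermo: ThermoState) -> float:
    """Exponential-average free-energy difference for one window, kcal/mol.

    Computed as -RT * logmeanexp(-dU/RT) with a max-shift, so the result is
    finite whenever the inputs are.
    """
    du = samples.delta_u if isinstance(samples, WindowSamples) else np.asarray(samples, float)
    if du.size < 1:
        raise ValueError("empty sample list")
    rt = thermo.RT
    x = -du / rt
    m = float(np.max(x))
    return -rt * (m + math.log(float(np.mean(np.exp(x - m)))))


def accumulate_decoupling(
    windows: list[WindowSamples], thermo: ThermoState
) -> tuple[float, pd.DataFrame]:
    """Sum per-window Zwanzig estimates along a contiguous coupling path.

    Returns the total decoupling free energy and a per-window table with
    forward estimates, reverse estimates where reverse samples exist, the
    forward/reverse discrepancy, and max |dU|/RT as an overlap diagnostic.
    """
    if not windows:
        raise ValueError("no windows")
    for a, b in zip(windows, windows[1:]):
        if not math.isclose(a.lam_to, b.lam_from, abs_tol=1e-12):
            raise ValueError(
                f"non-contiguous lambda path: window ends at {a.lam_to}, next starts at {b.lam_from}"
            )
    steps = [w.lam_to - w.lam_from for w in windows]
    if not (all(s < 0 for s in steps) or all(s > 0 for s in steps)):
        raise ValueError("lambda path must be monotone")

    rt = thermo.RT
    rows = []
    total = 0.0
    for w in windows:
        dg_fwd = zwanzig_window(w, thermo)
        total += dg_fwd
        dg_rev = None
        if w.delta_u_reverse is not None and w.delta_u_reverse.size:
            # reverse estimate of the same dG, from the lam_to ensemble
            x = w.delta_u_reverse / rt
            m = float(np.max(x))
            dg_rev = rt * (m + math.log(float(np.mean(np.exp(x - m)))))
        rows.append(
            {
                "lam_from": w.lam_from,
                "lam_to": w.lam_to,
                "n": w.n,
                "dg_forward_kcal_mol": dg_fwd,
                "dg_reverse_kcal_mol": dg_rev,
                "fwd_rev_gap_kcal_mol": None if dg_rev is None else dg_fwd - dg_rev,
                "max_abs_du_over_rt": float(np.max(np.abs(w.delta_u))) / rt,
            }
        )
    return total, pd.DataFrame(rows)


def standard_state_correction(
    v_site_A3: float, thermo: ThermoState, v0_A3: float | None = None
) -> float:
    """Entropic volume term -RT ln(V_site/V0), kcal/mol.

    Positive when the bound-site volume is smaller than the 1 M
    standard-state volume per molecule (binding costs entropy).
    """
    if not (v_site_A3 > 0):
        raise ValueError(f"site volume must be positive, got {v_site_A3}")
    if v0_A3 is None:
        v0_A3 = standard_state_volume_A3()
    return -thermo.RT * math.log(v_site_A3 / v0_A3)


def kd_from_delta_g(delta_g0: float, thermo: ThermoState) -> float:
    """Dissociation constant (mol/L) from the standard binding free energy.

    Negative-favorable convention: K_D = exp(dG0/RT) * 1 M.
    """
    if not math.isfinite(delta_g0):
        raise ValueError("non-finite dG0")
    return math.exp(delta_g0 / thermo.RT)


def delta_g_from_kd(kd_molar: float, thermo: ThermoState) -> float:
    """Inverse of :func:`kd_from_delta_g`."""
    if not (kd_molar > 0):
        raise ValueError(f"K_D must be positive, got {kd_molar}")
    return thermo.RT * math.log(kd_molar)


def round_sig(x: float, sig_figs: int) -> float:
    """Round to ``sig_figs`` significant figures, half away from zero."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    q = Decimal(1).scaleb(exp - sig_figs + 1)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class KdBand:
    """K_D with a +-delta free-energy uncertainty band.

    ``low``/``high`` are K_D * exp(-+delta/RT); the rounded forms mirror how
    such ranges are conventionally printed (1 significant figure).
    """

    kd_molar: float
    delta_kcal_mol: float
    low: float
    high: float
    low_rounded: float
    high_rounded: float
    sig_figs: int

    def __post_init__(self) -> None:
        if not (self.low <= self.kd_molar <= self.high):
            raise ValueError("band must bracket K_D")


def kd_uncertainty_band(
    kd_molar: float,
    delta_kcal_mol: float,
    thermo: ThermoState,
    sig_figs: int = 1,
) -> KdBand:
    """Band (K_D e^{-d/RT}, K_D e^{+d/RT}) for a dG uncertainty of d."""
    if not (kd_molar > 0):
        raise ValueError(f"K_D must be positive, got {kd_molar}")
    if delta_kcal_mol < 0:
        raise ValueError(f"delta must be >= 0, got {delta_kcal_mol}")
    f = math.exp(delta_kcal_mol / thermo.RT)
    low, high = kd_molar / f, kd_molar * f
    return KdBand(
        kd_molar=kd_molar,
        delta_kcal_mol=delta_kcal_mol,
        low=low,
        high=high,
        low_rounded=round_sig(low, sig_figs),
        high_rounded=round_sig(high, sig_figs),
        sig_figs=sig_figs,
    )


@dataclass
class FreeEnergyResult:
    """Assembled standard binding free energy and derived quantities."""

    dg_decouple: float
    dg_volume: float
    dg_solv: float
    dg0: float
    kd_molar: float
    band: KdBand
    per_window: pd.DataFrame = field(repr=False)
    temperature_K: float = 300.0

    def to_dict(self) -> dict:
        pw = self.per_window.to_dict(orient="records")
        return {
            "dg_decouple_kcal_mol": self.dg_decouple,
            "dg_volume_kcal_mol": self.dg_volume,
            "dg_solv_kcal_mol": self.dg_solv,
            "dg0_kcal_mol": self.dg0,
            "kd_molar": self.kd_molar,
            "kd_band_molar": {
                "low": self.band.low,
                "high": self.band.high,
                "low_rounded": self.band.low_rounded,
                "high_rounded": self.band.high_rounded,
                "delta_kcal_mol": self.band.delta_kcal_mol,
            },
            "temperature_K": self.temperature_K,
            "per_window": pw,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=float))


def assemble_binding_free_energy(
    windows: list[WindowSamples],
    thermo: ThermoState,
    v_site_A3: float,
    dg_solv: float = 0.0,
    delta_kcal_mol: float = 1.0,
    v0_A3: float | None = None,
    sig_figs: int = 1,
) -> FreeEnergyResult:
    """Decoupling windows -> dG0, K_D, and the delta-uncertainty band."""
    dg_dec, table = accumulate_decoupling(windows, thermo)
    dg_vol = standard_state_correction(v_site_A3, thermo, v0_A3)
    dg0 = -(dg_dec + dg_solv) + dg_vol
    kd = kd_from_delta_g(dg0, thermo)
    band = kd_uncertainty_band(kd, delta_kcal_mol, thermo, sig_figs)
    return FreeEnergyResult(
        dg_decouple=dg_dec,
        dg_volume=dg_vol,
        dg_solv=dg_solv,
        dg0=dg0,
        kd_molar=kd,
        band=band,
        per_window=table,
        temperature_K=thermo.T,
    )


def windows_to_csv(windows: list[WindowSamples], path: str | Path) -> None:
    """Write window samples as long-format CSV.

    Columns: lambda_from, lambda_to, delta_u_kcal_mol and, when reverse
    samples are present, delta_u_rev_kcal_mol.
    """
    frames = []
    has_rev = all(w.delta_u_reverse is not None for w in windows)
    for w in windows:
        df = pd.DataFrame(
            {
                "lambda_from": w.lam_from,
                "lambda_to": w.lam_to,
                "delta_u_kcal_mol": w.delta_u,
            }
        )
        if has_rev:
            df["delta_u_rev_kcal_mol"] = w.delta_u_reverse
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def windows_from_csv(path: str | Path) -> list[WindowSamples]:
    """Read window samples written by :func:`windows_to_csv`."""
    df = pd.read_csv(path)
    required = {"lambda_from", "lambda_to", "delta_u_kcal_mol"}
    if not required.issubset(df.columns):
        raise ValueError(f"window CSV must have columns {sorted(required)}")
    out = []
    for (lf, lt), g in df.groupby(["lambda_from", "lambda_to"], sort=False):
        rev = g["delta_u_rev_kcal_mol"].to_numpy() if "delta_u_rev_kcal_mol" in g else None
        out.append(WindowSamples(float(lf), float(lt), g["delta_u_kcal_mol"].to_numpy(), rev))
    return out
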