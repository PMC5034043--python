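"""Synthetic data generators with serialized ground truth.

Every pipeline input can be generated here with known parameters: Gaussian
per-window work samples (Zwanzig exercise), TMT quant tables with
spike-ins, dose-response and photolysis-decay curves, and noisy
selectivity records on a known line. Identical spec + seed gives
byte-identical output; each generator returns (data, truth) and the
``truth`` dict is what gets serialized alongside written files.

Noise conventions mirror how the corresponding measurements scatter in
practice: TMT channel intensities get multiplicative log-normal noise
specified as a log2-scale SD (replicate spread of reporter ratios is
conventionally reported in log2 space); dose-response and decay traces
get additive Gaussian noise.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .abpp import ProteinQuant
from .fep import WindowSamples
from .pharm import DoseResponse, hill_response
from .selectivity import InterfaceAffinity
from .thermo import ThermoState

__all__ = [
    "gen_work_samples",
    "gen_tmt_table",
    "gen_dose_response",
    "gen_decay",
    "gen_selectivity_records",
    "write_truth",
]


def write_truth(truth: dict, out_dir: str | Path, name: str = "truth.json") -> None:
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    (Path(out_dir) / name).write_text(json.dumps(truth, indent=1, default=float))


def gen_work_samples(
    mu: float,
    sigma: float,
    n: int,
    seed: int = 0,
    thermo: ThermoState = ThermoState(),
    lam_from: float = 1.0,
    lam_to: float = 0.0,
) -> tuple[WindowSamples, dict]:
    """Gaussian work samples with the exact exponential-average answer.

    For dU ~ N(mu, sigma^2) the Zwanzig free energy is analytically
    mu - sigma^2 / (2 RT), attached as ground truth.
    """
    if sigma < 0 or n < 1:
        raise ValueError("need sigma >= 0 and n >= 1")
    rng = np.random.default_rng(seed)
    du = mu + sigma * rng.standard_normal(n)
    truth = {
        "mu_kcal_mol": mu,
        "sigma_kcal_mol": sigma,
        "dg_exact_kcal_mol": mu - sigma**2 / (2.0 * thermo.RT),
        "seed": seed,
        "n": n,
    }
    return WindowSamples(lam_from, lam_to, du), truth


def gen_tmt_table(
    n_proteins: int,
    n_replicates: int = 4,
    spike_ins: list[tuple[float, float]] | None = None,
    log2_noise_sd: float = 0.28,
    background_log2_sd: float = 0.1,
    base_intensity: float = 1.0e5,
    seed: int = 0,
) -> tuple[list[ProteinQuant], pd.DataFrame]:
    """TMT-style channel table: background proteome plus labeled spike-ins.

    Background proteins draw a true enrichment factor from a tight
    log-normal around 1 (not exactly 1, so threshold behavior is
    exercised) and are unprotected. Each ``spike_ins`` entry
    (EF_capture, protection_pct) prescribes one target protein. Replicate
    ratios scatter multiplicatively with the given log2-scale SD.

    Returns the quant list and a truth table with per-protein true EFs and
    the expected specific/high-capture labels at noiseless thresholds.
    """
    if n_proteins < 1 or log2_noise_sd < 0:
        raise ValueError("need n_proteins >= 1 and log2_noise_sd >= 0")
    spike_ins = list(spike_ins or [])
    if len(spike_ins) > n_proteins:
        raise ValueError("more spike-ins than proteins")
    rng = np.random.default_rng(seed)

    quants: list[ProteinQuant] = []
    rows = []
    for i in range(n_proteins):
        pid = f"P{i:05d}"
        if i < len(spike_ins):
            ef_cap, protect_pct = spike_ins[i]
            ef_prot = ef_cap * (1.0 - protect_pct / 100.0)
            is_spike = True
        else:
            ef_cap = float(2.0 ** (background_log2_sd * rng.standard_normal()))
            ef_prot = ef_cap  # background is unprotected
            protect_pct = 0.0
            is_spike = False
        uv_minus = base_intensity * rng.lognormal(0.0, 0.25, n_replicates)
        noise_cap = 2.0 ** (log2_noise_sd * rng.standard_normal(n_replicates))
        noise_prot = 2.0 ** (log2_noise_sd * rng.standard_normal(n_replicates))
        uv_plus = uv_minus * ef_cap * noise_cap
        protected = uv_minus * ef_prot * noise_prot
        quants.append(ProteinQuant(pid, uv_plus, uv_minus, protected))
        rows.append(
            {
                "protein_id": pid,
                "spike_in": is_spike,
                "true_ef_capture": ef_cap,
                "true_ef_protected": ef_prot,
                "true_protection_pct": protect_pct,
            }
        )
    return quants, pd.DataFrame(rows)


def quants_to_csv(quants: list[ProteinQuant], path: str | Path) -> None:
    """Long-format CSV matching :func:`alkylbind.abpp.quant_from_csv`."""
    rows = []
    for q in quants:
        for rep in range(q.n_replicates):
            rows.append(
                {
                    "protein_id": q.protein_id,
                    "replicate": rep,
                    "uv_plus": q.uv_plus[rep],
                    "uv_minus": q.uv_minus[rep],
                    "protected": q.protected[rep],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def gen_dose_response(
    ec50: float,
    hill: float,
    doses: np.ndarray,
    sigma: float = 0.05,
    n_per_dose: int = 4,
    bottom: float = 0.0,
    top: float = 1.0,
    seed: int = 0,
) -> tuple[DoseResponse, dict]:
    """Sigmoidal dose-response data with additive Gaussian noise."""
    doses = np.asarray(doses, dtype=float)
    if sigma < 0 or n_per_dose < 1:
        raise ValueError("need sigma >= 0 and n_per_dose >= 1")
    rng = np.random.default_rng(seed)
    c = np.repeat(doses, n_per_dose)
    y = hill_response(c, ec50, hill, bottom, top) + sigma * rng.standard_normal(c.size)
    truth = {
        "ec50_molar": ec50,
        "hill": hill,
        "bottom": bottom,
        "top": top,
        "sigma": sigma,
        "seed": seed,
        "n": int(c.size),
    }
    return DoseResponse(c, y), truth


def gen_decay(
    t_half: float,
    a0: float,
    times: np.ndarray,
    sigma_frac: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Single-exponential decay trace; noise SD is ``sigma_frac * a0``."""
    times = np.asarray(times, dtype=float)
    if t_half <= 0 or a0 <= 0 or sigma_frac < 0:
        raise ValueError("need t_half > 0, a0 > 0, sigma_frac >= 0")
    rng = np.random.default_rng(seed)
    k = np.log(2) / t_half
    v = a0 * np.exp(-k * times) + sigma_frac * a0 * rng.standard_normal(times.size)
    df = pd.DataFrame({"time": times, "value": v})
    truth = {"t_half": t_half, "k": k, "a0": a0, "sigma_frac": sigma_frac, "seed": seed}
    return df, truth


def gen_selectivity_records(
    a: float = 3.4,
    b: float = 3.4,
    phb_values: np.ndarray = (0.2, 0.3, 0.8, 0.9),
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[list[InterfaceAffinity], dict]:
    """Interface records on the line pK_D = a * P_hb + b (+ noise)."""
    phb = np.asarray(phb_values, dtype=float)
    rng = np.random.default_rng(seed)
    pkd_vals = a * phb + b + sigma * rng.standard_normal(phb.size)
    records = [
        InterfaceAffinity(f"site-{i}", 10.0 ** (-p), float(x))
        for i, (x, p) in enumerate(zip(phb, pkd_vals))
    ]
    truth = {"a": a, "b": b, "sigma": sigma, "seed": seed, "phb": phb.tolist()}
    return records, truth
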