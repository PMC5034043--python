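"""Pharmacology curve fits: variable-slope Hill dose-response, the
Cheng-Prusoff competition correction, and single-exponential decay.

The four-parameter logistic is parameterized as

    response(c) = bottom + (top - bottom) / (1 + (EC50 / c)^h)

which is increasing in concentration for h > 0 and decreasing for h < 0,
so displacement curves are fitted by the same form with a negative slope.
EC50 is fitted on a log10 scale (positivity for free), with a
deterministic log-grid start so the optimizer has no run-to-run
variability. Confidence intervals are asymptotic (t-based on the local
curvature) by default, with an optional seeded case-resampling bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponse",
    "HillFit",
    "DecayFit",
    "fit_hill",
    "fit_exp_decay",
    "cheng_prusoff",
    "ec_fraction",
    "hill_response",
]


@dataclass
class DoseResponse:
    """Concentrations (mol/L, > 0) and matching normalized responses."""

    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentration and response arrays must match")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be positive")
        if not np.isfinite(self.responses).all():
            raise ValueError("non-finite responses")


def hill_response(c, ec50: float, hill: float, bottom: float, top: float):
    """Four-parameter logistic, vectorized over concentration."""
    c = np.asarray(c, dtype=float)
    z = np.clip(hill * (np.log(ec50) - np.log(c)), -500, 500)
    return bottom + (top - bottom) / (1.0 + np.exp(z))


@dataclass
class HillFit:
    ec50: float
    hill: float
    bottom: float
    top: float
    ci: dict[str, tuple[float, float]]
    n: int
    rss: float
    ci_method: str = "asymptotic"

    def __post_init__(self) -> None:
        if not (self.ec50 > 0):
            raise ValueError(f"EC50 must be positive, got {self.ec50}")

    def predict(self, c):
        return hill_response(c, self.ec50, self.hill, self.bottom, self.top)

    def to_dict(self) -> dict:
        return {
            "ec50_molar": self.ec50,
            "hill": self.hill,
            "bottom": self.bottom,
            "top": self.top,
            "ci95": {k: list(v) for k, v in self.ci.items()},
            "n": self.n,
            "rss": self.rss,
        }


_PARAMS = ("ec50", "hill", "bottom", "top")


def _hill_free_model(free_names, fixed):
    def model(c, *theta):
        p = dict(fixed)
        for name, v in zip(free_names, theta):
            p[name] = 10.0**v if name == "ec50" else v
        return hill_response(c, p["ec50"], p["hill"], p["bottom"], p["top"])

    return model


def fit_hill(
    data: DoseResponse,
    fix: dict[str, float] | None = None,
    ci_method: str = "asymptotic",
    n_boot: int = 500,
    seed: int = 0,
) -> HillFit:
    """Least-squares variable-slope Hill fit.

    ``fix`` pins any of top / bottom / hill (or even ec50) to a constant,
    which also relaxes the minimum-data requirement. Starting values come
    from a deterministic scan: EC50 over a log grid spanning
    [min dose / 10, max dose * 10], slope sign from the response trend.
    """
    fix = dict(fix or {})
    free_names = [p for p in _PARAMS if p not in fix]
    c, y = data.concentrations, data.responses
    n_distinct = np.unique(c).size
    if n_distinct < len(free_names):
        raise ValueError(
            f"need >= {len(free_names)} distinct concentrations for {len(free_names)} free parameters"
        )
    if np.ptp(y) == 0 and "top" not in fix and "bottom" not in fix:
        raise ValueError("degenerate data: responses are flat")

    trend = np.corrcoef(np.log(c), y)[0, 1] if np.ptp(y) > 0 else 1.0
    start = {
        "hill": 1.0 if trend >= 0 else -1.0,
        "bottom": float(np.min(y)),
        "top": float(np.max(y)),
    }
    # deterministic log-grid scan for the EC50 start
    grid = np.logspace(math.log10(c.min() / 10.0), math.log10(c.max() * 10.0), 40)
    if "ec50" in fix:
        start["ec50"] = fix["ec50"]
    else:
        trial = {**start, **fix}
        sse = [
            float(((hill_response(c, g, trial["hill"], trial["bottom"], trial["top"]) - y) ** 2).sum())
            for g in grid
        ]
        start["ec50"] = float(grid[int(np.argmin(sse))])

    p0 = [math.log10(start[p]) if p == "ec50" else start[p] for p in free_names]
    model = _hill_free_model(free_names, fix)
    popt, pcov = curve_fit(model, c, y, p0=p0, maxfev=20000)

    est = dict(fix)
    for name, v in zip(free_names, popt):
        est[name] = 10.0**v if name == "ec50" else v
    resid = y - hill_response(c, est["ec50"], est["hill"], est["bottom"], est["top"])
    rss = float((resid**2).sum())
    dof = max(len(y) - len(free_names), 1)

    ci: dict[str, tuple[float, float]] = {}
    if ci_method == "asymptotic":
        tq = stats.t.ppf(0.975, dof)
        se = np.sqrt(np.diag(pcov))
        for (name, v), s in zip(zip(free_names, popt), se):
            lo, hi = v - tq * s, v + tq * s
            if name == "ec50":
                ci[name] = (10.0**lo, 10.0**hi)
            else:
                ci[name] = (float(lo), float(hi))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = {name: [] for name in free_names}
        for _ in range(n_boot):
            idx = rng.integers(0, len(y), len(y))
            try:
                pb, _ = curve_fit(model, c[idx], y[idx], p0=popt, maxfev=5000)
            except RuntimeError:
                continue
            for name, v in zip(free_names, pb):
                draws[name].append(10.0**v if name == "ec50" else v)
        for name in free_names:
            lo, hi = np.percentile(draws[name], [2.5, 97.5])
            ci[name] = (float(lo), float(hi))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return HillFit(
        ec50=float(est["ec50"]),
        hill=float(est["hill"]),
        bottom=float(est["bottom"]),
        top=float(est["top"]),
        ci=ci,
        n=len(y),
        rss=rss,
        ci_method=ci_method,
    )


def ec_fraction(ec50: float, hill: float, fraction_pct: float) -> float:
    """Concentration giving the stated percent of maximal effect.

    EC_f = EC50 * (f / (100 - f))^(1/h); e.g. the EC10 used to set a
    low-baseline agonist response before testing a modulator.
    """
    if not (0 < fraction_pct < 100):
        raise ValueError("fraction_pct must be in (0, 100)")
    if ec50 <= 0 or hill == 0:
        raise ValueError("need EC50 > 0 and hill != 0")
    return ec50 * (fraction_pct / (100.0 - fraction_pct)) ** (1.0 / hill)


def cheng_prusoff(ic50: float, probe_conc: float, probe_kd: float) -> float:
    """Competition-corrected K_D = IC50 / (1 + [probe]/K_D(probe)).

    With no competing probe (probe_conc -> 0) the K_D equals the IC50.
    """
    if ic50 <= 0 or probe_kd <= 0 or probe_conc < 0:
        raise ValueError("ic50 and probe_kd must be > 0, probe_conc >= 0")
    return ic50 / (1.0 + probe_conc / probe_kd)


@dataclass
class DecayFit:
    k: float  # rate constant, 1/time
    t_half: float
    amplitude: float
    floor: float
    ci: dict[str, tuple[float, float]]
    n: int
    flags: list[str] = field(default_factory=list)

    def predict(self, t):
        return self.floor + self.amplitude * np.exp(-self.k * np.asarray(t, dtype=float))

    def to_dict(self) -> dict:
        return {
            "k_per_time": self.k,
            "t_half": self.t_half,
            "amplitude": self.amplitude,
            "floor": self.floor,
            "ci95": {key: list(v) for key, v in self.ci.items()},
            "n": self.n,
            "flags": self.flags,
        }


def fit_exp_decay(
    times: np.ndarray, values: np.ndarray, with_floor: bool = False
) -> DecayFit:
    """Fit A(t) = A0 exp(-k t) (+ optional floor); report t1/2 = ln2 / k.

    The t1/2 interval is the monotone image of the asymptotic k interval.
    Flat or rising data is fitted anyway but flagged, since k is then at
    (or beyond) its physical boundary.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.size < 3:
        raise ValueError("need >= 3 matching (time, value) points")
    if (v <= 0).any():
        raise ValueError("values must be positive for an exponential-decay fit")

    flags: list[str] = []
    slope = np.polyfit(t, np.log(v), 1)[0]
    if slope >= 0:
        flags.append("no-decay-trend")
    k0 = max(-slope, 1e-9)
    a0 = float(v.max())

    if with_floor:
        model = lambda tt, a, k, f: f + a * np.exp(-k * tt)
        p0, names = [a0, k0, float(v.min())], ["amplitude", "k", "floor"]
        bounds = ([0, 0, 0], [np.inf, np.inf, np.inf])
    else:
        model = lambda tt, a, k: a * np.exp(-k * tt)
        p0, names = [a0, k0], ["amplitude", "k"]
        bounds = ([0, 0], [np.inf, np.inf])
    popt, pcov = curve_fit(model, t, v, p0=p0, bounds=bounds, maxfev=20000)
    est = dict(zip(names, popt))
    k = float(est["k"])
    if k < 1e-8:
        flags.append("rate-at-zero-boundary")

    dof = max(t.size - len(names), 1)
    tq = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.diag(pcov))
    ci = {}
    for name, val, s in zip(names, popt, se):
        ci[name] = (float(val - tq * s), float(val + tq * s))
    k_lo, k_hi = ci["k"]
    ci["t_half"] = (
        math.log(2) / k_hi if k_hi > 0 else math.inf,
        math.log(2) / k_lo if k_lo > 0 else math.inf,
    )

    return DecayFit(
        k=k,
        t_half=math.log(2) / k if k > 0 else math.inf,
        amplitude=float(est["amplitude"]),
        floor=float(est.get("floor", 0.0)),
        ci=ci,
        n=t.size,
        flags=flags,
    )
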