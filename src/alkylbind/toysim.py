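"""Toy host-guest Metropolis Monte Carlo simulator.

A rigid three-atom ligand (C-O-H, an alkylphenol-hydroxyl proxy) moves in a
hard-walled box containing a composite of attractive Gaussian wells - the
"binding site". The site-ligand potential is scaled by a coupling parameter
``lambda`` in [0, 1]; lambda = 1 is the fully coupled (bound) state and
lambda = 0 the decoupled ideal-gas reference, so running a chain at each
value of a schedule and differencing energies yields the per-window work
samples of an alchemical decoupling calculation.

Model choices that keep the reference state exact:

* Only the hydroxyl oxygen (the interaction center the wells act on) is
  confined to the box; the C and H atoms are rigid decorations. At
  lambda = 0 the oxygen is therefore uniform over exactly V_box.
* The coupling is linear, U_lambda = lambda * U_site. Gaussian wells are
  bounded, so there is no endpoint singularity to soften.
* Proposals mix local translations with occasional uniform "box hops"
  (both symmetric), so chains with deep narrow wells still exchange
  between well and bulk. Orientation is proposed jointly by a small
  random-axis rotation; it carries no energy and rides along with the
  translational accept/reject decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .fep import WindowSamples
from .thermo import ThermoState
from .trajectory import Atom, Trajectory

__all__ = [
    "GaussianWell",
    "HBondSitePair",
    "SiteRegion",
    "ToyHostGuest",
    "LambdaSchedule",
    "sample_trajectory",
    "window_work_samples",
]


@dataclass(frozen=True)
class GaussianWell:
    """Isotropic attractive well -depth * exp(-|r-c|^2 / (2 w^2))."""

    center: tuple[float, float, float]
    depth: float  # kcal/mol, >= 0 (attractive)
    width: float  # angstrom, > 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"well depth must be >= 0, got {self.depth}")
        if not (self.width > 0):
            raise ValueError(f"well width must be > 0, got {self.width}")


@dataclass(frozen=True)
class HBondSitePair:
    """Fixed site hydrogen-bond partners: one acceptor atom and one donor.

    The donor's hydrogen is placed 1.0 angstrom from the donor position
    toward the acceptor position, so a ligand oxygen sitting between the
    two can receive a hydrogen bond from the site donor.
    """

    acceptor: tuple[float, float, float]
    donor: tuple[float, float, float]


@dataclass(frozen=True)
class SiteRegion:
    """Flat-bottom spherical region defining 'bound'; sets V_site."""

    center: tuple[float, float, float]
    radius: float  # angstrom

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"site radius must be > 0, got {self.radius}")

    @property
    def volume_A3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3


@dataclass
class ToyHostGuest:
    """Box + Gaussian-well site + optional hydrogen-bond partner geometry.

    Coordinates are Cartesian angstroms; the box is centered on the origin,
    spanning [-L_i/2, L_i/2] along each axis.
    """

    box_lengths: tuple[float, float, float]
    wells: list[GaussianWell]
    site_region: SiteRegion
    hb_sites: list[HBondSitePair] = field(default_factory=list)
    bond_co: float = 1.4  # rigid C-O length, angstrom
    bond_oh: float = 1.0  # rigid O-H length, angstrom
    angle_coh_deg: float = 108.5
    label: str = "toy"

    def __post_init__(self) -> None:
        if any(L <= 0 for L in self.box_lengths):
            raise ValueError("box lengths must be positive")
        half = np.asarray(self.box_lengths) / 2.0
        c = np.asarray(self.site_region.center)
        if np.any(np.abs(c) + self.site_region.radius > half + 1e-9):
            raise ValueError("site_region must lie fully inside the box")
        self._centers = np.array([w.center for w in self.wells], dtype=float).reshape(-1, 3)
        self._depths = np.array([w.depth for w in self.wells], dtype=float)
        self._inv2w2 = np.array([0.5 / w.width**2 for w in self.wells], dtype=float)

    @property
    def box_volume_A3(self) -> float:
        return float(np.prod(self.box_lengths))

    def site_energy(self, r: np.ndarray) -> np.ndarray | float:
        """Fully coupled site potential U_site(r) <= 0, vectorized over r."""
        r = np.asarray(r, dtype=float)
        if len(self.wells) == 0:
            return np.zeros(r.shape[:-1]) if r.ndim > 1 else 0.0
        d2 = ((r[..., None, :] - self._centers) ** 2).sum(axis=-1)
        u = -(self._depths * np.exp(-d2 * self._inv2w2)).sum(axis=-1)
        return float(u) if np.ndim(u) == 0 else u

    def _u_scalar(self, x: float, y: float, z: float) -> float:
        # hot path of the Metropolis loop; plain floats beat numpy here
        u = 0.0
        for (cx, cy, cz), d, a in zip(self._centers, self._depths, self._inv2w2):
            dx, dy, dz = x - cx, y - cy, z - cz
            u -= d * math.exp(-(dx * dx + dy * dy + dz * dz) * a)
        return u

    def ligand_body_frame(self) -> np.ndarray:
        """Rigid body-frame coordinates of (C, O, H), O at the origin."""
        ang = math.radians(self.angle_coh_deg)
        return np.array(
            [
                [self.bond_co * math.cos(ang), self.bond_co * math.sin(ang), 0.0],
                [0.0, 0.0, 0.0],
                [self.bond_oh, 0.0, 0.0],
            ]
        )

    def site_atoms(self) -> tuple[list[Atom], np.ndarray]:
        """Static site atoms (acceptor, donor, donor-H per pair) and coords."""
        atoms: list[Atom] = []
        coords: list[np.ndarray] = []
        for i, pair in enumerate(self.hb_sites):
            a = np.asarray(pair.acceptor, dtype=float)
            d = np.asarray(pair.donor, dtype=float)
            u = a - d
            norm = np.linalg.norm(u)
            if norm < 1e-9:
                raise ValueError("hb site acceptor and donor positions coincide")
            h = d + u / norm * 1.0
            atoms += [
                Atom(id=f"site_A{i}", element="O", role="acceptor", group="site"),
                Atom(id=f"site_D{i}", element="N", role="donor", group="site"),
                Atom(id=f"site_DH{i}", element="H", role="hydrogen", group="site", parent=f"site_D{i}"),
            ]
            coords += [a, d, h]
        return atoms, np.asarray(coords).reshape(-1, 3)


@dataclass(frozen=True)
class LambdaSchedule:
    """Decoupling schedule: coupling values from 1 (bound) to 0 (free)."""

    values: tuple[float, ...]
    samples_per_window: int = 10_000
    equilibration_per_window: int = 1_000

    def __post_init__(self) -> None:
        v = self.values
        if len(v) < 2:
            raise ValueError("schedule needs at least 2 lambda values")
        if v[0] != 1.0 or v[-1] != 0.0:
            raise ValueError("schedule must run from lambda=1 to lambda=0")
        diffs = np.diff(v)
        if not np.all(diffs < 0):
            raise ValueError("schedule must be strictly monotone decreasing")
        if self.samples_per_window < 1 or self.equilibration_per_window < 0:
            raise ValueError("invalid window sample counts")

    @classmethod
    def uniform(
        cls,
        n_windows: int = 24,
        samples_per_window: int = 10_000,
        equilibration_per_window: int = 1_000,
    ) -> "LambdaSchedule":
        vals = tuple(np.linspace(1.0, 0.0, n_windows + 1))
        return cls(vals, samples_per_window, equilibration_per_window)

    @property
    def n_windows(self) -> int:
        return len(self.values) - 1


def _check_steps(step_sizes: tuple[float, float]) -> tuple[float, float]:
    st, sr = step_sizes
    if st <= 0 or sr <= 0:
        raise ValueError(f"step sizes must be positive, got {step_sizes}")
    return float(st), float(sr)


def _run_chain(
    system: ToyHostGuest,
    rt: float,
    lam: float,
    n_record: int,
    *,
    step_t: float,
    step_r: float,
    rng: np.random.Generator,
    r0: np.ndarray,
    q0: np.ndarray,
    equil: int = 0,
    hop_prob: float = 0.25,
    record_orient: bool = False,
) -> dict:
    """Metropolis-Hastings chain on the hydroxyl-O position.

    Two move kinds keep the chain ergodic at any well depth: symmetric
    local translations (a mixture of a coarse and a fine step so both the
    bulk and narrow well interiors are explored), and an independence
    "hop" proposed from a fixed mixture density - uniform over the box
    plus one Gaussian per well - with the exact Hastings ratio, so
    well-bulk exchange stays efficient even when a direct escape is
    thermally forbidden. Returns recorded positions/energies (after
    ``equil`` discarded steps), the acceptance fraction, and the final
    state for warm-starting the next window.
    """
    half = np.asarray(system.box_lengths) / 2.0
    hx, hy, hz = float(half[0]), float(half[1]), float(half[2])
    total = equil + n_record
    n_wells = len(system.wells)
    inv_vbox = 1.0 / system.box_volume_A3
    # hop proposal density q(r) = 0.5 uniform + 0.5 equal-weight well Gaussians
    if n_wells:
        w_sig = np.array([w.width for w in system.wells])
        w_norm = 1.0 / ((2.0 * math.pi) ** 1.5 * w_sig**3 * n_wells)

    def hop_density(px: float, py: float, pz: float) -> float:
        dens = 0.5 * inv_vbox
        if n_wells:
            g = 0.0
            for (cx, cy, cz), s, nn in zip(system._centers, w_sig, w_norm):
                dx, dy, dz = px - cx, py - cy, pz - cz
                g += nn * math.exp(-(dx * dx + dy * dy + dz * dz) / (2.0 * s * s))
            dens += 0.5 * g
        return dens

    hop = rng.random(total) < hop_prob
    hop_from_well = rng.random(total) < (0.5 if n_wells else 0.0)
    well_idx = rng.integers(0, max(n_wells, 1), size=total)
    normals = rng.normal(size=(total, 3))
    scale = np.where(rng.random(total) < 0.5, step_t, step_t / 8.0)
    trans = rng.uniform(-1.0, 1.0, size=(total, 3)) * scale[:, None]
    hops_uniform = rng.uniform(-half, half, size=(total, 3))
    uacc = rng.random(total)
    axes = rng.normal(size=(total, 3))
    angles = rng.uniform(-step_r, step_r, size=total)

    x, y, z = float(r0[0]), float(r0[1]), float(r0[2])
    q = np.asarray(q0, dtype=float).copy()  # (x, y, z, w) scalar-last
    u_cur = system._u_scalar(x, y, z)
    if not math.isfinite(u_cur):
        raise RuntimeError(f"non-finite site energy at start point ({x}, {y}, {z})")

    pos = np.empty((n_record, 3))
    ener = np.empty(n_record)
    quats = np.empty((n_record, 4)) if record_orient else None
    n_accept = 0

    for i in range(total):
        if hop[i]:
            if hop_from_well[i]:
                k = well_idx[i]
                cx, cy, cz = system._centers[k]
                s = w_sig[k]
                px = cx + s * normals[i, 0]
                py = cy + s * normals[i, 1]
                pz = cz + s * normals[i, 2]
            else:
                px, py, pz = hops_uniform[i]
        else:
            px, py, pz = x + trans[i, 0], y + trans[i, 1], z + trans[i, 2]
        accept = False
        if -hx <= px <= hx and -hy <= py <= hy and -hz <= pz <= hz:
            up = system._u_scalar(px, py, pz)
            if not math.isfinite(up):
                raise RuntimeError(f"non-finite site energy at ({px}, {py}, {pz})")
            du = lam * (up - u_cur)
            if hop[i]:
                log_ratio = -du / rt + math.log(
                    hop_density(x, y, z) / hop_density(px, py, pz)
                )
                accept = log_ratio >= 0.0 or uacc[i] < math.exp(log_ratio)
            else:
                accept = du <= 0.0 or uacc[i] < math.exp(-du / rt)
        if accept:
            x, y, z, u_cur = px, py, pz, up
            n_accept += 1
            if record_orient:
                ax, ay, az = axes[i]
                n = math.sqrt(ax * ax + ay * ay + az * az)
                if n > 0:
                    half_ang = 0.5 * angles[i]
                    s = math.sin(half_ang) / n
                    rx, ry, rz, rw = ax * s, ay * s, az * s, math.cos(half_ang)
                    qx, qy, qz, qw = q
                    q = np.array(
                        [
                            rw * qx + rx * qw + ry * qz - rz * qy,
                            rw * qy - rx * qz + ry * qw + rz * qx,
                            rw * qz + rx * qy - ry * qx + rz * qw,
                            rw * qw - rx * qx - ry * qy - rz * qz,
                        ]
                    )
        if i >= equil:
            j = i - equil
            pos[j, 0], pos[j, 1], pos[j, 2] = x, y, z
            ener[j] = u_cur
            if record_orient:
                quats[j] = q

    return {
        "positions": pos,
        "energies": ener,
        "quaternions": quats,
        "acceptance": n_accept / total,
        "final_r": np.array([x, y, z]),
        "final_q": q,
    }


def sample_trajectory(
    system: ToyHostGuest,
    thermo: ThermoState,
    lam: float,
    n_frames: int,
    step_sizes: tuple[float, float] = (2.0, 0.5),
    seed: int = 0,
    equilibration: int = 0,
) -> Trajectory:
    """Sample an equilibrium trajectory at coupling ``lam``.

    Frames are the Metropolis chain states (one per step after the optional
    equilibration discard). Identical (system, lam, seed, n_frames) inputs
    give bit-identical trajectories.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    step_t, step_r = _check_steps(step_sizes)
    rng = np.random.default_rng(seed)

    r0 = np.asarray(system.site_region.center, dtype=float)
    q0 = Rotation.random(rng=rng).as_quat()
    out = _run_chain(
        system,
        thermo.RT,
        lam,
        n_frames,
        step_t=step_t,
        step_r=step_r,
        rng=rng,
        r0=r0,
        q0=q0,
        equil=equilibration,
        record_orient=True,
    )

    body = system.ligand_body_frame()  # (C, O, H) with O at origin
    rots = Rotation.from_quat(out["quaternions"])
    # (n_frames, 3 atoms, 3): rotate body frame, then translate by O position
    lig = np.einsum("nij,aj->nai", rots.as_matrix(), body) + out["positions"][:, None, :]

    lig_atoms = [
        Atom(id="lig_C", element="C", role="other", group="ligand"),
        Atom(id="lig_O", element="O", role="donor", group="ligand"),
        Atom(id="lig_H", element="H", role="hydrogen", group="ligand", parent="lig_O"),
    ]
    site_atoms, site_coords = system.site_atoms()
    if site_atoms:
        site_block = np.broadcast_to(site_coords, (n_frames, *site_coords.shape))
        coords = np.concatenate([lig, site_block], axis=1)
    else:
        coords = lig

    return Trajectory(
        atoms=lig_atoms + site_atoms,
        coords=coords,
        metadata={
            "seed": seed,
            "lambda": lam,
            "system": system.label,
            "step_sizes": [step_t, step_r],
            "acceptance": out["acceptance"],
            "u_site": out["energies"].tolist(),
        },
    )


def window_work_samples(
    system: ToyHostGuest,
    thermo: ThermoState,
    schedule: LambdaSchedule,
    seed: int = 0,
    step_sizes: tuple[float, float] = (2.0, 0.5),
) -> list[WindowSamples]:
    """Per-window energy differences for the decoupling path.

    For each adjacent pair (lam_k -> lam_{k+1}) of the schedule the chain is
    equilibrated and sampled at lam_k (warm-started from the previous
    window), and the forward work samples are
    dU = (lam_{k+1} - lam_k) * U_site evaluated on those states. The same
    pass also records dU evaluated on the lam_{k+1}-side states
    (``delta_u_reverse``), which the free-energy engine uses purely as an
    overlap diagnostic.
    """
    step_t, step_r = _check_steps(step_sizes)
    rng = np.random.default_rng(seed)
    lams = schedule.values

    r = np.asarray(system.site_region.center, dtype=float)
    q = np.array([0.0, 0.0, 0.0, 1.0])
    u_samples: list[np.ndarray] = []
    for lam in lams:
        out = _run_chain(
            system,
            thermo.RT,
            float(lam),
            schedule.samples_per_window,
            step_t=step_t,
            step_r=step_r,
            rng=rng,
            r0=r,
            q0=q,
            equil=schedule.equilibration_per_window,
        )
        u_samples.append(out["energies"])
        r = out["final_r"]

    windows = []
    for k in range(schedule.n_windows):
        dlam = lams[k + 1] - lams[k]
        windows.append(
            WindowSamples(
                lam_from=float(lams[k]),
                lam_to=float(lams[k + 1]),
                delta_u=dlam * u_samples[k],
                delta_u_reverse=dlam * u_samples[k + 1],
            )
        )
    return windows
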