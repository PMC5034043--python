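"""Geometric hydrogen-bond detection and trajectory occupancy.

A donor-H...acceptor triple is counted as bonded when the donor-acceptor
distance is within ``d_cut`` (default 3.3 angstrom) and the deviation
angle is within ``angle_cut`` (default 40 degrees). The default deviation
convention measures the angle at the donor between the D->H and D->A
directions, the criterion used by common trajectory-analysis tools; the
alternative convention (180 degrees minus the D-H...A angle at the
hydrogen) can be selected via the criterion's ``convention`` tag. Ties at
the exact cutoffs count as bonded.

The occupancy statistic P_hb is the fraction of post-burn-in frames in
which the ligand hydroxyl forms at least one hydrogen bond with any site
partner, in either direction (ligand as donor to a site acceptor, or site
donor to the ligand oxygen).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "HBondCriterion",
    "HBondGeometry",
    "OccupancyResult",
    "detect_hbond",
    "frame_bonded",
    "occupancy",
    "classify_site_by_phb",
]

CONVENTIONS = ("hda-at-donor", "dha-supplement")
_EPS = 1e-8


@dataclass(frozen=True)
class HBondCriterion:
    d_cut: float = 3.3  # donor-acceptor distance cutoff, angstrom
    angle_cut: float = 40.0  # deviation-angle cutoff, degrees
    convention: str = "hda-at-donor"

    def __post_init__(self) -> None:
        if not (self.d_cut > 0):
            raise ValueError(f"d_cut must be positive, got {self.d_cut}")
        if not (0 < self.angle_cut <= 180):
            raise ValueError(f"angle_cut must be in (0, 180], got {self.angle_cut}")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}; expected {CONVENTIONS}")


@dataclass(frozen=True)
class HBondGeometry:
    bonded: bool
    d_da: float  # donor-acceptor distance, angstrom
    deviation_deg: float


def _deviation_deg(
    donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray, convention: str
) -> np.ndarray:
    """Deviation angle (degrees), vectorized over leading axes."""
    if convention == "hda-at-donor":
        v1 = hydrogen - donor
        v2 = acceptor - donor
    else:  # dha-supplement: deviation of D-H...A from linearity
        v1 = donor - hydrogen
        v2 = acceptor - hydrogen
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = np.clip((v1 * v2).sum(axis=-1) / (n1 * n2), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    if convention == "dha-supplement":
        ang = 180.0 - ang
    return ang


def detect_hbond(
    donor,
    hydrogen,
    acceptor,
    criterion: HBondCriterion = HBondCriterion(),
) -> HBondGeometry:
    """Test one donor/hydrogen/acceptor geometry against the criterion."""
    d = np.asarray(donor, dtype=float)
    h = np.asarray(hydrogen, dtype=float)
    a = np.asarray(acceptor, dtype=float)
    for p, q, names in ((d, h, "donor/hydrogen"), (d, a, "donor/acceptor"), (h, a, "hydrogen/acceptor")):
        if np.linalg.norm(p - q) < _EPS:
            raise ValueError(f"coincident {names} positions")
    if not (np.isfinite(d).all() and np.isfinite(h).all() and np.isfinite(a).all()):
        raise ValueError("non-finite coordinates")
    d_da = float(np.linalg.norm(a - d))
    dev = float(_deviation_deg(d, h, a, criterion.convention))
    bonded = d_da <= criterion.d_cut and dev <= criterion.angle_cut
    return HBondGeometry(bonded=bonded, d_da=d_da, deviation_deg=dev)


def _candidate_triples(
    traj: Trajectory, ligand_group: str, partner_group: str
) -> list[tuple[int, int, int, str]]:
    """(donor_idx, hydrogen_idx, acceptor_idx, partner_atom_id) triples.

    Directions covered: ligand donor-H to site acceptors, and site donor-H
    to ligand oxygens (ligand atoms with role acceptor or donor - a
    hydroxyl oxygen plays both parts).
    """
    idx = {a.id: i for i, a in enumerate(traj.atoms)}
    lig = [a for a in traj.atoms if a.group == ligand_group]
    site = [a for a in traj.atoms if a.group == partner_group]
    if not site:
        raise ValueError(f"no partner atoms in group {partner_group!r}")
    if not lig:
        raise ValueError(f"no ligand atoms in group {ligand_group!r}")

    def donor_pairs(atoms):
        pairs = []
        for h in atoms:
            if h.role == "hydrogen":
                pairs.append((idx[h.parent], idx[h.id]))
        return pairs

    triples = []
    site_acceptors = [a for a in site if a.role == "acceptor"]
    for d_i, h_i in donor_pairs(lig):
        for acc in site_acceptors:
            triples.append((d_i, h_i, idx[acc.id], acc.id))
    lig_acceptors = [a for a in lig if a.role in ("acceptor", "donor")]
    for d_i, h_i in donor_pairs(site):
        for acc in lig_acceptors:
            triples.append((d_i, h_i, idx[acc.id], traj.atoms[d_i].id))
    return triples


def _bonded_matrix(
    traj: Trajectory,
    criterion: HBondCriterion,
    ligand_group: str,
    partner_group: str,
) -> tuple[np.ndarray, list[str]]:
    """(n_frames, n_triples) bonded mask plus partner id per triple."""
    triples = _candidate_triples(traj, ligand_group, partner_group)
    c = traj.coords
    masks = np.zeros((traj.n_frames, len(triples)), dtype=bool)
    partners = []
    for j, (d_i, h_i, a_i, partner) in enumerate(triples):
        d, h, a = c[:, d_i], c[:, h_i], c[:, a_i]
        d_da = np.linalg.norm(a - d, axis=-1)
        dev = _deviation_deg(d, h, a, criterion.convention)
        masks[:, j] = (d_da <= criterion.d_cut) & (dev <= criterion.angle_cut)
        partners.append(partner)
    return masks, partners


def frame_bonded(
    traj: Trajectory,
    frame: int,
    criterion: HBondCriterion = HBondCriterion(),
    ligand_group: str = "ligand",
    partner_group: str = "site",
) -> bool:
    """True iff any candidate triple in the frame satisfies the criterion."""
    triples = _candidate_triples(traj, ligand_group, partner_group)
    c = traj.coords[frame]
    for d_i, h_i, a_i, _ in triples:
        if detect_hbond(c[d_i], c[h_i], c[a_i], criterion).bonded:
            return True
    return False


@dataclass
class OccupancyResult:
    p_hb: float
    frames_used: int
    frames_excluded: int
    partner_counts: dict[str, int]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_hb <= 1.0):
            raise ValueError(f"P_hb out of [0, 1]: {self.p_hb}")


def occupancy(
    traj: Trajectory,
    criterion: HBondCriterion = HBondCriterion(),
    burn_in_fraction: float = 0.25,
    ligand_group: str = "ligand",
    partner_group: str = "site",
) -> OccupancyResult:
    """Hydrogen-bond probability P_hb with initial burn-in excluded.

    The first floor(burn_in_fraction * n_frames) frames are discarded
    (equilibration transient); P_hb is the fraction of the remaining frames
    with at least one ligand-site hydrogen bond. ``partner_counts`` gives,
    per site partner atom, the number of retained frames bonded through it.
    """
    if not (0.0 <= burn_in_fraction < 1.0):
        raise ValueError(f"burn_in_fraction must be in [0, 1), got {burn_in_fraction}")
    n_excl = int(np.floor(burn_in_fraction * traj.n_frames))
    n_used = traj.n_frames - n_excl
    if n_used < 1:
        raise ValueError("no frames left after burn-in")
    masks, partners = _bonded_matrix(traj, criterion, ligand_group, partner_group)
    masks = masks[n_excl:]
    per_partner: dict[str, int] = {}
    for j, p in enumerate(partners):
        per_partner[p] = per_partner.get(p, 0) + int(masks[:, j].sum())
    return OccupancyResult(
        p_hb=float(masks.any(axis=1).mean()),
        frames_used=n_used,
        frames_excluded=n_excl,
        partner_counts=per_partner,
    )


def classify_site_by_phb(
    p_hb: float, high_threshold: float = 0.8, low_threshold: float = 0.3
) -> str:
    """Bucket a site as 'high' (P_hb > 0.8), 'low' (< 0.3) or 'intermediate'."""
    if not (0.0 <= p_hb <= 1.0):
        raise ValueError(f"P_hb must be in [0, 1], got {p_hb}")
    if p_hb > high_threshold:
        return "high"
    if p_hb < low_threshold:
        return "low"
    return "intermediate"
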