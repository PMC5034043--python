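"""Packaged toy host-guest systems.

Two small validation systems (single-well and three-well) are used for
oracle-equivalence checks of the Monte Carlo / Zwanzig pipeline, and four
engineered "interface" sites mimic the qualitative pattern of a
heteropentameric receptor: two deep wells whose hydrogen-bond partner
geometry is aligned with the bound ligand (high-affinity,
hydrogen-bonding sites) and two shallower wells whose partners sit 5
angstroms off the binding position (low-affinity sites whose polar
partners are engaged elsewhere, as in a hydrated cavity).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .toysim import GaussianWell, HBondSitePair, SiteRegion, ToyHostGuest

__all__ = [
    "single_well_system",
    "three_well_system",
    "demo_interface_system",
    "DEMO_INTERFACES",
    "system_from_yaml",
    "system_to_yaml",
]

_BOX = (20.0, 20.0, 20.0)


def _aligned_hb_pair(center, axis=(0.0, 0.0, 1.0), reach: float = 2.9) -> HBondSitePair:
    """Donor and acceptor diametrically across ``center`` along ``axis``.

    The site donor's hydrogen then points straight at a ligand oxygen
    sitting at the well center, at a donor-acceptor distance of ``reach``.
    """
    c = np.asarray(center, dtype=float)
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    return HBondSitePair(
        acceptor=tuple(float(v) for v in c - reach * u),
        donor=tuple(float(v) for v in c + reach * u),
    )


def single_well_system() -> ToyHostGuest:
    """One moderate Gaussian well; the basic oracle-validation system."""
    return ToyHostGuest(
        box_lengths=_BOX,
        wells=[GaussianWell(center=(0.0, 0.0, 0.0), depth=5.0, width=1.2)],
        site_region=SiteRegion(center=(0.0, 0.0, 0.0), radius=4.0),
        hb_sites=[_aligned_hb_pair((0.0, 0.0, 0.0))],
        label="single-well",
    )


def three_well_system() -> ToyHostGuest:
    """Three separated wells of unequal depth; multi-minimum validation."""
    return ToyHostGuest(
        box_lengths=_BOX,
        wells=[
            GaussianWell(center=(-4.0, -3.0, 0.0), depth=4.0, width=1.0),
            GaussianWell(center=(4.0, 2.0, 1.0), depth=3.0, width=1.2),
            GaussianWell(center=(0.0, 4.0, -3.0), depth=2.0, width=1.5),
        ],
        site_region=SiteRegion(center=(0.0, 0.0, 0.0), radius=5.0),
        label="three-well",
    )


#: Engineered demo interfaces: depth (kcal/mol) and whether the
#: hydrogen-bond partner pair is aligned with the well (True) or offset
#: 5 angstroms away (False). Deeper well = tighter binding by design.
DEMO_INTERFACES: dict[str, tuple[float, bool]] = {
    "alpha+/beta-": (16.0, True),
    "beta+/alpha-": (14.0, True),
    "alpha+/gamma-": (11.0, False),
    "gamma+/beta-": (10.0, False),
}


def demo_interface_system(name: str) -> ToyHostGuest:
    """Build one engineered interface site by name."""
    try:
        depth, aligned = DEMO_INTERFACES[name]
    except KeyError:
        raise KeyError(f"unknown demo interface {name!r}; choose from {list(DEMO_INTERFACES)}")
    center = (0.0, 0.0, 0.0)
    if aligned:
        pair = _aligned_hb_pair(center)
    else:
        pair = _aligned_hb_pair((0.0, 5.0, 0.0))
    return ToyHostGuest(
        box_lengths=_BOX,
        wells=[GaussianWell(center=center, depth=depth, width=0.8)],
        site_region=SiteRegion(center=center, radius=4.0),
        hb_sites=[pair],
        label=name,
    )


def system_from_yaml(path: str | Path) -> ToyHostGuest:
    cfg = yaml.safe_load(Path(path).read_text())
    return ToyHostGuest(
        box_lengths=tuple(cfg["box_lengths"]),
        wells=[
            GaussianWell(tuple(w["center"]), float(w["depth"]), float(w["width"]))
            for w in cfg.get("wells", [])
        ],
        site_region=SiteRegion(
            tuple(cfg["site_region"]["center"]), float(cfg["site_region"]["radius"])
        ),
        hb_sites=[
            HBondSitePair(tuple(h["acceptor"]), tuple(h["donor"]))
            for h in cfg.get("hb_sites", [])
        ],
        label=str(cfg.get("label", "toy")),
    )


def system_to_yaml(system: ToyHostGuest, path: str | Path) -> None:
    cfg = {
        "label": system.label,
        "box_lengths": [float(v) for v in system.box_lengths],
        "wells": [
            {"center": [float(v) for v in w.center], "depth": float(w.depth), "width": float(w.width)}
            for w in system.wells
        ],
        "site_region": {
            "center": [float(v) for v in system.site_region.center],
            "radius": float(system.site_region.radius),
        },
        "hb_sites": [
            {"acceptor": [float(v) for v in h.acceptor], "donor": [float(v) for v in h.donor]} for h in system.hb_sites
        ],
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
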