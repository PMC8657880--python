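"""Backbone-library prefilter: buriedness runs, terminal distance, compactness.

A library member survives iff (1) its longest run of buried residues — buried
meaning main-chain solvent accessibility below 5 A^2 with a 3.0 A probe — is
at most 3 ("less than 4"), and (2) its N/C-terminal CA atoms lie closer than
12 A (a rough TM5-TM6 gap).  Survivors are then ranked by radius of gyration
and the most compact fraction kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import biotite.structure as struc
import numpy as np

from .geometry import radius_of_gyration
from .model import ATOM_NAMES, BackboneModel
from .report import ScreenReport

#: van der Waals radii (A) used for main-chain SASA.
VDW_RADII = {"N": 1.55, "C": 1.70, "O": 1.52}


@dataclass
class FilterConfig:
    probe_radius: float = 3.0
    buried_asa_cutoff: float = 5.0
    max_buried_run: int = 3
    terminal_distance_cutoff: float = 12.0
    rg_keep_fraction: float = 1.0
    n_sphere_points: int = 960

    def __post_init__(self) -> None:
        if min(self.probe_radius, self.buried_asa_cutoff, self.terminal_distance_cutoff) <= 0:
            raise ValueError("cutoffs must be positive")
        if not 0 < self.rg_keep_fraction <= 1:
            raise ValueError("rg_keep_fraction must be in (0, 1]")
        if self.max_buried_run < 0:
            raise ValueError("max_buried_run must be >= 0")


def atom_sasa(
    coords: np.ndarray,
    elements: list[str],
    probe_radius: float = 3.0,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Shrake-Rupley numeric SASA per atom, in A^2.

    Sphere-sampled accessibility with element radii N 1.55 / C 1.70 /
    O 1.52 A; n_sphere_points controls the sampling density.
    """
    if n_sphere_points < 100:
        raise ValueError("n_sphere_points must be >= 100")
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords.astype(np.float32)
    arr.chain_id[:] = "A"
    arr.res_id = np.arange(1, n + 1)
    arr.res_name[:] = "GLY"
    arr.atom_name = np.asarray(elements)
    arr.element = np.asarray(elements)
    arr.hetero[:] = False
    radii = np.array([VDW_RADII[e] for e in elements], dtype=np.float32)
    out = struc.sasa(arr, probe_radius=probe_radius, point_number=n_sphere_points, vdw_radii=radii)
    return np.asarray(out, dtype=float)


def residue_sasa(
    model: BackboneModel,
    probe_radius: float = 3.0,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-residue main-chain solvent accessibility, in A^2.

    Atom-level Shrake-Rupley SASA summed over each residue's N/CA/C/O atoms.
    """
    L = len(model)
    elements = ["N", "C", "C", "O"] * L
    per_atom = atom_sasa(model.atoms_flat(), elements, probe_radius, n_sphere_points)
    return per_atom.reshape(L, 4).sum(axis=1)


def buried_mask(asa: np.ndarray | list[float], cutoff: float = 5.0) -> list[bool]:
    """Strict less-than: a residue is buried iff its ASA < cutoff."""
    return [bool(a < cutoff) for a in np.asarray(asa, dtype=float)]


def max_consecutive_true(mask: list[bool]) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def terminal_ca_distance(model: BackboneModel) -> float:
    """Euclidean distance between the CA atoms of residues 1 and L."""
    if len(model) < 2:
        raise ValueError("need at least 2 residues")
    return float(np.linalg.norm(model.ca[0] - model.ca[-1]))


def prefilter_library(
    models: list[BackboneModel], cfg: FilterConfig | None = None
) -> tuple[list[BackboneModel], ScreenReport]:
    """Apply the three library restrictions; returns survivors and a report.

    The buried-run and terminal-distance clauses are hard gates; the radius
    of gyration clause keeps the ceil(rg_keep_fraction * n) most compact
    survivors.
    """
    cfg = cfg or FilterConfig()
    report = ScreenReport()
    report.meta.update(
        probe_radius=cfg.probe_radius,
        vdw_radii=",".join(f"{k}:{v}" for k, v in sorted(VDW_RADII.items())),
    )
    survivors: list[tuple[float, BackboneModel]] = []
    for m in models:
        asa = residue_sasa(m, cfg.probe_radius, cfg.n_sphere_points)
        run = max_consecutive_true(buried_mask(asa, cfg.buried_asa_cutoff))
        dist = terminal_ca_distance(m)
        reasons = []
        if run > cfg.max_buried_run:
            reasons.append("buried_run")
        if not dist < cfg.terminal_distance_cutoff:
            reasons.append("terminal_distance")
        if reasons:
            report.add(m.label, "prefilter", False, reason=",".join(reasons))
        else:
            survivors.append((radius_of_gyration(m), m))
    survivors.sort(key=lambda t: (t[0], t[1].label))
    n_keep = ceil(cfg.rg_keep_fraction * len(survivors)) if survivors else 0
    kept = [m for _, m in survivors[:n_keep]]
    kept_labels = {m.label for m in kept}
    for rg, m in survivors:
        ok = m.label in kept_labels
        report.add(m.label, "prefilter", ok, reason="" if ok else "radius_of_gyration", score=rg)
    return kept, report
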