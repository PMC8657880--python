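"""Per-position amino-acid constraints for sequence design.

The sequence-design engine itself (Rosetta-style flexible-backbone design)
is external; this module prepares its input restrictions and audits its
output.  Positions are layered by main-chain buriedness (core / boundary /
surface) and then pruned by helix- and torsion-specific rules: no cysteine
(disulfide risk) or histidine (protonation ambiguity) anywhere, glycine
fixed at positive-phi (ABEGO 'G') positions and at helix termini, no
serine/threonine inside helices (helix benders), and no lysine/arginine in
the first three residues of a helix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import abego_string
from .model import BackboneModel

CORE_SET = set("AFILMVWY")
SURFACE_SET = set("DEKNQRST")
BOUNDARY_SET = CORE_SET | SURFACE_SET

DEFAULT_CORE_CUT = 10.0
DEFAULT_SURF_CUT = 40.0
#: SASA probe for layer assignment (water-sized, unlike the 3.0 A burial probe).
LAYER_PROBE_RADIUS = 1.4


@dataclass
class PositionConstraint:
    index: int
    layer: str
    allowed: set[str]
    reasons: list[str] = field(default_factory=list)


@dataclass
class DesignConstraintSet:
    positions: list[PositionConstraint]

    def __post_init__(self) -> None:
        for p in self.positions:
            if not p.allowed:
                raise ValueError(f"position {p.index}: no allowed residues after rules {p.reasons}")

    def allowed_at(self, index: int) -> set[str]:
        return self.positions[index - 1].allowed


def assign_layers(
    model: BackboneModel,
    asa: np.ndarray,
    core_cut: float = DEFAULT_CORE_CUT,
    surf_cut: float = DEFAULT_SURF_CUT,
) -> list[str]:
    """core if ASA < core_cut, surface if ASA > surf_cut, else boundary."""
    out = []
    for a in np.asarray(asa, dtype=float):
        if a < core_cut:
            out.append("core")
        elif a > surf_cut:
            out.append("surface")
        else:
            out.append("boundary")
    return out


def _helix_position_flags(L: int, helices: list[tuple[int, int]]):
    in_helix = np.zeros(L, dtype=bool)
    terminal = np.zeros(L, dtype=bool)
    first_three = np.zeros(L, dtype=bool)
    for s, e in helices:
        in_helix[s - 1 : e] = True
        terminal[s - 1] = True
        terminal[e - 1] = True
        first_three[s - 1 : min(s + 2, e)] = True
    return in_helix, terminal, first_three


def allowed_residues(
    model: BackboneModel,
    layers: list[str],
    abego: str | None = None,
    helices: list[tuple[int, int]] | None = None,
) -> DesignConstraintSet:
    """Compose the layer base sets with the pruning rules, tracking reasons.

    The glycine-fixing rules (ABEGO 'G' positions, helix termini) override
    the layer sets entirely; all other rules only remove residue types.
    """
    L = len(model)
    abego = abego if abego is not None else abego_string(model)
    helices = helices if helices is not None else model.helices
    if len(layers) != L or len(abego) != L:
        raise ValueError("layers/abego length mismatch with model")
    in_helix, terminal, first_three = _helix_position_flags(L, helices)
    base = {"core": CORE_SET, "surface": SURFACE_SET, "boundary": BOUNDARY_SET}
    positions = []
    for i in range(L):
        allowed = set(base[layers[i]])
        reasons = [f"layer_{layers[i]}"]
        for aa, rule in (("C", "no_cys"), ("H", "no_his")):
            if aa in allowed:
                allowed.discard(aa)
            reasons.append(rule)
        if in_helix[i] and not terminal[i] and allowed & {"S", "T"}:
            allowed -= {"S", "T"}
            reasons.append("no_ser_thr_midhelix")
        if first_three[i] and allowed & {"K", "R"}:
            allowed -= {"K", "R"}
            reasons.append("no_lys_arg_helix_start")
        if abego[i] == "G":
            allowed = {"G"}
            reasons.append("abego_G_gly")
        if terminal[i]:
            allowed = {"G"}
            reasons.append("helix_terminal_gly")
        positions.append(PositionConstraint(index=i + 1, layer=layers[i], allowed=allowed, reasons=sorted(set(reasons))))
    return DesignConstraintSet(positions)


def abego_pattern_changed(designed: BackboneModel, reference: BackboneModel) -> bool:
    """True iff the backbone torsion pattern differs anywhere from the reference."""
    if len(designed) != len(reference):
        raise ValueError("models differ in length")
    return abego_string(designed) != abego_string(reference)


def write_constraints(cs: DesignConstraintSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "index": [p.index for p in cs.positions],
            "layer": [p.layer for p in cs.positions],
            "allowed": ["".join(sorted(p.allowed)) for p in cs.positions],
            "reasons": [",".join(sorted(p.reasons)) for p in cs.positions],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_constraints(path: str | Path) -> DesignConstraintSet:
    df = pd.read_csv(path, sep="\t", dtype={"allowed": str, "reasons": str})
    positions = [
        PositionConstraint(
            index=int(r["index"]),
            layer=str(r["layer"]),
            allowed=set(str(r["allowed"])),
            reasons=str(r["reasons"]).split(","),
        )
        for _, r in df.iterrows()
    ]
    return DesignConstraintSet(positions)
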