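"""Chimera assembly and post-design exclusion gates.

The matched design replaces the receptor's third intracellular loop: the
chain runs receptor N-part up to the end of the matched TM5 window, then the
design between its matched terminal windows, then the receptor from the
matched TM6 window onward.  Before assembly a placed design is discarded if
any of its CA atoms comes within 5.5 A of a receptor CA (outside the
junction regions) or if any of its atoms lies inside the membrane slab.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import RigidTransform, transform_model
from .model import BackboneModel, FusionMatch, MembraneSlab, ReceptorScaffold
from .report import ScreenReport


def place_design(design: BackboneModel, match: FusionMatch) -> BackboneModel:
    """Move a design into the receptor frame with its match transform."""
    return transform_model(design, RigidTransform(match.rotation, match.translation))


def ca_clash_count(
    placed: BackboneModel,
    receptor: ReceptorScaffold,
    match: FusionMatch,
    cutoff: float = 5.5,
    junction_margin: int = 1,
    width: int = 3,
) -> int:
    """CA pairs closer than cutoff (strict <) between placed design and receptor.

    Excluded from counting: design residues at or beyond the matched terminal
    windows (the tails removed by splicing) and receptor residues of the
    replaced segment between the matched TM5/TM6 windows, each widened by
    junction_margin residues.
    """
    L_d, L_r = len(placed), len(receptor.model)
    d_excl = np.zeros(L_d, dtype=bool)
    d_excl[: match.n_start + width - 1 + junction_margin] = True  # 1..n_start+2 (+margin)
    d_excl[max(0, match.c_start - 1 - junction_margin):] = True  # c_start..L (+margin)
    r_excl = np.zeros(L_r, dtype=bool)
    lo = max(0, match.tm5_start - 1 - junction_margin)
    hi = min(L_r, match.tm6_start + width - 1 + junction_margin)
    r_excl[lo:hi] = True  # tm5 window .. tm6 window (+margin)
    d_ca = placed.ca[~d_excl]
    r_ca = receptor.model.ca[~r_excl]
    if len(d_ca) == 0 or len(r_ca) == 0:
        return 0
    return int((cdist(d_ca, r_ca) < cutoff).sum())


def membrane_overlap(placed: BackboneModel, slab: MembraneSlab) -> bool:
    """True iff any main-chain atom lies in z_min <= z <= z_max (closed slab)."""
    z = placed.atoms_flat()[:, 2]
    return bool(((z >= slab.z_min) & (z <= slab.z_max)).any())


@dataclass
class ChimeraResult:
    model: BackboneModel
    sequence: str
    junction_table: list[tuple[str, int, int]]  # (source, old index, new index)


def splice_chimera(
    receptor: ReceptorScaffold,
    design: BackboneModel,
    match: FusionMatch,
    width: int = 3,
) -> ChimeraResult:
    """Fuse design into the receptor ICL3 at the matched windows.

    Chimera = receptor 1..tm5_start+2 + design n_start+3..c_start-1 (placed
    by the match transform) + receptor tm6_start..end, renumbered 1..L with a
    junction table recording old -> new indices.  Receptor coordinates win at
    the junctions.
    """
    placed = place_design(design, match)
    r5_end = match.tm5_start + width - 1
    d_lo = match.n_start + width
    d_hi = match.c_start - 1
    if d_lo > d_hi:
        raise ValueError("empty design segment between matched windows")
    if r5_end >= match.tm6_start:
        raise ValueError("receptor segments overlap: tm5 window end after tm6 window start")
    parts = [
        ("receptor", range(1, r5_end + 1), receptor.model),
        ("design", range(d_lo, d_hi + 1), placed),
        ("receptor", range(match.tm6_start, len(receptor.model) + 1), receptor.model),
    ]
    coords, seq, table = [], [], []
    new = 0
    for source, idx_range, src in parts:
        for old in idx_range:
            new += 1
            coords.append(src.coords[old - 1])
            seq.append(src.sequence[old - 1])
            table.append((source, old, new))
    model = BackboneModel(
        coords=np.array(coords),
        sequence="".join(seq),
        helices=[],
        label=f"{receptor.model.label}-{design.label}",
    )
    return ChimeraResult(model=model, sequence=model.sequence, junction_table=table)


def assembly_gate(
    candidates: list[tuple[BackboneModel, FusionMatch]],
    receptor: ReceptorScaffold,
    clash_cutoff: float = 5.5,
    junction_margin: int = 1,
) -> tuple[list[tuple[BackboneModel, FusionMatch]], ScreenReport]:
    """Discard placed designs that clash with the receptor or enter the membrane."""
    report = ScreenReport()
    kept = []
    for design, match in candidates:
        placed = place_design(design, match)
        clashes = ca_clash_count(placed, receptor, match, clash_cutoff, junction_margin)
        in_slab = membrane_overlap(placed, receptor.slab)
        reasons = []
        if clashes > 0:
            reasons.append("clash")
        if in_slab:
            reasons.append("membrane")
        ok = not reasons
        report.add(design.label, "assembly_gate", ok, reason=",".join(reasons), clash_count=clashes)
        if ok:
            kept.append((design, match))
    return kept, report
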