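"""Sliding-window fusibility screen against receptor TM5/TM6.

Every pair of 3-residue windows in a design's N- and C-terminal helices is
jointly superposed — one rigid transform fitting both windows at once — onto
every pair of 3-residue windows on the cytoplasmic ends of TM5 and TM6.  A
design is fusible when its best main-chain RMSD over all window-pair
combinations is at or below the gate (0.65 A for backbone screening, 0.4 A
after sequence design).  The joint fit is what pins the TM5-TM6 relative
geometry, and hence the receptor state, to the fusion partner.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .geometry import kabsch, kabsch_rmsd_batch
from .model import BackboneModel, FusionMatch, ReceptorScaffold
from .report import ScreenReport

WINDOW_WIDTH = 3

#: Default cytoplasmic-side search ranges (1-based, inclusive): design
#: N-terminal residues 2-11, design C-terminal last 11 residues, receptor
#: TM5 204-211 and TM6 219-229.
DEFAULT_N_RANGE = (2, 11)
DEFAULT_TM5_RANGE = (204, 211)
DEFAULT_TM6_RANGE = (219, 229)


@dataclass
class WindowRanges:
    n_range: tuple[int, int]
    c_range: tuple[int, int]
    tm5_range: tuple[int, int]
    tm6_range: tuple[int, int]
    width: int = WINDOW_WIDTH

    def __post_init__(self) -> None:
        for name in ("n_range", "c_range", "tm5_range", "tm6_range"):
            lo, hi = getattr(self, name)
            if hi - lo + 1 < self.width:
                raise ValueError(f"{name} [{lo},{hi}] narrower than window width {self.width}")

    @classmethod
    def defaults(cls, design_length: int, receptor: ReceptorScaffold | None = None) -> "WindowRanges":
        """Protocol-default ranges: N 2-11, C last-11, TM windows from the receptor."""
        tm5 = receptor.tm5_range if receptor else DEFAULT_TM5_RANGE
        tm6 = receptor.tm6_range if receptor else DEFAULT_TM6_RANGE
        return cls(
            n_range=DEFAULT_N_RANGE,
            c_range=(design_length - 10, design_length),
            tm5_range=tm5,
            tm6_range=tm6,
        )

    def starts(self, name: str) -> list[int]:
        lo, hi = getattr(self, name)
        return list(range(lo, hi - self.width + 2))


def enumerate_window_pairs(ranges: WindowRanges) -> list[tuple[int, int, int, int]]:
    """All (n_start, c_start, tm5_start, tm6_start) combinations, lexicographic."""
    return list(
        itertools.product(
            ranges.starts("n_range"),
            ranges.starts("c_range"),
            ranges.starts("tm5_range"),
            ranges.starts("tm6_range"),
        )
    )


def _pair_atoms(model: BackboneModel, start_a: int, start_b: int, width: int) -> np.ndarray:
    """Joint main-chain atom block of two windows: (2 * width * 4, 3)."""
    return np.concatenate([model.window_atoms(start_a, width), model.window_atoms(start_b, width)])


def best_fusion_match(
    design: BackboneModel,
    receptor: ReceptorScaffold,
    ranges: WindowRanges | None = None,
) -> FusionMatch:
    """Exhaustive window-pair search; returns the minimum-RMSD combination.

    Ties break to the first combination in lexicographic enumeration order.
    """
    ranges = ranges or WindowRanges.defaults(len(design), receptor)
    combos = enumerate_window_pairs(ranges)
    w = ranges.width
    design_pairs = {
        (ns, cs): _pair_atoms(design, ns, cs, w)
        for ns in ranges.starts("n_range")
        for cs in ranges.starts("c_range")
    }
    receptor_pairs = {
        (t5, t6): _pair_atoms(receptor.model, t5, t6, w)
        for t5 in ranges.starts("tm5_range")
        for t6 in ranges.starts("tm6_range")
    }
    mobile = np.stack([design_pairs[(ns, cs)] for ns, cs, _, _ in combos])
    target = np.stack([receptor_pairs[(t5, t6)] for _, _, t5, t6 in combos])
    rmsds = kabsch_rmsd_batch(mobile, target)
    best = int(np.argmin(rmsds))
    ns, cs, t5, t6 = combos[best]
    transform, rmsd = kabsch(design_pairs[(ns, cs)], receptor_pairs[(t5, t6)])
    return FusionMatch(
        n_start=ns,
        c_start=cs,
        tm5_start=t5,
        tm6_start=t6,
        rotation=transform.rotation,
        translation=transform.translation,
        rmsd=rmsd,
    )


def screen_fusibility(
    models: list[BackboneModel],
    receptor: ReceptorScaffold,
    ranges: WindowRanges | None = None,
    rmsd_cutoff: float = 0.65,
    stage: str = "fusion_screen",
) -> tuple[list[tuple[BackboneModel, FusionMatch]], ScreenReport]:
    """Keep designs whose best window-pair RMSD is <= rmsd_cutoff (inclusive gate)."""
    report = ScreenReport()
    kept: list[tuple[BackboneModel, FusionMatch]] = []
    for m in models:
        match = best_fusion_match(m, receptor, ranges)
        ok = match.rmsd <= rmsd_cutoff
        report.add(m.label, stage, ok, reason="" if ok else "rmsd_gate", rmsd=match.rmsd)
        if ok:
            kept.append((m, match))
    return kept, report
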