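"""Fragment-based local sequence-structure compatibility score.

For every 9-residue frame of a design, a set of reference 9-residue backbone
fragments (nominally 200, picked externally for the frame's sequence) is
superposed onto the local structure; the frame's quality is the fraction of
fragments within 1.5 A main-chain RMSD.  The design's score is the sum over
frames of the natural log of that fraction (with a small pseudocount so
zero-pass frames stay finite): 0 is perfect, more negative is worse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import kabsch_rmsd_batch
from .model import BackboneModel

FRAME_WIDTH = 9
DEFAULT_RMSD_CUTOFF = 1.5
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class FragmentSet:
    """Reference fragments for one frame: (M, 36, 3) main-chain coordinates."""

    frame_start: int
    fragments: np.ndarray

    def __post_init__(self) -> None:
        self.fragments = np.asarray(self.fragments, dtype=float)
        if self.fragments.ndim != 3 or self.fragments.shape[1:] != (FRAME_WIDTH * 4, 3):
            raise ValueError(f"fragments must be (M, {FRAME_WIDTH * 4}, 3)")
        if len(self.fragments) == 0:
            raise ValueError("empty fragment set")


def frames(model: BackboneModel, width: int = FRAME_WIDTH) -> list[int]:
    """1-based start indices of all width-residue frames: 1..L-width+1."""
    L = len(model)
    if L < width:
        raise ValueError(f"model of length {L} has no {width}-residue frame")
    return list(range(1, L - width + 2))


def frame_pass_count(
    frame_coords: np.ndarray, fs: FragmentSet, cutoff: float = DEFAULT_RMSD_CUTOFF
) -> int:
    """Fragments whose post-superposition main-chain RMSD is strictly < cutoff."""
    frame_coords = np.asarray(frame_coords, dtype=float)
    if frame_coords.shape != fs.fragments.shape[1:]:
        raise ValueError("frame/fragment shape mismatch")
    target = np.broadcast_to(frame_coords, fs.fragments.shape)
    rmsds = kabsch_rmsd_batch(fs.fragments, target)
    return int((rmsds < cutoff).sum())


def compatibility_score(
    model: BackboneModel,
    fragment_sets: list[FragmentSet],
    cutoff: float = DEFAULT_RMSD_CUTOFF,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    width: int = FRAME_WIDTH,
) -> tuple[float, list[float]]:
    """Sum of per-frame log pass-ratios; returns (total, per-frame terms).

    Requires exactly one FragmentSet per frame, matched on frame_start.
    """
    starts = frames(model, width)
    by_start = {fs.frame_start: fs for fs in fragment_sets}
    missing = [s for s in starts if s not in by_start]
    if missing:
        raise ValueError(f"missing fragment sets for frame starts {missing[:5]}")
    terms = []
    for s in starts:
        fs = by_start[s]
        n_pass = frame_pass_count(model.window_atoms(s, width), fs, cutoff)
        n_total = len(fs.fragments)
        terms.append(float(np.log((n_pass + pseudocount) / (n_total + pseudocount))))
    return float(sum(terms)), terms


def rank_designs(scores: dict[str, float], top_k: int | None = None) -> list[str]:
    """Labels ordered by descending score; ties resolve lexicographically."""
    ordered = sorted(scores, key=lambda k: (-scores[k], k))
    return ordered if top_k is None else ordered[:top_k]
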