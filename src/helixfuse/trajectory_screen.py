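"""Trajectory-based terminal-helix fluctuation screen.

For every snapshot of a molecular-dynamics trajectory of a design, the
matched 3-residue terminal windows (fixed at the positions found by the
fusibility screen, not re-searched per snapshot) are jointly superposed onto
the receptor TM5/TM6 windows and the main-chain RMSD recorded.  A design
whose trajectory-average RMSD exceeds 0.75 A is discarded: its termini
fluctuate too much to pin the receptor state.
"""

from __future__ import annotations

import numpy as np

from .fusion_screen import WINDOW_WIDTH, _pair_atoms
from .geometry import kabsch
from .model import BackboneModel, FusionMatch, ReceptorScaffold
from .report import ScreenReport

DEFAULT_MEAN_RMSD_THRESHOLD = 0.75


def per_frame_rmsd(
    traj: list[BackboneModel],
    receptor: ReceptorScaffold,
    match: FusionMatch,
    width: int = WINDOW_WIDTH,
) -> np.ndarray:
    """Joint window-pair RMSD of each snapshot against the receptor windows.

    The first element is the initial-frame RMSD.
    """
    if not traj:
        raise ValueError("empty trajectory")
    target = _pair_atoms(receptor.model, match.tm5_start, match.tm6_start, width)
    out = np.empty(len(traj))
    for i, snap in enumerate(traj):
        mobile = _pair_atoms(snap, match.n_start, match.c_start, width)
        _, out[i] = kabsch(mobile, target)
    return out


def fluctuation_gate(
    series: np.ndarray, threshold: float = DEFAULT_MEAN_RMSD_THRESHOLD
) -> tuple[float, bool]:
    """(mean RMSD, discard flag); discard iff mean > threshold (strict)."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty RMSD series")
    mean = float(series.mean())
    return mean, mean > threshold


def screen_trajectories(
    candidates: list[tuple[BackboneModel, FusionMatch, list[BackboneModel]]],
    receptor: ReceptorScaffold,
    threshold: float = DEFAULT_MEAN_RMSD_THRESHOLD,
) -> tuple[list[BackboneModel], ScreenReport]:
    """Apply the fluctuation gate to (design, match, trajectory) triples."""
    report = ScreenReport()
    kept = []
    for design, match, traj in candidates:
        series = per_frame_rmsd(traj, receptor, match)
        mean, discard = fluctuation_gate(series, threshold)
        report.add(design.label, "mdscreen", not discard, reason="fluctuation" if discard else "", mean_traj_rmsd=mean)
        if not discard:
            kept.append(design)
    return kept, report
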