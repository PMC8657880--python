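"""Stage orchestration of the screening funnel.

The funnel mirrors the design protocol: library prefilter, terminal-helix
elongation, fusibility screen at 0.65 A, design-constraint export (the
external sequence-design hook), post-design screen at 0.4 A, chimera
assembly with clash/membrane gates, fragment compatibility ranking, and the
trajectory fluctuation screen.  Stages are composable; each returns its
survivors and a ScreenReport, and the pipeline is deterministic given
(config, seed, inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import chimera as chi
from . import design_rules as dr
from . import elongation as elo
from . import fragment_score as fsc
from . import fusion_screen as fus
from . import library_filter as lf
from . import trajectory_screen as ts
from .config import PipelineConfig
from .model import BackboneModel, FusionMatch, ReceptorScaffold
from .report import ScreenReport

STAGES = (
    "prefilter",
    "elongate",
    "screen",
    "constraints",
    "screen_post",
    "assemble",
    "fragscore",
    "mdscreen",
)


@dataclass
class PipelineState:
    """Inputs plus accumulated per-stage outputs."""

    models: list[BackboneModel]
    receptor: ReceptorScaffold | None = None
    config: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0
    matches: dict[str, FusionMatch] = field(default_factory=dict)
    chimeras: dict[str, chi.ChimeraResult] = field(default_factory=dict)
    constraints: dict[str, dr.DesignConstraintSet] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)
    fragment_sets: dict[str, list[fsc.FragmentSet]] = field(default_factory=dict)
    trajectories: dict[str, list[BackboneModel]] = field(default_factory=dict)
    report: ScreenReport = field(default_factory=ScreenReport)


def _window_ranges(state: PipelineState) -> fus.WindowRanges:
    cfg = state.config
    L = len(state.models[0]) if state.models else 0
    return fus.WindowRanges(
        n_range=tuple(cfg.n_range),
        c_range=(L - 10, L),
        tm5_range=tuple(cfg.tm5_range),
        tm6_range=tuple(cfg.tm6_range),
    )


def run_stage(stage: str, state: PipelineState) -> PipelineState:
    """Run one named stage in place; unknown names raise with the valid list."""
    cfg = state.config
    if stage == "prefilter":
        fcfg = lf.FilterConfig(
            probe_radius=cfg.probe_radius,
            buried_asa_cutoff=cfg.buried_asa_cutoff,
            max_buried_run=cfg.max_buried_run,
            terminal_distance_cutoff=cfg.terminal_distance_cutoff,
            rg_keep_fraction=cfg.rg_keep_fraction,
            n_sphere_points=cfg.n_sphere_points,
        )
        state.models, rep = lf.prefilter_library(state.models, fcfg)
    elif stage == "elongate":
        ecfg = elo.ElongationConfig(
            n_extra=cfg.n_extra,
            n_trials=cfg.n_trials,
            dihedral_noise_sd=cfg.dihedral_noise_sd,
            clash_ca_cutoff=cfg.clash_ca_cutoff,
            clash_seq_sep=cfg.clash_seq_sep,
            seed=state.seed,
        )
        state.models, rep = elo.elongate_library(state.models, ecfg)
    elif stage in ("screen", "screen_post"):
        cutoff = cfg.screen_rmsd_cutoff if stage == "screen" else cfg.post_design_rmsd_cutoff
        kept, rep = fus.screen_fusibility(
            state.models, state.receptor, _window_ranges(state), cutoff, stage=stage
        )
        state.models = [m for m, _ in kept]
        state.matches.update({m.label: match for m, match in kept})
    elif stage == "constraints":
        rep = ScreenReport()
        for m in state.models:
            asa = lf.residue_sasa(m, dr.LAYER_PROBE_RADIUS, cfg.n_sphere_points)
            layers = dr.assign_layers(m, asa, cfg.core_asa_cutoff, cfg.surface_asa_cutoff)
            state.constraints[m.label] = dr.allowed_residues(m, layers)
            rep.add(m.label, "constraints", True)
    elif stage == "assemble":
        pairs = [(m, state.matches[m.label]) for m in state.models]
        kept, rep = chi.assembly_gate(
            pairs, state.receptor, cfg.receptor_clash_cutoff, cfg.junction_margin
        )
        state.models = [m for m, _ in kept]
        for m, match in kept:
            state.chimeras[m.label] = chi.splice_chimera(state.receptor, m, match)
    elif stage == "fragscore":
        rep = ScreenReport()
        for m in state.models:
            if m.label not in state.fragment_sets:
                raise ValueError(f"no fragment sets provided for {m.label}")
            total, _ = fsc.compatibility_score(
                m, state.fragment_sets[m.label], cfg.fragment_rmsd_cutoff, cfg.fragment_pseudocount
            )
            state.scores[m.label] = total
            rep.add(m.label, "fragscore", True, score=total)
        order = fsc.rank_designs(state.scores)
        state.models.sort(key=lambda m: order.index(m.label))
    elif stage == "mdscreen":
        triples = [
            (m, state.matches[m.label], state.trajectories[m.label]) for m in state.models
        ]
        kept, rep = ts.screen_trajectories(triples, state.receptor, cfg.mean_traj_rmsd_threshold)
        kept_labels = {m.label for m in kept}
        state.models = [m for m in state.models if m.label in kept_labels]
    else:
        raise ValueError(f"unknown stage {stage!r}; valid stages: {', '.join(STAGES)}")
    state.report.extend(rep)
    return state


def run_pipeline(state: PipelineState, stages: tuple[str, ...] = STAGES) -> PipelineState:
    """Run stages in order, skipping ones whose external inputs are absent.

    The fragment-score and trajectory stages consume externally produced
    inputs (fragment sets, MD snapshots); when none are attached to the
    state, those stages are recorded as skipped rather than failing.
    """
    for stage in stages:
        if stage == "fragscore" and not state.fragment_sets:
            continue
        if stage == "mdscreen" and not state.trajectories:
            continue
        if stage in ("screen", "screen_post", "assemble", "mdscreen") and state.receptor is None:
            raise ValueError(f"stage {stage!r} needs a receptor scaffold")
        run_stage(stage, state)
    return state


def write_reports(state: PipelineState, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state.report.to_tsv(out / "report.tsv")
    state.report.to_json(out / "report.json")
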