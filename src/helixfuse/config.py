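"""YAML configuration with published-protocol defaults for every threshold."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable thresholds of the screening funnel (Angstrom unless noted).

    Defaults are the published protocol values: 3.0 A SASA probe, 5.0 A^2
    burial cutoff, buried runs < 4, terminal distance < 12.0 A, 7 appended
    residues per terminus over 100 trials, 0.65 / 0.4 A fusibility gates,
    5.5 A CA clash distance, 1.5 A fragment RMSD cutoff, 0.75 A mean
    trajectory RMSD gate, and search ranges N 2-11 / TM5 204-211 /
    TM6 219-229.
    """

    probe_radius: float = 3.0
    buried_asa_cutoff: float = 5.0
    max_buried_run: int = 3
    terminal_distance_cutoff: float = 12.0
    rg_keep_fraction: float = 1.0
    n_sphere_points: int = 960
    n_extra: int = 7
    n_trials: int = 100
    dihedral_noise_sd: float = 3.0
    clash_ca_cutoff: float = 4.0
    clash_seq_sep: int = 5
    screen_rmsd_cutoff: float = 0.65
    post_design_rmsd_cutoff: float = 0.4
    receptor_clash_cutoff: float = 5.5
    junction_margin: int = 1
    fragment_rmsd_cutoff: float = 1.5
    fragment_pseudocount: float = 0.5
    mean_traj_rmsd_threshold: float = 0.75
    core_asa_cutoff: float = 10.0
    surface_asa_cutoff: float = 40.0
    n_range: list[int] = field(default_factory=lambda: [2, 11])
    tm5_range: list[int] = field(default_factory=lambda: [204, 211])
    tm6_range: list[int] = field(default_factory=lambda: [219, 229])

    def __post_init__(self) -> None:
        positive = [
            "probe_radius", "buried_asa_cutoff", "terminal_distance_cutoff",
            "screen_rmsd_cutoff", "post_design_rmsd_cutoff", "receptor_clash_cutoff",
            "fragment_rmsd_cutoff", "mean_traj_rmsd_threshold", "clash_ca_cutoff",
            "core_asa_cutoff", "surface_asa_cutoff",
        ]
        errors = [f"{k} must be positive (got {getattr(self, k)})" for k in positive if getattr(self, k) <= 0]
        if not 0 < self.rg_keep_fraction <= 1:
            errors.append(f"rg_keep_fraction must be in (0, 1] (got {self.rg_keep_fraction})")
        if self.n_extra < 0 or self.n_trials < 1:
            errors.append("n_extra must be >= 0 and n_trials >= 1")
        for name in ("n_range", "tm5_range", "tm6_range"):
            pair = getattr(self, name)
            if len(pair) != 2 or pair[1] - pair[0] + 1 < 3:
                errors.append(f"{name} must be an inclusive pair spanning >= 3 residues")
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; absent keys take defaults, unknown keys are rejected."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root in {path} must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; valid keys: {sorted(known)}")
    return PipelineConfig(**data)
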