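"""Terminal-helix elongation: seven ideal helical residues per terminus.

Each candidate's terminal helices are prolonged by internal-coordinate
chaining with alpha-helical torsions.  The construction is attempted many
times (default 100) with small Gaussian torsion noise; a trial succeeds if
the elongated backbone is free of internal CA clashes, and the candidate
advances only when every trial succeeds, carrying the ensemble-averaged
structure forward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import geometry as geom
from .model import BackboneModel
from .report import ScreenReport


@dataclass
class ElongationConfig:
    n_extra: int = 7
    n_trials: int = 100
    dihedral_noise_sd: float = 3.0
    clash_ca_cutoff: float = 4.0
    clash_seq_sep: int = 5
    seed: int = 0
    min_success: int | None = None  # None: all trials must succeed

    def __post_init__(self) -> None:
        if self.n_extra < 0 or self.n_trials < 1 or self.dihedral_noise_sd < 0:
            raise ValueError("invalid elongation configuration")


@dataclass
class ElongationResult:
    model: BackboneModel | None
    n_success: int
    n_trials: int

    @property
    def ok(self) -> bool:
        return self.model is not None


def _terminal_helix(model: BackboneModel, side: str) -> tuple[int, int]:
    for start, end in model.helices:
        if side == "N" and start == 1 and end - start + 1 >= 4:
            return start, end
        if side == "C" and end == len(model) and end - start + 1 >= 4:
            return start, end
    raise ValueError(f"{side}-terminus is not part of a helix of >= 4 residues")


def _as_array(x, n: int) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()
    return arr


def extend_terminus(
    model: BackboneModel,
    side: str,
    n_extra: int,
    phi=geom.HELIX_PHI,
    psi=geom.HELIX_PSI,
    omega=geom.HELIX_OMEGA,
) -> BackboneModel:
    """Append n_extra residues beyond one terminus with the given torsions.

    phi/psi/omega may be scalars or per-appended-residue arrays.  Existing
    atoms are never moved; on the N side the old residues shift up in number
    by n_extra.  The extension continues the terminal helix axis when the
    torsions are helical.
    """
    if side not in ("N", "C"):
        raise ValueError("side must be 'N' or 'C'")
    if n_extra == 0:
        return model.copy()
    _terminal_helix(model, side)
    phi = _as_array(phi, n_extra)
    psi = _as_array(psi, n_extra)
    omega = _as_array(omega, n_extra)
    L = len(model)
    X = model.coords

    if side == "C":
        n0, ca0, c0 = X[L - 1, 0], X[L - 1, 1], X[L - 1, 2]
        # torsions[k] = (psi of the residue preceding new residue k, omega,
        # phi of new residue k); psi[0] stands in for the old terminal
        # residue's psi so the extension prolongs the helix axis.
        torsions = [(psi[k], omega[k], phi[k]) for k in range(n_extra)]
        triples = geom._chain_forward(n0, ca0, c0, torsions)
        new = np.empty((n_extra, 4, 3))
        for k, (n, ca, c) in enumerate(triples):
            new[k, 0], new[k, 1], new[k, 2] = n, ca, c
            o_psi = psi[k + 1] if k + 1 < n_extra else psi[-1]
            new[k, 3] = geom.carbonyl_oxygen(n, ca, c, o_psi)
        coords = np.concatenate([X, new], axis=0)
        helices = [list(h) for h in model.helices]
        helices[-1][1] = L + n_extra
        seq = model.sequence + "X" * n_extra
    else:
        # chain backwards: place C(i-1), CA(i-1), N(i-1) from residue i
        new = np.empty((n_extra, 4, 3))
        n1, ca1, c1 = X[0, 0], X[0, 1], X[0, 2]
        for k in range(n_extra):
            c_prev = geom.place_atom(c1, ca1, n1, geom.BOND_C_N, geom.ANGLE_C_N_CA, phi[k])
            ca_prev = geom.place_atom(ca1, n1, c_prev, geom.BOND_CA_C, geom.ANGLE_CA_C_N, omega[k])
            n_prev = geom.place_atom(n1, c_prev, ca_prev, geom.BOND_N_CA, geom.ANGLE_N_CA_C, psi[k])
            o_prev = geom.carbonyl_oxygen(n_prev, ca_prev, c_prev, psi[k])
            slot = n_extra - 1 - k
            new[slot] = [n_prev, ca_prev, c_prev, o_prev]
            n1, ca1, c1 = n_prev, ca_prev, c_prev
        coords = np.concatenate([new, X], axis=0)
        helices = [[s + n_extra, e + n_extra] for s, e in model.helices]
        helices[0][0] = 1
        seq = "X" * n_extra + model.sequence
    return BackboneModel(
        coords=coords,
        sequence=seq,
        helices=[tuple(h) for h in helices],
        label=model.label,
    )


def internal_clash(model: BackboneModel, ca_cutoff: float = 4.0, seq_sep: int = 5) -> bool:
    """True iff any CA pair at sequence separation >= seq_sep is closer than ca_cutoff."""
    L = len(model)
    if L < seq_sep + 1:
        return False
    d = squareform(pdist(model.ca))
    i, j = np.triu_indices(L, k=seq_sep)
    return bool((d[i, j] < ca_cutoff).any())


def elongate_ensemble(model: BackboneModel, cfg: ElongationConfig) -> ElongationResult:
    """Stochastic elongation ensemble with a strict all-trials success gate.

    Each trial perturbs the appended torsions with zero-mean Gaussian noise
    (seeded, reproducible) and extends both termini; a trial succeeds iff the
    result has no internal CA clash.  The averaged structure is returned only
    when the required number of trials (default: all) succeed.
    """
    rng = np.random.default_rng(cfg.seed)
    required = cfg.n_trials if cfg.min_success is None else cfg.min_success
    successes: list[BackboneModel] = []
    for _ in range(cfg.n_trials):
        noise = rng.normal(0.0, cfg.dihedral_noise_sd, size=(2, 3, cfg.n_extra)) if cfg.dihedral_noise_sd > 0 else np.zeros((2, 3, cfg.n_extra))
        trial = extend_terminus(
            model, "N", cfg.n_extra,
            phi=geom.HELIX_PHI + noise[0, 0], psi=geom.HELIX_PSI + noise[0, 1], omega=geom.HELIX_OMEGA + noise[0, 2],
        )
        trial = extend_terminus(
            trial, "C", cfg.n_extra,
            phi=geom.HELIX_PHI + noise[1, 0], psi=geom.HELIX_PSI + noise[1, 1], omega=geom.HELIX_OMEGA + noise[1, 2],
        )
        if not internal_clash(trial, cfg.clash_ca_cutoff, cfg.clash_seq_sep):
            successes.append(trial)
    if len(successes) < required:
        return ElongationResult(None, len(successes), cfg.n_trials)
    return ElongationResult(geom.average_models(successes), len(successes), cfg.n_trials)


def elongate_library(
    models: list[BackboneModel], cfg: ElongationConfig
) -> tuple[list[BackboneModel], ScreenReport]:
    """Elongate every candidate; keep those whose ensembles fully succeed."""
    report = ScreenReport()
    kept = []
    for i, m in enumerate(models):
        res = elongate_ensemble(m, ElongationConfig(**{**cfg.__dict__, "seed": cfg.seed + i}))
        if res.ok:
            out = res.model.copy(label=m.label)
            kept.append(out)
            report.add(m.label, "elongate", True, score=float(res.n_success))
        else:
            report.add(m.label, "elongate", False, reason=f"clashes:{cfg.n_trials - res.n_success}", score=float(res.n_success))
    return kept, report
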