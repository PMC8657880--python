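"""Seeded synthetic inputs for every pipeline stage.

These generators stand in for the real inputs — an all-alpha backbone
library, a membrane-embedded receptor structure, externally picked fragment
sets, MD trajectories — with constructions whose ground truth is known and
verified at generation time: helix bundles with controllable terminal
geometry, a mock two-helix TM5/TM6 scaffold whose fusion windows are planted
copies of a chosen design window pair, libraries with known fusible/
non-fusible labels, and fragment sets with controlled pass fractions.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .fragment_score import FRAME_WIDTH, FragmentSet, frame_pass_count, frames
from .fusion_screen import WindowRanges, best_fusion_match
from .geometry import RigidTransform, ideal_helix, kabsch, transform_model
from .model import BackboneModel, MembraneSlab, ReceptorScaffold


def random_transform(rng: np.random.Generator, translation_scale: float = 30.0) -> RigidTransform:
    q = rng.normal(size=4)
    R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    t = rng.uniform(-translation_scale, translation_scale, size=3)
    return RigidTransform(R, t)


def _canonical_helix(n: int) -> BackboneModel:
    """Ideal helix with its exact axis on +z through the origin, CA(1) at z = 0.

    The axis is the screw axis of the residue-to-residue rigid motion, which
    for an ideal helix is exact (independent of end effects).
    """
    h = ideal_helix(max(n, 4))
    step, _ = kabsch(h.coords[:-1].reshape(-1, 3), h.coords[1:].reshape(-1, 3))
    rotvec = Rotation.from_matrix(step.rotation).as_rotvec()
    axis = rotvec / np.linalg.norm(rotvec)
    t_perp = step.translation - (axis @ step.translation) * axis
    # point on the axis: (I - R) p = t_perp, solved in the plane normal to axis
    p = np.linalg.pinv(np.eye(3) - step.rotation) @ t_perp
    rot, _ = Rotation.align_vectors(np.array([[0.0, 0.0, 1.0]]), axis[None, :])
    out = transform_model(h, RigidTransform(rot.as_matrix(), -rot.as_matrix() @ p))
    if len(out) != n:
        out.coords = out.coords[:n]
        out = BackboneModel(out.coords, "X" * n, [(1, n)], out.label)
    rise = out.ca[-1][2] - out.ca[0][2]
    if rise < 0:  # orient N -> C along +z
        out.coords = (out.atoms_flat() @ np.diag([1.0, -1.0, -1.0]).T).reshape(out.coords.shape)
    out.coords[:, :, 2] -= out.ca[0][2]
    return out


def _loop_residues(start: np.ndarray, end: np.ndarray, n: int, template: np.ndarray) -> np.ndarray:
    """n residues with valid internal geometry strung along the start->end line."""
    out = np.empty((n, 4, 3))
    for k in range(n):
        f = (k + 1) / (n + 1)
        center = start + f * (end - start)
        out[k] = template - template[1] + center
    return out


def make_bundle(
    n_helices: int = 6,
    helix_len: int = 18,
    loop_len: int = 3,
    spacing: float = 11.0,
    seed: int = 0,
    terminal_splay_deg: float = 8.0,
) -> BackboneModel:
    """Antiparallel helix bundle on a ring, serpentine-connected.

    Helices alternate up/down around a circle whose adjacent-helix chord is
    `spacing`, so with an even helix count the chain's first and last
    residues end up on adjacent ring positions at the same height — the
    terminal CA distance is close to `spacing` minus two helix radii.  The
    two terminal helices are tilted outward by `terminal_splay_deg` about
    their terminal CA so that elongations of the termini diverge instead of
    converging.  Total length is n_helices*helix_len + (n_helices-1)*loop_len.
    """
    if n_helices < 2:
        raise ValueError("need at least 2 helices")
    rng = np.random.default_rng(seed)
    base = _canonical_helix(helix_len)
    template = base.coords[helix_len // 2].copy()
    ring_r = spacing / (2.0 * np.sin(np.pi / n_helices))
    z_top = base.ca[-1][2]
    centers = [
        np.array([ring_r * np.cos(2.0 * np.pi * k / n_helices), ring_r * np.sin(2.0 * np.pi * k / n_helices), 0.0])
        for k in range(n_helices)
    ]
    segments: list[np.ndarray] = []
    helices: list[tuple[int, int]] = []
    pos = 0
    prev_end_ca: np.ndarray | None = None
    for k in range(n_helices):
        center = centers[k]
        down = k % 2 == 1
        h = base.copy()
        # phase about the helix axis: random for interior helices, aimed for
        # the chain termini so the terminal CA atoms face each other
        if k == 0:
            want = centers[-1] - centers[0]
            have = h.ca[0]
            phase_deg = np.degrees(np.arctan2(want[1], want[0]) - np.arctan2(have[1], have[0]))
        elif k == n_helices - 1:
            want = centers[0] - centers[-1]
            have = h.ca[-1].copy()
            if down:
                have[1] = -have[1]
            delta = np.degrees(np.arctan2(want[1], want[0]) - np.arctan2(have[1], have[0]))
            phase_deg = -delta if down else delta
        else:
            phase_deg = rng.uniform(0, 360)
        phase = Rotation.from_euler("z", phase_deg, degrees=True).as_matrix()
        h.coords = (h.atoms_flat() @ phase.T).reshape(helix_len, 4, 3)
        if down:
            flip = np.diag([1.0, -1.0, -1.0])
            h.coords = (h.atoms_flat() @ flip.T).reshape(helix_len, 4, 3)
            h.coords[:, :, 2] += z_top
        h.coords[:, :, 0] += center[0]
        h.coords[:, :, 1] += center[1]
        if terminal_splay_deg > 0 and k in (0, n_helices - 1):
            other = centers[-1] if k == 0 else centers[0]
            d = center - other
            d /= np.linalg.norm(d)
            pivot = h.ca.mean(axis=0)
            tilt_axis = np.cross([0.0, 0.0, 1.0], d)
            tilt_axis /= np.linalg.norm(tilt_axis)
            down = np.array([0.0, 0.0, -1.0])  # both terminal ends point down
            best = None
            for sign in (1.0, -1.0):
                R = Rotation.from_rotvec(np.radians(sign * terminal_splay_deg) * tilt_axis).as_matrix()
                score = (R @ down) @ d
                if best is None or score > best[0]:
                    best = (score, R)
            R = best[1]
            h.coords = ((h.atoms_flat() - pivot) @ R.T + pivot).reshape(helix_len, 4, 3)
        if prev_end_ca is not None and loop_len > 0:
            loop = _loop_residues(prev_end_ca, h.ca[0], loop_len, template)
            segments.append(loop)
            pos += loop_len
        segments.append(h.coords)
        helices.append((pos + 1, pos + helix_len))
        pos += helix_len
        prev_end_ca = h.ca[-1]
    coords = np.concatenate(segments, axis=0)
    return BackboneModel(
        coords=coords,
        sequence="X" * len(coords),
        helices=helices,
        label=f"bundle_s{seed}",
    )


@dataclass
class MockReceptor:
    """A planted TM5/TM6 scaffold plus the ground truth used to build it."""

    scaffold: ReceptorScaffold
    ranges: WindowRanges
    truth: dict[str, int]  # n_start, c_start, tm5_start, tm6_start
    transform: RigidTransform
    template: BackboneModel


def make_mock_receptor(
    design: BackboneModel,
    ranges: WindowRanges | None = None,
    perturb_sd: float = 0.0,
    slab_margin: float = 15.0,
    slab_thickness: float = 30.0,
    seed: int = 0,
) -> MockReceptor:
    """Two-helix receptor stand-in whose fusion windows copy a design window pair.

    One window pair of `design` (chosen from `ranges`, recorded as ground
    truth) is rigidly moved into the receptor frame and becomes the TM5/TM6
    windows; surrounding TM residues are displaced away from the design so
    no other window combination matches.  With perturb_sd = 0 the planted
    combination superposes exactly (RMSD 0); with large perturb_sd the
    receptor is a verified negative control (best RMSD > 0.65 A).  The
    membrane slab is placed `slab_margin` above the placed design.
    """
    ranges = ranges or WindowRanges.defaults(len(design))
    rng = np.random.default_rng(seed)
    truth = {
        "n_start": int(rng.choice(ranges.starts("n_range"))),
        "c_start": int(rng.choice(ranges.starts("c_range"))),
        "tm5_start": int(rng.choice(ranges.starts("tm5_range"))),
        "tm6_start": int(rng.choice(ranges.starts("tm6_range"))),
    }
    T = random_transform(rng)
    placed = transform_model(design, T)
    w = ranges.width
    L_r = ranges.tm6_range[1] + 1
    coords = np.empty((L_r, 4, 3))
    template = ideal_helix(1).coords[0]
    for i in range(L_r):  # far-away filler chain
        coords[i] = template - template[1] + np.array([800.0 + 5.0 * i, 0.0, 0.0])
    design_centroid = placed.atoms_flat().mean(axis=0)

    for _ in range(60):
        test = coords.copy()
        for tm_range, tm_truth, d_truth in (
            (ranges.tm5_range, truth["tm5_start"], truth["n_start"]),
            (ranges.tm6_range, truth["tm6_start"], truth["c_start"]),
        ):
            window = placed.coords[d_truth - 1 : d_truth - 1 + w]
            centroid = window.reshape(-1, 3).mean(axis=0)
            away = centroid - design_centroid
            away /= max(np.linalg.norm(away), 1e-9)
            for i in range(tm_range[0], tm_range[1] + 1):
                off = i - tm_truth
                if 0 <= off < w:
                    test[i - 1] = window[off]
                    if perturb_sd > 0:
                        test[i - 1] = test[i - 1] + rng.normal(0, perturb_sd, size=(4, 3))
                else:
                    test[i - 1] = window[abs(off) % w] + away * (20.0 + 6.0 * abs(off))
        model = BackboneModel(
            coords=test,
            sequence="X" * L_r,
            helices=[tuple(ranges.tm5_range), tuple(ranges.tm6_range)],
            label=f"mock_receptor_s{seed}",
        )
        z = placed.atoms_flat()[:, 2].max() + slab_margin
        scaffold = ReceptorScaffold(
            model=model,
            tm5_range=tuple(ranges.tm5_range),
            tm6_range=tuple(ranges.tm6_range),
            slab=MembraneSlab(z_min=float(z), z_max=float(z + slab_thickness)),
        )
        match = best_fusion_match(design, scaffold, ranges)
        if perturb_sd == 0:
            starts = (match.n_start, match.c_start, match.tm5_start, match.tm6_start)
            expect = (truth["n_start"], truth["c_start"], truth["tm5_start"], truth["tm6_start"])
            if starts == expect and match.rmsd < 1e-9:
                break
        elif match.rmsd > 0.65:
            break
    else:
        raise RuntimeError("could not realize the requested receptor planting")
    return MockReceptor(scaffold=scaffold, ranges=ranges, truth=truth, transform=T, template=design.copy())


def _twist_n_segment(m, n_seg: int, rng: np.random.Generator) -> None:
    """Rigidly twist the first n_seg residues about their centroid in place.

    Residue-internal geometry stays valid while the joint N/C window-pair
    geometry breaks.
    """
    angle = rng.uniform(35.0, 80.0)
    axis = rng.normal(size=3)
    R = Rotation.from_rotvec(np.radians(angle) * axis / np.linalg.norm(axis)).as_matrix()
    seg = m.coords[:n_seg].reshape(-1, 3)
    c = seg.mean(axis=0)
    m.coords[:n_seg] = ((seg - c) @ R.T + c).reshape(n_seg, 4, 3)


def make_library(
    n_models: int,
    fraction_fusible: float,
    seed: int,
    receptor: MockReceptor,
    perturb_sd: float = 0.0,
    cutoff: float = 0.65,
    template: BackboneModel | None = None,
    verify: bool = True,
) -> tuple[list[BackboneModel], dict[str, bool]]:
    """Library of planted fusible positives and verified non-fusible negatives.

    Positives are rigid copies of the template design (optionally with small
    coordinate noise, re-verified to stay under the gate); negatives have
    their N-terminal segment rigidly twisted so the joint window-pair
    geometry no longer matches (re-verified above the gate).  Returns the
    shuffled models and a label -> is-fusible truth table.  With a custom
    `template` (e.g. the pre-elongation backbone when the receptor was
    planted on the elongated one) set verify=False, since the planted
    windows only exist after elongation.
    """
    if not 0.0 <= fraction_fusible <= 1.0:
        raise ValueError("fraction_fusible must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pos = round(fraction_fusible * n_models)
    template = template if template is not None else receptor.template
    n_seg = min(receptor.ranges.n_range[1] + receptor.ranges.width, len(template) // 2)
    models: list[BackboneModel] = []
    truth: dict[str, bool] = {}
    for i in range(n_models):
        positive = i < n_pos
        label = f"lib{i:03d}"
        for attempt in range(60):
            m = transform_model(template, random_transform(rng))
            if positive:
                if perturb_sd > 0:
                    m.coords = m.coords + rng.normal(0, perturb_sd, m.coords.shape)
            else:
                _twist_n_segment(m, n_seg, rng)
            m.label = label
            if not verify:
                break
            rmsd = best_fusion_match(m, receptor.scaffold, receptor.ranges).rmsd
            if (positive and rmsd <= cutoff) or (not positive and rmsd > cutoff):
                break
        else:
            raise RuntimeError(f"could not plant {'positive' if positive else 'negative'} {label}")
        models.append(m)
        truth[label] = positive
    order = rng.permutation(n_models)
    models = [models[i] for i in order]
    return models, truth


@dataclass
class ScreenDataset:
    """Full-funnel synthetic dataset: raw library plus a receptor planted on
    the elongated template, with ground-truth fusibility labels."""

    library: list[BackboneModel]
    truth: dict[str, bool]
    receptor: MockReceptor
    template: BackboneModel
    elongated_template: BackboneModel


def make_screen_dataset(
    n_models: int = 8,
    fraction_fusible: float = 0.5,
    seed: int = 0,
    helix_len: int = 18,
    loop_len: int = 3,
) -> ScreenDataset:
    """Dataset for end-to-end funnel runs.

    The receptor's fusion windows are planted on the *elongated* template,
    matching the protocol order (elongate first, then screen the terminal
    windows), while the library contains pre-elongation models: positives
    are rigid copies of the template, negatives carry a twisted N-terminal
    segment.
    """
    from .elongation import ElongationConfig, elongate_ensemble

    template = make_bundle(helix_len=helix_len, loop_len=loop_len, seed=seed)
    res = elongate_ensemble(template, ElongationConfig(seed=seed))
    if not res.ok:
        raise RuntimeError("template elongation failed")
    elongated = res.model.copy(label=template.label + "_elong")
    receptor = make_mock_receptor(elongated, seed=seed + 1)
    library, truth = make_library(
        n_models, fraction_fusible, seed + 2, receptor, template=template, verify=False
    )
    return ScreenDataset(
        library=library,
        truth=truth,
        receptor=receptor,
        template=template,
        elongated_template=elongated,
    )


def make_trajectory(
    model: BackboneModel, noise_sd: float, n_frames: int, seed: int
) -> list[BackboneModel]:
    """Snapshots = model plus i.i.d. per-atom Gaussian noise (an MD stand-in)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_frames):
        snap = model.copy(label=f"{model.label}#f{i}")
        if noise_sd > 0:
            snap.coords = snap.coords + rng.normal(0, noise_sd, snap.coords.shape)
        out.append(snap)
    return out


def make_fragment_sets(
    model: BackboneModel,
    n_frag: int = 200,
    pass_fraction: float = 1.0,
    pass_noise_sd: float = 0.3,
    fail_offset: float = 4.0,
    seed: int = 0,
    cutoff: float = 1.5,
) -> list[FragmentSet]:
    """Per-frame fragment sets with a controlled pass fraction.

    Each frame gets floor(pass_fraction * n_frag) fragments within the RMSD
    cutoff of the local structure (small noise on a rigid copy, verified and
    resampled on violation) and the remainder distorted beyond it (verified
    likewise).
    """
    if not 0.0 <= pass_fraction <= 1.0:
        raise ValueError("pass_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pass = int(np.floor(pass_fraction * n_frag))
    sets = []
    for s in frames(model):
        frame = model.window_atoms(s, FRAME_WIDTH)
        frags = np.empty((n_frag, FRAME_WIDTH * 4, 3))
        for j in range(n_frag):
            want_pass = j < n_pass
            for attempt in range(50):
                cand = random_transform(rng).apply(frame)
                if want_pass:
                    if pass_noise_sd > 0:
                        cand = cand + rng.normal(0, pass_noise_sd, cand.shape)
                else:
                    signs = np.where(np.arange(len(cand)) % 2 == 0, 1.0, -1.0)
                    cand = cand + np.outer(signs, [fail_offset, 0.0, 0.0])
                _, rmsd = kabsch(cand, frame)
                if (want_pass and rmsd < cutoff) or (not want_pass and rmsd >= cutoff):
                    break
            else:
                raise RuntimeError("could not realize fragment with requested pass status")
            frags[j] = cand
        fs = FragmentSet(frame_start=s, fragments=frags)
        assert frame_pass_count(frame, fs, cutoff) == n_pass
        sets.append(fs)
    return sets
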