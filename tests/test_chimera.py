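"""Chimera splicing and the clash/membrane exclusion gates."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from helixfuse.chimera import (
    assembly_gate,
    ca_clash_count,
    membrane_overlap,
    place_design,
    splice_chimera,
)
from helixfuse.fixtures import random_transform
from helixfuse.fusion_screen import best_fusion_match
from helixfuse.geometry import ideal_helix, transform_model
from helixfuse.model import MembraneSlab


@pytest.fixture(scope="module")
def match(bundle, receptor):
    return best_fusion_match(bundle, receptor.scaffold, receptor.ranges)


@pytest.fixture()
def placed(bundle, match):
    return place_design(bundle, match)


class TestTransform:
    def test_identity(self, bundle):
        from helixfuse.geometry import RigidTransform

        out = transform_model(bundle, RigidTransform.identity())
        assert np.allclose(out.coords, bundle.coords)

    def test_inverse_round_trip(self, bundle, rng):
        t = random_transform(rng)
        out = transform_model(transform_model(bundle, t), t.inverse())
        assert np.abs(out.coords - bundle.coords).max() < 1e-9

    def test_isometry(self, bundle, rng):
        t = random_transform(rng)
        out = transform_model(bundle, t)
        d0 = np.linalg.norm(bundle.ca[0] - bundle.ca[-1])
        d1 = np.linalg.norm(out.ca[0] - out.ca[-1])
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestClashCount:
    def test_distant_design_has_no_clash(self, bundle, receptor, match):
        far = bundle.copy()
        far.coords = far.coords + 1000.0
        assert ca_clash_count(far, receptor.scaffold, match) == 0

    def test_single_planted_contact_below_cutoff(self, placed, receptor, match):
        assert ca_clash_count(placed, receptor.scaffold, match) == 0
        # plant one non-excluded design CA 5.4 A from a non-excluded receptor CA
        mod = placed.copy()
        mid = (match.n_start + 3 + match.c_start - 2) // 2
        # offset perpendicular to the receptor chain so only one CA is near
        mod.coords[mid - 1, 1] = receptor.scaffold.model.ca[10] + np.array([0.0, 5.4, 0.0])
        assert ca_clash_count(mod, receptor.scaffold, match) == 1
        # exactly at the cutoff: strict less-than means no clash
        mod.coords[mid - 1, 1] = receptor.scaffold.model.ca[10] + np.array([0.0, 5.5, 0.0])
        assert ca_clash_count(mod, receptor.scaffold, match) == 0

    def test_brute_force_oracle(self, bundle, receptor, match, rng):
        w, margin = 3, 1
        L_r = len(receptor.scaffold.model)
        d_excluded = set(range(1, match.n_start + w + margin)) | set(
            range(match.c_start - margin, len(bundle) + 1)
        )
        r_excluded = set(range(match.tm5_start - margin, match.tm6_start + w + margin))
        for _ in range(5):
            moved = transform_model(bundle, random_transform(rng))
            moved.coords = moved.coords + rng.normal(0, 50.0, size=3)
            expected = 0
            for i in range(1, len(moved) + 1):
                if i in d_excluded:
                    continue
                for j in range(1, L_r + 1):
                    if j in r_excluded:
                        continue
                    d = np.linalg.norm(moved.ca[i - 1] - receptor.scaffold.model.ca[j - 1])
                    if d < 5.5:
                        expected += 1
            assert ca_clash_count(moved, receptor.scaffold, match) == expected


class TestMembrane:
    def test_below_slab(self):
        h = ideal_helix(5)
        zmin = h.coords[..., 2].max() + 1.0
        assert membrane_overlap(h, MembraneSlab(zmin, zmin + 30)) is False

    def test_boundary_atom_counts_as_inside(self):
        h = ideal_helix(5)
        zmax = float(h.coords[..., 2].max())
        assert membrane_overlap(h, MembraneSlab(zmax, zmax + 30)) is True

    def test_planted_design_below_mock_slab(self, placed, receptor):
        assert membrane_overlap(placed, receptor.scaffold.slab) is False


class TestSplice:
    def test_length_arithmetic_from_window_starts(self, bundle, receptor, match):
        ch = splice_chimera(receptor.scaffold, bundle, match)
        n_part = match.tm5_start + 2
        mid = (match.c_start - 1) - (match.n_start + 3) + 1
        c_part = len(receptor.scaffold.model) - match.tm6_start + 1
        assert len(ch.model) == n_part + mid + c_part
        assert len(ch.sequence) == len(ch.model)

    def test_junction_bonds_continuous_for_exact_planting(self, bundle, receptor, match):
        ch = splice_chimera(receptor.scaffold, bundle, match)
        # boundaries: receptor->design and design->receptor
        sources = [row[0] for row in ch.junction_table]
        for k in range(len(sources) - 1):
            if sources[k] != sources[k + 1]:
                c = ch.model.coords[k, 2]
                n = ch.model.coords[k + 1, 0]
                assert np.linalg.norm(c - n) < 2.0

    def test_receptor_coordinates_bit_identical_outside_replacement(self, bundle, receptor, match):
        ch = splice_chimera(receptor.scaffold, bundle, match)
        for src, old, new in ch.junction_table:
            if src == "receptor":
                assert np.array_equal(
                    ch.model.coords[new - 1], receptor.scaffold.model.coords[old - 1]
                )

    def test_empty_design_segment_rejected(self, bundle, receptor, match):
        from dataclasses import replace

        bad = replace(match, c_start=match.n_start + 3)
        with pytest.raises(ValueError, match="empty design segment"):
            splice_chimera(receptor.scaffold, bundle, bad)


class TestGate:
    def test_planted_positive_kept(self, bundle, receptor, match):
        kept, report = assembly_gate([(bundle, match)], receptor.scaffold)
        assert len(kept) == 1
        assert report.records[0]["passed"] is True

    def test_clashing_candidate_discarded_with_reason(self, bundle, receptor, match):
        bad = bundle.copy(label="clasher")
        mid = (match.n_start + 3 + match.c_start - 2) // 2
        # place a mid-segment CA right on a receptor CA after the match transform
        from helixfuse.geometry import RigidTransform

        t = RigidTransform(match.rotation, match.translation).inverse()
        target = receptor.scaffold.model.ca[10] + np.array([1.0, 0.0, 0.0])
        bad.coords[mid - 1, 1] = t.apply(target[None, :])[0]
        kept, report = assembly_gate([(bad, match)], receptor.scaffold)
        assert kept == []
        assert "clash" in report.records[0]["reason"]

    def test_membrane_violator_discarded_with_reason(self, bundle, receptor, match):
        bad = bundle.copy(label="floater")
        from helixfuse.geometry import RigidTransform

        t = RigidTransform(match.rotation, match.translation).inverse()
        z_mid = (receptor.scaffold.slab.z_min + receptor.scaffold.slab.z_max) / 2
        mid = (match.n_start + 3 + match.c_start - 2) // 2
        bad.coords[mid - 1, 1] = t.apply(np.array([[0.0, 0.0, z_mid]]))[0]
        kept, report = assembly_gate([(bad, match)], receptor.scaffold)
        assert kept == []
        assert "membrane" in report.records[0]["reason"]

    def test_raising_cutoff_never_grows_kept_set(self, bundle, receptor, match, rng):
        candidates = []
        for i in range(6):
            m = bundle.copy(label=f"c{i}")
            m.coords = m.coords + rng.normal(0, 0.5, m.coords.shape)
            candidates.append((m, match))
        loose, _ = assembly_gate(candidates, receptor.scaffold, clash_cutoff=5.5)
        tight, _ = assembly_gate(candidates, receptor.scaffold, clash_cutoff=8.0)
        assert {m.label for m, _ in tight} <= {m.label for m, _ in loose}
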