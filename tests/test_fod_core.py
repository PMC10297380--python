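"""T/O/R profiles, divergence entropy, RD and exclusion re-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_cloud, random_rotation
from fodm.fod_core import (
    fit_gaussian_field,
    kl_divergence,
    levitt_weight,
    observed_profile,
    read_profiles_tsv,
    relative_distance,
    score_structure,
    theoretical_profile,
    uniform_profile,
    write_profiles_tsv,
)
from fodm.structure_io import ResidueCloud, ResidueRecord
from fodm.synth import SynthSpec, generate_cloud


class TestGaussianField:
    def test_two_point_cloud(self):
        cloud = make_cloud([[3, 0, 0], [-3, 0, 0]], [0.5, 0.5])
        f = fit_gaussian_field(cloud)
        np.testing.assert_allclose(f.center, [0, 0, 0], atol=1e-12)
        assert f.sigmas[0] == pytest.approx(1.0)  # extent 3 / 3

    def test_axis_aligned_cloud_gets_identity_frame(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((200, 3)) * [10, 5, 2]
        f = fit_gaussian_field(pts - pts.mean(axis=0))
        np.testing.assert_allclose(np.abs(f.axes), np.eye(3), atol=0.15)
        assert f.sigmas[0] > f.sigmas[1] > f.sigmas[2]

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-10, 10, (50, 3)) * [1.5, 1.0, 0.5]
        rot = random_rotation(11)
        shift = np.array([5.0, -2.0, 7.0])
        f0 = fit_gaussian_field(pts)
        f1 = fit_gaussian_field(pts @ rot.T + shift)
        np.testing.assert_allclose(f1.center, rot @ f0.center + shift, atol=1e-9)
        np.testing.assert_allclose(f1.sigmas, f0.sigmas, atol=1e-6)

    def test_coincident_points_error_and_flat_axis_warning(self):
        with pytest.raises(ValueError, match="coincident"):
            fit_gaussian_field(np.zeros((5, 3)))
        flat = np.array([[0, 0, 0], [6, 0, 0], [3, 3, 0], [3, -3, 0]], float)
        with pytest.warns(RuntimeWarning, match="zero extent"):
            f = fit_gaussian_field(flat)
        assert np.all(f.sigmas > 0)


class TestTheoreticalProfile:
    def test_symmetric_pair_splits_evenly(self):
        cloud = make_cloud([[3, 0, 0], [-3, 0, 0]], [0.5, 0.5])
        t = theoretical_profile(cloud, fit_gaussian_field(cloud))
        np.testing.assert_allclose(t.values, [0.5, 0.5])

    def test_center_to_three_sigma_ratio(self):
        # a residue at the centre vs one 3 sigma out: exp(0)/exp(-4.5)
        from fodm.fod_core import GaussianField
        f = GaussianField(center=np.zeros(3), axes=np.eye(3),
                          sigmas=np.array([1.0, 1.0, 1.0]))
        pts = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        t = theoretical_profile(pts, f)
        assert t.values[0] / t.values[1] == pytest.approx(np.exp(4.5), rel=1e-9)

    def test_strictly_positive(self):
        cloud = generate_cloud(SynthSpec(seed=5))
        t = theoretical_profile(cloud, fit_gaussian_field(cloud))
        assert t.values.min() > 0
        assert t.values.sum() == pytest.approx(1.0, abs=1e-12)


class TestObservedProfile:
    def test_levitt_weight_endpoints_and_monotonicity(self):
        assert levitt_weight(0.0) == pytest.approx(1.0)
        assert levitt_weight(1.0) == pytest.approx(0.0)
        x = np.linspace(0, 1, 2001)
        g = levitt_weight(x)
        assert np.all(np.diff(g) <= 1e-12)
        assert np.all((g >= -1e-12) & (g <= 1 + 1e-12))

    def test_all_pairs_beyond_cutoff_is_an_error(self):
        cloud = make_cloud([[0, 0, 0], [20, 0, 0]], [0.5, 0.5])
        with pytest.raises(ValueError, match="farther apart than the cutoff"):
            observed_profile(cloud, cutoff=9.0)

    def test_middle_residue_dominates_collinear_triple(self):
        cloud = make_cloud([[0, 0, 0], [4, 0, 0], [8, 0, 0]], [0.4, 0.4, 0.4])
        o = observed_profile(cloud, cutoff=9.0)
        assert o.values[1] == max(o.values)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        pts = rng.uniform(-8, 8, (n, 3))
        h = rng.uniform(0.05, 1.0, n)
        cloud = make_cloud(pts, h)
        c = 9.0
        raw = np.zeros(n)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                r = np.linalg.norm(pts[i] - pts[j])
                if r <= c:
                    x = r / c
                    raw[i] += (h[i] + h[j]) * (
                        1 - 0.5 * (7 * x**2 - 9 * x**4 + 5 * x**6 - x**8))
            o = observed_profile(cloud, cutoff=c)
        np.testing.assert_allclose(o.values, raw / raw.sum(), atol=1e-12)

    def test_self_term_flag_changes_profile(self):
        cloud = make_cloud([[0, 0, 0], [4, 0, 0], [6, 2, 0]], [0.9, 0.1, 0.5])
        o = observed_profile(cloud)
        o_self = observed_profile(cloud, include_self=True)
        assert not np.allclose(o.values, o_self.values)
        assert o_self.values.sum() == pytest.approx(1.0, abs=1e-12)


class TestDivergenceAndRD:
    def test_hand_computed_values(self):
        assert kl_divergence(np.array([0.5, 0.5]), np.array([0.5, 0.5])) == 0.0
        expected = 0.5 * np.log2(2) + 0.5 * np.log2(2 / 3)
        assert kl_divergence(np.array([0.5, 0.5]),
                             np.array([0.25, 0.75])) == pytest.approx(expected)
        assert kl_divergence(np.array([1.0, 0.0]),
                             np.array([0.5, 0.5])) == pytest.approx(1.0)

    def test_zero_q_on_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            kl_divergence(np.array([0.5, 0.5]), np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="length mismatch"):
            kl_divergence(np.array([1.0]), np.array([0.5, 0.5]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 10), min_size=2, max_size=12),
           st.lists(st.floats(0.01, 10), min_size=2, max_size=12))
    def test_nonnegative_with_equality_iff_equal(self, a, b):
        n = min(len(a), len(b))
        p = np.array(a[:n]) / np.sum(a[:n])
        q = np.array(b[:n]) / np.sum(b[:n])
        d = kl_divergence(p, q)
        assert d >= -1e-12
        if np.allclose(p, q, atol=1e-15):
            assert d == pytest.approx(0.0, abs=1e-9)
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_relative_distance_endpoints_and_midpoint(self):
        assert relative_distance(0.0, 0.7) == 0.0
        assert relative_distance(0.7, 0.0) == 1.0
        assert relative_distance(0.2, 0.3) == pytest.approx(0.4)
        with pytest.raises(ValueError, match="undefined"):
            relative_distance(0.0, 0.0)


class TestScoreStructure:
    def test_rigid_motion_invariance_of_rd(self):
        cloud = generate_cloud(SynthSpec(n_residues=80, seed=2, discordance=0.3))
        rot = random_rotation(5)
        shift = np.array([11.0, -4.0, 3.0])
        moved = ResidueCloud(
            [ResidueRecord(r.chain_id, r.seq_number, r.insertion_code,
                           r.residue_name, rot @ r.effective_position + shift,
                           r.intrinsic_hydrophobicity)
             for r in cloud.records], source_id=cloud.source_id)
        r0 = score_structure(cloud)
        r1 = score_structure(moved)
        assert 0.0 <= r0.rd <= 1.0
        assert r1.rd == pytest.approx(r0.rd, abs=1e-6)

    def test_empty_exclusion_is_a_no_op(self):
        cloud = generate_cloud(SynthSpec(seed=4))
        a, b = score_structure(cloud), score_structure(cloud, exclude=[])
        assert a.rd == b.rd and a.dkl_OT == b.dkl_OT and a.excluded == b.excluded

    def test_exclusion_removes_before_refitting(self):
        cloud = generate_cloud(SynthSpec(n_residues=60, seed=9, discordance=0.5))
        keys = [("A", 1, ""), ("A", 2, "")]
        res = score_structure(cloud, exclude=keys)
        assert res.n_residues == 58
        assert res.excluded == keys
        # full re-derivation: matches scoring the pre-filtered cloud
        manual = score_structure(cloud.without(keys))
        assert res.rd == pytest.approx(manual.rd, abs=1e-12)

    def test_unknown_exclusion_is_an_error(self):
        cloud = generate_cloud(SynthSpec(seed=4))
        with pytest.raises(KeyError, match="not present"):
            score_structure(cloud, exclude=[("Z", 999, "")])

    def test_classification_boundary(self):
        ideal = score_structure(generate_cloud(SynthSpec(seed=1, discordance=0.0)))
        inverted = score_structure(generate_cloud(SynthSpec(seed=1, discordance=1.0)))
        assert ideal.rd < 0.5 and ideal.classification == "core_present"
        assert inverted.rd > 0.5 and inverted.classification == "core_absent"


def test_uniform_profile():
    r = uniform_profile(4)
    np.testing.assert_allclose(r.values, [0.25] * 4)
    assert uniform_profile(2).values.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        uniform_profile(1)


def test_profiles_tsv_round_trip(tmp_path):
    cloud = generate_cloud(SynthSpec(n_residues=20, seed=3))
    f = fit_gaussian_field(cloud)
    t = theoretical_profile(cloud, f)
    o = observed_profile(cloud)
    r = uniform_profile(len(cloud), cloud.keys)
    path = tmp_path / "profiles.tsv"
    write_profiles_tsv(path, cloud, [t, o, r])
    back = read_profiles_tsv(path)
    np.testing.assert_allclose(back["T"].values, t.values, rtol=1e-9)
    np.testing.assert_allclose(back["O"].values, o.values, rtol=1e-9)
    assert back["O"].residue_keys == cloud.keys
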