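"""Directional statistics: resultant length, ellipses, grouping, Watson U2
and paired t."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sstats

from lightzones import (
    GroupedSettings,
    angular_difference,
    circular_histogram,
    deviation_report,
    generate_settings,
    group_probes_exp2,
    mean_direction_and_R,
    mirror_settings,
    paired_t,
    rotate_settings_azimuth,
    sample_vmf,
    sd_ellipse,
    slice_grid,
    watson_u2,
)
from lightzones.probe_settings import SETTINGS_COLUMNS
from lightzones.synthetic_observers import ObserverProfile
from lightzones.zone_stats import _u2_null_moments, _u2_statistic


class TestMeanDirection:
    def test_identical_vectors_give_R_one(self):
        s = mean_direction_and_R([[0, 0, 1]] * 10)
        assert s.R == pytest.approx(1.0)
        assert s.dispersion == pytest.approx(1.0)
        np.testing.assert_allclose(s.mean_direction, [0, 0, 1])

    def test_balanced_axes_give_R_zero_dispersion_infinite(self):
        v = [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
        s = mean_direction_and_R(v)
        assert s.R == 0.0
        assert math.isinf(s.dispersion)
        assert s.mean_direction is None

    def test_two_orthogonal_vectors(self):
        s = mean_direction_and_R([[1, 0, 0], [0, 1, 0]])
        assert s.R == pytest.approx(np.sqrt(2) / 2)
        assert s.dispersion == pytest.approx(np.sqrt(2))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            mean_direction_and_R(np.empty((0, 3)))

    def test_permutation_invariance_and_rotation_equivariance(self, rng):
        v = sample_vmf([0.3, 0.5, 0.8], 5.0, 50, seed=rng)
        s1 = mean_direction_and_R(v)
        s2 = mean_direction_and_R(v[rng.permutation(len(v))])
        assert s1.R == pytest.approx(s2.R)
        theta = np.deg2rad(37.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        s3 = mean_direction_and_R(v @ rot.T)
        assert s3.R == pytest.approx(s1.R)
        np.testing.assert_allclose(s3.mean_direction, rot @ s1.mean_direction,
                                   atol=1e-12)


class TestSdEllipse:
    def test_degenerate_scatter(self):
        major, minor, _ = sd_ellipse([[0, 0, 1]] * 5)
        assert major == 0.0 and minor == 0.0

    def test_isotropic_scatter_has_near_equal_axes(self):
        v = sample_vmf([0, 0, 1], 50.0, 2000, seed=7)
        major, minor, _ = sd_ellipse(v)
        assert 0.8 <= major / minor <= 1.25

    def test_rank_one_scatter(self):
        # points spread along a single tangent direction only
        eps = 0.01
        base = np.array([0, 0, 1.0])
        t = np.array([1.0, 0, 0])
        v = [base + s * eps * t for s in (-2, -1, 1, 2)]
        v = [x / np.linalg.norm(x) for x in v]
        major, minor, _ = sd_ellipse(v)
        assert minor < 1e-6
        assert major > eps / 2

    def test_no_mean_direction_errors(self):
        with pytest.raises(ValueError, match="no mean direction"):
            sd_ellipse([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]])


class TestAngularDifference:
    def test_basic_angles(self):
        v = np.array([0.2, -0.5, 0.84])
        v = v / np.linalg.norm(v)
        assert angular_difference(v, v) == pytest.approx(0.0)
        assert angular_difference(v, -v) == pytest.approx(180.0)
        assert angular_difference([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)


def _settings_df(rows):
    return pd.DataFrame(rows, columns=SETTINGS_COLUMNS)


class TestGrouping:
    def test_slice_grid_partitions_into_five_groups(self, exp1_design_and_grids):
        design, grids = exp1_design_and_grids
        cond = design.conditions[0]
        cohort = [ObserverProfile(observer_id="solo")]
        df = generate_settings(design, cohort, master_seed=0)
        df = df[df["condition_id"] == cond.condition_id]
        df = df[df["repetition"] == 1]  # one setting per node
        probe_pos = dict(zip(cond.probes.probe_ids, cond.probes.positions))
        groups = slice_grid(df, grids[cond.condition_id], "x", probe_pos)
        assert len(groups) == 5
        assert [len(g) for g in groups] == [15] * 5  # 5 x 3 nodes per slice
        total = sum(len(g) for g in groups)
        assert total == len(df)

    def test_slice_grid_empty_table_gives_five_empty_groups(
        self, exp1_design_and_grids
    ):
        design, grids = exp1_design_and_grids
        cond = design.conditions[0]
        probe_pos = dict(zip(cond.probes.probe_ids, cond.probes.positions))
        groups = slice_grid(
            _settings_df([]), grids[cond.condition_id], "x", probe_pos
        )
        assert len(groups) == 5
        assert all(len(g) == 0 for g in groups)

    def test_slice_grid_unknown_probe_errors(self, exp1_design_and_grids):
        design, grids = exp1_design_and_grids
        cond = design.conditions[0]
        df = _settings_df([["o", cond.condition_id, "bogus", 1, 0, 0, 0.5, 0.2,
                            False]])
        probe_pos = dict(zip(cond.probes.probe_ids, cond.probes.positions))
        with pytest.raises(ValueError, match="unknown probe_id"):
            slice_grid(df, grids[cond.condition_id], "x", probe_pos)

    def test_group_probes_exp2_sizes(self, exp2_design):
        cond = exp2_design.condition("1LR")
        df = generate_settings(
            exp2_design, [ObserverProfile(observer_id="solo")], master_seed=0
        )
        df = df[df["condition_id"] == "1LR"]
        groups = group_probes_exp2(df, cond)
        assert [g.label for g in groups] == ["zone1", "middle", "zone2"]
        assert [len(g) for g in groups] == [6, 3, 6]  # (2, 1, 2) probes x 3 reps

    def test_group_probes_exp2_unknown_probe(self, exp2_design):
        cond = exp2_design.condition("1LR")
        df = _settings_df([["o", "1LR", "nope", 1, 0, 0, 0.5, 0.2, False]])
        with pytest.raises(ValueError, match="unknown probe_id"):
            group_probes_exp2(df, cond)


class TestRotateAndMirror:
    def test_rotation_shifts_azimuth(self):
        df = _settings_df([["o", "c", "p", 1, 0.0, 10.0, 0.5, 0.2, False]])
        out = rotate_settings_azimuth(df, 90.0)
        assert out["azimuth_deg"].iloc[0] == 90.0
        assert out["elevation_deg"].iloc[0] == 10.0

    def test_full_turn_and_inverse_are_identity(self):
        df = _settings_df(
            [["o", "c", "p", 1, a, 0.0, 0.5, 0.2, False] for a in (0, 123.4, 359)]
        )
        out = rotate_settings_azimuth(df, 360.0)
        np.testing.assert_allclose(out["azimuth_deg"], df["azimuth_deg"])
        out = rotate_settings_azimuth(rotate_settings_azimuth(df, 90), -90)
        np.testing.assert_allclose(out["azimuth_deg"], df["azimuth_deg"])

    def test_mirror_flips(self):
        df = _settings_df([["o", "c", "p", 1, 30.0, 5.0, 0.5, 0.2, False]])
        assert mirror_settings(df, "lr")["azimuth_deg"].iloc[0] == 150.0
        assert mirror_settings(df, "fb")["azimuth_deg"].iloc[0] == 330.0
        with pytest.raises(ValueError):
            mirror_settings(df, "ud")


class TestWatsonU2:
    def test_rotation_invariance(self, rng):
        a = rng.uniform(0, 360, 15)
        b = rng.uniform(0, 360, 12)
        u1, _ = watson_u2(a, b)
        u2, _ = watson_u2((a + 77.3) % 360, (b + 77.3) % 360)
        assert u2 == pytest.approx(u1, abs=1e-12)

    def test_identical_samples_have_large_permutation_p(self):
        a = np.array([10, 50, 90, 170, 250, 330.0])
        for seed in (0, 1, 2):
            _, p = watson_u2(a, a, mode="permutation", n_perm=499, seed=seed)
            assert p >= 0.5

    def test_shifted_distributions_detected(self, rng):
        a = (rng.normal(0, 15, 40)) % 360
        b = (rng.normal(180, 15, 40)) % 360
        _, p_asym = watson_u2(a, b)
        _, p_perm = watson_u2(a, b, mode="permutation", n_perm=499, seed=0)
        assert p_asym < 0.01
        assert p_perm < 0.01

    def test_too_small_samples_error(self):
        with pytest.raises(ValueError):
            watson_u2([1.0], [2.0, 3.0])

    def test_exact_null_moments_match_enumeration(self):
        # closed-form permutation-null moments vs exhaustive enumeration
        for n, m in [(3, 4), (4, 4), (4, 5)]:
            big_n = n + m
            vals = []
            x = np.arange(big_n, dtype=float)  # ranks; any tie-free data
            for comb_idx in itertools.combinations(range(big_n), n):
                mask = np.zeros(big_n, dtype=bool)
                mask[list(comb_idx)] = True
                vals.append(_u2_statistic(x[mask], x[~mask]))
            vals = np.array(vals)
            mean, var = _u2_null_moments(n, m)
            assert mean == pytest.approx(vals.mean(), abs=1e-12)
            assert var == pytest.approx(vals.var(), abs=1e-12)

    def test_asymptotic_close_to_permutation_oracle(self, rng):
        for _ in range(5):
            mu = rng.uniform(0, 360)
            a = (rng.normal(mu, 30, 16)) % 360
            b = (rng.normal(mu + rng.uniform(0, 60), 30, 14)) % 360
            _, pa = watson_u2(a, b)
            _, pp = watson_u2(a, b, mode="permutation", n_perm=999, seed=rng)
            p = min(max(pa, 1e-3), 1 - 1e-3)
            assert abs(pa - pp) < max(3 * np.sqrt(p * (1 - p) / 999), 0.02)


class TestPairedT:
    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([1, 2, 3], [1, 2, 3])

    def test_balanced_differences_give_zero_t(self):
        t, p = paired_t([1, 0, 1, 0], [0, 1, 0, 1])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        t, p = paired_t([1, 2, 3], [0, 0, 0])
        assert t == pytest.approx(2 * np.sqrt(3))  # dbar=2, sd=1, n=3
        assert 0 < p < 1

    @given(st.integers(min_value=0, max_value=1000))
    def test_matches_scipy_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        a = rng.normal(0, 1, n)
        b = rng.normal(0.3, 1.2, n)
        t, p = paired_t(a, b)
        ref = sstats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestCircularHistogram:
    def test_all_mass_in_one_bin(self):
        counts = circular_histogram([100.0] * 24, 24)
        assert counts.sum() == 24
        assert counts.max() == 24

    def test_quadrants(self):
        counts = circular_histogram([0, 90, 180, 270], 4)
        np.testing.assert_array_equal(counts, [1, 1, 1, 1])

    def test_conservation(self, rng):
        az = rng.uniform(-720, 720, 137)
        assert circular_histogram(az, 24).sum() == 137

    def test_min_bins(self):
        with pytest.raises(ValueError):
            circular_histogram([0.0, 1.0], 2)


class TestDeviationReport:
    def test_noise_free_settings_have_tiny_deviations(self, exp2_design):
        cohort = [
            ObserverProfile(observer_id="a", kappa_dir=1e9, sd_intensity=0,
                            sd_diffuseness=0),
            ObserverProfile(observer_id="b", kappa_dir=1e9, sd_intensity=0,
                            sd_diffuseness=0),
        ]
        df = generate_settings(exp2_design, cohort, master_seed=0)
        cond = exp2_design.condition("1LR")
        sub = df[df["condition_id"] == "1LR"]
        groups = group_probes_exp2(sub, cond)
        from lightzones.cli_io import _view_frame_veridical

        rep = deviation_report(groups, _view_frame_veridical(cond))
        assert (rep["mean_dev_3d_deg"] < 1.0).all()
        # the two probes of a zone see the distant source from slightly
        # different angles (~5 deg apart), which alone bounds the pooled
        # dispersion away from 1 even for noise-free observers
        assert (rep["between_dispersion"] < 1.005).all()
        assert (rep["within_dispersion"] < 1.005).all()

    def test_groups_partition_input(self, exp2_design):
        cohort = [ObserverProfile(observer_id="a")]
        df = generate_settings(exp2_design, cohort, master_seed=3)
        sub = df[df["condition_id"] == "2FB"]
        groups = group_probes_exp2(sub, exp2_design.condition("2FB"))
        assert sum(len(g) for g in groups) == len(sub)
        ids = [set(map(tuple, g.settings[["probe_id", "repetition"]].values))
               for g in groups]
        for i, j in itertools.combinations(range(3), 2):
            assert not (ids[i] & ids[j])

    def test_between_dispersion_at_least_within(self, exp2_design):
        # heterogeneous cohort (mixed confusion): pooling across observers
        # cannot be tighter than the average individual spread
        from lightzones.cli_io import _view_frame_veridical, default_cohort

        df = generate_settings(exp2_design, default_cohort(8), master_seed=5)
        cond = exp2_design.condition("2FB")
        sub = df[df["condition_id"] == "2FB"]
        groups = group_probes_exp2(sub, cond)
        rep = deviation_report(groups, _view_frame_veridical(cond))
        back = rep[rep["group"] == "zone2"].iloc[0]
        assert back["between_dispersion"] >= back["within_dispersion"] - 1e-9

    def test_missing_veridical_errors(self, exp2_design):
        cohort = [ObserverProfile(observer_id="a")]
        df = generate_settings(exp2_design, cohort, master_seed=3)
        sub = df[df["condition_id"] == "1LR"]
        groups = group_probes_exp2(sub, exp2_design.condition("1LR"))
        with pytest.raises(ValueError, match="missing veridical"):
            deviation_report(groups, {"q1": np.array([1.0, 0, 0])})
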