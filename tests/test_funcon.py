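import numpy as np
import pandas as pd
import pytest

import lesionkit as lk
from lesionkit import (
    ConnectivityMap,
    build_confound_matrix,
    first_eigenvariate,
    make_lesion,
    make_rsfmri,
    median_map,
    network_mask,
    regress_confounds,
    seed_correlation_map,
    temporal_derivative,
)

AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])


@pytest.fixture(scope="module")
def planted():
    template = lk.make_template(shape=(12, 12, 12), seed=0)
    seed_mask = make_lesion(template, (3, 3, 3), 2.0)
    target_mask = make_lesion(template, (8, 8, 8), 2.0)
    ts, conf = make_rsfmri(template, seed_mask, target_mask, coupling=0.8, n_frames=200, seed=1)
    brain = lk.MaskVolume(np.ones(template.data.shape, np.uint8), template.affine)
    return template, seed_mask, target_mask, ts, conf, brain


class TestEigenvariate:
    def test_rank_one_matrix_recovers_latent_course(self, rng):
        s = rng.normal(size=80)
        weights = rng.normal(size=30)
        mat = np.outer(weights, s)
        eig = first_eigenvariate(mat)
        assert abs(np.corrcoef(eig, s)[0, 1]) == pytest.approx(1.0, abs=1e-10)
        assert eig.std() == pytest.approx(1.0)

    def test_single_voxel_is_standardized_copy(self, rng):
        x = rng.normal(size=40)
        eig = first_eigenvariate(x[None, :])
        expected = (x - x.mean()) / (x - x.mean()).std()
        np.testing.assert_allclose(eig, expected, atol=1e-10)

    def test_sign_convention_follows_mean_course(self, rng):
        """The eigenvariate correlates non-negatively with the mean time
        course; negating all inputs negates the mean, hence the output."""
        mat = rng.normal(size=(20, 50)) + rng.normal(size=50)
        eig = first_eigenvariate(mat)
        mean_course = (mat - mat.mean(axis=1, keepdims=True)).mean(axis=0)
        assert np.dot(eig, mean_course) >= 0
        np.testing.assert_allclose(first_eigenvariate(-mat), -eig, atol=1e-8)

    def test_direction_invariant_to_per_voxel_sign_flips(self, rng):
        """Negating any subset of voxel series leaves the principal temporal
        direction unchanged up to sign (the Gram matrix is unchanged)."""
        mat = rng.normal(size=(20, 50)) + rng.normal(size=50)
        mat = mat - mat.mean(axis=1, keepdims=True)
        flip = rng.random(20) > 0.5
        flipped = mat * np.where(flip, -1.0, 1.0)[:, None]
        a, b = first_eigenvariate(mat), first_eigenvariate(flipped)
        assert abs(np.corrcoef(a, b)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            first_eigenvariate(np.ones((5, 10)))


class TestDerivative:
    def test_constant_maps_to_zero(self):
        np.testing.assert_array_equal(temporal_derivative(np.full(10, 3.0)), np.zeros(10))

    def test_linear_ramp_has_interior_value_two(self):
        d = temporal_derivative(np.arange(10.0))
        assert d[0] == 0.0 and d[-1] == 0.0
        np.testing.assert_array_equal(d[1:-1], np.full(8, 2.0))

    def test_linearity(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        np.testing.assert_allclose(
            temporal_derivative(2 * x + 3 * y),
            2 * temporal_derivative(x) + 3 * temporal_derivative(y),
            atol=1e-12,
        )


class TestConfoundMatrix:
    def test_sixteen_named_columns(self, rng):
        motion = rng.normal(size=(50, 6))
        wm = rng.normal(size=(10, 50))
        csf = rng.normal(size=(8, 50))
        conf = build_confound_matrix(motion, wm, csf)
        assert conf.shape == (50, 16)
        assert len(set(conf.columns)) == 16
        assert "wm_eig" in conf.columns and "csf_eig_dt" in conf.columns

    def test_constant_motion_has_zero_derivative(self, rng):
        motion = np.ones((40, 6))
        conf = build_confound_matrix(motion, rng.normal(size=(5, 40)), rng.normal(size=(5, 40)))
        for i in range(1, 7):
            assert conf[f"motion_{i}_dt"].abs().max() == 0.0

    def test_frame_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            build_confound_matrix(
                rng.normal(size=(50, 6)), rng.normal(size=(5, 40)), rng.normal(size=(5, 50))
            )


class TestRegression:
    def test_residuals_orthogonal_to_all_confounds(self, planted):
        _, _, _, ts, conf, brain = planted
        full = build_confound_matrix(
            conf[[f"motion_{i}" for i in range(1, 7)]],
            conf["phys_wm"].to_numpy()[None, :],
            conf["phys_csf"].to_numpy()[None, :],
        )
        clean = regress_confounds(ts, full, brain)
        resid = clean.data[brain.astype_bool()].T  # frames x voxels
        n = resid.shape[0]
        for col in full.columns:
            x = full[col].to_numpy(dtype=float)
            if x.std() == 0:
                continue
            x = (x - x.mean()) / x.std()
            r = resid / np.maximum(resid.std(axis=0), 1e-30)
            inner = np.abs(x @ r) / n
            assert inner.max() < 1e-8

    def test_voxel_equal_to_confound_becomes_zero(self, rng):
        t = 60
        conf = pd.DataFrame({"c1": rng.normal(size=t)})
        data = rng.normal(size=(4, 4, 4, t))
        data[1, 1, 1] = conf["c1"].to_numpy()
        ts = lk.TimeSeriesVolume(data, AFFINE)
        brain = lk.MaskVolume(np.ones((4, 4, 4), np.uint8), AFFINE)
        clean = regress_confounds(ts, conf, brain)
        assert np.abs(clean.data[1, 1, 1]).max() < 1e-10

    def test_no_confounds_demeans(self, rng):
        t = 30
        data = rng.normal(size=(3, 3, 3, t)) + 5.0
        ts = lk.TimeSeriesVolume(data, AFFINE)
        brain = lk.MaskVolume(np.ones((3, 3, 3), np.uint8), AFFINE)
        clean = regress_confounds(ts, pd.DataFrame(index=range(t)), brain)
        np.testing.assert_allclose(
            clean.data, data - data.mean(axis=3, keepdims=True), atol=1e-10
        )

    def test_collinear_columns_dropped_with_warning(self, rng, caplog):
        import logging

        t = 40
        base = rng.normal(size=t)
        conf = pd.DataFrame({"a": base, "b": 2 * base})
        data = rng.normal(size=(3, 3, 3, t))
        ts = lk.TimeSeriesVolume(data, AFFINE)
        brain = lk.MaskVolume(np.ones((3, 3, 3), np.uint8), AFFINE)
        with caplog.at_level(logging.WARNING, logger="lesionkit.funcon"):
            regress_confounds(ts, conf, brain)
        assert "rank-deficient" in caplog.text


class TestSeedCorrelation:
    def test_single_voxel_seed_self_correlation_is_one(self, planted):
        _, seed_mask, _, ts, _, brain = planted
        vox = tuple(np.argwhere(seed_mask.astype_bool())[0])
        single = np.zeros(ts.data.shape[:3], np.uint8)
        single[vox] = 1
        cmap = seed_correlation_map(ts, lk.MaskVolume(single, ts.affine), brain)
        assert cmap.r.data[vox] == pytest.approx(1.0)

    def test_planted_target_ranks_above_background(self, planted):
        template, seed_mask, target_mask, _, _, brain = planted
        for seed in range(20):
            ts, _ = make_rsfmri(
                template, seed_mask, target_mask, coupling=0.8, n_frames=200,
                seed=100 + seed, confound_amplitude=0.0,
            )
            cmap = seed_correlation_map(ts, seed_mask, brain)
            tgt = cmap.r.data[target_mask.astype_bool()].mean()
            bg_mask = brain.astype_bool() & ~target_mask.astype_bool() & ~seed_mask.astype_bool()
            bg = cmap.r.data[bg_mask].mean()
            assert tgt > bg

    def test_scale_free_in_seed_summary(self, planted):
        _, seed_mask, _, ts, _, brain = planted
        scaled = lk.TimeSeriesVolume(ts.data * 3.7 + 11.0, ts.affine, ts.tr_seconds)
        a = seed_correlation_map(ts, seed_mask, brain)
        b = seed_correlation_map(scaled, seed_mask, brain)
        np.testing.assert_allclose(a.r.data, b.r.data, atol=1e-10)

    def test_empty_seed_rejected(self, planted):
        _, _, _, ts, _, brain = planted
        empty = lk.MaskVolume(np.zeros(ts.data.shape[:3], np.uint8), ts.affine)
        with pytest.raises(ValueError):
            seed_correlation_map(ts, empty, brain)

    def test_regression_noop_on_confound_free_data(self, planted):
        """Residualizing data that never contained the confounds barely moves r."""
        template, seed_mask, target_mask, _, _, brain = planted
        ts, conf = make_rsfmri(
            template, seed_mask, target_mask, coupling=0.8, n_frames=500,
            seed=9, confound_amplitude=0.0,
        )
        full = build_confound_matrix(
            conf[[f"motion_{i}" for i in range(1, 7)]],
            conf["phys_wm"].to_numpy()[None, :],
            conf["phys_csf"].to_numpy()[None, :],
        )
        raw = seed_correlation_map(ts, seed_mask, brain)
        cleaned = seed_correlation_map(regress_confounds(ts, full, brain), seed_mask, brain)
        assert np.abs(raw.r.data - cleaned.r.data).max() < 0.05


class TestMedianAndMask:
    def _cmap(self, value_grid):
        return ConnectivityMap(lk.Volume(value_grid, AFFINE))

    def test_median_of_three(self):
        vals = [0.1, 0.2, 0.9]
        maps = [self._cmap(np.full((2, 2, 2), v)) for v in vals]
        med = median_map(maps)
        assert med.r.data[0, 0, 0] == pytest.approx(0.2)

    def test_even_count_averages_central_pair(self):
        maps = [self._cmap(np.full((2, 2, 2), v)) for v in (0.0, 0.4, 0.6, 1.0)]
        assert median_map(maps).r.data[0, 0, 0] == pytest.approx(0.5)

    def test_matches_sort_based_reference_and_order_invariant(self, rng):
        stacks = rng.uniform(-1, 1, size=(7, 4, 4, 4))
        maps = [self._cmap(s) for s in stacks]
        med = median_map(maps)
        ref = np.sort(stacks, axis=0)[3]
        np.testing.assert_allclose(med.r.data, ref, atol=1e-15)
        perm = [maps[i] for i in rng.permutation(7)]
        np.testing.assert_array_equal(median_map(perm).r.data, med.r.data)

    def test_network_mask_strict_threshold_and_lesion_exclusion(self):
        r = np.zeros((3, 1, 1))
        r[0, 0, 0] = 0.3   # exactly at threshold: excluded
        r[1, 0, 0] = 0.9   # above threshold but lesioned: excluded
        r[2, 0, 0] = 0.31  # kept
        lesion = np.zeros((3, 1, 1), np.uint8)
        lesion[1, 0, 0] = 1
        mask = network_mask(self._cmap(r), 0.3, lk.MaskVolume(lesion, AFFINE))
        assert mask.data.ravel().tolist() == [0, 0, 1]

    def test_no_lesion_pure_threshold(self):
        r = np.array([0.2, 0.5]).reshape(2, 1, 1)
        mask = network_mask(self._cmap(r), 0.3)
        assert mask.data.ravel().tolist() == [0, 1]
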