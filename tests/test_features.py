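"""Feature extraction: fit, PCA, segments, combination, scaling, leakage."""

import numpy as np
import pandas as pd
import pytest

from nervespec.features import (
    FIT_FEATURE_NAMES,
    FeatureMatrix,
    combine_features,
    fit_features,
    pca_features,
    scale_features,
    segment_features,
)
from nervespec.grid import WavelengthGrid


@pytest.fixture()
def spectra_pair(rng):
    train = rng.uniform(0.2, 2.0, size=(40, 1311))
    apply = rng.uniform(0.2, 2.0, size=(10, 1311))
    tid = [f"T{i}" for i in range(40)]
    aid = [f"A{i}" for i in range(10)]
    return train, apply, tid, aid


class TestFitFeatures:
    def _table(self, n=6, converged=None):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(0, 1, (n, len(FIT_FEATURE_NAMES))),
                          columns=FIT_FEATURE_NAMES,
                          index=[f"L{i}" for i in range(n)])
        df["converged"] = converged if converged is not None else True
        return df

    def test_twelve_features_identity_mapping(self):
        table = self._table()
        fm = fit_features(table)
        assert fm.n_features == 12
        np.testing.assert_array_equal(fm.values,
                                      table[FIT_FEATURE_NAMES].to_numpy())

    def test_non_converged_rows_excluded(self):
        table = self._table(converged=[True] * 5 + [False])
        fm = fit_features(table)
        assert fm.values.shape[0] == 5
        assert "L5" not in fm.location_ids


class TestPCAFeatures:
    def test_full_basis_reconstructs_training_spectra(self, spectra_pair):
        train, apply, tid, aid = spectra_pair
        fm_tr, _ = pca_features(train, apply, tid, aid, n_components=40)
        st = fm_tr.train_stats
        recon = fm_tr.values @ st["components"] + st["mean"]
        np.testing.assert_allclose(recon, train, rtol=1e-8, atol=1e-10)

    def test_training_scores_uncorrelated(self, spectra_pair):
        train, apply, tid, aid = spectra_pair
        fm_tr, _ = pca_features(train, apply, tid, aid, n_components=10)
        corr = np.corrcoef(fm_tr.values, rowvar=False)
        off = corr - np.diag(np.diag(corr))
        assert np.max(np.abs(off)) < 1e-8

    def test_explained_variance_non_increasing(self, spectra_pair):
        train, apply, tid, aid = spectra_pair
        fm_tr, _ = pca_features(train, apply, tid, aid, n_components=30)
        ev = fm_tr.train_stats["explained_variance"]
        assert np.all(np.diff(ev) <= 1e-12)

    def test_too_many_components_rejected(self, spectra_pair):
        train, apply, tid, aid = spectra_pair
        with pytest.raises(ValueError):
            pca_features(train, apply, tid, aid, n_components=41)


class TestSegmentFeatures:
    def test_default_segmentation_yields_65_segments(self, spectra_pair):
        train, apply, tid, aid = spectra_pair
        fm_tr, fm_ap = segment_features(train, apply, tid, aid)
        assert fm_tr.n_features == 65
        assert fm_ap.n_features == 65
        # last segment absorbs the 11 leftover points: 1300..1710 nm span
        assert fm_tr.feature_names[-1] == "seg_1680_1710"

    def test_training_set_mean_is_zero(self, spectra_pair):
        train, apply, tid, aid = spectra_pair
        fm_tr, _ = segment_features(train, apply, tid, aid)
        assert np.max(np.abs(fm_tr.values.mean(axis=0))) < 1e-10

    def test_invariant_to_positive_rescaling(self, spectra_pair):
        train, apply, tid, aid = spectra_pair
        _, fm1 = segment_features(train, apply, tid, aid)
        scaled = apply * np.array([[7.3]] * 5 + [[0.02]] * 5)
        _, fm2 = segment_features(train, scaled, tid, aid)
        np.testing.assert_allclose(fm2.values, fm1.values, rtol=1e-10)

    def test_hand_worked_two_segment_example(self):
        """3 spectra on a 6-point grid, two 3-point segments; expected
        values computed independently by direct normalise/z-score/sum
        arithmetic and frozen here."""
        grid = WavelengthGrid(400, 405, 1)
        X = np.array([[1., 2, 3, 4, 5, 6],
                      [2., 2, 2, 2, 2, 2],
                      [3., 4, 2, 1, 4, 1]])
        fm_tr, fm_ap = segment_features(X, X, list("abc"), list("abc"),
                                        segment_length_nm=3.0, grid=grid)
        expected = np.array([
            [-2.874335383388421, 2.515679050931383],
            [1.660096502982456, -0.956178870887663],
            [1.214238880405962, -1.559500180043719],
        ])
        np.testing.assert_allclose(fm_tr.values, expected, rtol=1e-12)
        np.testing.assert_allclose(fm_ap.values, expected, rtol=1e-12)

    def test_spectrum_above_training_mean_all_positive(self, spectra_pair):
        train, _, tid, _ = spectra_pair
        # after unit-mean normalisation, equality with the training mean
        # shape plus a tilt makes every z-score sign follow the tilt
        mu_shape = (train / train.mean(axis=1, keepdims=True)).mean(axis=0)
        tilt = mu_shape * np.linspace(1.0, 1.5, 1311)
        _, fm = segment_features(train, tilt[None, :], tid, ["x"])
        # tilted spectrum is below the mean early, above late: check signs
        assert fm.values[0, 0] < 0 < fm.values[0, -1]

    def test_degenerate_segment_length_rejected(self, spectra_pair):
        train, apply, tid, aid = spectra_pair
        with pytest.raises(ValueError):
            segment_features(train, apply, tid, aid, segment_length_nm=1000.0)


class TestCombineAndScale:
    def test_combined_width_is_sum_and_order_preserved(self, spectra_pair, rng):
        train, apply, tid, aid = spectra_pair
        p_tr, _ = pca_features(train, apply, tid, aid, n_components=30)
        s_tr, _ = segment_features(train, apply, tid, aid)
        fit_fm = FeatureMatrix(rng.uniform(0, 1, (40, 12)),
                               [f"fit_{n}" for n in FIT_FEATURE_NAMES],
                               tid, "fit")
        combo = combine_features(fit_fm, p_tr, s_tr)
        assert combo.n_features == 12 + 30 + 65
        assert combo.location_ids == tid
        np.testing.assert_array_equal(combo.values[:, :12], fit_fm.values)

    def test_combining_with_empty_matrix_is_identity(self, spectra_pair):
        train, apply, tid, aid = spectra_pair
        p_tr, _ = pca_features(train, apply, tid, aid, n_components=5)
        empty = FeatureMatrix(np.zeros((40, 0)), [], tid, "fit")
        combo = combine_features(p_tr, empty)
        np.testing.assert_array_equal(combo.values, p_tr.values)
        assert combo.feature_names == p_tr.feature_names

    def test_row_order_mismatch_rejected(self, spectra_pair):
        train, apply, tid, aid = spectra_pair
        p_tr, _ = pca_features(train, apply, tid, aid, n_components=5)
        s_tr, _ = segment_features(train, apply, list(reversed(tid)), aid)
        with pytest.raises(ValueError):
            combine_features(p_tr, s_tr)

    def test_scaled_training_matrix_standardised(self, spectra_pair, rng):
        train, apply, tid, aid = spectra_pair
        p_tr, p_ap = pca_features(train, apply, tid, aid, n_components=10)
        z_tr, z_ap = scale_features(p_tr, p_ap)
        assert np.max(np.abs(z_tr.values.mean(axis=0))) < 1e-10
        assert np.max(np.abs(z_tr.values.std(axis=0) - 1)) < 1e-10
        # apply set is scaled with TRAINING stats, not its own
        assert np.max(np.abs(z_ap.values.mean(axis=0))) > 1e-6

    def test_constant_feature_scales_to_zero(self):
        tr = FeatureMatrix(np.column_stack([np.ones(5), np.arange(5.)]),
                           ["const", "ramp"], list("abcde"), "fit")
        z_tr, _ = scale_features(tr, tr)
        assert np.all(z_tr.values[:, 0] == 0)


def test_train_stats_ignore_apply_partition(spectra_pair):
    """Leakage guard: perturbing the apply spectra must not change any
    training statistic of any transform."""
    train, apply, tid, aid = spectra_pair

    def stats(apply_arr):
        p_tr, _ = pca_features(train, apply_arr, tid, aid, n_components=10)
        s_tr, _ = segment_features(train, apply_arr, tid, aid)
        return p_tr.train_stats, s_tr.train_stats

    (p1, s1) = stats(apply)
    (p2, s2) = stats(apply * 3.7 + 0.1)
    np.testing.assert_array_equal(p1["mean"], p2["mean"])
    np.testing.assert_array_equal(p1["components"], p2["components"])
    np.testing.assert_array_equal(s1["mean"], s2["mean"])
    np.testing.assert_array_equal(s1["sd"], s2["sd"])
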