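"""Preprocessing: binning, transforms, recalibration, filters, selection."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from msiseg import preprocess as pp
from msiseg.io import MSIDataset, RawSpectrum
from msiseg.phantom import generate_phantom_series

from conftest import brute_force_best_lag, small_spec


def _one_pixel_dataset(mz, inten, t=1, label="embryo"):
    s = RawSpectrum(np.asarray(mz, float), np.asarray(inten, float), (0, 0))
    ds = MSIDataset(time_point=t, spectra=[s], grid_shape=(1, 1))
    ds.labels[0, 0] = label
    return ds


class TestBinning:
    def test_sum_within_window(self):
        ds = _one_pixel_dataset([100.04, 100.09], [5.0, 3.0])
        M = pp.bin_to_common_axis([ds], bin_width=0.1)
        assert M.axis_start == pytest.approx(100.0)
        assert M.matrix[0, 0] == pytest.approx(8.0)

    def test_half_open_edge(self):
        ds = _one_pixel_dataset([100.05, 100.10], [1.0, 2.0])
        M = pp.bin_to_common_axis([ds], bin_width=0.1)
        assert M.matrix[0, 0] == pytest.approx(1.0)
        assert M.matrix[0, 1] == pytest.approx(2.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.floats(100.0, 200.0), st.floats(0.0, 50.0)),
        min_size=1, max_size=40))
    def test_total_intensity_conserved(self, peaks_list):
        mz = np.sort(np.unique([round(p[0], 4) for p in peaks_list]))
        inten = np.array([p[1] for p in peaks_list[:len(mz)]])
        mz = mz[:len(inten)]
        ds = _one_pixel_dataset(mz, inten)
        M = pp.bin_to_common_axis([ds], bin_width=0.1)
        assert M.matrix.sum() == pytest.approx(inten.sum())

    def test_row_count_and_index(self, small_series):
        datasets, _ = small_series
        M = pp.bin_to_common_axis(datasets)
        assert M.n_spectra == sum(d.n_spectra for d in datasets)
        assert list(M.index.columns) == ["t", "r", "x", "y"]
        assert sorted(M.index.t.unique()) == [1, 2, 3]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pp.bin_to_common_axis([])


class TestSqrtAndMedian:
    def test_sqrt_values(self):
        ds = _one_pixel_dataset([100.0, 100.2], [4.0, 0.0])
        M = pp.sqrt_transform(pp.bin_to_common_axis([ds]))
        assert M.matrix[0, 0] == pytest.approx(2.0)
        assert M.matrix[0, 2] == 0.0

    def test_sqrt_rejects_negative(self):
        ds = _one_pixel_dataset([100.0], [1.0])
        M = pp.bin_to_common_axis([ds])
        M.matrix.data[0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            pp.sqrt_transform(M)

    def test_median_single_row(self):
        row = np.array([[1.0, 0.0, 3.0]])
        np.testing.assert_array_equal(pp.median_spectrum(row), row[0])

    def test_median_odd_count(self):
        rows = np.array([[1.0], [2.0], [9.0]])
        assert pp.median_spectrum(rows)[0] == 2.0

    def test_median_sparse_matches_dense(self):
        rng = np.random.default_rng(0)
        dense = rng.random((11, 30))
        dense[dense < 0.6] = 0.0
        sparse = sp.csr_matrix(dense)
        np.testing.assert_allclose(pp.median_spectrum(sparse),
                                   np.median(dense, axis=0), atol=1e-12)

    def test_median_all_zero(self):
        assert not pp.median_spectrum(np.zeros((4, 5))).any()

    def test_median_zero_rows_rejected(self):
        with pytest.raises(ValueError):
            pp.median_spectrum(np.zeros((0, 5)))


class TestEstimateShift:
    def test_identical_inputs_give_zero(self):
        v = np.random.default_rng(0).random(64)
        assert pp.estimate_shift(v, v, max_lag=5) == 0

    def test_recovers_known_translation(self):
        rng = np.random.default_rng(1)
        s = rng.random(128)
        ref = np.zeros(128)
        ref[3:] = s[:-3]  # reference equals spectrum shifted by +3 bins
        assert pp.estimate_shift(s, ref, max_lag=5) == 3

    def test_lag_capped_at_max(self):
        rng = np.random.default_rng(2)
        s = rng.random(256)
        ref = np.zeros(256)
        ref[7:] = s[:-7]
        lag = pp.estimate_shift(s, ref, max_lag=4)
        assert abs(lag) <= 4

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(16, 512))
            s = rng.random(n)
            ref = rng.random(n)
            L = int(rng.integers(1, 8))
            assert pp.estimate_shift(s, ref, L) == \
                brute_force_best_lag(s, ref, L)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pp.estimate_shift(np.ones(5), np.ones(6), 2)


class TestRecalibration:
    def test_zero_drift_means_zero_shifts(self, peaks):
        spec = small_spec(drift_per_dataset=[0.0, 0.0, 0.0])
        datasets, _ = generate_phantom_series(spec, seed=1)
        M = pp.sqrt_transform(pp.bin_to_common_axis(datasets))
        _, report = pp.recalibrate_multipass(M)
        assert (report.table.shift_bins == 0).all()

    def test_known_drifts_recovered(self):
        spec = small_spec(drift_per_dataset=[-0.3, 0.2, 0.4])
        datasets, truth = generate_phantom_series(spec, seed=2)
        M = pp.sqrt_transform(pp.bin_to_common_axis(datasets))
        M2, report = pp.recalibrate_multipass(M)
        total = report.table.groupby("spectrum").shift_da.sum().to_numpy()
        true_d = np.array([truth.drift[t] for t in M.index.t])
        resid = (total + true_d) - np.median(total + true_d)
        assert (np.abs(resid) <= 0.1 + 1e-9).mean() >= 0.95

    def test_every_shift_below_cutoff(self):
        spec = small_spec(drift_per_dataset=[0.7, -0.7, 0.0])
        datasets, _ = generate_phantom_series(spec, seed=3)
        M = pp.sqrt_transform(pp.bin_to_common_axis(datasets))
        _, report = pp.recalibrate_multipass(M)
        assert (report.table.shift_da.abs() < 0.5).all()
        report.validate()

    def test_pass_order_in_report(self, small_result):
        passes = small_result.report.table["pass"].unique().tolist()
        assert passes == list(pp.RECAL_PASSES)

    def test_second_run_is_near_identity(self, peaks):
        """Recalibration is contraction-like: re-running the multipass on
        already-recalibrated data applies (almost) no further shifts."""
        spec = small_spec()
        datasets, _ = generate_phantom_series(spec, seed=4)
        M = pp.sqrt_transform(pp.bin_to_common_axis(datasets))
        M1, _ = pp.recalibrate_multipass(M)
        _, rep2 = pp.recalibrate_multipass(M1)
        frac_zero = (rep2.table.shift_bins == 0).mean()
        assert frac_zero >= 0.99


class TestBackgroundFilter:
    def _matrix_with_reference(self):
        rng = np.random.default_rng(5)
        n_rows = 60
        ref = rng.random(n_rows) + 0.5
        data = np.zeros((n_rows, 6))
        data[:, 0] = ref                  # the reference bin itself
        data[:, 1] = 2.0 * ref            # identical image (r = 1)
        data[:, 2] = 1.0 - 0.5 * ref      # anti-correlated
        data[:, 3] = 0.7                  # constant
        data[:, 4] = rng.random(n_rows)   # unrelated
        data[:, 5] = 0.0
        index = pd.DataFrame({
            "t": 1, "r": "embryo",
            "x": np.arange(n_rows) % 10, "y": np.arange(n_rows) // 10})
        M = pp.BinnedMatrix(100.0, 0.1, sp.csr_matrix(data), index)
        return M

    def test_identical_image_removed_reference_removed(self):
        M = self._matrix_with_reference()
        out, removed = pp.filter_background_images(M, [100.05],
                                                   r_threshold=0.9)
        assert 0 in removed and 1 in removed
        assert 2 in out.bins and 3 in out.bins and 4 in out.bins

    def test_anticorrelated_image_retained(self):
        M = self._matrix_with_reference()
        out, _ = pp.filter_background_images(M, [100.05], r_threshold=0.25)
        assert 2 in out.bins

    def test_constant_image_retained(self):
        M = self._matrix_with_reference()
        out, _ = pp.filter_background_images(M, [100.05], r_threshold=0.25)
        assert 3 in out.bins

    def test_empty_reference_is_noop(self):
        M = self._matrix_with_reference()
        with pytest.warns(UserWarning):
            out, removed = pp.filter_background_images(M, [])
        assert out.n_bins == M.n_bins and len(removed) == 0


class TestRoiFilter:
    def _mixed(self):
        data = sp.csr_matrix(np.ones((10, 3)))
        labels = ["background"] * 4 + ["embryo"] * 3 + ["endosperm"] * 3
        index = pd.DataFrame({"t": 1, "r": labels,
                              "x": np.arange(10), "y": 0})
        return pp.BinnedMatrix(100.0, 0.1, data, index)

    def test_background_rows_removed(self):
        out = pp.filter_roi_spectra(self._mixed())
        assert out.n_spectra == 6
        assert set(out.index.r) == {"embryo", "endosperm"}

    def test_no_background_is_identity(self):
        M = self._mixed()
        M2 = M.select_rows(np.arange(4, 10))
        out = pp.filter_roi_spectra(M2)
        assert out.n_spectra == 6

    def test_all_background_rejected(self):
        M = self._mixed()
        M2 = M.select_rows(np.arange(0, 4))
        with pytest.raises(ValueError):
            pp.filter_roi_spectra(M2)


class TestVarianceExplained:
    def test_rank_one_image(self):
        img = np.outer([1.0, 2.0, 3.0], [4.0, 0.5, 2.0, 1.0])
        assert pp.variance_explained(img) == pytest.approx(1.0)

    def test_identity_2x2(self):
        assert pp.variance_explained(np.eye(2)) == pytest.approx(0.5)

    def test_all_zero_defined_as_zero(self):
        assert pp.variance_explained(np.zeros((4, 4))) == 0.0

    def test_random_images_score_low(self):
        rng = np.random.default_rng(7)
        ve = [pp.variance_explained(rng.standard_normal((50, 50)))
              for _ in range(100)]
        assert max(ve) < 0.2

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0), st.integers(0, 2 ** 31 - 1))
    def test_invariant_under_positive_scaling(self, c, seed):
        img = np.random.default_rng(seed).random((6, 8))
        assert pp.variance_explained(c * img) == \
            pytest.approx(pp.variance_explained(img), rel=1e-9)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            pp.variance_explained(np.ones((1, 5)))


class TestInformativeFilter:
    def test_mean_rule_inclusive_boundary(self):
        # three bins engineered to VE ~ {1.0, ~1.0 boundary, low}
        rng = np.random.default_rng(8)
        n = 64
        structured = np.outer(np.linspace(1, 2, 8),
                              np.linspace(1, 3, 8)).ravel()
        noise = np.abs(rng.standard_normal(n)) + 1e-3
        data = np.column_stack([structured, structured * 2.0, noise])
        index = pd.DataFrame({"t": 1, "r": "embryo",
                              "x": np.tile(np.arange(8), 8),
                              "y": np.repeat(np.arange(8), 8)})
        M = pp.BinnedMatrix(100.0, 0.1, sp.csr_matrix(data), index)
        out, info = pp.filter_informative_images(M)
        assert info.ve_per_image[0] == pytest.approx(1.0)
        assert 0 in out.bins and 1 in out.bins
        assert 2 not in out.bins

    def test_all_equal_ve_keeps_everything(self):
        data = np.column_stack([np.linspace(1, 2, 16)] * 3)
        index = pd.DataFrame({"t": 1, "r": "embryo",
                              "x": np.tile(np.arange(4), 4),
                              "y": np.repeat(np.arange(4), 4)})
        M = pp.BinnedMatrix(100.0, 0.1, sp.csr_matrix(data), index)
        out, info = pp.filter_informative_images(M)
        assert out.n_bins == 3

    def test_phantom_vacant_bins_depleted(self, small_result):
        """On the phantom the filter removes the vacant bulk of the axis
        (at least a 20-fold bin reduction) while every structured feature
        region keeps representation among the retained bins."""
        info = small_result.informative
        n_before = small_result.counts["bins_after_background_filter"]
        n_after = small_result.counts["bins_informative"]
        assert n_after * 20 <= n_before
        retained_mz = (small_result.recalibrated.axis_start
                       + (info.retained_bins + 0.5)
                       * small_result.recalibrated.bin_width)
        # each selected feature has a retained bin within the half-window
        for mz in small_result.profiles.feature_mz:
            assert np.abs(retained_mz - mz).min() <= 0.25


class TestNormalizeMedian:
    def _from_dense(self, data):
        index = pd.DataFrame({"t": 1, "r": "embryo",
                              "x": np.arange(len(data)), "y": 0})
        return pp.BinnedMatrix(100.0, 0.1, sp.csr_matrix(np.asarray(data)),
                               index)

    def test_examples(self):
        P, rows = pp.normalize_median(self._from_dense(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))
        np.testing.assert_allclose(P.matrix.toarray(),
                                   [[0.5, 1.0, 1.5], [1.0, 1.0, 1.0]])

    def test_zero_row_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            P, rows = pp.normalize_median(self._from_dense(
                [[1.0, 3.0, 0.0], [0.0, 0.0, 0.0]]))
        assert P.n_spectra == 1 and list(rows) == [0]

    def test_median_of_positives_is_one(self, small_result):
        P = small_result.informative.normalized
        X = P.matrix.tocsr()
        for i in range(0, X.shape[0], 97):
            v = X.data[X.indptr[i]:X.indptr[i + 1]]
            pos = v[v > 0]
            if len(pos):
                assert abs(np.median(pos) - 1.0) < 1e-12


class TestSelectFeatures:
    def _profile_matrix(self, mz_values, strength=None):
        mz_values = np.asarray(mz_values, dtype=float)
        n = 30
        rng = np.random.default_rng(9)
        axis_start = np.floor(mz_values.min() / 0.1) * 0.1 - 0.5
        n_bins = int((mz_values.max() - axis_start) / 0.1) + 10
        data = np.zeros((n, n_bins))
        for k, mz in enumerate(mz_values):
            b = int(np.floor((mz - axis_start + 1e-9) / 0.1))
            amp = 1.0 if strength is None else strength[k]
            data[:, b] = amp * (1.0 + rng.random(n))
        index = pd.DataFrame({"t": 1, "r": "embryo",
                              "x": np.arange(n), "y": 0})
        return pp.BinnedMatrix(axis_start, 0.1, sp.csr_matrix(data), index)

    @staticmethod
    def _peaklist(mz_values):
        from msiseg.io import TargetPeakList

        table = pd.DataFrame({
            "mz": mz_values,
            "label": [f"f{m}" for m in mz_values],
            "class": "unknown",
            "flagged_duplicate": False}).sort_values("mz")
        return TargetPeakList(table.reset_index(drop=True))

    def test_near_isobars_collapse_to_lower_mz(self):
        P = self._profile_matrix([589.26, 589.29])
        out = pp.select_features(P, self._peaklist([589.26, 589.29]))
        assert list(out.feature_mz) == [589.26]

    def test_fixture_flagged_pairs_collapse(self, small_result, peaks):
        selected = np.asarray(small_result.profiles.feature_mz)
        # selected features never sit within one bin of each other, so the
        # flagged near-isobaric adducts never survive next to their partner
        assert np.all(np.diff(np.sort(selected)) >= 0.1 - 1e-9)
        flagged = peaks.table[peaks.table.flagged_duplicate]
        for mz in flagged.mz:
            partners = peaks.mz[(np.abs(peaks.mz - mz) < 0.1)
                                & (peaks.mz < mz)]
            if len(partners):
                assert mz not in set(np.round(selected, 2))

    def test_well_separated_peaks_identity(self):
        mzs = [500.0, 500.9, 501.8]
        P = self._profile_matrix(mzs)
        out = pp.select_features(P, self._peaklist(mzs))
        assert list(out.feature_mz) == mzs

    def test_triple_collision_keeps_lowest(self):
        mzs = [700.00, 700.04, 700.08]
        P = self._profile_matrix(mzs)
        out = pp.select_features(P, self._peaklist(mzs))
        assert list(out.feature_mz) == [700.00]

    def test_result_invariant_to_peak_order(self):
        mzs = [500.0, 500.9, 501.8, 700.0, 700.04]
        P = self._profile_matrix(mzs)
        a = pp.select_features(P, self._peaklist(mzs))
        b = pp.select_features(P, self._peaklist(mzs[::-1]))
        np.testing.assert_array_equal(a.feature_mz, b.feature_mz)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_no_peak_in_range_rejected(self):
        P = self._profile_matrix([500.0])
        with pytest.raises(ValueError):
            pp.select_features(P, self._peaklist([900.0]))


def test_pipeline_counts_decrease(small_result):
    c = small_result.counts
    assert c["bins_informative"] <= c["bins_after_background_filter"] \
        <= c["bins_in"]
    assert c["profiles_out"] <= c["spectra_in_roi"] <= c["spectra_in"]
    assert c["features_out"] <= c["bins_informative"]
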