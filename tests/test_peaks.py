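"""OMP peak detection, centroid-matched feature extraction and skyline
spectra."""

import numpy as np
import pytest

from ovimsi.io import IonImageDataset
from ovimsi.peaks import (
    FeatureTable,
    PeakSet,
    average_peak_intensity,
    extract_features,
    mean_spectrum,
    omp_detect_peaks,
    skyline_spectrum,
)

MZ = np.arange(700.0, 760.0 + 1e-9, 0.1)
SIGMA = 0.25


def gaussians(centers, amps, sigma=SIGMA, mz=MZ):
    y = np.zeros_like(mz)
    for c, a in zip(centers, amps):
        y += a * np.exp(-0.5 * ((mz - c) / sigma) ** 2)
    return y


def dataset_from_matrix(intensities, mz=MZ, **kw):
    intensities = np.atleast_2d(intensities)
    params = dict(
        sample_id="s",
        group="CTRL",
        timepoint="16w",
        mode="positive",
        coords=[(i, 0) for i in range(intensities.shape[0])],
        mz_axis=mz,
        intensities=intensities,
    )
    params.update(kw)
    return IonImageDataset(**params)


class TestMeanAndSkyline:
    def test_single_spot_is_identity(self):
        row = gaussians([720.0], [5.0])
        ds = dataset_from_matrix(row)
        np.testing.assert_allclose(mean_spectrum([ds]), row)
        np.testing.assert_allclose(skyline_spectrum([ds]), row)

    def test_two_spot_mean_and_max(self):
        ds = dataset_from_matrix(np.array([[0.0, 2.0], [2.0, 0.0]]), mz=np.array([700.0, 701.0]))
        np.testing.assert_allclose(mean_spectrum([ds]), [1.0, 1.0])
        np.testing.assert_allclose(skyline_spectrum([ds]), [2.0, 2.0])

    def test_matches_brute_force_over_datasets(self, rng):
        stacks = [rng.random((4, MZ.size)), rng.random((3, MZ.size))]
        datasets = [dataset_from_matrix(s, sample_id=f"s{i}") for i, s in enumerate(stacks)]
        all_rows = np.vstack(stacks)
        np.testing.assert_allclose(mean_spectrum(datasets), all_rows.mean(axis=0))
        np.testing.assert_allclose(skyline_spectrum(datasets), all_rows.max(axis=0))
        assert np.all(skyline_spectrum(datasets) >= mean_spectrum(datasets))

    def test_axis_mismatch_rejected(self):
        a = dataset_from_matrix(np.ones((1, MZ.size)))
        b = dataset_from_matrix(np.ones((1, 10)), mz=MZ[:10], sample_id="b")
        with pytest.raises(ValueError):
            mean_spectrum([a, b])

    def test_skyline_requires_one_group(self):
        a = dataset_from_matrix(np.ones((1, MZ.size)))
        b = dataset_from_matrix(np.ones((1, MZ.size)), group="HFHS", sample_id="b")
        with pytest.raises(ValueError):
            skyline_spectrum([a, b])


class TestOmp:
    def test_single_peak_center_within_half_channel(self):
        y = gaussians([730.07], [10.0])
        ps = omp_detect_peaks(y, MZ, sigma=SIGMA, residual_tol=0.01)
        assert len(ps) == 1
        assert abs(ps.centers[0] - 730.07) <= 0.05

    def test_greedy_selects_larger_peak_first(self):
        y = gaussians([715.0, 745.0], [1.0, 10.0])
        ps = omp_detect_peaks(y, MZ, sigma=SIGMA, max_peaks=1, residual_tol=0.01)
        assert len(ps) == 1
        assert abs(ps.centers[0] - 745.0) <= 0.05

    def test_recovers_planted_peak_set(self, rng):
        centers = np.sort(rng.uniform(705, 755, 8))
        while np.any(np.diff(centers) < 6 * SIGMA * 2):
            centers = np.sort(rng.uniform(705, 755, 8))
        amps = rng.uniform(3, 30, centers.size)
        y = gaussians(centers, amps)
        ps = omp_detect_peaks(y, MZ, sigma=SIGMA, residual_tol=0.01)
        assert len(ps) == centers.size
        assert np.max(np.abs(ps.centers - centers)) <= 0.1  # within one channel

    def test_residual_norm_non_increasing(self):
        y = gaussians([710.0, 720.0, 730.0, 740.0], [5, 4, 3, 2]) + 0.05
        ps = omp_detect_peaks(y, MZ, sigma=SIGMA, residual_tol=0.001, max_peaks=50)
        norms = ps.provenance["residual_norms"]
        assert all(b <= a + 1e-9 for a, b in zip(norms, norms[1:]))

    def test_all_zero_spectrum_yields_empty_set(self):
        ps = omp_detect_peaks(np.zeros(MZ.size), MZ)
        assert len(ps) == 0

    @pytest.mark.parametrize(
        "kw", [dict(sigma=0), dict(max_peaks=0), dict(residual_tol=0.0), dict(residual_tol=1.0)]
    )
    def test_bad_params_rejected(self, kw):
        with pytest.raises(ValueError):
            omp_detect_peaks(np.ones(MZ.size), MZ, **{**dict(sigma=SIGMA), **kw})

    def test_intervals_disjoint_for_close_peaks(self):
        y = gaussians([729.0, 730.0], [10.0, 8.0])  # closer than 6 sigma
        ps = omp_detect_peaks(y, MZ, sigma=SIGMA, residual_tol=0.01)
        lo = ps.centers - ps.half_widths
        hi = ps.centers + ps.half_widths
        assert np.all(hi[:-1] <= lo[1:] + 1e-9)


class TestFeatureExtraction:
    def test_delta_like_peak_value_is_area(self):
        y = np.zeros(MZ.size)
        ch = np.argmin(np.abs(MZ - 730.0))
        y[ch] = 42.0
        ds = dataset_from_matrix(y)
        ps = PeakSet([730.0], [0.75], SIGMA)
        table = extract_features(ds, ps)
        assert table.values[0, 0] == pytest.approx(42.0)

    def test_zero_signal_interval_gives_zero(self):
        ds = dataset_from_matrix(np.zeros(MZ.size))
        table = extract_features(ds, PeakSet([730.0], [0.75], SIGMA))
        assert table.values[0, 0] == 0.0

    def test_shifted_peak_still_assigned(self):
        shift = 0.3  # well inside the half-width
        y = gaussians([730.0 + shift], [10.0])
        ds = dataset_from_matrix(y)
        table = extract_features(ds, PeakSet([730.0], [0.75], SIGMA))
        expected = y[np.abs(MZ - 730.0) <= 0.75].sum()  # interval sum, not full area
        assert expected > 0
        assert table.values[0, 0] == pytest.approx(expected, rel=1e-6)

    def test_interval_outside_axis_rejected(self):
        ds = dataset_from_matrix(np.ones(MZ.size))
        with pytest.raises(ValueError):
            extract_features(ds, PeakSet([900.0], [0.75], SIGMA))

    def test_column_sum_conserves_isolated_peak_signal(self, rng):
        """For isolated peaks, summed features over spots equal the total
        signal in the peak intervals."""
        centers = [715.0, 735.0]
        spots = np.vstack([gaussians(centers, rng.uniform(2, 9, 2)) for _ in range(6)])
        ds = dataset_from_matrix(spots)
        ps = PeakSet(centers, [0.75, 0.75], SIGMA)
        table = extract_features(ds, ps)
        for j, c in enumerate(centers):
            window = np.abs(MZ - c) <= 0.75
            np.testing.assert_allclose(
                table.values[:, j].sum(), spots[:, window].sum(), rtol=1e-3
            )


class TestAveragePeakIntensity:
    def make_table(self, values):
        values = np.asarray(values, dtype=float)
        import pandas as pd

        spots = pd.DataFrame(
            {
                "sample_id": "s",
                "group": "CTRL",
                "timepoint": "16w",
                "mode": "positive",
                "x": range(values.shape[0]),
                "y": 0,
            }
        )
        ps = PeakSet(
            700.0 + 10 * np.arange(values.shape[1]), np.full(values.shape[1], 0.75), SIGMA
        )
        return FeatureTable(spots=spots, values=values, peak_set=ps)

    def test_constant_table(self):
        t = self.make_table(np.full((4, 3), 2.5))
        assert average_peak_intensity(t, np.ones(4, bool)) == 2.5

    def test_single_spot_two_peaks(self):
        t = self.make_table([[1.0, 3.0], [9.0, 9.0]])
        roi = np.array([True, False])
        assert average_peak_intensity(t, roi) == 2.0

    def test_empty_roi_rejected(self):
        t = self.make_table(np.ones((3, 2)))
        with pytest.raises(ValueError):
            average_peak_intensity(t, np.zeros(3, bool))
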