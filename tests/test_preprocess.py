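"""Baseline correction, TIC normalization and mass-filter behaviour.

The Tophat oracle here is a brute-force morphological opening (sliding
minimum then sliding maximum over the structuring element) written
independently of the scipy-based implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovimsi.io import IonImageDataset
from ovimsi.preprocess import (
    MATRIX_EXCLUSION,
    PreprocessParams,
    apply_mass_filters,
    preprocess_dataset,
    tic_normalize,
    tophat_baseline_correct,
)
from ovimsi.synth import generate_study
from tests.conftest import make_config


def brute_force_opening(y: np.ndarray, width: int) -> np.ndarray:
    """Erosion then dilation with a flat element, edge-padded, by sliding
    windows."""
    half = width // 2
    pad = np.pad(y, half, mode="edge")
    eroded = np.array([pad[i : i + width].min() for i in range(y.size)])
    pad2 = np.pad(eroded, half, mode="edge")
    return np.array([pad2[i : i + width].max() for i in range(y.size)])


def simple_dataset(intensities, mz=None):
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    n = intensities.shape[1]
    mz = np.linspace(400, 410, n) if mz is None else mz
    return IonImageDataset(
        sample_id="p",
        group="CTRL",
        timepoint="3d",
        mode="positive",
        coords=[(i, 0) for i in range(intensities.shape[0])],
        mz_axis=mz,
        intensities=intensities,
    )


class TestTophat:
    def test_constant_spectrum_maps_to_zero(self):
        out = tophat_baseline_correct(np.full(101, 7.3), width=11)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_isolated_narrow_peak_preserved(self):
        x = np.arange(201.0)
        peak = 50 * np.exp(-0.5 * ((x - 100) / 2.0) ** 2)
        out = tophat_baseline_correct(peak, width=31)
        np.testing.assert_allclose(out, peak, atol=1e-9)

    def test_peak_on_ramp_recovered_within_slope_bound(self):
        x = np.arange(301.0)
        slope = 0.05
        peak = 40 * np.exp(-0.5 * ((x - 150) / 2.0) ** 2)
        width = 41
        out = tophat_baseline_correct(peak + slope * x, width=width)
        # opening of a ramp under-tracks by at most slope * width
        assert np.all(np.abs(out - peak) <= slope * width + 1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_opening(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.random(80) * 100
        width = int(rng.choice([3, 5, 9, 15]))
        expected = y - brute_force_opening(y, width)
        out = tophat_baseline_correct(y, width)
        np.testing.assert_allclose(out, expected, atol=1e-9)
        assert np.all(out >= -1e-12) and np.all(out <= y + 1e-12)

    @pytest.mark.parametrize("width", [2, 1, 4, 1001])
    def test_bad_width_rejected(self, width):
        with pytest.raises(ValueError):
            tophat_baseline_correct(np.zeros(100), width)

    def test_second_pass_nearly_idempotent(self):
        datasets, _ = generate_study(make_config(), seed=0)
        once = tophat_baseline_correct(datasets[0].intensities.astype(float), 31)
        twice = tophat_baseline_correct(once, 31)
        removed = once.sum() - twice.sum()
        assert removed < 0.01 * once.sum()


class TestTicNormalize:
    def test_unit_sum(self):
        ds = simple_dataset([[1.0] * 10, [2.0] * 10])
        out = tic_normalize(ds, "unit_sum")
        np.testing.assert_allclose(out.intensities.sum(axis=1), 1.0)

    def test_mean_tic_single_spot_unchanged(self):
        ds = simple_dataset([np.arange(10.0)])
        out = tic_normalize(ds, "mean_tic")
        np.testing.assert_allclose(out.intensities, ds.intensities)

    def test_cv_of_spot_sums_is_zero(self, rng):
        ds = simple_dataset(rng.random((30, 40)) + 0.1)
        out = tic_normalize(ds, "mean_tic")
        sums = out.intensities.sum(axis=1)
        assert sums.std() / sums.mean() < 1e-12

    def test_relative_peak_ratios_unchanged(self, rng):
        ds = simple_dataset(rng.random((5, 20)) + 0.5)
        out = tic_normalize(ds, "unit_sum")
        for before, after in zip(ds.intensities, out.intensities):
            np.testing.assert_allclose(after / after[0], before / before[0], rtol=1e-9)

    def test_zero_tic_spot_dropped_with_warning(self, caplog):
        ds = simple_dataset([[1.0] * 10, [0.0] * 10])
        with caplog.at_level("WARNING"):
            out = tic_normalize(ds, "unit_sum")
        assert out.n_spots == 1
        assert "zero-TIC" in caplog.text

    def test_all_zero_rejected(self):
        ds = simple_dataset([[0.0] * 10])
        with pytest.raises(ValueError):
            tic_normalize(ds, "unit_sum")


class TestMassFilters:
    def test_deflection_crops_low_masses(self):
        mz = np.linspace(350, 2000, 1000)
        ds = simple_dataset(np.ones((2, 1000)), mz=np.linspace(399, 2000, 1000))
        out = apply_mass_filters(ds, PreprocessParams())
        assert out.mz_axis.min() >= 400.0
        assert out.intensities.shape[1] == out.mz_axis.size

    def test_matrix_window_excluded(self):
        mz = np.linspace(400, 600, 2001)
        ds = simple_dataset(np.ones((1, 2001)), mz=mz)
        out = apply_mass_filters(ds, PreprocessParams())
        lo, hi = MATRIX_EXCLUSION
        assert not np.any((out.mz_axis >= lo) & (out.mz_axis <= hi))

    def test_empty_exclusion_list_is_identity(self):
        mz = np.linspace(400, 600, 100)
        ds = simple_dataset(np.ones((1, 100)), mz=mz)
        out = apply_mass_filters(ds, PreprocessParams(exclusion_windows=[]))
        np.testing.assert_array_equal(out.mz_axis, ds.mz_axis)
        np.testing.assert_array_equal(out.intensities, ds.intensities)

    def test_removing_all_channels_rejected(self):
        mz = np.linspace(494, 506, 50)
        ds = simple_dataset(np.ones((1, 50)), mz=mz)
        with pytest.raises(ValueError):
            apply_mass_filters(ds, PreprocessParams())

    @pytest.mark.parametrize(
        "kw",
        [
            dict(tophat_width=4),
            dict(tophat_width=1),
            dict(tic_target="median"),
            dict(exclusion_windows=[(507, 493)]),
            dict(exclusion_windows=[(300, 350)]),
        ],
    )
    def test_bad_params_rejected(self, kw):
        with pytest.raises(ValueError):
            PreprocessParams(**kw)


class TestPipelineOrder:
    def test_spot_count_and_coords_preserved(self):
        datasets, _ = generate_study(make_config(), seed=2)
        ds = datasets[0]
        out = preprocess_dataset(ds)
        assert out.n_spots == ds.n_spots
        np.testing.assert_array_equal(out.coords, ds.coords)

    def test_matrix_peak_absent_downstream(self):
        """A planted matrix-cluster peak at m/z 500 never reaches the
        preprocessed axis."""
        config = make_config(mz_range=(450.0, 550.0), n_peaks=4)
        datasets, manifest = generate_study(config, seed=0)
        assert any(p.is_matrix for p in manifest.planted_peaks["positive"])
        out = preprocess_dataset(datasets[0])
        lo, hi = MATRIX_EXCLUSION
        assert not np.any((out.mz_axis >= lo) & (out.mz_axis <= hi))

    def test_filter_normalize_order_matters(self):
        """TIC depends on retained channels, so excluding after normalizing
        gives a different result — the pipeline's fixed order is load-bearing."""
        mz = np.linspace(400, 600, 2001)
        intens = np.ones((1, 2001))
        intens[0, 1000] = 100.0  # large peak inside the matrix window (500.0)
        ds = simple_dataset(intens, mz=mz)
        params = PreprocessParams(tophat_width=3)
        filtered_first = tic_normalize(apply_mass_filters(ds, params), "unit_sum")
        normalized_first = apply_mass_filters(tic_normalize(ds, "unit_sum"), params)
        a = filtered_first.intensities.sum()
        b = normalized_first.intensities.sum()
        assert not np.isclose(a, b)
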