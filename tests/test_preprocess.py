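"""Temporal preprocessing: volume dropping, Friston-24, regression, bandpass."""

import numpy as np
import pytest

from fcslat.grid import BinaryMask, Bold4D, ImageGrid
from fcslat.io_nifti import FormatError
from fcslat.preprocess import (
    bandpass,
    build_friston24,
    build_nuisance_matrix,
    drop_initial_volumes,
    nuisance_regress,
    preprocess_run,
    tissue_mean_signal,
    NuisanceMatrix,
)


def _bold(values, tr=3.0):
    values = np.asarray(values, dtype=float)
    grid = ImageGrid(values.shape[:3])
    return Bold4D(grid, values, tr_seconds=tr)


class TestDropInitialVolumes:
    def test_study_setting_124_minus_4(self, rng):
        bold = _bold(rng.standard_normal((2, 2, 2, 124)))
        assert drop_initial_volumes(bold, 4).n_frames == 120

    def test_zero_drop_is_identity(self, rng):
        bold = _bold(rng.standard_normal((2, 2, 2, 10)))
        assert drop_initial_volumes(bold, 0) is bold

    def test_remaining_order_preserved(self, rng):
        vals = rng.standard_normal((1, 1, 1, 12))
        out = drop_initial_volumes(_bold(vals), 3)
        np.testing.assert_array_equal(out.values[0, 0, 0], vals[0, 0, 0, 3:])

    def test_dropping_all_frames_rejected(self, rng):
        bold = _bold(rng.standard_normal((1, 1, 1, 10)))
        with pytest.raises(ValueError):
            drop_initial_volumes(bold, 10)


class TestFriston24:
    def test_exactly_24_columns(self, rng):
        assert build_friston24(rng.standard_normal((30, 6))).n_columns == 24

    def test_all_zero_motion_gives_all_zero_columns(self):
        out = build_friston24(np.zeros((10, 6)))
        assert not out.data.any()

    def test_lag_and_square_definitions(self):
        m = np.zeros((5, 6))
        m[:, 0] = [0, 1, 2, 3, 4]
        out = build_friston24(m)
        np.testing.assert_array_equal(out.data[:, 0], [0, 1, 2, 3, 4])       # m_t
        np.testing.assert_array_equal(out.data[:, 6], [0, 0, 1, 2, 3])       # m_{t-1}
        np.testing.assert_array_equal(out.data[:, 12], [0, 1, 4, 9, 16])     # m_t^2
        np.testing.assert_array_equal(out.data[:, 18], [0, 0, 1, 4, 9])      # m_{t-1}^2

    def test_wrong_column_count_rejected(self):
        with pytest.raises(FormatError):
            build_friston24(np.zeros((10, 5)))


class TestNuisanceRegress:
    def test_series_equal_to_design_column_zeroed(self, rng):
        t = 30
        col = rng.standard_normal(t)
        design = NuisanceMatrix(np.column_stack([np.ones(t), col]))
        vals = np.tile(col, (2, 2, 1, 1)).reshape(2, 2, 1, t)
        out = nuisance_regress(_bold(vals), design)
        assert np.abs(out.values).max() < 1e-10

    def test_intercept_only_demeans(self, rng):
        vals = rng.standard_normal((2, 2, 1, 20)) + 5.0
        design = NuisanceMatrix(np.ones((20, 1)))
        out = nuisance_regress(_bold(vals), design)
        np.testing.assert_allclose(
            out.values, vals - vals.mean(axis=3, keepdims=True), atol=1e-10)

    def test_residuals_orthogonal_to_every_column(self, rng):
        t = 40
        design = NuisanceMatrix(np.column_stack([np.ones(t), rng.standard_normal((t, 4))]))
        out = nuisance_regress(_bold(rng.standard_normal((3, 2, 2, t))), design)
        resid = out.values.reshape(-1, t)
        assert np.abs(resid @ design.data).max() < 1e-8

    def test_idempotent(self, rng):
        t = 30
        design = NuisanceMatrix(np.column_stack([np.ones(t), rng.standard_normal((t, 3))]))
        once = nuisance_regress(_bold(rng.standard_normal((2, 2, 1, t))), design)
        twice = nuisance_regress(once, design)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_rank_deficient_design_warns(self, rng):
        t = 20
        col = rng.standard_normal(t)
        design = NuisanceMatrix(np.column_stack([np.ones(t), col, col]))
        with pytest.warns(UserWarning, match="rank-deficient"):
            nuisance_regress(_bold(rng.standard_normal((1, 1, 1, t))), design)

    def test_outside_mask_passes_through_as_zero(self, rng):
        t = 20
        grid = ImageGrid((2, 2, 1))
        mask = BinaryMask(grid, np.array([[[True], [False]], [[False], [False]]]))
        design = NuisanceMatrix(np.ones((t, 1)))
        out = nuisance_regress(_bold(rng.standard_normal((2, 2, 1, t))), design, mask=mask)
        assert not out.values[~mask.membership].any()


class TestBandpass:
    def _sinusoid(self, freq_hz, t=200, tr=3.0):
        times = np.arange(t) * tr
        vals = np.sin(2 * np.pi * freq_hz * times).reshape(1, 1, 1, t)
        return _bold(vals, tr=tr)

    def test_passband_preserves_amplitude(self):
        out = bandpass(self._sinusoid(0.05), 0.01, 0.1)
        ratio = out.values.std() / self._sinusoid(0.05).values.std()
        assert ratio > 0.9

    def test_stopband_suppresses(self):
        out = bandpass(self._sinusoid(0.15), 0.01, 0.1)
        ratio = out.values.std() / self._sinusoid(0.15).values.std()
        assert ratio < 0.1

    def test_dc_removed(self):
        bold = _bold(np.full((2, 2, 1, 50), 7.0))
        out = bandpass(bold, 0.01, 0.1)
        assert np.abs(out.values).max() < 1e-10

    def test_idempotent_projection(self, rng):
        bold = _bold(rng.standard_normal((2, 2, 2, 64)))
        once = bandpass(bold, 0.01, 0.1)
        twice = bandpass(once, 0.01, 0.1)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_linear(self, rng):
        a = rng.standard_normal((1, 1, 1, 64))
        b = rng.standard_normal((1, 1, 1, 64))
        lhs = bandpass(_bold(a + b), 0.01, 0.1).values
        rhs = bandpass(_bold(a), 0.01, 0.1).values + bandpass(_bold(b), 0.01, 0.1).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_rejects_band_at_nyquist(self, rng):
        bold = _bold(rng.standard_normal((1, 1, 1, 50)), tr=3.0)  # nyquist 1/6 Hz
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(bold, 0.01, 0.2)


class TestTissueMeanSignal:
    def test_single_voxel_mask_returns_its_series(self, rng):
        vals = rng.standard_normal((2, 2, 1, 15))
        grid = ImageGrid((2, 2, 1))
        mask = np.zeros(grid.dims, bool); mask[1, 0, 0] = True
        out = tissue_mean_signal(_bold(vals), BinaryMask(grid, mask))
        np.testing.assert_array_equal(out, vals[1, 0, 0])

    def test_constant_image(self):
        vals = np.full((2, 2, 1, 10), 3.5)
        grid = ImageGrid((2, 2, 1))
        out = tissue_mean_signal(_bold(vals), BinaryMask(grid, np.ones(grid.dims, bool)))
        np.testing.assert_allclose(out, 3.5)

    def test_opposite_series_cancel(self, rng):
        s = rng.standard_normal(12)
        vals = np.zeros((2, 1, 1, 12))
        vals[0, 0, 0], vals[1, 0, 0] = s, -s
        grid = ImageGrid((2, 1, 1))
        out = tissue_mean_signal(_bold(vals), BinaryMask(grid, np.ones(grid.dims, bool)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_empty_mask_rejected(self, rng):
        grid = ImageGrid((2, 2, 1))
        with pytest.raises(ValueError, match="empty"):
            tissue_mean_signal(_bold(rng.standard_normal((2, 2, 1, 10))),
                               BinaryMask(grid, np.zeros(grid.dims, bool)))


def test_preprocess_run_records_fixed_stage_order(rng):
    grid = ImageGrid((4, 4, 2))
    bold = Bold4D(grid, 100 + rng.standard_normal(grid.dims + (40,)), tr_seconds=3.0)
    gm = BinaryMask(grid, np.ones(grid.dims, bool))
    cleaned, meta = preprocess_run(bold, rng.standard_normal((40, 6)) * 0.01, gm, n_drop=4)
    assert meta["pipeline_order"] == ["drop_initial_volumes", "nuisance_regress", "bandpass"]
    assert cleaned.n_frames == 36
    assert meta["n_frames_out"] == 36
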