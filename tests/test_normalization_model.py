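"""Normalization-model unit and property tests.

Brute-force convolution oracles are plain O(N^2) summations written
independently of the implementation's ndimage/circulant path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from normsupp import normalization_model as nm
from normsupp.config import DEFAULT_CRITERIA


def brute_force_pool(values, positions, features, space_width, feature_width):
    """Direct-summation pooling oracle (2-D space, wrapped feature).

    Each feature column is embedded as a circular 2-D field and pooled
    by an explicit outer-product double sum over every grid cell with
    the truncated (5 SD), unit-sum separable Gaussian; the central row
    is kept.  The feature axis is then circularly convolved by plain
    loops.  Independent of the implementation's row-restricted
    separable shortcut.
    """
    dx = positions[1] - positions[0]
    half = int(np.ceil(5.0 * space_width / dx))
    sk = np.exp(-0.5 * (np.arange(-half, half + 1) * dx / space_width) ** 2)
    sk /= sk.sum()
    n_pos, n_feat = values.shape
    center = int(np.argmin(np.abs(positions)))

    def k1(offset):
        return sk[offset + half] if -half <= offset <= half else 0.0

    krow_center = np.array([k1(i - center) for i in range(n_pos)])
    out_s = np.zeros_like(values)
    for f in range(n_feat):
        field = nm.radial_embed(values[:, f], positions)
        for u in range(n_pos):
            krow_u = np.array([k1(j - u) for j in range(n_pos)])
            out_s[u, f] = np.sum(field * np.outer(krow_center, krow_u))

    step = 360.0 / n_feat
    fk = np.zeros(n_feat)
    for m in range(n_feat):
        for wrap in (-3, -2, -1, 0, 1, 2, 3):
            fk[m] += np.exp(-0.5 * ((m * step + 360.0 * wrap) / feature_width) ** 2)
    fk /= fk.sum()
    out = np.zeros_like(values)
    for q in range(n_feat):
        for m in range(n_feat):
            out[:, q] += fk[m] * out_s[:, (q - m) % n_feat]
    return out


class TestStimulusDrive:
    def test_zero_contrast_gives_zero_field(self, grid, params):
        stim = nm.StimulusSpec(contrast=0.0, diameter=2.0)
        drive = nm.build_stimulus_drive(stim, grid, params)
        assert np.all(drive.values == 0)

    def test_aperture_center_and_far_field(self, grid):
        # unit exponent isolates the aperture geometry
        p = nm.ModelParams(contrast_gain_exponent=1.0)
        stim = nm.StimulusSpec(contrast=0.98, diameter=2.0)
        drive = nm.build_stimulus_drive(stim, grid, p)
        center = drive.values[grid.center_index, 0]
        # the blurred edge removes a ~6e-5 fraction even at the center
        assert center == pytest.approx(0.98, rel=1e-3)
        far = drive.values[np.argmin(np.abs(grid.positions - 4.0)), 0]
        assert far < 0.01 * 0.98

    def test_contrast_gain_scales_input(self, grid):
        p = nm.ModelParams(contrast_gain=0.5, contrast_gain_exponent=1.0)
        stim = nm.StimulusSpec(contrast=0.03, diameter=2.0)
        drive = nm.build_stimulus_drive(stim, grid, p)
        assert drive.values[grid.center_index, 0] == pytest.approx(0.015, rel=1e-3)

    def test_contrast_exponent_is_expansive(self, grid):
        p = nm.ModelParams(contrast_gain_exponent=2.0)
        stim = nm.StimulusSpec(contrast=0.03, diameter=2.0)
        drive = nm.build_stimulus_drive(stim, grid, p)
        assert drive.values[grid.center_index, 0] == pytest.approx(0.03 ** 2,
                                                                   rel=1e-3)

    def test_oversized_stimulus_raises_with_required_extent(self, params):
        grid = nm.SpatialGrid.for_stimuli(2.0, params)
        stim = nm.StimulusSpec(contrast=0.5, diameter=12.0)
        with pytest.raises(ValueError, match="deg"):
            nm.build_stimulus_drive(stim, grid, params)

    def test_sharp_edge_when_blur_zero(self, grid, params):
        stim = nm.StimulusSpec(contrast=1.0, diameter=2.0, edge_sd=0.0)
        drive = nm.build_stimulus_drive(stim, grid, params)
        assert set(np.unique(drive.values)) <= {0.0, 1.0}


class TestPooledDrive:
    def test_zero_in_zero_out(self, small_grid):
        zero = nm.PopulationResponse(
            values=np.zeros((small_grid.positions.size,
                             small_grid.features.size)), grid=small_grid)
        out = nm.pooled_drive(zero, 0.5, 30.0)
        assert np.all(out.values == 0)

    def test_uniform_field_unchanged(self, small_grid):
        c = 0.37
        uni = nm.PopulationResponse(
            values=np.full((small_grid.positions.size,
                            small_grid.features.size), c), grid=small_grid)
        out = nm.pooled_drive(uni, 0.5, 30.0)
        interior = out.values[40:-40]   # away from the zero-padded boundary
        assert np.allclose(interior, c, rtol=1e-6)

    def test_delta_input_gives_gaussian_profile(self, small_grid):
        """A point at the origin pools to the central row of the 2-D
        Gaussian kernel: k(x) * k(0) for the unit-sum 1-D factor k."""
        v = np.zeros((small_grid.positions.size, small_grid.features.size))
        ci = small_grid.center_index
        v[ci, 0] = 1.0
        out = nm.pooled_drive(nm.PopulationResponse(values=v, grid=small_grid),
                              space_width=0.5, feature_width=1e6)
        profile = out.values[:, 0] * small_grid.features.size
        x = small_grid.positions
        k = np.exp(-0.5 * (x / 0.5) ** 2)
        k[np.abs(x) > 5 * 0.5] = 0.0     # kernels truncate at 5 SD
        k /= k.sum()
        expected = k * k.max()
        # huge feature width spreads the delta evenly over directions
        assert np.allclose(profile, expected, atol=1e-12)

    @pytest.mark.parametrize("space_width,feature_width",
                             [(0.3, 25.0), (0.8, 60.0), (1.5, 120.0)])
    def test_matches_brute_force_oracle(self, small_grid, space_width,
                                        feature_width):
        rng = np.random.default_rng(7)
        v = rng.random((small_grid.positions.size, small_grid.features.size))
        resp = nm.PopulationResponse(values=v, grid=small_grid)
        out = nm.pooled_drive(resp, space_width, feature_width)
        oracle = brute_force_pool(v, small_grid.positions, small_grid.features,
                                  space_width, feature_width)
        assert np.max(np.abs(out.values - oracle)) < 1e-10

    def test_embedded_volume_conserved_and_row_consistent(self, grid, params):
        """The unit-volume 2-D kernel conserves the volume of the
        embedded circular field; the row-restricted implementation
        matches the full 2-D convolution's central row."""
        from scipy import ndimage
        stim = nm.StimulusSpec(contrast=0.9, diameter=2.0)
        drive = nm.build_stimulus_drive(stim, grid, params)
        out = nm.pooled_drive(drive, params.sup_space_width,
                              params.sup_feature_width)
        field = nm.radial_embed(drive.values[:, 0], grid.positions)
        k = nm._space_kernel(params.sup_space_width, grid.spacing,
                             grid.positions.size)
        full = ndimage.convolve1d(
            ndimage.convolve1d(field, k, axis=0, mode="constant", cval=0.0),
            k, axis=1, mode="constant", cval=0.0)
        assert full.sum() == pytest.approx(field.sum(), rel=1e-3)
        assert np.allclose(out.values[:, 0], full[grid.center_index],
                           atol=1e-12)

    def test_kernel_wider_than_grid_raises(self, small_grid):
        v = np.zeros((small_grid.positions.size, small_grid.features.size))
        resp = nm.PopulationResponse(values=v, grid=small_grid)
        with pytest.raises(ValueError, match="kernel"):
            nm.pooled_drive(resp, space_width=50.0, feature_width=30.0)


class TestNormalizedResponse:
    def test_zero_contrast_zero_response(self, grid, params):
        stim = nm.StimulusSpec(contrast=0.0, diameter=2.0)
        resp = nm.normalized_response(stim, grid, params)
        assert np.all(resp.values == 0)

    def test_equal_drives_with_unit_sigma_halve_response(self):
        # interior of a huge full-contrast stimulus: pooled E = S = 1
        p = nm.ModelParams(sigma=1.0, response_gain=1.3)
        grid = nm.SpatialGrid.for_stimuli(40.0, p)
        stim = nm.StimulusSpec(contrast=1.0, diameter=40.0, edge_sd=0.0)
        resp = nm.normalized_response(stim, grid, p)
        assert resp.values[grid.center_index, 0] == pytest.approx(
            0.5 * 1.3, rel=1e-3)

    def test_peak_size_dependence_by_contrast(self, grid, params):
        """High contrast: peak response falls with size; low contrast: the
        peak grows from 1 to 2 degrees (summation regime)."""
        def peak(contrast, diameter):
            stim = nm.StimulusSpec(contrast=contrast, diameter=diameter)
            return nm.readout_peak(nm.normalized_response(stim, grid, params))

        high = [peak(0.98, d) for d in (1.0, 2.0, 12.0)]
        assert high[0] > high[1] > high[2]
        assert peak(0.03, 2.0) > peak(0.03, 1.0)


class TestReadout:
    def test_uniform_and_zero_fields(self, small_grid):
        shape = (small_grid.positions.size, small_grid.features.size)
        assert nm.readout_peak(nm.PopulationResponse(
            values=np.full(shape, 2.5), grid=small_grid)) == 2.5
        assert nm.readout_peak(nm.PopulationResponse(
            values=np.zeros(shape), grid=small_grid)) == 0.0

    def test_peak_is_field_maximum(self, grid, params):
        stim = nm.StimulusSpec(contrast=0.98, diameter=2.0)
        resp = nm.normalized_response(stim, grid, params)
        assert nm.readout_peak(resp) == resp.values.max()

    def test_asymmetric_field_warns(self, small_grid):
        v = np.zeros((small_grid.positions.size, small_grid.features.size))
        v[3, 0] = 1.0
        resp = nm.PopulationResponse(values=v, grid=small_grid)
        with pytest.warns(UserWarning, match="symmetric"):
            nm.readout_peak(resp)


class TestPredictThreshold:
    @pytest.mark.parametrize("criterion,response,expected",
                             [(1.0, 2.0, 0.5), (2.0, 1.0, 2.0)])
    def test_direct_substitution(self, criterion, response, expected):
        assert nm.predict_threshold(response, criterion) == expected

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError, match="unresponsive"):
            nm.predict_threshold(0.0, 1.0)
        with pytest.raises(ValueError):
            nm.predict_threshold(1.0, -1.0)


class TestConditionTable:
    def test_si_sign_pattern(self, params):
        table = nm.predict_condition_table(params, criteria=DEFAULT_CRITERIA)
        si = table.size_indices
        assert (si.loc[si.contrast == 0.98, "si"] < 0).all()
        assert (si.loc[si.contrast == 0.03, "si"] > 0).all()

    def test_response_gain_scaling_halves_thresholds(self, params):
        base = nm.predict_condition_table(params, criteria=DEFAULT_CRITERIA)
        halved = nm.predict_condition_table(params.with_(response_gain=0.5),
                                            criteria=DEFAULT_CRITERIA)
        assert np.allclose(halved.thresholds.predicted_threshold_ms,
                           2 * base.thresholds.predicted_threshold_ms)
        assert (halved.size_indices.si.to_numpy()
                == base.size_indices.si.to_numpy()).all()

    @settings(max_examples=10, deadline=None)
    @given(k=st.floats(min_value=0.05, max_value=20.0,
                       allow_nan=False, allow_infinity=False))
    def test_criterion_invariance_of_si(self, k):
        """Scaling every criterion by k scales thresholds but cannot move
        any size index (the SI is a log-threshold difference)."""
        p = nm.ModelParams()
        crit = {c: v * k for c, v in DEFAULT_CRITERIA.items()}
        base = nm.predict_condition_table(p, criteria=DEFAULT_CRITERIA)
        scaled = nm.predict_condition_table(p, criteria=crit)
        assert (scaled.size_indices.si.to_numpy()
                == base.size_indices.si.to_numpy()).all()

    def test_sigma_sweep_flips_low_contrast_si(self):
        """Summation at 3% contrast requires sigma comparable to the
        suppressive drive; shrinking sigma far below it flips the SI."""
        big_sigma = nm.ModelParams(sigma=0.01)
        tiny_sigma = nm.ModelParams(sigma=1e-6)
        si_big = nm.predict_condition_table(
            big_sigma, contrasts=(0.03,)).size_indices
        si_tiny = nm.predict_condition_table(
            tiny_sigma, contrasts=(0.03,)).size_indices
        sb = lambda df: df.loc[df.larger_deg == 12.0, "si"].iloc[0]
        assert sb(si_big) > 0
        assert sb(si_tiny) < 0


class TestValidation:
    def test_param_invariants(self):
        with pytest.raises(ValueError):
            nm.ModelParams(sigma=0.0)
        with pytest.raises(ValueError, match="broader"):
            nm.ModelParams(exc_space_width=2.0, sup_space_width=1.0)
        with pytest.raises(ValueError):
            nm.ModelParams(response_gain=-1.0)

    def test_stimulus_invariants(self):
        with pytest.raises(ValueError):
            nm.StimulusSpec(contrast=1.2, diameter=1.0)
        with pytest.raises(ValueError):
            nm.StimulusSpec(contrast=0.5, diameter=-1.0)

    def test_grid_must_be_symmetric_and_uniform(self):
        with pytest.raises(ValueError, match="symmetric"):
            nm.SpatialGrid(positions=np.arange(0.0, 5.0, 0.1))
        with pytest.raises(ValueError, match="uniform"):
            nm.SpatialGrid(positions=np.array([-1.0, -0.5, 0.2, 0.5, 1.0]))
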