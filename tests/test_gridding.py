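"""Grid construction, shape correction and running average."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from elemap.gridding import (
    IntensityGrid,
    RasterGeometry,
    ShapeCorrection,
    apply_shape_correction,
    build_grids,
    running_average,
)
from elemap.segmentation import ScanTiming, segment_lines
from elemap.simulate import AcquisitionSpec, simulate_run
from elemap.tra import TRASeries

from conftest import two_phase_phantom


def grid_of(values, mask=None, pitch_x=1.0, pitch_y=1.0):
    return IntensityGrid(
        values=np.asarray(values, dtype=float),
        mask=mask,
        pitch_x=pitch_x,
        pitch_y=pitch_y,
        isotope_label="28Si",
    )


class TestBuildGrids:
    def test_single_line_column_centers_and_pitch(self):
        t = np.array([0.0, 0.5, 1.0, 30.0, 30.5, 31.0, 46.0])
        s = TRASeries(
            times=t,
            intensities=np.arange(7, dtype=float)[:, None],
            isotope_labels=["28Si"],
        )
        timing = ScanTiming(first_line_start=0.0, line_duration=1.5, line_interval=30.0, n_lines=2)
        seg = segment_lines(s, timing)
        g = build_grids(s, seg, RasterGeometry(raster_rate=10.0, line_spacing=5.0))["28Si"]
        assert g.pitch_x == pytest.approx(5.0)
        np.testing.assert_allclose(g.x_centers, [0.0, 5.0, 10.0])
        np.testing.assert_allclose(g.values[0], [0, 1, 2])

    def test_silicate_cadence_gives_3_dots_per_10_um(self, small_acq, clean_grids):
        g = clean_grids["28Si"]
        assert g.pitch_x == pytest.approx(3.5)
        assert 10.0 / g.pitch_x == pytest.approx(2.857, abs=0.01)

    def test_all_readings_preserved_as_multiset(self, small_acq, clean_run):
        seg = segment_lines(clean_run.series, small_acq.timing())
        grids = build_grids(clean_run.series, seg, small_acq.geometry())
        idx = seg.line_index_of(clean_run.series.times)
        for j, lab in enumerate(clean_run.series.isotope_labels):
            g = grids[lab]
            assert sorted(g.unmasked()) == sorted(clean_run.series.intensities[idx >= 0, j])

    def test_unequal_rows_padded_and_masked(self):
        # second line shortened: drop its last two readings
        t = np.concatenate([np.arange(0, 2.0, 0.5), np.arange(30, 31.0, 0.5), [70.0]])
        s = TRASeries(
            times=t,
            intensities=np.ones((t.size, 1)),
            isotope_labels=["28Si"],
        )
        timing = ScanTiming(first_line_start=0.0, line_duration=2.0, line_interval=30.0, n_lines=2)
        seg = segment_lines(s, timing)
        g = build_grids(s, seg, RasterGeometry(raster_rate=10.0, line_spacing=5.0))["28Si"]
        assert g.shape == (2, 4)
        assert g.mask[0].all()
        np.testing.assert_array_equal(g.mask[1], [True, True, False, False])

    def test_serpentine_reverses_odd_rows(self, small_acq, clean_run):
        seg = segment_lines(clean_run.series, small_acq.timing())
        geom = RasterGeometry(raster_rate=10.0, line_spacing=11.0, scan_direction="serpentine")
        g = build_grids(clean_run.series, seg, geom)["28Si"]
        ref = build_grids(clean_run.series, seg, small_acq.geometry())["28Si"]
        np.testing.assert_array_equal(
            g.values[0][g.mask[0]], ref.values[0][ref.mask[0]]
        )
        np.testing.assert_array_equal(
            g.values[1][g.mask[1]], ref.values[1][ref.mask[1]][::-1]
        )

    def test_noise_free_grid_equals_phantom_truth(self, clean_grids, clean_run):
        for lab, g in clean_grids.items():
            t = clean_run.truth.intensity[lab]
            np.testing.assert_array_equal(g.mask, t.mask)
            np.testing.assert_allclose(
                g.values[g.mask], t.values[t.mask], atol=1e-9
            )


class TestShapeCorrection:
    def test_zero_correction_is_identity(self, clean_grids):
        out = apply_shape_correction(clean_grids, ShapeCorrection())
        for lab in clean_grids:
            np.testing.assert_array_equal(out[lab].values, clean_grids[lab].values)
            np.testing.assert_array_equal(out[lab].mask, clean_grids[lab].mask)

    def test_integer_pitch_shift_translates_whole_cells(self):
        g = grid_of([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        out = apply_shape_correction(g, ShapeCorrection(per_line_offset=np.array([1.0, 0.0])))
        np.testing.assert_array_equal(out.mask[0], [False, True, True, True])
        np.testing.assert_allclose(out.values[0][1:], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(out.values[1], g.values[1])

    def test_fractional_shift_interpolates_linearly(self):
        g = grid_of([[0.0, 10.0, 20.0, 30.0]])
        out = apply_shape_correction(g, ShapeCorrection(per_line_offset=0.5))
        np.testing.assert_allclose(out.values[0][1:], [5.0, 15.0, 25.0])
        assert not out.mask[0][0]

    def test_per_file_offset_uses_row_provenance(self):
        g = IntensityGrid(
            values=np.tile([1.0, 2.0, 3.0], (2, 1)),
            pitch_x=1.0,
            pitch_y=1.0,
            row_files=np.array([0, 1]),
        )
        out = apply_shape_correction(g, ShapeCorrection(per_file_offset={1: 1.0}))
        np.testing.assert_array_equal(out.values[0], g.values[0])
        np.testing.assert_allclose(out.values[1][1:], [1.0, 2.0])

    def test_corrections_compose_additively(self):
        # linear interpolation is exact on affine rows, so composition can be
        # checked to round-off there; masks still mark the union of edges
        ramp = np.tile(np.arange(20.0) * 3.0 + 1.0, (3, 1))
        g = grid_of(ramp)
        once = apply_shape_correction(g, ShapeCorrection(shear=0.7))
        twice = apply_shape_correction(
            apply_shape_correction(g, ShapeCorrection(shear=0.4)),
            ShapeCorrection(shear=0.3),
        )
        both = np.asarray(once.mask & twice.mask)
        assert both.any()
        np.testing.assert_allclose(once.values[both], twice.values[both], atol=1e-9)

    def test_known_timing_error_recovered_by_shear(self):
        """A run emitted with a +0.5 s/line interval that the reader does not
        know about reconstructs slanted; shear = raster_rate * 0.5 um/line
        restores the unslanted truth."""
        acq_true = AcquisitionSpec(
            isotopes=("28Si", "24Mg", "56Fe"),
            raster_rate=10.0,
            line_spacing=11.0,
            line_length=100.0,
            n_lines=8,
            reading_interval=0.25,
            line_interval=15.5,
            first_line_start=5.0,
        )
        run = simulate_run(two_phase_phantom(background=0.0), acq_true)
        declared = ScanTiming(
            first_line_start=5.0, line_duration=10.0, line_interval=15.0, n_lines=8
        )
        seg = segment_lines(run.series, declared)
        grids = build_grids(run.series, seg, acq_true.geometry())
        g = grids["28Si"]
        truth = run.truth.intensity["28Si"]
        # slanted: late rows disagree with truth before correction
        before = np.abs(g.values[:, : truth.shape[1]] - truth.values)
        assert np.nanmax(before) > 0.1 * np.nanmax(truth.values)
        fixed = apply_shape_correction(g, ShapeCorrection(shear=-0.5 * 10.0))
        both = fixed.mask[:, : truth.shape[1]] & truth.mask
        err = np.abs(fixed.values[:, : truth.shape[1]][both] - truth.values[both])
        assert err.max() < 1e-6 * np.nanmax(truth.values)


class TestRunningAverage:
    def test_half_width_zero_is_identity(self, clean_grids):
        g = clean_grids["28Si"]
        out = running_average(g, 0)
        np.testing.assert_array_equal(out.values, g.values)

    def test_constant_row_unchanged(self):
        g = grid_of(np.full((2, 9), 7.0))
        out = running_average(g, 2)
        np.testing.assert_allclose(out.values, 7.0)

    def test_spike_spreads_to_five_cells_of_20(self):
        g = grid_of(np.zeros((1, 11)))
        g.values[0, 5] = 100.0
        out = running_average(g, 2)
        expected = np.zeros(11)
        expected[3:8] = 20.0
        np.testing.assert_allclose(out.values[0], expected)

    def test_mask_excluded_from_window_mean(self):
        vals = np.array([[1.0, np.nan, 3.0]])
        g = grid_of(vals)
        out = running_average(g, 1)
        np.testing.assert_allclose(out.values[0, 0], 1.0)
        np.testing.assert_allclose(out.values[0, 2], 3.0)
        assert not out.mask[0, 1]

    @given(const=st.floats(-50, 50), scale=st.floats(0.1, 10))
    def test_linear_and_commutes_with_constant_shift(self, const, scale):
        rng = np.random.default_rng(7)
        base = rng.uniform(0, 100, size=(2, 15))
        g1 = running_average(grid_of(base), 2).values
        g2 = running_average(grid_of(scale * base + const), 2).values
        np.testing.assert_allclose(g2, scale * g1 + const, atol=1e-9)
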