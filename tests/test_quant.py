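"""RSF calibration, normalization closures, ROI statistics, deviations."""
from __future__ import annotations

import numpy as np
import pytest

from elemap import constants
from elemap.exceptions import QuantError
from elemap.gridding import IntensityGrid, build_grids
from elemap.quant import (
    RSFTable,
    StandardTable,
    compute_rsf,
    deviation_table,
    quantify_internal,
    quantify_norm100,
    relative_response,
    roi_stats,
)
from elemap.refdata import phase_means, phase_reference, silicate_epma_comparison
from elemap.regions import ROIPolygon
from elemap.segmentation import estimate_background, segment_lines, subtract_background
from elemap.simulate import simulate_run, uniform_standard_run

from conftest import PHASE_A, PHASE_B, SENSITIVITIES, two_phase_phantom

STD_CONC = {"Si": 330000.0, "Mg": 465.0, "Fe": 458.0}


def response_grid(values, element="Si"):
    return IntensityGrid(
        values=np.asarray(values, dtype=float), pitch_x=1.0, pitch_y=1.0,
        isotope_label=element, unit="ug/g@alpha=1",
    )


@pytest.fixture(scope="module")
def std_rsf(small_acq):
    run = uniform_standard_run(STD_CONC, small_acq, SENSITIVITIES)
    seg = segment_lines(run.series, small_acq.timing())
    return compute_rsf(run.series, seg, StandardTable(STD_CONC, "glass"))


class TestComputeRSF:
    def test_mean_over_concentration(self, small_acq):
        run = uniform_standard_run({"Si": 500.0}, small_acq, {"Si": 2.0})
        seg = segment_lines(run.series, small_acq.timing())
        rsf = compute_rsf(run.series, seg, StandardTable({"Si": 500.0}))
        # mean standard intensity is eps*C = 1000 CPS at C = 500 ug/g
        assert rsf.sensitivities["28Si"] == pytest.approx(2.0)

    def test_noise_free_rsf_equals_simulator_sensitivity(self, std_rsf):
        for iso, el in std_rsf.isotope_to_element.items():
            assert std_rsf.sensitivities[iso] == pytest.approx(SENSITIVITIES[el], rel=1e-12)

    def test_two_isotopes_of_one_element_rejected(self):
        with pytest.raises(QuantError, match="one quantification isotope"):
            RSFTable(
                sensitivities={"24Mg": 1.0, "25Mg": 1.0},
                isotope_to_element={"24Mg": "Mg", "25Mg": "Mg"},
            )

    def test_missing_element_named(self, small_acq):
        run = uniform_standard_run(STD_CONC, small_acq, SENSITIVITIES)
        seg = segment_lines(run.series, small_acq.timing())
        with pytest.raises(QuantError, match="Fe"):
            compute_rsf(
                run.series, seg, StandardTable({"Si": 1.0, "Mg": 1.0}),
                isotopes=["28Si", "24Mg", "56Fe"],
            )


class TestRelativeResponse:
    def test_intensity_over_sensitivity(self):
        rsf = RSFTable({"28Si": 2.0}, {"28Si": "Si"})
        grids = {"28Si": response_grid([[2000.0, 0.0]], "28Si")}
        r = relative_response(grids, rsf)
        np.testing.assert_allclose(r["Si"].values, [[1000.0, 0.0]])

    def test_negative_responses_floored_with_warning(self):
        rsf = RSFTable({"28Si": 2.0}, {"28Si": "Si"})
        grids = {"28Si": response_grid([[-10.0, 4.0]], "28Si")}
        with pytest.warns(UserWarning, match="floored"):
            r = relative_response(grids, rsf)
        assert r["Si"].values[0, 0] == 0.0


class TestNorm100:
    def test_two_elements_unity_factors(self):
        responses = {
            "A_": response_grid([[60.0]]),
            "B_": response_grid([[40.0]]),
        }
        # unknown oxide stoichiometry -> factor 1 with a warning
        with pytest.warns(UserWarning, match="stoichiometry"):
            out = quantify_norm100(responses, oxide_mode=True)
        assert out.concentrations["A_"].values[0, 0] == pytest.approx(60.0)
        assert out.concentrations["B_"].values[0, 0] == pytest.approx(40.0)

    def test_scale_invariance_per_pixel(self, rng):
        base = {el: rng.uniform(10, 100, size=(3, 4)) for el in ("Si", "Mg", "Fe")}
        r1 = {el: response_grid(v, el) for el, v in base.items()}
        r5 = {el: response_grid(5.0 * v, el) for el, v in base.items()}
        out1 = quantify_norm100(r1)
        out5 = quantify_norm100(r5)
        for sp in out1.concentrations:
            np.testing.assert_allclose(
                out1.concentrations[sp].values, out5.concentrations[sp].values, rtol=1e-12
            )
        np.testing.assert_allclose(out1.alpha.values, 5.0 * out5.alpha.values, rtol=1e-12)

    def test_conservation_at_every_pixel(self, rng):
        responses = {
            el: response_grid(rng.uniform(0, 500, size=(6, 10)), el)
            for el in ("Si", "Mg", "Fe", "Al", "Ca")
        }
        out = quantify_norm100(responses, oxide_mode=True)
        total = sum(g.values for g in out.concentrations.values())
        ok = out.alpha.mask
        np.testing.assert_allclose(total[ok], 100.0, atol=1e-9)

    def test_element_mode_sums_to_one(self, rng):
        responses = {
            el: response_grid(rng.uniform(1, 500, size=(4, 4)), el)
            for el in ("Si", "Mg")
        }
        out = quantify_norm100(responses, oxide_mode=False)
        total = sum(g.values for g in out.concentrations.values())
        np.testing.assert_allclose(total[out.alpha.mask], 1.0, atol=1e-12)

    def test_all_zero_pixel_masked(self):
        responses = {
            "Si": response_grid([[0.0, 10.0]]),
            "Mg": response_grid([[0.0, 10.0]]),
        }
        out = quantify_norm100(responses)
        assert not out.alpha.mask[0, 0]
        assert out.alpha.mask[0, 1]


@pytest.fixture(scope="module")
def recovered(clean_grids, std_rsf):
    responses = relative_response(clean_grids, std_rsf)
    return quantify_norm100(responses, oxide_mode=True)


class TestEndToEndRecovery:
    def test_noise_free_phantom_recovered_exactly(self, recovered, clean_run):
        for species, grid in recovered.concentrations.items():
            truth = clean_run.truth.oxide_wt[species]
            ok = grid.mask & truth.mask
            np.testing.assert_allclose(
                grid.values[ok], truth.values[ok], rtol=1e-9
            )

    def test_internal_standard_agrees_with_norm100(self, recovered, clean_run, clean_grids, std_rsf):
        """When the phantom's composition sums to 100% and the internal
        element's true map is supplied, both closures coincide."""
        responses = relative_response(clean_grids, std_rsf)
        truth_si = clean_run.truth.conc_ugg["Si"]
        out = quantify_internal(responses, "Si", truth_si.values)
        f = constants.oxide_factor("Si")
        np.testing.assert_allclose(
            out.concentrations["Si"].values[out.alpha.mask] * f * 1e-4,
            recovered.concentrations["SiO2"].values[out.alpha.mask],
            rtol=1e-9,
        )

    def test_internal_identity_calibration(self):
        responses = {
            "Si": response_grid([[250000.0]]),
            "Mg": response_grid([[1000.0]]),
        }
        out = quantify_internal(responses, "Si", 250000.0)
        assert out.alpha.values[0, 0] == pytest.approx(1.0)
        assert out.concentrations["Mg"].values[0, 0] == pytest.approx(1000.0)

    def test_internal_scale_invariance(self):
        r1 = {"Si": response_grid([[100.0]]), "Mg": response_grid([[40.0]])}
        r2 = {"Si": response_grid([[200.0]]), "Mg": response_grid([[80.0]])}
        o1 = quantify_internal(r1, "Si", 500.0)
        o2 = quantify_internal(r2, "Si", 500.0)
        np.testing.assert_allclose(
            o1.concentrations["Mg"].values, o2.concentrations["Mg"].values
        )

    def test_poisson_noise_recovery_within_counting_statistics(self, small_acq):
        """With ~1e4+ counts per reading, recovered major-species wt% match
        the phantom within a few percent (median over pixels)."""
        eps = {"Si": 40.0, "Mg": 45.0, "Fe": 50.0}
        phantom = two_phase_phantom(noise="poisson", seed=11)
        phantom = type(phantom)(
            width=phantom.width, height=phantom.height, phases=phantom.phases,
            sensitivities=eps, background_cps=50.0, noise="poisson", seed=11,
        )
        run = simulate_run(phantom, small_acq)
        seg = segment_lines(run.series, small_acq.timing())
        bg = estimate_background(run.series, seg)
        sub = subtract_background(run.series, seg, bg)
        grids = build_grids(sub, seg, small_acq.geometry())

        std = uniform_standard_run(
            STD_CONC, small_acq, eps, background_cps=50.0, noise="poisson", seed=12
        )
        std_seg = segment_lines(std.series, small_acq.timing())
        std_bg = estimate_background(std.series, std_seg)
        std_sub = subtract_background(std.series, std_seg, std_bg)
        rsf = compute_rsf(std_sub, std_seg, StandardTable(STD_CONC))

        out = quantify_norm100(relative_response(grids, rsf), oxide_mode=True)
        rel_errors = []
        for species, grid in out.concentrations.items():
            truth = simulate_run(phantom, small_acq).truth.oxide_wt[species]
            ok = grid.mask & truth.mask & (truth.values > 1.0)
            rel_errors.append(np.abs(grid.values[ok] / truth.values[ok] - 1.0))
        med = np.median(np.concatenate(rel_errors))
        assert med < 0.05


class TestROIStats:
    def test_single_pixel_region(self):
        out = quantify_norm100(
            {"Si": response_grid(np.full((3, 3), 60.0)),
             "Mg": response_grid(np.full((3, 3), 40.0))},
            oxide_mode=False,
        )
        stats = roi_stats(out, ROIPolygon.rectangle("px", 0.8, 0.8, 1.2, 1.2))
        assert stats.loc["Si", "n"] == 1
        assert np.isnan(stats.loc["Si", "sd"])

    def test_constant_region_sd_zero(self):
        out = quantify_norm100(
            {"Si": response_grid(np.full((3, 3), 60.0)),
             "Mg": response_grid(np.full((3, 3), 40.0))},
            oxide_mode=False,
        )
        stats = roi_stats(out, (-0.5, -0.5, 2.5, 2.5))
        assert stats.loc["Mg", "mean"] == pytest.approx(0.4)
        assert stats.loc["Mg", "sd"] == 0.0
        assert stats.loc["Mg", "n"] == 9

    def test_phase_mean_within_sampling_error(self, small_acq):
        phantom = two_phase_phantom(noise="poisson", seed=5)
        run = simulate_run(phantom, small_acq)
        seg = segment_lines(run.series, small_acq.timing())
        bg = estimate_background(run.series, seg)
        grids = build_grids(subtract_background(run.series, seg, bg), seg, small_acq.geometry())
        std = uniform_standard_run(STD_CONC, small_acq, SENSITIVITIES)
        std_seg = segment_lines(std.series, small_acq.timing())
        rsf = compute_rsf(std.series, std_seg, StandardTable(STD_CONC))
        out = quantify_norm100(relative_response(grids, rsf))
        stats = roi_stats(out, (5.0, 5.0, 40.0, 60.0))
        row = stats.loc["SiO2"]
        assert row["mean"] == pytest.approx(
            PHASE_A["Si"], abs=max(4 * row["sd"] / np.sqrt(row["n"]), 0.5)
        )


class TestDeviationTable:
    def test_published_comparison_rows(self):
        df = deviation_table({"SiO2": 58.00}, {"SiO2": 54.36})
        assert df.loc["SiO2", "deviation"] == pytest.approx(0.067, abs=5e-4)
        df = deviation_table({"Al2O3": 4.88}, {"Al2O3": 5.64})
        assert df.loc["Al2O3", "deviation_raw"] == pytest.approx(-0.1348, abs=5e-4)

    def test_equal_values_deviate_zero(self):
        df = deviation_table({"MgO": 3.0}, {"MgO": 3.0})
        assert df.loc["MgO", "deviation"] == 0.0

    def test_zero_reference_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            df = deviation_table({"CaO": 1.0, "MgO": 2.0}, {"CaO": 0.0, "MgO": 4.0})
        assert list(df.index) == ["MgO"]

    def test_full_reference_table_arithmetic(self):
        """The bundled EPMA comparison's printed deviations agree with the
        recomputed (ICPMS/EPMA)-1 arithmetic at the printed precision."""
        df = silicate_epma_comparison()
        for phase in ("garnet", "wadsleyite"):
            meas = phase_means(df, phase)
            ref = phase_reference(df, phase)
            dev = deviation_table(meas, ref)
            printed = df[(df["phase"] == phase) & df["deviation_printed"].notna()]
            for _, row in printed.iterrows():
                sp = row["species"]
                if row["epma_wt"] >= 1.0:  # printed means rounded too coarsely below
                    assert dev.loc[sp, "deviation_raw"] == pytest.approx(
                        row["deviation_printed"], abs=1.5e-3
                    )
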