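"""LET engine: conversions, averages, LET_cut, uncertainty budget."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pixelet import (DetectorConfig, GeometryConfig, RecalibrationParams,
                     Spectrum, dose_avg_events, edep_to_let, histogram_events,
                     let_dose_avg, let_si_to_water, let_track_avg,
                     propagate_let_uncertainty, saturate, scenario_params,
                     recalibrate, separate_by_let_cut, track_avg_events,
                     water_equivalent_depth)
from pixelet.calibration import KEV_PER_MEV
from pixelet.errors import (SeparationError, UndefinedAverageError, UsageError)

from conftest import random_spectrum


def make_spectrum(edges, weights, quantity="let", medium="water"):
    return Spectrum(np.asarray(edges, float), np.asarray(weights, float),
                    quantity=quantity, medium=medium)


class TestConversions:
    def test_energy_to_silicon_let_unit_ratio(self):
        det = DetectorConfig()
        spec = make_spectrum([0.0, 137.0, 1370.0], [5.0, 3.0],
                             quantity="energy", medium=None)
        si = edep_to_let(spec, det)
        assert si.medium == "silicon" and si.quantity == "let"
        assert si.edges[1] == pytest.approx(1.00)
        assert si.edges[2] == pytest.approx(10.0)
        assert si.total == spec.total  # fluence conserved exactly

    def test_si_to_water_factor(self):
        det = DetectorConfig()
        si = make_spectrum([0.5, 1.5], [1.0], medium="silicon")
        water = let_si_to_water(si, det)
        assert water.midpoints[0] == pytest.approx(0.541)
        assert water.medium == "water"
        with pytest.raises(UsageError):
            let_si_to_water(water, det)

    def test_factor_one_is_identity(self):
        det = DetectorConfig(si_to_water_factor=1.0)
        si = make_spectrum([0.0, 1.0, 2.0], [1.0, 2.0], medium="silicon")
        water = let_si_to_water(si, det)
        np.testing.assert_allclose(water.edges, si.edges)

    def test_conversion_commutes_with_averaging(self, rng):
        det = DetectorConfig()
        si = random_spectrum(rng, medium="silicon")
        water = let_si_to_water(si, det)
        assert let_dose_avg(water) == pytest.approx(0.541 * let_dose_avg(si), rel=1e-12)
        assert let_track_avg(water) == pytest.approx(0.541 * let_track_avg(si), rel=1e-12)


class TestAverages:
    def test_monoenergetic(self):
        spec = make_spectrum([4.5, 5.5], [7.0])
        assert let_track_avg(spec) == let_dose_avg(spec) == pytest.approx(5.0)

    def test_two_point_arithmetic(self):
        spec = make_spectrum([0.5, 1.5, 2.5, 3.5], [1.0, 0.0, 1.0])
        assert let_track_avg(spec) == pytest.approx(2.0)
        assert let_dose_avg(spec) == pytest.approx(2.5)

    def test_matches_unbinned_oracle(self, rng):
        # Oracle: direct summation over the synthetic event list, binned with
        # events exactly at bin midpoints so binning introduces no error.
        edges = np.arange(51, dtype=float)
        counts = rng.integers(0, 20, size=50)
        events = np.repeat(edges[:-1] + 0.5, counts)
        spec = Spectrum(edges, counts.astype(float), quantity="let", medium="water")
        assert let_track_avg(spec) == pytest.approx(events.mean(), rel=1e-12)
        assert let_dose_avg(spec) == pytest.approx(
            (events**2).sum() / events.sum(), rel=1e-12)
        assert track_avg_events(events) == pytest.approx(events.mean())
        assert dose_avg_events(events) == pytest.approx((events**2).sum() / events.sum())

    def test_dose_avg_dominates_track_avg(self, rng):
        for _ in range(100):
            spec = random_spectrum(rng)
            assert let_dose_avg(spec) >= let_track_avg(spec) - 1e-12

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=30)
    def test_scale_invariance_property(self, seed):
        spec = random_spectrum(np.random.default_rng(seed))
        scaled = spec.replace(weights=spec.weights * 7.5)
        assert let_track_avg(scaled) == pytest.approx(let_track_avg(spec), rel=1e-12)
        assert let_dose_avg(scaled) == pytest.approx(let_dose_avg(spec), rel=1e-12)

    def test_zero_fluence_rejected(self):
        spec = make_spectrum([0.0, 1.0], [0.0])
        with pytest.raises(UndefinedAverageError):
            let_track_avg(spec)
        with pytest.raises(UndefinedAverageError):
            let_dose_avg(spec)


class TestLetCut:
    def bimodal(self):
        edges = np.linspace(0.0, 15.0, 151)
        mids = 0.5 * (edges[:-1] + edges[1:])
        w = 400 * np.exp(-0.5 * ((mids - 1.0) / 0.3) ** 2) \
            + 900 * np.exp(-0.5 * ((mids - 10.0) / 1.0) ** 2)
        return Spectrum(edges, w, quantity="let", medium="water")

    def test_cut_falls_in_the_valley(self):
        spec = self.bimodal()
        hyd, he, cut = separate_by_let_cut(spec)
        assert 2.0 < cut < 8.0
        # component fluences recover the two modes' weights
        assert hyd.total == pytest.approx(400 * np.sqrt(2 * np.pi) * 0.3 / 0.1, rel=0.02)
        assert he.total == pytest.approx(900 * np.sqrt(2 * np.pi) * 1.0 / 0.1, rel=0.02)

    def test_partition_conserves_fluence(self):
        spec = self.bimodal()
        hyd, he, _ = separate_by_let_cut(spec)
        np.testing.assert_allclose(hyd.weights + he.weights, spec.weights)

    def test_unimodal_rejected(self):
        edges = np.linspace(0.0, 10.0, 101)
        mids = 0.5 * (edges[:-1] + edges[1:])
        w = np.exp(-0.5 * ((mids - 5.0) / 1.0) ** 2)
        with pytest.raises(SeparationError):
            separate_by_let_cut(Spectrum(edges, w, quantity="let", medium="water"))


class TestWaterEquivalentDepth:
    @pytest.mark.parametrize("depth,expected", [(100.0, 115.8), (0.0, 0.0), (42.0, 48.636)])
    def test_rsp_scaling(self, depth, expected):
        wed, _ = water_equivalent_depth(depth, GeometryConfig())
        assert wed == pytest.approx(expected, rel=1e-12)

    def test_uncertainty_scales_with_depth(self):
        _, u = water_equivalent_depth(100.0, GeometryConfig())
        assert u == pytest.approx(0.8)


class TestUncertaintyPropagation:
    def test_all_sigmas_zero_gives_zero_combined(self, rng):
        det = DetectorConfig(u_thickness_um=0.0)
        recal = RecalibrationParams(u_k=0.0, u_p=0.0, u_q=0.0)
        e = rng.uniform(100, 1000, size=200)
        res = propagate_let_uncertainty(e, det, recal)
        assert res.u_let_t == 0.0 and res.u_let_d == 0.0
        assert res.u_stat_t > 0  # type A still reported, separately

    def test_thickness_only_is_exactly_relative(self, rng):
        det = DetectorConfig(u_thickness_um=3.0)
        recal = RecalibrationParams(u_k=0.0, u_p=0.0, u_q=0.0)
        e = rng.uniform(100, 1000, size=200)
        res = propagate_let_uncertainty(e, det, recal)
        assert res.u_let_t / res.let_t == pytest.approx(3.0 / 137.0, rel=1e-12)
        assert res.u_let_d / res.let_d == pytest.approx(3.0 / 137.0, rel=1e-12)

    def test_combined_equals_componentwise_quadrature_oracle(self, rng):
        det = DetectorConfig()
        recal = RecalibrationParams()
        e_kev = rng.uniform(100, 2000, size=1000)
        sys_rel = 0.01
        res = propagate_let_uncertainty(e_kev, det, recal, systematic_rel=sys_rel)

        # Oracle: recompute every component independently from first principles.
        def water_let_avgs(pars, thickness):
            rec = recalibrate(e_kev / KEV_PER_MEV, pars) * KEV_PER_MEV
            L = rec / thickness * det.si_to_water_factor
            return L.mean(), (L**2).sum() / L.sum()

        t_mean, d_mean = water_let_avgs(recal, det.depleted_thickness_um)
        t_up, d_up = water_let_avgs(scenario_params(recal, "upper"), det.depleted_thickness_um)
        t_lo, d_lo = water_let_avgs(scenario_params(recal, "lower"), det.depleted_thickness_um)
        u_recal_t = 0.5 * abs(t_up - t_lo)
        u_recal_d = 0.5 * abs(d_up - d_lo)
        u_thick_t = t_mean * det.u_thickness_um / det.depleted_thickness_um
        u_thick_d = d_mean * det.u_thickness_um / det.depleted_thickness_um
        exp_t = np.sqrt(u_recal_t**2 + u_thick_t**2 + (sys_rel * t_mean)**2)
        exp_d = np.sqrt(u_recal_d**2 + u_thick_d**2 + (sys_rel * d_mean)**2)
        assert res.let_t == pytest.approx(t_mean, rel=1e-12)
        assert res.let_d == pytest.approx(d_mean, rel=1e-12)
        assert res.u_let_t == pytest.approx(exp_t, rel=1e-10)
        assert res.u_let_d == pytest.approx(exp_d, rel=1e-10)

    def test_recalibration_beats_no_correction_across_replicates(self):
        """Recalibrated LET_d is closer to the ground truth than uncorrected
        LET_d in >= 95% of seeded replicates of a saturated beam."""
        from pixelet import BeamScenario, sample_true_events
        det = DetectorConfig()
        recal = RecalibrationParams()
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            sc = BeamScenario(species="helium", depth_pmma=125.0,
                              n_primaries=400, seed=seed)
            e_true = sample_true_events(sc)["e_dep_true"].to_numpy()
            e_meas = saturate(e_true / KEV_PER_MEV, recal) * KEV_PER_MEV
            truth_d = dose_avg_events(e_true / det.depleted_thickness_um
                                      * det.si_to_water_factor)
            rec_d = propagate_let_uncertainty(e_meas, det, recal).let_d
            raw_d = dose_avg_events(e_meas / det.depleted_thickness_um
                                    * det.si_to_water_factor)
            if abs(rec_d - truth_d) < abs(raw_d - truth_d):
                wins += 1
        assert wins >= 0.95 * n_rep


class TestHistogramming:
    def test_half_open_bins_and_species_widths(self):
        spec = histogram_events([0.5, 1.0, 1.5], species="proton", bin_width=1.0)
        # value 1.0 falls in [1, 2), not [0, 1)
        assert spec.weights[0] == 1.0 and spec.weights[1] == 2.0

    def test_default_widths_follow_stated_ranges(self):
        from pixelet.let import default_bin_width
        assert 1.0 <= default_bin_width("proton", 200.0) <= 30.0
        assert 1.0 <= default_bin_width("proton", 5000.0) <= 30.0
        assert 10.0 <= default_bin_width("helium", 800.0) <= 400.0
        assert 10.0 <= default_bin_width("helium", 20000.0) <= 400.0
        # wider spectra never get narrower bins
        for sp in ("proton", "helium"):
            widths = [default_bin_width(sp, v) for v in (100, 1000, 5000, 20000)]
            assert widths == sorted(widths)
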