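import dataclasses

import numpy as np
import pytest

from nucphase.phasing import (
    PeakSet,
    compare_conditions,
    detect_peaks,
    occupancy_change,
    summarize_phasing,
)
from nucphase.pipeline import profile_from_fragments, run_synthetic_cohort
from nucphase.profile import aggregate, normalize, smooth
from nucphase.simulate import (
    ArrayModel,
    DigestionModel,
    ScenarioSpec,
    scenario_presets,
    simulate_chip_fragments,
    simulate_fragments,
    simulate_sites,
)

from conftest import make_profile


def noiseless_spec(seed=0, **array_kw):
    array = ArrayModel(
        jitter_sd0=0.0,
        jitter_growth=0.0,
        background_rate=0.0,
        bound_fraction=1.0,
        **array_kw,
    )
    return ScenarioSpec("control", array, DigestionModel(overhang_mean=0.0), seed=seed)


class TestDetectPeaks:
    def test_cosine_peaks_at_period_multiples(self):
        offs = np.arange(-1000, 1001)
        prof = make_profile(2.0 + np.cos(2 * np.pi * offs / 200.0))
        peaks = detect_peaks(prof, min_separation=120)
        # window-edge maxima at +/-1000 are not interior local maxima
        np.testing.assert_allclose(
            peaks.peak_offsets, [-800, -600, -400, -200, 0, 200, 400, 600, 800],
            atol=1e-6,
        )

    def test_flat_profile_yields_empty_set(self, flat_profile):
        assert detect_peaks(flat_profile).peak_offsets.size == 0

    def test_equal_maxima_within_separation_keep_closer_to_anchor(self):
        values = np.ones(2001)
        values[1000 - 30] = values[1000 + 30] = 5.0  # equal peaks 60 bp apart
        prof = make_profile(values)
        peaks = detect_peaks(prof, min_separation=120, refine=False)
        assert list(peaks.peak_offsets) == [-30]

    def test_noiseless_lattice_recovered_exactly(self):
        sites = simulate_sites(50, 600_000, 3000, seed=1)
        frags, _ = simulate_fragments(sites, noiseless_spec())
        prof = profile_from_fragments(frags, sites, half_window=1000, smooth_bp=50)
        peaks = detect_peaks(prof)
        d, nrl = 280, 176
        expected = sorted(
            s * (d / 2 + k * nrl) for s in (-1, 1) for k in range(5)
        )
        np.testing.assert_allclose(peaks.peak_offsets, expected, atol=1e-9)

    def test_offsets_strictly_increasing_invariant(self):
        with pytest.raises(ValueError):
            PeakSet(np.array([10.0, 10.0]), 0.25)


class TestSummarizePhasing:
    def test_constructed_lattice_arithmetic(self, flat_profile):
        peaks = PeakSet(np.array([-303.0, -127.0, 127.0, 303.0, 479.0]), 0.25)
        s = summarize_phasing(flat_profile, peaks)
        assert s.plus_one == 127 and s.minus_one == -127
        assert s.p1m1_distance == 254
        assert s.nrl_right == pytest.approx(176.0)
        assert s.nrl_left == pytest.approx(176.0)
        assert s.nrl == pytest.approx(176.0)
        assert s.n_peaks_used_per_side == (2, 3)

    def test_single_flank_case(self, flat_profile):
        s = summarize_phasing(flat_profile, PeakSet(np.array([150.0, 330.0]), 0.25))
        assert s.nrl_right == pytest.approx(180.0)
        assert s.nrl == pytest.approx(180.0)
        assert s.p1m1_distance is None and s.minus_one is None

    def test_translation_invariance_of_slope(self, flat_profile):
        base = np.array([130.0, 310.0, 490.0])
        s1 = summarize_phasing(flat_profile, PeakSet(base, 0.25))
        s2 = summarize_phasing(flat_profile, PeakSet(base + 37.0, 0.25))
        assert s1.nrl_right == pytest.approx(s2.nrl_right)

    def test_no_flank_peaks_raises(self, flat_profile):
        with pytest.raises(ValueError, match="no peaks"):
            summarize_phasing(flat_profile, PeakSet(np.array([0.0]), 0.25))

    def test_control_cohort_recovers_generator_nrl(self):
        # parameter recovery across independent seeds of the control preset
        control = scenario_presets()["control"]
        estimates = [
            run_synthetic_cohort(control, n_sites=800, seed=seed).summary.nrl
            for seed in range(20)
        ]
        assert abs(np.mean(estimates) - control.array.nrl) <= 2.0

    def test_preset_nrl_difference_recovered(self):
        presets = scenario_presets()
        deltas = []
        for seed in range(8):
            c = run_synthetic_cohort(presets["control"], n_sites=800, seed=seed)
            e = run_synthetic_cohort(presets["snf2h_depleted"], n_sites=800, seed=seed)
            deltas.append(e.summary.nrl - c.summary.nrl)
        expected = presets["snf2h_depleted"].array.nrl - presets["control"].array.nrl
        assert abs(np.mean(deltas) - expected) <= 2.0


class TestCompareConditions:
    def _cohorts(self):
        presets = scenario_presets()
        c = run_synthetic_cohort(presets["control"], n_sites=400, seed=3)
        e = run_synthetic_cohort(presets["snf2h_depleted"], n_sites=400, seed=3)
        return c, e

    def test_identical_inputs_zero_deltas(self):
        c, _ = self._cohorts()
        d = compare_conditions(c.summary, c.profile, c.summary, c.profile)
        assert d.delta_p1m1 == 0 and d.delta_nrl == 0 and d.delta_center_occupancy == 0

    def test_antisymmetry(self):
        c, e = self._cohorts()
        fwd = compare_conditions(c.summary, c.profile, e.summary, e.profile)
        rev = compare_conditions(e.summary, e.profile, c.summary, c.profile)
        assert fwd.delta_p1m1 == pytest.approx(-rev.delta_p1m1)
        assert fwd.delta_nrl == pytest.approx(-rev.delta_nrl)
        assert fwd.delta_center_occupancy == pytest.approx(-rev.delta_center_occupancy)

    def test_known_nrl_shifts(self, flat_profile):
        def summary_with_nrl(nrl):
            half = 140.0
            peaks = PeakSet(
                np.array([-(half + nrl), -half, half, half + nrl]), 0.25
            )
            return summarize_phasing(flat_profile, peaks)

        d = compare_conditions(
            summary_with_nrl(176), flat_profile, summary_with_nrl(183), flat_profile
        )
        assert d.delta_nrl == pytest.approx(7.0)
        d2 = compare_conditions(
            summary_with_nrl(176), flat_profile, summary_with_nrl(173), flat_profile
        )
        assert d2.delta_nrl == pytest.approx(-3.0)

    def test_missing_flank_raises(self, flat_profile):
        good = summarize_phasing(
            flat_profile, PeakSet(np.array([-316.0, -140.0, 140.0, 316.0]), 0.25)
        )
        bad = summarize_phasing(flat_profile, PeakSet(np.array([150.0, 330.0]), 0.25))
        with pytest.raises(ValueError, match="experimental"):
            compare_conditions(good, flat_profile, bad, flat_profile)

    def test_mismatched_digestion_warns(self, flat_profile):
        s = summarize_phasing(
            flat_profile, PeakSet(np.array([-316.0, -140.0, 140.0, 316.0]), 0.25)
        )
        with pytest.warns(UserWarning, match="digestion"):
            compare_conditions(s, flat_profile, s, flat_profile, digestion_matched=False)


class TestOccupancyChange:
    def _bump_profile(self, height):
        offs = np.arange(-1000, 1001)
        return make_profile(1.0 + height * np.exp(-0.5 * (offs / 40.0) ** 2))

    def test_identical_profiles_zero(self):
        p = self._bump_profile(3.0)
        assert occupancy_change(p, p) == pytest.approx(0.0)

    def test_half_bump_is_fifty_percent(self):
        # experimental bump exactly half the control's above the flat background
        full, half = self._bump_profile(2.0), self._bump_profile(1.0)
        # central band mean scales linearly with bump height over a flat bg of 1
        assert occupancy_change(full, half) == pytest.approx(50.0, abs=1e-6)

    def test_chip_cohorts_recover_enrichment_reduction(self):
        # peak/background ratios 10 vs 4.6: reduction (9 - 3.6) / 9 = 60%
        sites = simulate_sites(300, 3_000_000, 4000, seed=9)
        kw = dict(peak_sd=100.0, n_fragments=400_000, frag_len_mean=200, seed=9)
        control = simulate_chip_fragments(sites, enrichment=10.0, **kw)
        depleted = simulate_chip_fragments(sites, enrichment=4.6, **kw)
        profs = [
            profile_from_fragments(f, sites, half_window=1000, smooth_bp=50)
            for f in (control, depleted)
        ]
        change = occupancy_change(profs[0], profs[1], center_halfwidth=100)
        assert change == pytest.approx(60.0, abs=6.0)

    def test_zero_control_signal_raises(self, flat_profile):
        with pytest.raises(ValueError):
            occupancy_change(flat_profile, flat_profile)
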