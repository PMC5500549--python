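import numpy as np
import pytest

from polbind import (
    LaneTrace,
    assign_lengths,
    calibrate_ladder,
    processivity_estimate,
    simulate_gel_lanes,
    single_hit_check,
)
from polbind.errors import CalibrationError, ContractError
from polbind.gel import LengthDistribution

from conftest import LADDER_LENGTHS

A_TRUE, B_TRUE = 600.0, 80.0


def exact_ladder_trace(a=A_TRUE, b=B_TRUE, lengths=LADDER_LENGTHS):
    """Trace whose local maxima sit exactly at a − b·log(L)."""
    centers = sorted(a - b * np.log(L) for L in lengths)
    migration, intensity = [], []
    for i, m in enumerate(centers):
        if i == 0:
            migration.append(m - 1.0)
            intensity.append(0.0)
        migration.append(m)
        intensity.append(1.0)
        migration.append(m + 1.0 if i == len(centers) - 1 else (m + centers[i + 1]) / 2)
        intensity.append(0.0)
    return LaneTrace(np.array(migration), np.array(intensity), role="ladder")


class TestLadderCalibration:
    def test_exact_model_recovers_parameters(self):
        cal = calibrate_ladder(exact_ladder_trace(), LADDER_LENGTHS)
        assert cal.a == pytest.approx(A_TRUE, abs=1e-9)
        assert cal.b == pytest.approx(B_TRUE, abs=1e-9)
        assert np.allclose(cal.residuals, 0.0, atol=1e-9)

    def test_midpoint_band_maps_to_geometric_mean(self):
        cal = calibrate_ladder(exact_ladder_trace(), LADDER_LENGTHS)
        m1 = cal.migration_at(100.0)
        m2 = cal.migration_at(200.0)
        assert cal.length_at((m1 + m2) / 2.0) == pytest.approx(np.sqrt(100.0 * 200.0), rel=1e-9)

    def test_anchor_order_invariance(self):
        shuffled = [200, 800, 50, 400, 100, 600, 300, 700, 500]
        cal_a = calibrate_ladder(exact_ladder_trace(), LADDER_LENGTHS)
        cal_b = calibrate_ladder(exact_ladder_trace(), shuffled)
        assert cal_b.a == pytest.approx(cal_a.a, abs=1e-12)
        assert cal_b.b == pytest.approx(cal_a.b, abs=1e-12)

    def test_peak_count_mismatch(self):
        with pytest.raises(CalibrationError):
            calibrate_ladder(exact_ladder_trace(), [50, 100, 200])


class TestAssignLengths:
    def test_fluorophore_offset_maps_apparent_80_to_36(self):
        cal = calibrate_ladder(exact_ladder_trace(), LADDER_LENGTHS)
        m80 = float(cal.migration_at(80.0))
        lane = LaneTrace(np.array([m80 - 1, m80, m80 + 1]),
                         np.array([0.0, 5.0, 0.0]))
        dist = assign_lengths(lane, cal, mobility_offset=44.0)
        assert dist.lengths[np.argmax(dist.intensity)] == 36

    def test_zero_offset_is_identity_shift(self):
        cal = calibrate_ladder(exact_ladder_trace(), LADDER_LENGTHS)
        m = float(cal.migration_at(100.0))
        lane = LaneTrace(np.array([m - 1, m, m + 1]), np.array([0.0, 3.0, 0.0]))
        dist = assign_lengths(lane, cal, mobility_offset=0.0)
        assert dist.lengths[np.argmax(dist.intensity)] == 100

    def test_total_intensity_conserved(self):
        lane, ladder = simulate_gel_lanes({50: 1.0, 120: 2.0}, noise_sd=0.001, seed=5)
        cal = calibrate_ladder(ladder, LADDER_LENGTHS)
        dist = assign_lengths(lane, cal, mobility_offset=44.0)
        assert dist.intensity.sum() == pytest.approx(lane.intensity.sum(), rel=1e-9)

    def test_extrapolation_recorded_as_warning(self):
        cal = calibrate_ladder(exact_ladder_trace(), LADDER_LENGTHS)
        lane = LaneTrace(np.array([1.0, 2.0]), np.array([1.0, 1.0]))  # far off range
        dist = assign_lengths(lane, cal)
        assert dist.warnings


def dist_of(lengths, intensity, offset=0.0):
    return LengthDistribution(np.asarray(lengths), np.asarray(intensity, dtype=float),
                              mobility_offset=offset)


class TestProcessivityEstimate:
    def test_point_mass_at_primer_plus_100(self):
        d = dist_of([36, 136], [5.0, 2.0])
        est = processivity_estimate(d, primer_length=36)
        assert est.estimate_nt == 100

    def test_uniform_extension_gives_85(self):
        lengths = np.arange(37, 137)          # extensions 1..100, uniform
        d = dist_of(lengths, np.ones(100))
        est = processivity_estimate(d, primer_length=36, percentile=0.85)
        assert est.estimate_nt == 85

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(8)
        d = dist_of(np.arange(37, 200), rng.random(163))
        prev = -1
        for p in (0.1, 0.3, 0.5, 0.85, 0.99):
            est = processivity_estimate(d, 36, p).estimate_nt
            assert est >= prev
            prev = est

    def test_invariant_under_intensity_scaling(self):
        rng = np.random.default_rng(9)
        intens = rng.random(100)
        a = processivity_estimate(dist_of(np.arange(37, 137), intens), 36)
        b = processivity_estimate(dist_of(np.arange(37, 137), 1e4 * intens), 36)
        assert a.estimate_nt == b.estimate_nt

    def test_no_extension_yields_zero_not_error(self):
        d = dist_of([30, 36], [1.0, 5.0])
        est = processivity_estimate(d, primer_length=36)
        assert est.estimate_nt == 0.0
        assert est.note
        assert est.extended_fraction == 0.0

    def test_extended_fraction_bounds(self):
        d = dist_of([36, 100], [3.0, 1.0])
        est = processivity_estimate(d, 36)
        assert est.extended_fraction == pytest.approx(0.25)


class TestEndToEnd:
    def test_point_mass_recovered_within_two_nt(self):
        lane, ladder = simulate_gel_lanes({100: 1.0}, seed=1)
        cal = calibrate_ladder(ladder, LADDER_LENGTHS)
        est = processivity_estimate(assign_lengths(lane, cal, 44.0), 36)
        assert abs(est.estimate_nt - 100) <= 2

    def test_geometric_spec_matches_analytic_quantile(self):
        p = 0.02
        ext = np.arange(1, 401)
        w = p * (1 - p) ** (ext - 1)
        lane, ladder = simulate_gel_lanes(
            dict(zip(ext.tolist(), w.tolist())), noise_sd=5e-5, seed=3
        )
        cal = calibrate_ladder(ladder, LADDER_LENGTHS)
        est = processivity_estimate(assign_lengths(lane, cal, 44.0), 36)
        cum = np.cumsum(w) / w.sum()
        oracle = ext[np.searchsorted(cum, 0.85)]
        assert abs(est.estimate_nt - oracle) <= 2

    def test_ladder_render_recovers_mobility_parameters(self):
        _, ladder = simulate_gel_lanes({100: 1.0}, a=600.0, b=80.0, seed=0)
        cal = calibrate_ladder(ladder, LADDER_LENGTHS)
        assert cal.a == pytest.approx(600.0, abs=0.5)
        assert cal.b == pytest.approx(80.0, abs=0.2)


class TestSingleHitCheck:
    def test_limiting_enzyme_with_trap_is_single_hit(self):
        regime, _ = single_hit_check(5.0, 12.5, 400)
        assert regime == "single-hit"

    def test_excess_enzyme_is_multi_hit(self):
        regime, note = single_hit_check(250.0, 12.5, 400)
        assert regime == "multi-hit"
        assert "not limiting" in note

    def test_no_trap_is_multi_hit(self):
        regime, note = single_hit_check(5.0, 12.5, 0)
        assert regime == "multi-hit"
        assert "trap" in note


def test_lane_trace_validation():
    with pytest.raises(ContractError):
        LaneTrace(np.array([1.0, 1.0]), np.array([0.0, 0.0]))
    with pytest.raises(ContractError):
        LaneTrace(np.array([1.0, 2.0]), np.array([0.0, -1.0]))
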