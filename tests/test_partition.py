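"""Hydrogenotrophic partition bound and breakpoint detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoslurry.partition import (
    BreakpointResult,
    detect_breakpoint,
    h2_fraction_bound,
    partition_profile,
)
from thermoslurry.rates import RateEstimate


def r(process, rate, temp=60.0, time=40.0):
    return RateEstimate(process=process, temperature=temp, time=time, rate=rate)


class TestH2FractionBound:
    def test_majority_hydrogenotrophic(self):
        # SRR 100 vs acetate oxidation 58 (CO2 units): at least 71% on H2
        res = h2_fraction_bound(r("srr", 100.0), r("acox", 58.0))
        assert res.acox_acetate_units == pytest.approx(29.0)
        assert res.fraction_h2_min == pytest.approx(0.71)

    def test_acetate_supply_exceeds_demand(self):
        res = h2_fraction_bound(r("srr", 100.0), r("acox", 400.0))
        assert res.fraction_h2_min == 0.0

    def test_zero_srr_degenerate(self):
        res = h2_fraction_bound(r("srr", 0.0), r("acox", 10.0))
        assert res.fraction_h2_min == 0.0
        assert res.degenerate

    def test_no_acetate_oxidation_means_all_h2(self):
        res = h2_fraction_bound(r("srr", 50.0), r("acox", 0.0))
        assert res.fraction_h2_min == 1.0

    def test_mismatched_temperature_rejected(self):
        with pytest.raises(ValueError):
            h2_fraction_bound(r("srr", 10.0, temp=10.0), r("acox", 10.0, temp=20.0))

    @given(st.floats(0.0, 500.0), st.floats(0.0, 500.0), st.floats(0.1, 500.0))
    @settings(max_examples=60, derandomize=True)
    def test_anti_monotone_in_acox(self, acox1, acox2, srr):
        lo, hi = sorted([acox1, acox2])
        f_hi = h2_fraction_bound(r("srr", srr), r("acox", lo)).fraction_h2_min
        f_lo = h2_fraction_bound(r("srr", srr), r("acox", hi)).fraction_h2_min
        assert f_hi >= f_lo - 1e-12


class TestPartitionProfile:
    def _rates(self, acox_by_temp):
        out = []
        for t, (srr, acox) in acox_by_temp.items():
            out.append(r("sulphate_removal", srr, temp=t))
            out.append(r("acetate_oxidation", acox, temp=t))
        return out

    def test_threshold_never_reached_flagged(self):
        rates = self._rates({t: (50.0, 200.0) for t in (10.0, 20.0, 30.0)})
        prof = partition_profile(rates)
        assert prof.threshold_temperature is None

    def test_constructed_crossing_at_grid_point(self):
        # monotone profile crossing 0.5 between 42 and 44 reports the 43
        # degC grid point
        table = {40.0: (100.0, 180.0), 42.0: (100.0, 120.0),
                 43.0: (100.0, 80.0), 44.0: (100.0, 40.0)}
        prof = partition_profile(self._rates(table))
        assert prof.threshold_temperature == 43.0

    def test_disjoint_grids_error_lists_temperatures(self):
        rates = [r("sulphate_removal", 10.0, temp=10.0), r("acetate_oxidation", 10.0, temp=20.0)]
        with pytest.raises(ValueError, match="10.0"):
            partition_profile(rates, pairing="timewise")

    def test_default_configuration_threshold_near_43(self, full_sim_noise_free):
        from thermoslurry.io import aggregate_tracer_rates
        from thermoslurry.observe import observe_concentrations, observe_tracers
        from thermoslurry.rates import sulphate_removal_rates

        design, sim = full_sim_noise_free
        rates = aggregate_tracer_rates(observe_tracers(sim, design))
        rates += sulphate_removal_rates(observe_concentrations(sim, design))
        prof = partition_profile(rates, pairing="max")
        assert prof.threshold_temperature is not None
        assert abs(prof.threshold_temperature - 43.0) <= 3.0


def brute_force_breakpoint(x, y, grid, min_points=3):
    """Independent naive two-segment least squares."""
    def line_sse(xs, ys):
        xs = np.asarray(xs); ys = np.asarray(ys)
        if len(set(xs.tolist())) == 1:
            return float(np.sum((ys - ys.mean()) ** 2))
        A = np.vstack([xs, np.ones_like(xs)]).T
        coef, *_ = np.linalg.lstsq(A, ys, rcond=None)
        return float(np.sum((ys - A @ coef) ** 2))

    best = None
    for b in sorted(grid):
        l = x <= b
        if l.sum() < min_points or (~l).sum() < min_points:
            continue
        total = line_sse(x[l], y[l]) + line_sse(x[~l], y[~l])
        if best is None or total < best[0] - 1e-15:
            best = (total, b)
    return best


def piecewise(x, kink=43.0, s1=2.0, s2=-1.0):
    return np.where(x <= kink, s1 * (x - kink), s2 * (x - kink))


class TestDetectBreakpoint:
    def test_exact_kink_recovery(self):
        # the kink point itself lies on both segments, so candidates within
        # one grid spacing below the kink are exactly tied (tie rule picks
        # the lower); recovery is exact up to that ambiguity
        x = np.arange(20.0, 66.0, 1.0)
        res = detect_breakpoint(x, piecewise(x), grid=np.arange(30.0, 61.0, 1.0))
        assert abs(res.break_temp - 43.0) <= 1.0
        assert res.sse_total == pytest.approx(0.0, abs=1e-16)
        assert res.improvement > 0.9

    def test_noisy_recovery_sanity(self, rng):
        x = np.arange(20.0, 66.0, 0.5)
        y = piecewise(x)
        span = y.max() - y.min()
        hits = 0
        for _ in range(50):
            noisy = y + rng.normal(0, 0.05 * span, size=len(x))
            res = detect_breakpoint(x, noisy, grid=np.arange(30.0, 61.0, 1.0))
            hits += abs(res.break_temp - 43.0) <= 2.0
        assert hits >= 47

    def test_straight_line_small_improvement(self):
        # a single straight line leaves nothing for a break to explain
        x = np.arange(20.0, 66.0, 2.0)
        res = detect_breakpoint(x, 3.0 * x + 1.0, grid=np.arange(30.0, 61.0, 1.0))
        assert res.improvement < 0.05

    def test_null_improvement_far_below_kinked_improvement(self, rng):
        # under a noisy null the (selection-inflated) improvement stays well
        # below the improvement a genuine kink produces
        x = np.arange(20.0, 66.0, 0.5)
        null_imp, kink_imp = [], []
        for _ in range(30):
            noise = rng.normal(0, 2.0, size=len(x))
            null_imp.append(
                detect_breakpoint(x, 3.0 * x + 1.0 + noise, np.arange(30.0, 61.0, 1.0)).improvement
            )
            kink_imp.append(
                detect_breakpoint(x, piecewise(x) + noise, np.arange(30.0, 61.0, 1.0)).improvement
            )
        assert np.median(null_imp) < 0.15
        assert np.median(kink_imp) > 0.9
        assert np.median(null_imp) < np.median(kink_imp) / 5.0

    def test_no_feasible_candidate(self):
        x = np.arange(20.0, 66.0, 2.0)
        with pytest.raises(ValueError):
            detect_breakpoint(x, piecewise(x), grid=[5.0])

    def test_oracle_equivalence(self, rng):
        x = np.arange(10.0, 76.0, 1.0)
        y = piecewise(x, kink=47.0) + rng.normal(0, 2.0, size=len(x))
        grid = np.arange(15.0, 71.0, 0.7)[:100]
        res = detect_breakpoint(x, y, grid)
        sse_oracle, brk_oracle = brute_force_breakpoint(x, y, grid)
        assert res.break_temp == brk_oracle
        assert res.sse_total == pytest.approx(sse_oracle, rel=1e-9)


def test_bound_never_exceeds_true_share(full_sim_noise_free):
    """The partition bound is a true lower bound on the simulator's
    hydrogenotrophic share, cell by cell."""
    from thermoslurry.observe import assay_true_rate, true_sulphate_reduction
    from thermoslurry.catalogue import TRACER_ASSAYS

    _, sim = full_sim_noise_free
    acox_co2 = assay_true_rate(sim, TRACER_ASSAYS[0]) * 2.0
    truth = true_sulphate_reduction(sim)
    h2 = truth.pivot(index="temperature", columns="time", values="hydrogenotrophic").to_numpy()
    ac = truth.pivot(index="temperature", columns="time", values="acetoclastic").to_numpy()
    srr = h2 + ac
    mask = srr > 0
    bound = (srr - np.minimum(srr, acox_co2 / 2.0))[mask] / srr[mask]
    share = h2[mask] / srr[mask]
    assert np.all(bound <= share + 1e-9)
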