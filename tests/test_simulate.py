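"""Simulator dynamics: temperature windows, stoichiometric stepping, mass
conservation and determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoslurry.simulate import (
    ConfigurationError,
    ExperimentDesign,
    IntegrationError,
    ProcessSpec,
    SourceTerm,
    ThermalWindow,
    simulate,
    step_state,
    window_response,
)


class TestWindowResponse:
    def test_peak_is_one(self):
        assert window_response(30.0, [ThermalWindow(30.0, 5.0, 5.0)]) == pytest.approx(1.0)

    def test_one_sigma_above_peak(self):
        w = ThermalWindow(30.0, 5.0, 4.0, weight=1.0)
        assert window_response(34.0, [w]) == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_asymmetry_uses_left_sigma_below_peak(self):
        w = ThermalWindow(30.0, 10.0, 2.0)
        assert window_response(20.0, [w]) == pytest.approx(math.exp(-0.5))
        assert window_response(40.0, [w]) < 1e-5

    def test_gap_between_two_windows(self):
        # activity gap between a mesophilic and a thermophilic window: a
        # temperature >5 sigma from both optima is effectively silent
        windows = [ThermalWindow(15.0, 3.5, 3.5), ThermalWindow(60.0, 3.5, 3.5)]
        assert window_response(40.0, windows) < 1e-6

    def test_max_combination(self):
        windows = [ThermalWindow(15.0, 5.0, 5.0, weight=0.5), ThermalWindow(15.0, 5.0, 5.0)]
        assert window_response(15.0, windows) == pytest.approx(1.0)

    def test_empty_windows_rejected(self):
        with pytest.raises(ConfigurationError):
            window_response(30.0, [])

    def test_invalid_window_parameters(self):
        with pytest.raises(ConfigurationError):
            ThermalWindow(30.0, -1.0, 5.0)
        with pytest.raises(ConfigurationError):
            ThermalWindow(30.0, 5.0, 5.0, weight=1.5)


def _h2_sr(r_max=100.0, k_h2=0.0):
    half = {"hydrogen": k_h2} if k_h2 else {}
    return ProcessSpec(
        name="h2_sr",
        stoichiometry={"hydrogen": -4, "sulphate": -1},
        rate_species="sulphate",
        r_max=r_max,
        windows=(ThermalWindow(30.0, 10.0, 10.0),),
        half_saturation=half,
    )


class TestStepState:
    def test_no_processes_leaves_state_unchanged(self):
        state = {"hydrogen": 10.0, "sulphate": 100.0}
        new, rates = step_state(state, [], 30.0, 0.1)
        assert new == state
        assert rates == {}

    def test_zero_rmax_leaves_state_unchanged(self):
        state = {"hydrogen": 10.0, "sulphate": 100.0}
        new, _ = step_state(state, [_h2_sr(r_max=0.0)], 30.0, 0.1)
        assert new == state

    def test_limiting_substrate_exact_stoichiometry(self):
        # H2 pool smaller than 4*r*dt: H2 ends exactly 0 and the sulphate
        # decrement is exactly H2_consumed / 4.
        state = {"hydrogen": 10.0, "sulphate": 100.0}
        new, _ = step_state(state, [_h2_sr(r_max=100.0)], 30.0, 1.0)
        assert new["hydrogen"] == pytest.approx(0.0, abs=1e-12)
        assert 100.0 - new["sulphate"] == pytest.approx(10.0 / 4.0, rel=1e-12)

    def test_hydrogenotrophic_methanogenesis_stoichiometry(self):
        spec = ProcessSpec(
            name="h2_meth",
            stoichiometry={"hydrogen": -4, "dic": -1, "methane": 1},
            rate_species="methane",
            r_max=5.0,
            windows=(ThermalWindow(30.0, 10.0, 10.0),),
        )
        state = {"hydrogen": 1000.0, "dic": 1000.0, "methane": 0.0}
        new, _ = step_state(state, [spec], 30.0, 0.1)
        d_ch4 = new["methane"] - state["methane"]
        d_dic = new["dic"] - state["dic"]
        d_h2 = new["hydrogen"] - state["hydrogen"]
        assert d_ch4 == pytest.approx(-d_dic, rel=1e-12)
        assert d_h2 == pytest.approx(4.0 * d_dic, rel=1e-12)

    def test_negative_pool_rejected(self):
        with pytest.raises(IntegrationError):
            step_state({"hydrogen": -1.0, "sulphate": 10.0}, [_h2_sr()], 30.0, 0.1)

    def test_onset_gate(self):
        spec = _h2_sr()
        state = {"hydrogen": 100.0, "sulphate": 100.0}
        from dataclasses import replace

        gated = replace(spec, onset_day=5.0)
        new, rates = step_state(state, [gated], 30.0, 0.1, t_day=1.0)
        assert rates["h2_sr"] == 0.0
        _, rates2 = step_state(state, [gated], 30.0, 0.1, t_day=6.0)
        assert rates2["h2_sr"] > 0


class TestSimulate:
    def test_empty_process_list_constant(self):
        design = ExperimentDesign(
            temperatures=[10, 50], time_points=[1.0, 5.0],
            initial_state={"sulphate": 100.0, "acetate": 5.0},
        )
        sim = simulate(design, [])
        assert np.all(sim.state == sim.state[:, :1, :])

    def test_carbon_ledger_matches_tracked_carbon(self, small_sim):
        # independent mass ledger: DIC + CH4 + 2*acetate + methylamine
        _, sim = small_sim
        tracked = (
            sim.state[:, :, sim.species_index("dic")]
            + sim.state[:, :, sim.species_index("methane")]
            + 2.0 * sim.state[:, :, sim.species_index("acetate")]
            + sim.state[:, :, sim.species_index("methylamine")]
        )
        delta = tracked[:, -1] - tracked[:, 0]
        np.testing.assert_allclose(delta, sim.carbon_ledger[:, -1], rtol=1e-6)

    def test_carbon_ledger_non_decreasing(self, small_sim):
        _, sim = small_sim
        assert np.all(np.diff(sim.carbon_ledger, axis=1) >= -1e-12)

    def test_pools_never_negative(self, full_sim_noise_free):
        _, sim = full_sim_noise_free
        assert sim.state.min() >= 0.0

    def test_sulphate_monotone_without_reoxidation(self, full_sim_noise_free):
        # no sulphide re-oxidation in the default catalogue, so sulphate can
        # only fall at every temperature
        _, sim = full_sim_noise_free
        so4 = sim.state[:, :, sim.species_index("sulphate")]
        assert np.all(np.diff(so4, axis=1) <= 1e-9)

    def test_window_locality(self):
        spec = ProcessSpec(
            name="cold_only",
            stoichiometry={"acetate": -1, "dic": 2},
            rate_species="acetate",
            r_max=100.0,
            windows=(ThermalWindow(20.0, 8.0, 5.0), ThermalWindow(35.0, 4.0, 1.5)),
        )
        design = ExperimentDesign(
            temperatures=[60.0], time_points=[10.0],
            initial_state={"acetate": 1000.0, "dic": 0.0},
        )
        sim = simulate(design, [spec])
        assert sim.rates.max() < 1e-9

    def test_design_validation(self):
        with pytest.raises(ConfigurationError):
            ExperimentDesign(temperatures=[90.0], time_points=[1.0], initial_state={})
        with pytest.raises(ConfigurationError):
            ExperimentDesign(temperatures=[10.0], time_points=[5.0, 1.0], initial_state={})
        with pytest.raises(ConfigurationError):
            ExperimentDesign(temperatures=[10.0], time_points=[200.0], initial_state={})


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    r_max=st.floats(0.0, 500.0),
    k=st.floats(0.1, 100.0),
    t_opt=st.floats(0.0, 80.0),
    pool_a=st.floats(0.0, 1000.0),
    pool_b=st.floats(0.0, 1000.0),
    src_amp=st.floats(0.0, 50.0),
    dt=st.floats(0.01, 1.0),
)
def test_non_negativity_property(r_max, k, t_opt, pool_a, pool_b, src_amp, dt):
    """Pools stay non-negative for arbitrary configurations."""
    specs = [
        ProcessSpec(
            name="p1",
            stoichiometry={"a": -2, "b": -1, "c": 3},
            rate_species="b",
            r_max=r_max,
            windows=(ThermalWindow(t_opt, 5.0, 5.0),),
            half_saturation={"a": k},
        ),
        ProcessSpec(
            name="p2",
            stoichiometry={"c": -1, "a": 1},
            rate_species="c",
            r_max=r_max / 2.0,
            windows=(ThermalWindow(80.0 - t_opt, 10.0, 10.0),),
        ),
    ]
    sources = [SourceTerm("a", src_amp, mode="logistic", t_mid=40.0, width=5.0)]
    state = {"a": pool_a, "b": pool_b, "c": 0.0}
    for step in range(30):
        state, _ = step_state(state, specs, t_opt + 3.0, dt, t_day=step * dt, sources=sources)
        assert min(state.values()) >= 0.0
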