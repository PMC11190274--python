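"""Gating kinetics, membrane equation, OU noise and the reference stepper."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biosnn import hh_core, load_preset
from biosnn.hh_core import (
    ConfigError,
    NeuronState,
    OUNoiseParams,
    eval_gate_rates,
    gate_step_exact,
    make_gate,
    ou_stationary_stats,
    ou_step,
    reference_step,
    simulate_neuron,
    total_membrane_current,
)


class TestGateRates:
    def test_constant_alpha_beta_kinetics(self):
        gate = make_gate("c", "const", 1, {"alpha": 1.0, "beta": 1.0})
        assert eval_gate_rates(gate, -65.0) == (1.0, 1.0)
        assert eval_gate_rates(gate, 40.0) == (1.0, 1.0)

    def test_kd_gate_matches_published_rate_expressions(self):
        # independent hand evaluation of the delayed-rectifier K kinetics
        # alpha_n = -0.032 (V - V_T - 15) / (exp(-(V - V_T - 15)/5) - 1)
        # beta_n  = 0.5 exp(-(V - V_T - 10)/40)
        V, V_T = -65.0, -56.2
        u = V - V_T - 15.0
        alpha_expect = -0.032 * u / (math.exp(-u / 5.0) - 1.0)
        beta_expect = 0.5 * math.exp(-(V - V_T - 10.0) / 40.0)
        gate = make_gate("n", "kd_n", 4, {"V_T": V_T})
        a, b = eval_gate_rates(gate, V)
        assert a == pytest.approx(alpha_expect, rel=1e-12)
        assert b == pytest.approx(beta_expect, rel=1e-12)

    def test_na_activation_is_finite_at_its_singular_voltage(self):
        # alpha_m has a removable 0/0 singularity at V = V_T + 13
        gate = make_gate("m", "na_m", 3, {"V_T": -56.2})
        a, b = eval_gate_rates(gate, -43.2)
        assert np.isfinite(a) and np.isfinite(b)
        # limit value: 0.32 * 4 = 1.28
        assert a == pytest.approx(1.28, abs=1e-6)

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError):
            make_gate("x", "nope", 1, {})


class TestMembraneCurrent:
    def test_zero_conductances_zero_inputs_give_zero(self):
        gate = make_gate("c", "const", 1, {})
        params = hh_core.NeuronModelParams(
            preset_id="custom",
            C_m=1.0,
            g_leak=0.0,
            E_leak=-70.0,
            currents=(hh_core.CurrentSpec("z", 0.0, 0.0, (gate,)),),
        )
        state = NeuronState(V=-55.0, gates=np.array([0.5]), I_noise=0.0)
        assert total_membrane_current(params, state) == 0.0

    def test_leak_at_reversal_is_zero(self):
        params = load_preset("RS")
        state = params.init_state(params.E_leak)
        # zero out every voltage-gated conductance by zeroing the gates
        state.gates[:] = 0.0
        state.I_noise = 0.0
        assert total_membrane_current(params, state) == pytest.approx(0.0)

    def test_single_current_direct_product(self):
        gate = make_gate("c", "const", 1, {})
        params = hh_core.NeuronModelParams(
            preset_id="custom",
            C_m=1.0,
            g_leak=0.0,
            E_leak=-70.0,
            currents=(hh_core.CurrentSpec("k", 1.0, -65.0, (gate,)),),
        )
        state = NeuronState(V=-55.0, gates=np.array([1.0]), I_noise=0.0)
        # g=1, gate=1, V-E = 10 mV -> -10 uA/cm^2
        assert total_membrane_current(params, state) == pytest.approx(-10.0)


class TestOUNoise:
    def test_deterministic_relaxation_step(self):
        p = OUNoiseParams(mu=1.0, theta=1.0, sigma=0.0)
        assert ou_step(0.0, p, 0.03125, 0.0) == pytest.approx(0.03125)

    def test_stationary_mean_and_variance(self, rng):
        # Monte-Carlo vs the closed-form stationary moments
        p = OUNoiseParams(mu=0.5, theta=0.2, sigma=0.3)
        n = 200_000
        dt = 0.03125
        draws = rng.standard_normal(n)
        x = np.empty(n)
        cur = p.mu
        for i in range(n):
            cur = cur + p.theta * (p.mu - cur) * dt + p.sigma * math.sqrt(dt) * draws[i]
            x[i] = cur
        x = x[n // 10 :]  # discard burn-in
        mean_expect, var_expect = ou_stationary_stats(p)
        se = math.sqrt(var_expect / (len(x) * p.theta * dt))  # effective sample size
        assert abs(x.mean() - mean_expect) < 3 * se
        assert x.var() == pytest.approx(var_expect, rel=0.05)


class TestReferenceStep:
    def test_no_dynamics_without_conductances_or_inputs(self):
        gate = make_gate("c", "const", 1, {"alpha": 0.0, "beta": 0.0})
        params = hh_core.NeuronModelParams(
            preset_id="custom",
            C_m=1.0,
            g_leak=0.0,
            E_leak=-70.0,
            currents=(hh_core.CurrentSpec("z", 0.0, 0.0, (gate,)),),
            noise=OUNoiseParams(mu=0.0, theta=0.1, sigma=0.0),
        )
        state = NeuronState(V=-60.0, gates=np.array([0.25]), I_noise=0.0)
        new = reference_step(params, state, 0.03125)
        assert new.V == state.V
        assert new.gates[0] == state.gates[0]

    def test_leak_only_monotone_relaxation_to_rest(self):
        params = load_preset("RS")
        zero = dataclasses.replace(
            params,
            currents=tuple(
                dataclasses.replace(c, g_max=0.0) for c in params.currents
            ),
            noise=OUNoiseParams(mu=0.0, theta=0.1, sigma=0.0),
        )
        state = zero.init_state(V0=-50.0)
        state.I_noise = 0.0
        gaps = []
        for _ in range(2000):
            state = reference_step(zero, state, 0.03125)
            gaps.append(abs(state.V - zero.E_leak))
        assert all(b < a for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < abs(-50.0 - zero.E_leak)

    def test_rs_spiking_period_matches_fine_step_integration(self):
        # step-refinement oracle: dt vs dt/10 over 2 s of tonic firing
        params = dataclasses.replace(
            load_preset("RS"), noise=OUNoiseParams(mu=0.0, theta=0.1, sigma=0.0)
        )
        coarse = simulate_neuron(params, 2000.0, dt=0.03125, I_stim=1.0)
        fine = simulate_neuron(params, 2000.0, dt=0.003125, I_stim=1.0)
        sp_c, sp_f = coarse["spike_times"], fine["spike_times"]
        assert len(sp_c) >= 10 and len(sp_c) == len(sp_f)
        period_c = np.diff(sp_c)[-5:].mean()
        period_f = np.diff(sp_f)[-5:].mean()
        assert abs(period_c - period_f) < 1.0

    @settings(max_examples=25, deadline=None)
    @given(
        v0=st.floats(min_value=-90.0, max_value=30.0),
        stim=st.floats(min_value=-2.0, max_value=2.0),
    )
    def test_gates_remain_in_unit_interval(self, v0, stim):
        params = dataclasses.replace(
            load_preset("LTS"), noise=OUNoiseParams(mu=0.0, theta=0.1, sigma=0.0)
        )
        state = params.init_state(V0=v0)
        for _ in range(200):
            state = reference_step(params, state, 0.03125, I_stim=stim)
            assert np.all(state.gates >= 0.0) and np.all(state.gates <= 1.0)

    def test_identical_seeds_are_bit_identical(self):
        params = load_preset("RS")  # preset noise is active
        a = simulate_neuron(params, 200.0, seed=7, record_V=True)
        b = simulate_neuron(params, 200.0, seed=7, record_V=True)
        assert np.array_equal(a["V"], b["V"])
        assert np.array_equal(a["spike_times"], b["spike_times"])
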