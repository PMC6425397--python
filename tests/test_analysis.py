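"""Dynamics characterization: periods, phases, responsiveness, robustness."""

import numpy as np
import pytest

import dynome as dy
from dynome.analysis import (ScenarioSpec, estimate_period, phase_difference,
                             responsive_neurons, robustness_scan, run_scenario)
from dynome.synthetic import RING_DRIVE_NA, RING_GOLDEN_SEED

DT = 0.01


def ring_spec(**kw):
    defaults = dict(name="ring",
                    stimuli_nA={f"R{i}": RING_DRIVE_NA for i in range(3)},
                    duration=30.0, settle_time=10.0, seed=RING_GOLDEN_SEED)
    defaults.update(kw)
    return ScenarioSpec(**defaults)


class TestEstimatePeriod:
    def test_pure_sine(self):
        t = np.arange(0, 20, DT)
        est = estimate_period(np.sin(2 * np.pi * t / 2.0), DT)
        assert est == pytest.approx(2.0, abs=0.01)

    def test_constant_trace_is_aperiodic(self):
        assert estimate_period(np.full(3000, 7.0), DT) is None

    def test_noisy_multicomponent_signal(self):
        """Dominant 2 s component recovered despite a fast secondary
        component and additive noise (Monte-Carlo over seeds)."""
        t = np.arange(0, 20, DT)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = (np.sin(2 * np.pi * t / 2.0)
                 + 0.3 * np.sin(2 * np.pi * t / 0.37)
                 + 0.1 * rng.standard_normal(t.size))
            assert estimate_period(x, DT) == pytest.approx(2.0, abs=0.02)

    def test_recovery_across_period_and_noise_grid(self):
        rng = np.random.default_rng(42)
        for period in (0.5, 1.5, 3.0, 6.0):
            for sigma in (0.0, 0.2):
                t = np.arange(0, max(30.0, 5 * period), DT)
                x = np.sin(2 * np.pi * t / period) \
                    + sigma * rng.standard_normal(t.size)
                est = estimate_period(x, DT)
                assert est == pytest.approx(period, rel=0.02)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            estimate_period(np.ones(4), DT)


class TestPhaseDifference:
    def test_identical_series_zero_phase(self):
        t = np.arange(0, 20, DT)
        a = np.sin(2 * np.pi * t / 2.0)
        assert phase_difference(a, a, 2.0, DT) == pytest.approx(0.0, abs=1e-6)

    def test_antiphase_is_pi(self):
        t = np.arange(0, 20, DT)
        a = np.sin(2 * np.pi * t / 2.0)
        assert phase_difference(a, -a, 2.0, DT) == pytest.approx(np.pi)

    def test_quarter_period_delay_is_half_pi(self):
        t = np.arange(0, 20, DT)
        a = np.sin(2 * np.pi * t / 2.0)
        b = np.sin(2 * np.pi * (t - 0.5) / 2.0)
        assert phase_difference(a, b, 2.0, DT) == pytest.approx(
            np.pi / 2, abs=0.05)

    def test_aperiodic_input_rejected(self):
        with pytest.raises(ValueError):
            phase_difference(np.ones(100), np.ones(100), -1.0, DT)


class TestResponsiveNeurons:
    def test_resting_network_empty_set(self):
        V = np.full((100, 4), -35.0)
        vth = np.full(4, -35.0)
        hit, frac = responsive_neurons(
            np.arange(100) * DT, V, vth, ["a", "b", "c", "d"],
            np.ones(4, dtype=bool))
        assert hit == set() and frac == 0.0

    def test_single_driven_neuron_detected(self):
        V = np.full((100, 3), -35.0)
        V[:, 1] = -15.0  # 20 mV above threshold
        vth = np.full(3, -35.0)
        hit, frac = responsive_neurons(
            np.arange(100) * DT, V, vth, ["a", "b", "c"],
            np.ones(3, dtype=bool), threshold_mV=5.0)
        assert hit == {"b"}
        assert frac == pytest.approx(1 / 3)

    def test_fraction_invariant_under_relabeling(self):
        rng = np.random.default_rng(0)
        V = rng.uniform(-50, 0, size=(50, 6))
        vth = np.full(6, -35.0)
        names = list("abcdef")
        active = np.ones(6, dtype=bool)
        _, f1 = responsive_neurons(None, V, vth, names, active)
        perm = rng.permutation(6)
        _, f2 = responsive_neurons(None, V[:, perm], vth[perm],
                                   [names[i] for i in perm], active[perm])
        assert f1 == pytest.approx(f2)

    def test_ablated_neurons_excluded(self):
        V = np.full((10, 2), -10.0)
        vth = np.full(2, -35.0)
        active = np.array([True, False])
        hit, frac = responsive_neurons(None, V, vth, ["a", "b"], active)
        assert hit == {"a"} and frac == 1.0


class TestRunScenario:
    def test_zero_stimulus_network_is_quiet(self, small_connectome):
        spec = ScenarioSpec(name="rest", duration=6.0, settle_time=3.0, seed=0)
        res = run_scenario(spec, small_connectome)
        assert res.responsive == set()
        assert res.periods == {}
        assert res.consensus_period is None

    def test_ring_oscillator_matches_golden_period(self):
        """Fresh integration of the ring fixture reproduces the committed
        golden trajectory's period within 2%."""
        c, p, exp = dy.fixture("ring_oscillator")
        golden = exp["golden"]
        res = run_scenario(ring_spec(seed=golden["seed"]), c)
        assert res.consensus_period == pytest.approx(
            golden["period_s"], rel=0.02)
        # voltage trace itself matches the stored samples
        stride = round(golden["dt_s"] / DT)
        v0 = res.V[::stride, 0]
        stored = np.array(golden["V_mV"])
        m = min(v0.size, stored.size)
        assert np.max(np.abs(v0[:m] - stored[:m])) < 1e-3

    def test_ring_phases_are_three_way_balanced(self):
        c, _, _ = dy.fixture("ring_oscillator")
        res = run_scenario(ring_spec(), c)
        phases = sorted(abs(v) for v in res.phases.values())
        assert phases[0] == pytest.approx(0.0, abs=0.1)
        assert phases[1] == pytest.approx(2 * np.pi / 3, abs=0.2)
        assert phases[2] == pytest.approx(2 * np.pi / 3, abs=0.2)

    def test_reproducible_given_seed(self):
        c, _, _ = dy.fixture("ring_oscillator")
        r1 = run_scenario(ring_spec(), c)
        r2 = run_scenario(ring_spec(), c)
        np.testing.assert_array_equal(r1.V, r2.V)
        assert r1.periods == r2.periods

    def test_ablation_applies(self):
        c, _, _ = dy.fixture("ring_oscillator")
        res = run_scenario(ring_spec(ablated=frozenset({"R1"})), c)
        # breaking the ring kills the oscillation
        assert "R1" not in res.periods
        assert res.consensus_period is None

    def test_unknown_stimulus_name_rejected(self, small_connectome):
        spec = ScenarioSpec(name="bad", stimuli_nA={"QQQ": 1.0},
                            duration=2.0, settle_time=1.0)
        with pytest.raises(KeyError):
            run_scenario(spec, small_connectome)

    def test_cell_class_prefix_expansion(self, small_connectome):
        """A class name (shared prefix) expands to all member neurons."""
        from dynome.analysis import _expand_names
        amps = _expand_names(small_connectome, {"N00": 1.0})
        # N000..N009 all share the N00 prefix
        assert len(amps) == 10


class TestRobustnessScan:
    def test_zero_perturbation_identical_to_baseline(self):
        c, _, _ = dy.fixture("ring_oscillator")
        spec = ring_spec()
        base = run_scenario(spec, c)
        recs = robustness_scan(spec, c, perturbation=0.0, n_draws=2, seed=0)
        for r in recs:
            assert r["period"] == pytest.approx(base.consensus_period)

    def test_draws_reproducible_given_seed(self):
        c, _, _ = dy.fixture("ring_oscillator")
        spec = ring_spec(duration=16.0, settle_time=6.0, seed=3)
        a = robustness_scan(spec, c, n_draws=2, seed=5)
        b = robustness_scan(spec, c, n_draws=2, seed=5)
        assert a == b

    def test_oscillation_survives_20_percent_perturbation(self):
        c, _, _ = dy.fixture("ring_oscillator")
        recs = robustness_scan(ring_spec(), c, perturbation=0.20,
                               n_draws=3, seed=1)
        assert all(r["oscillating"] for r in recs)

    def test_period_varies_continuously_with_single_connection(self):
        """Scaling one ring synapse sweeps the period smoothly."""
        periods = []
        for scale in (0.85, 1.0, 1.15):
            c, _, _ = dy.fixture("ring_oscillator")
            c.syn[1, 0] *= scale
            c.reference_syn = c.syn.copy()
            res = run_scenario(ring_spec(), c)
            periods.append(res.consensus_period)
        assert all(p is not None for p in periods)
        spread = max(periods) - min(periods)
        assert 0 < spread < 0.3 * min(periods)
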