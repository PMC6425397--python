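"""Integration engine: initial conditions, oracles, invariants, events."""

import numpy as np
import pytest

import dynome as dy
from dynome.integrate import StructuralEvent
from dynome.model import NetworkState
from tests.conftest import prepared_params


class TestInitState:
    def test_deterministic_given_seed(self):
        a = dy.init_state(20, 5)
        b = dy.init_state(20, 5)
        np.testing.assert_array_equal(a.V, b.V)
        np.testing.assert_array_equal(a.s, b.s)

    def test_dimension_279_gives_558(self):
        st = dy.init_state(279, 0)
        assert st.dim == 558

    def test_s_clamped_to_unit_interval(self):
        st = dy.init_state(1000, 3)
        assert np.all(st.s >= 0) and np.all(st.s <= 1)

    def test_half_normal_mean_of_V(self):
        """Monte-Carlo: E|V| for a N(0, 0.94)*1e-4 draw is
        0.94e-4 * sqrt(2/pi)."""
        draws = np.concatenate([np.abs(dy.init_state(500, s).V)
                                for s in range(40)])
        expected = 0.94e-4 * np.sqrt(2 / np.pi)
        assert np.mean(draws) == pytest.approx(expected, rel=0.02)


class TestIntegrateBlock:
    def test_leak_decay_matches_closed_form(self):
        c, p, _ = dy.fixture("single")
        p.vth_mV = dy.compute_vth(c, p)
        state = NetworkState(t=0.0, V=np.array([-25.0]), s=np.array([0.0]))
        sched = dy.StimulusSchedule.zeros(1)
        blk = dy.integrate_interval(state, c, p, sched, dy.SolverConfig(), 0.6)
        exact = -35.0 + 10.0 * np.exp(-blk.times / 0.15)
        assert np.max(np.abs(blk.V_samples[:, 0] - exact)) < 1e-6

    def test_fixed_point_is_stationary(self, small_connectome):
        """Starting the zero-input network at V = Vth with s at its
        equilibrium activation leaves the state unchanged."""
        c = small_connectome
        p = prepared_params(c)
        phi = dy.sigmoid_phi(p.vth_mV, p.beta_per_mV, p.vth_mV)  # = 1/2
        s_star = p.rise_rate * phi / (p.rise_rate * phi + p.decay_rate)
        state = NetworkState(t=0.0, V=p.vth_mV.copy(), s=s_star)
        # Vth is the fixed point with s frozen at s_eq = s*(phi=1/2)
        sched = dy.StimulusSchedule.zeros(c.n)
        blk = dy.integrate_block(state, c, p, sched, dy.SolverConfig())
        assert np.max(np.abs(blk.end_state.V - state.V)) < 1e-6
        assert np.max(np.abs(blk.end_state.s - state.s)) < 1e-8

    def test_reintegration_is_bit_identical(self, small_connectome, cfg):
        c = small_connectome
        p = prepared_params(c)
        sched = dy.StimulusSchedule.zeros(c.n)
        s0 = dy.init_state(c.n, cfg.seed)
        b1 = dy.integrate_block(s0, c, p, sched, cfg)
        b2 = dy.integrate_block(b1.end_state, c, p, sched, cfg)
        b2_again = dy.integrate_block(b1.end_state, c, p, sched, cfg)
        np.testing.assert_array_equal(b2.V_samples, b2_again.V_samples)
        np.testing.assert_array_equal(b2.s_samples, b2_again.s_samples)

    def test_block_decomposition_invariance(self, small_connectome, cfg):
        """One [0, 2*dt] call equals two chained dt blocks within the
        solver's mixed error scale 10*(atol + rtol*|V|)."""
        c = small_connectome
        p = prepared_params(c)
        sched = dy.StimulusSchedule.zeros(c.n)
        s0 = dy.init_state(c.n, cfg.seed)
        one = dy.integrate_interval(s0, c, p, sched, cfg, 2 * cfg.block_dt)
        b1 = dy.integrate_block(s0, c, p, sched, cfg)
        b2 = dy.integrate_block(b1.end_state, c, p, sched, cfg)
        chained = np.vstack([b1.V_samples, b2.V_samples])
        tol = 10 * (cfg.atol + cfg.rtol * np.max(np.abs(one.V_samples)))
        assert np.max(np.abs(one.V_samples - chained)) < tol

    def test_tolerance_convergence(self, small_connectome):
        """Halving rtol/atol moves trajectories by less than the coarser
        tolerance scale."""
        c = small_connectome
        p = prepared_params(c)
        sched = dy.StimulusSchedule.zeros(c.n)
        s0 = dy.init_state(c.n, 1)
        coarse = dy.SolverConfig(rtol=2e-8, atol=2e-9)
        fine = dy.SolverConfig(rtol=1e-8, atol=1e-9)
        a = dy.integrate_interval(s0, c, p, sched, coarse, 1.0)
        b = dy.integrate_interval(s0, c, p, sched, fine, 1.0)
        scale = coarse.atol + coarse.rtol * np.max(np.abs(a.V_samples))
        assert np.max(np.abs(a.V_samples - b.V_samples)) < 100 * scale

    def test_s_stays_in_unit_interval_random_networks(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            c = dy.random_connectome(dy.SynthSpec(n=6, seed=seed))
            I = rng.uniform(0, 20, c.n)
            p = prepared_params(c, I)
            sched = dy.StimulusSchedule(baseline=dy.nA_from_arb(I))
            blk = dy.integrate_interval(dy.init_state(c.n, seed), c, p,
                                        sched, dy.SolverConfig(), 1.0)
            assert blk.s_samples.min() >= -1e-9
            assert blk.s_samples.max() <= 1 + 1e-9

    def test_voltages_bounded_by_drive(self):
        """For bounded inputs V stays within the envelope set by the reversal
        potentials, the leak and the input-over-conductance shift."""
        for seed in range(5):
            c = dy.random_connectome(dy.SynthSpec(n=8, seed=seed))
            I = np.random.default_rng(seed).uniform(0, 10, c.n)
            p = prepared_params(c, I)
            sched = dy.StimulusSchedule(baseline=dy.nA_from_arb(I))
            blk = dy.integrate_interval(dy.init_state(c.n, seed), c, p,
                                        sched, dy.SolverConfig(), 2.0)
            lo = min(-48.0, -35.0) - 1.0
            hi = -35.0 + np.max(I) / 0.1 + 1.0
            assert blk.V_samples.min() >= lo
            assert blk.V_samples.max() <= hi


class TestStructuralEvents:
    def test_ablation_leaves_disconnected_component_untouched(self):
        """Two disconnected pairs: ablating in one pair does not change the
        other pair's trajectory."""
        from dynome.connectome import Connectome, NeuronInfo
        gap = np.zeros((4, 4))
        gap[0, 1] = gap[1, 0] = 100.0
        gap[2, 3] = gap[3, 2] = 100.0
        c = Connectome(roster=[NeuronInfo(f"N{i}") for i in range(4)],
                       gap=gap, syn=np.zeros((4, 4)))
        cfg = dy.SolverConfig(seed=2)
        sched = dy.StimulusSchedule.zeros(4)
        s0 = dy.init_state(4, 2)

        p_ref = prepared_params(c)
        ref = dy.integrate_block(s0, c.copy(), p_ref, sched, cfg)

        c_abl = c.copy()
        p_abl = prepared_params(c_abl)
        dy.apply_structural_event(s0, c_abl, p_abl,
                                  StructuralEvent("ablate", (0,)))
        abl = dy.integrate_block(s0, c_abl, p_abl, sched, cfg)
        np.testing.assert_allclose(abl.V_samples[:, 2:], ref.V_samples[:, 2:],
                                   atol=1e-9)

    def test_ablate_then_reinsert_restores_dynamics(self, small_connectome, cfg):
        c = small_connectome.copy()
        p = prepared_params(c)
        sched = dy.StimulusSchedule.zeros(c.n)
        s0 = dy.init_state(c.n, 0)
        ref = dy.integrate_block(s0, c, p, sched, cfg)

        c2 = small_connectome.copy()
        p2 = prepared_params(c2)
        dy.apply_structural_event(s0, c2, p2, StructuralEvent("ablate", (1, 5)))
        dy.apply_structural_event(s0, c2, p2, StructuralEvent("reinsert", (1, 5)))
        np.testing.assert_array_equal(c2.gap, small_connectome.gap)
        again = dy.integrate_block(s0, c2, p2, sched, cfg)
        # matrices restore exactly; trajectories to solver precision (the
        # threshold refresh goes through the LU path, which may differ from
        # the direct solve in the last bits)
        np.testing.assert_allclose(again.V_samples, ref.V_samples, atol=1e-9)

    def test_ablate_all_relaxes_to_leak_potential(self, small_connectome, cfg):
        c = small_connectome.copy()
        p = prepared_params(c)
        s0 = NetworkState(t=0.0, V=np.full(c.n, -20.0), s=np.zeros(c.n))
        dy.apply_structural_event(s0, c, p,
                                  StructuralEvent("ablate", tuple(range(c.n))))
        sched = dy.StimulusSchedule.zeros(c.n)
        blk = dy.integrate_interval(s0, c, p, sched, cfg, 0.3)
        exact = -35.0 + (-20.0 + 35.0) * np.exp(-blk.times / 0.15)
        assert np.max(np.abs(blk.V_samples - exact[:, None])) < 1e-6

    def test_vth_refreshed_after_ablation(self, small_connectome):
        c = small_connectome.copy()
        p = prepared_params(c)
        s0 = dy.init_state(c.n, 0)
        dy.apply_structural_event(s0, c, p,
                                  StructuralEvent("ablate", tuple(range(c.n))))
        np.testing.assert_allclose(p.vth_mV, np.full(c.n, -35.0), atol=1e-9)


class TestExport:
    def test_csv_and_npy_round_trip(self, small_connectome, cfg, tmp_path):
        import pandas as pd
        c = small_connectome
        p = prepared_params(c)
        sched = dy.StimulusSchedule.zeros(c.n)
        blk = dy.integrate_block(dy.init_state(c.n, 1), c, p, sched, cfg)
        from dynome.integrate import export_csv, export_npy
        export_npy([blk], tmp_path / "out.npy")
        arr = np.load(tmp_path / "out.npy")
        assert arr.shape == (cfg.samples_per_block, 1 + 2 * c.n)
        np.testing.assert_array_equal(arr[:, 1:c.n + 1], blk.V_samples)
        export_csv([blk], tmp_path / "out.csv", names=c.names)
        df = pd.read_csv(tmp_path / "out.csv")
        assert list(df.columns[1:c.n + 1]) == [f"V_{n}" for n in c.names]
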