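import numpy as np
import pytest
from scipy import stats

from spinetraffic.engine import (
    SimState,
    integrate_meanfield,
    sample_waiting_times,
    simulate,
)
from spinetraffic.network import ReactionChannel
from spinetraffic.calibration import equilibrium_solve


def make_toy(factory, species, channels, initial):
    return factory(species, channels, initial)


class TestSSA:
    def test_empty_reaction_set_is_constant(self, toy_system_factory):
        sys_ = make_toy(toy_system_factory, ["X"], [], [7])
        traj = simulate(sys_, duration=5.0, seed=1)
        assert np.all(traj.counts == 7)

    def test_birth_death_long_run_mean(self, toy_system_factory):
        """Stationary mean of a birth-death process is b/d; the SSA
        time-average must agree within 3 standard errors."""
        b, d = 20.0, 1.0
        sys_ = make_toy(
            toy_system_factory, ["X"],
            [ReactionChannel("birth", (), ((0, +1),), b),
             ReactionChannel("death", (0,), ((0, -1),), d)],
            [0])
        traj = simulate(sys_, duration=2000.0, seed=3, burn_in=50.0)
        x = traj.counts[:, 0].astype(float)
        # stationary variance = mean (Poisson), autocorrelation time 1/d
        se = np.sqrt(2.0 * (b / d) * (1.0 / d) / 2000.0)
        assert abs(x.mean() - b / d) < 3.0 * se

    def test_isolated_psd_binding_matches_analytic_equilibrium(self, toy_system_factory):
        """SSA mean bound count on a closed single-PSD system equals the
        root of the mass-action equilibrium within Monte-Carlo error."""
        n_s, n_r, area, kf, kb = 300, 120, 0.0707, 1.0, 100.0
        sys_ = make_toy(
            toy_system_factory, ["S", "R", "C"],
            [ReactionChannel("bind", (0, 1), ((0, -1), (1, -1), (2, +1)), kf / area),
             ReactionChannel("unbind", (2,), ((2, -1), (0, +1), (1, +1)), kb)],
            [n_s, n_r, 0])
        traj = simulate(sys_, duration=300.0, seed=11, burn_in=5.0)
        c = traj.counts[:, 2].astype(float)
        expected = equilibrium_solve(n_s, n_r, area, kf, kb)
        # relaxation time ~ 1/(kb + kf*(S+R)/A) << 1 s; samples ~independent
        se = c.std(ddof=1) / np.sqrt(c.size / 4.0)
        assert abs(c.mean() - expected) < 3.0 * se

    def test_determinism_bit_identical(self, small_system):
        t1 = simulate(small_system, duration=5.0, seed=42)
        t2 = simulate(small_system, duration=5.0, seed=42)
        t3 = simulate(small_system, duration=5.0, seed=43)
        assert np.array_equal(t1.counts, t2.counts)
        assert not np.array_equal(t1.counts, t3.counts)

    def test_waiting_times_exponential(self, toy_system_factory):
        """Exactness: waiting times of a constant-propensity 2-channel toy
        follow Exp(total propensity) (KS test at alpha=0.01, n=10^4)."""
        sys_ = make_toy(
            toy_system_factory, ["X"],
            [ReactionChannel("a", (), ((0, +1),), 3.0),
             ReactionChannel("b", (), ((0, +1),), 7.0)],
            [0])
        waits = sample_waiting_times(sys_, n_events=10_000, seed=5)
        res = stats.kstest(waits, "expon", args=(0, 1.0 / 10.0))
        assert res.pvalue > 0.01

    def test_invalid_inputs_rejected(self, small_system):
        with pytest.raises(ValueError):
            simulate(small_system, duration=-1.0, seed=1)
        with pytest.raises(ValueError):
            simulate(small_system, duration=1.0, seed=1, method="leapfrog")
        with pytest.raises(ValueError):
            simulate(small_system, np.full(small_system.n_species, -1), 1.0, seed=1)


class TestConservation:
    def test_receptor_total_conserved_every_sample(self, small_trajs):
        for tr in small_trajs:
            totals = tr.total_receptor_series()
            assert np.all(totals == totals[0])

    def test_scaffold_totals_conserved(self, small_trajs, small_system):
        per_psd = small_system.params.n_scaffold_per_psd
        for tr in small_trajs:
            scaff = tr.counts @ small_system.scaffold_load()
            assert np.all(scaff == per_psd * len(small_system.spine_indices()))


class TestTauLeap:
    def test_tau_leap_matches_ssa_mean(self):
        """Per-PSD mean synaptic receptors at the end of the reduced-model
        run differ by <2% between tau-leap and exact SSA (20 seeds each).

        The step must resolve the fastest first-order channel, so the
        comparison uses the reduced model with its baseline trafficking
        rates (fastest rate ~1000/s, step 0.2 ms)."""
        from spinetraffic.network import ParameterSet
        from spinetraffic.protocols import make_protocol

        base = ParameterSet()
        proto = make_protocol(
            "fixture_small",
            **{k: getattr(base, k) for k in ("k_f2", "k_b2", "k_f3", "k_b3")})
        system = proto.build_system()
        seeds = range(100, 120)
        res = {}
        for method in ("ssa", "tau_leap"):
            vals = []
            for s in seeds:
                tr = simulate(system, duration=50.0, seed=s, method=method,
                              burn_in=10.0, tau_dt=2e-4)
                mask = tr.times >= 30.0
                vals.append(np.mean([tr.synaptic_series(i)[mask].mean()
                                     for i in system.spine_indices()]))
            res[method] = np.mean(vals)
        assert res["tau_leap"] == pytest.approx(res["ssa"], rel=0.02)

    def test_tau_leap_step_cap(self, small_system):
        with pytest.raises(ValueError):
            simulate(small_system, duration=1.0, seed=1, method="tau_leap", tau_dt=0.05)

    def test_tau_leap_never_goes_negative(self, toy_system_factory):
        """A fast-draining pool forces step rejection, not clamping."""
        sys_ = make_toy(
            toy_system_factory, ["X", "Y"],
            [ReactionChannel("decay", (0,), ((0, -1), (1, +1)), 500.0),
             ReactionChannel("back", (1,), ((1, -1), (0, +1)), 500.0)],
            [5, 0])
        tr = simulate(sys_, duration=2.0, seed=9, method="tau_leap", tau_dt=0.01)
        assert tr.counts.min() >= 0
        assert np.all(tr.counts.sum(axis=1) == 5)

    def test_tau_leap_deterministic(self, small_system):
        a = simulate(small_system, duration=3.0, seed=7, method="tau_leap")
        b = simulate(small_system, duration=3.0, seed=7, method="tau_leap")
        assert np.array_equal(a.counts, b.counts)


class TestMeanField:
    def test_conservation_along_ode_solution(self, small_system):
        traj = integrate_meanfield(small_system, duration=30.0)
        totals = traj.counts @ small_system.receptor_load()
        assert np.allclose(totals, totals[0], rtol=1e-6)

    def test_ode_equilibrium_matches_equilibrium_solve(self, toy_system_factory):
        n_s, n_r, area, kf, kb = 300, 120, 0.0707, 1.0, 100.0
        sys_ = make_toy(
            toy_system_factory, ["S", "R", "C"],
            [ReactionChannel("bind", (0, 1), ((0, -1), (1, -1), (2, +1)), kf / area),
             ReactionChannel("unbind", (2,), ((2, -1), (0, +1), (1, +1)), kb)],
            [n_s, n_r, 0])
        traj = integrate_meanfield(sys_, duration=20.0)
        expected = equilibrium_solve(n_s, n_r, area, kf, kb)
        assert traj.counts[-1, 2] == pytest.approx(expected, rel=1e-5)

    def test_ssa_ensemble_mean_near_ode(self, small_system):
        """Law of large numbers: the 20-seed SSA ensemble mean of each PSD's
        synaptic count at t=40 s lies within 3 SE of the ODE solution."""
        ode = integrate_meanfield(small_system, duration=40.0, burn_in=10.0)
        ens = np.array([
            [simulate(small_system, duration=40.0, seed=s, burn_in=10.0
                      ).synaptic_series(i)[-1] for i in small_system.spine_indices()]
            for s in range(200, 220)])
        for col, i in enumerate(small_system.spine_indices()):
            target = ode.synaptic_series(i)[-1]
            se = ens[:, col].std(ddof=1) / np.sqrt(ens.shape[0])
            assert abs(ens[:, col].mean() - target) < 3.0 * se + 1e-9
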