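import numpy as np
import pytest

from spinetraffic.analysis import (
    anova_tukey,
    compare_to_control,
    percent_change,
    percent_changes,
    summarize_percent_changes,
    synaptic_count,
)
from spinetraffic.engine import Trajectory


def constant_trajectory(system, values: dict[int, float], n_times: int = 41):
    """Trajectory with constant synaptic counts (receptors parked as bound)."""
    times = np.arange(n_times) * 0.5
    counts = np.zeros((n_times, system.n_species))
    for spine, v in values.items():
        idx = system.synaptic_indices(spine)[0]
        counts[:, idx] = v
    return Trajectory(times=times, counts=counts, system=system, seed=0)


def ramp_trajectory(system, spine, v0, v1, n_times: int = 41):
    traj = constant_trajectory(system, {spine: v0}, n_times)
    # step to v1 halfway through
    idx = system.synaptic_indices(spine)[0]
    traj.counts[n_times // 2:, idx] = v1
    return traj


class TestSynapticCount:
    def test_all_receptors_cytosolic_gives_zero(self, small_system):
        n = np.zeros(small_system.n_species, dtype=np.int64)
        for cyt in small_system.graph.of_kind("SPINE_CYTOSOL"):
            n[small_system.idx("Rc", cyt.id)] = 100
        traj = Trajectory(times=np.array([0.0, 0.5]), counts=np.vstack([n, n]),
                          system=small_system, seed=0)
        assert synaptic_count(traj, 1, 0.5).count == 0.0

    def test_conservation_across_pools(self, small_trajs, small_system):
        """Synaptic + extrasynaptic + cytosolic + in-transit receptors sum to
        the released total at every sample."""
        p = small_system.params
        total = p.n_ampar_surface + 2 * p.n_ampar_cyt_per_spine
        for tr in small_trajs:
            assert np.all(tr.total_receptor_series() == total)

    def test_smoothing_window_is_trailing(self, small_system):
        traj = ramp_trajectory(small_system, 1, 50, 100)
        # at the step time the trailing window still sees only the old level
        t_step = traj.times[len(traj.times) // 2]
        before = synaptic_count(traj, 1, t_step - 0.5, smooth=2.0).count
        assert before == 50.0


class TestPercentChange:
    def test_constant_series_zero(self, small_system):
        traj = constant_trajectory(small_system, {1: 80})
        assert percent_change(traj, 1, 5.0, 20.0).value == 0.0

    def test_doubling_and_halving(self, small_system):
        up = ramp_trajectory(small_system, 1, 50, 100)
        down = ramp_trajectory(small_system, 1, 100, 50)
        assert percent_change(up, 1, 5.0, 20.0, smooth=4.0).value == pytest.approx(100.0)
        assert percent_change(down, 1, 5.0, 20.0, smooth=4.0).value == pytest.approx(-50.0)

    def test_zero_baseline_raises(self, small_system):
        traj = constant_trajectory(small_system, {1: 0})
        with pytest.raises(ZeroDivisionError):
            percent_change(traj, 1, 5.0, 20.0)

    def test_outside_range_raises(self, small_system):
        traj = constant_trajectory(small_system, {1: 10})
        with pytest.raises(ValueError):
            percent_change(traj, 1, 5.0, 99.0)

    def test_summary_table(self, small_system):
        trajs = [ramp_trajectory(small_system, 1, 50, 55 + k) for k in range(4)]
        df = summarize_percent_changes(trajs, (5.0, 20.0), psd_indices=[1], smooth=4.0)
        row = df.iloc[0]
        expected = [100 * (55 + k - 50) / 50 for k in range(4)]
        assert row["mean"] == pytest.approx(np.mean(expected))
        assert row["std"] == pytest.approx(np.std(expected, ddof=1))
        assert row["n"] == 4


class TestTwoSample:
    def test_identical_samples(self):
        res = compare_to_control([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_welch_hand_computed(self):
        """{1,2,3} vs {4,5,6}: t = -3/sqrt(2/3) = -3.674..., dof = 4."""
        res = compare_to_control([1, 2, 3], [4, 5, 6], mode="welch_t")
        assert res.statistic == pytest.approx(-3.6742346, abs=1e-6)
        assert res.dof == pytest.approx(4.0)

    def test_paired_requires_matched_sizes(self):
        with pytest.raises(ValueError):
            compare_to_control([1, 2, 3], [1, 2], mode="paired_t")

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_to_control([1.0], [2.0, 3.0])


class TestAnovaTukey:
    def test_brute_force_sums_of_squares(self):
        """F statistic equals the explicit between/within decomposition."""
        groups = [[6.0, 8.0, 4.0, 5.0, 3.0, 4.0],
                  [8.0, 12.0, 9.0, 11.0, 6.0, 8.0],
                  [13.0, 9.0, 11.0, 8.0, 7.0, 12.0]]
        res = anova_tukey(groups)[0]
        allv = np.concatenate(groups)
        grand = allv.mean()
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ss_within = sum(((np.array(g) - np.mean(g)) ** 2).sum() for g in groups)
        k, n = len(groups), allv.size
        f_expected = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert res.test == "anova_oneway"
        assert res.statistic == pytest.approx(f_expected, rel=1e-10)
        assert res.dof == (k - 1, n - k)

    def test_tukey_matches_statsmodels(self):
        """Pairwise adjusted p-values agree with an independent studentized-
        range implementation."""
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(0)
        groups = [rng.normal(m, 1.0, 8) for m in (0.0, 0.5, 1.5)]
        ours = [r for r in anova_tukey(groups) if r.test == "tukey_hsd"]
        data = np.concatenate(groups)
        labels = np.repeat([0, 1, 2], 8)
        sm = statsmodels.pairwise_tukeyhsd(data, labels)
        for our, p_sm in zip(ours, sm.pvalues):
            # statsmodels interpolates studentized-range tables; agreement is
            # to table precision rather than machine precision
            assert our.p_value == pytest.approx(p_sm, abs=5e-3)

    def test_identical_constant_groups(self):
        res = anova_tukey([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])[0]
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([[1.0], [1.0, 2.0], [3.0, 4.0]])
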