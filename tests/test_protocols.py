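import time

import numpy as np
import pytest

from spinetraffic.protocols import (
    InductionEvent,
    Protocol,
    list_protocols,
    make_protocol,
    run_protocol,
)

# every figure-level experiment must have a registered protocol
FIGURE_COVERAGE = {
    "fig1F/1G sweeps": ["control_rest"],  # sweeps run on overrides of this model
    "fig2 rest": ["control_rest"],
    "fig3 single-spine": ["ltp_at_1", "ltd_at_1"],
    "fig4 multi-LTP": ["ltp_at_1", "ltp_at_12", "ltp_at_123", "ltp_at_1234"],
    "fig5 multi-LTD": ["ltd_at_1", "ltd_at_12", "ltd_at_123", "ltd_at_1234"],
    "fig6 sequential same-sign": ["seq_ltp12_ltp3", "seq_ltp123_ltp4",
                                  "seq_ltd12_ltd3", "seq_ltd123_ltd4",
                                  "ctrl_post_ltp3", "ctrl_post_ltd3"],
    "fig7 sequential mixed-sign": ["seq_ltp12_ltd3", "seq_ltp123_ltd4",
                                   "seq_ltd12_ltp3", "seq_ltd123_ltp4"],
    "fig8 two-state same-sign": ["ts_seq_ltp12_ltp3", "ts_seq_ltd12_ltd3",
                                 "ts_ltp_at_12", "ts_ltd_at_12"],
    "fig9 two-state mixed-sign": ["ts_seq_ltp12_ltd3", "ts_seq_ltd12_ltp3"],
    "open boundary": ["open_bath_rest"],
    "reduced test model": ["fixture_small"],
}


class TestRegistry:
    def test_registry_covers_every_figure_experiment(self):
        names = set(list_protocols())
        for fig, protos in FIGURE_COVERAGE.items():
            missing = set(protos) - names
            assert not missing, f"{fig}: missing {missing}"

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            make_protocol("ltp_at_everything")

    def test_ltp_at_1_structure(self):
        p = make_protocol("ltp_at_1")
        assert p.duration == 180.0 and p.burn_in == 30.0
        assert len(p.events) == 1
        ev = p.events[0]
        assert (ev.time, ev.spine_index, ev.enzyme) == (10.0, 1, "enzLTP")

    def test_sequential_structure(self):
        p = make_protocol("seq_ltp12_ltp3")
        assert p.duration == 330.0
        times = sorted(ev.time for ev in p.events)
        assert times == [10.0, 10.0, 180.0]
        posterior = [ev for ev in p.events if ev.time == 180.0]
        assert posterior[0].spine_index == 3

    def test_two_state_burn_in(self):
        p = make_protocol("ts_seq_ltp12_ltp3")
        assert p.variant.name == "two_state"
        assert p.burn_in == 50.0

    def test_control_has_no_events(self):
        assert make_protocol("control_rest").events == ()

    def test_replicate_counts_in_reported_range(self):
        for name in list_protocols():
            p = make_protocol(name)
            if p.benchmark_protocol:
                assert 5 <= p.n_replicates <= 12

    def test_parameter_override(self):
        p = make_protocol("control_rest", n_scaffold_per_psd=200)
        assert p.params.n_scaffold_per_psd == 200

    def test_invalid_override_rejected(self):
        with pytest.raises(ValueError):
            make_protocol("control_rest", n_replicates=99)
        with pytest.raises(ValueError):
            Protocol("x", duration=100.0,
                     events=(InductionEvent(150.0, 1, "enzLTP"),),
                     benchmark_protocol=False)

    def test_event_validation(self):
        with pytest.raises(ValueError):
            InductionEvent(10.0, 1, "enzXXX")
        with pytest.raises(ValueError):
            InductionEvent(10.0, 1, "enzLTP", copies=0)


class TestRun:
    def test_replicates_have_distinct_seeds(self, small_protocol, small_trajs):
        assert len(small_trajs) == small_protocol.n_replicates
        assert len({tr.seed for tr in small_trajs}) == len(small_trajs)

    def test_rerun_same_seeds_identical(self, small_protocol, small_trajs, small_system):
        again = run_protocol(small_protocol, seeds=[tr.seed for tr in small_trajs],
                             system=small_system)
        for a, b in zip(small_trajs, again):
            assert np.array_equal(a.counts, b.counts)

    def test_duplicate_seeds_rejected(self, small_protocol):
        with pytest.raises(ValueError):
            run_protocol(small_protocol, seeds=[1, 1, 2])

    def test_reduced_model_runs_fast(self, small_protocol, small_system):
        t0 = time.time()
        run_protocol(small_protocol, seeds=[991], system=small_system)
        assert time.time() - t0 < 30.0

    def test_induction_events_change_target_psd(self, small_protocol, small_system):
        proto = make_protocol("fixture_small")
        from dataclasses import replace
        proto = replace(proto, events=(InductionEvent(10.0, 1, "enzLTP"),))
        tr = run_protocol(proto, seeds=[55], system=None)[0]
        s1 = tr.synaptic_series(1)
        early = s1[tr.times <= 8].mean()
        late = s1[tr.times >= 50].mean()
        assert late > 1.3 * early
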