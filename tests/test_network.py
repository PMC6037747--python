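import numpy as np
import pytest

from spinetraffic.geometry import build_dendrite_model, PSD, SPINE_CYTOSOL
from spinetraffic.network import (
    ModelVariant,
    ParameterSet,
    apply_induction,
    build_network,
    ENZ_LTP,
    ENZ_LTD,
)
from spinetraffic.engine import integrate_meanfield


@pytest.fixture(scope="module")
def graph():
    return build_dendrite_model()


@pytest.fixture(scope="module")
def params():
    return ParameterSet()


@pytest.fixture(scope="module")
def three_state(graph, params):
    return build_network(graph, params, "three_state")


@pytest.fixture(scope="module")
def two_state(graph, params):
    return build_network(graph, params, ModelVariant("two_state"))


class TestParameterSet:
    def test_affinity_shift_identities(self, params):
        assert params.k_b1_LTP == params.k_b1 / 10.0
        assert params.k_b1_LTD == params.k_b1 * 10.0

    def test_defaults_are_model_constants(self, params):
        assert params.k_f1 == 1.0 and params.k_b1 == 100.0
        assert params.n_ampar_surface == 1000
        assert params.n_scaffold_per_psd == 300
        assert params.n_eep_per_ez == 10
        assert params.n_ampar_cyt_per_spine == 100
        assert params.n_enzyme_released == 100

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet(k_f2=-1.0)

    def test_bad_high_fraction_rejected(self):
        with pytest.raises(ValueError):
            ModelVariant("two_state", two_state_high_fraction=1.5)


class TestConstruction:
    def test_binding_channel_families_per_psd(self, three_state):
        for psd in three_state.graph.of_kind(PSD):
            binds = [c for c in three_state.channels
                     if c.name.startswith("bind:") and c.name.endswith(psd.id)]
            unbinds = [c for c in three_state.channels
                       if c.name.startswith("unbind:") and c.name.endswith(psd.id)]
            assert len(binds) == 3 and len(unbinds) == 3

    def test_diffusion_channels_double_couplings(self, three_state):
        hops = [c for c in three_state.channels if c.name.startswith("hop:")]
        assert len(hops) == 2 * len(three_state.graph.couplings)

    def test_two_state_initial_mixture(self, two_state):
        n0 = two_state.initial_state()
        for psd in two_state.graph.of_kind(PSD):
            assert n0[two_state.idx("S_hi", psd.id)] == 120
            assert n0[two_state.idx("S_lo", psd.id)] == 180

    def test_scaffolds_and_eep_have_no_diffusion(self, three_state):
        mobile = set()
        for c in three_state.channels:
            if c.name.startswith(("hop:", "bath_")):
                for sp, _ in c.stoich:
                    mobile.add(three_state.species_names[sp][0])
        assert mobile == {"R"}

    def test_every_channel_conserves_receptors(self, three_state, two_state):
        for system in (three_state, two_state):
            load = system.receptor_load()
            scaff = system.scaffold_load()
            for c in system.channels:
                assert sum(load[sp] * d for sp, d in c.stoich) == 0
                assert sum(scaff[sp] * d for sp, d in c.stoich) == 0

    def test_initial_receptor_total(self, three_state):
        assert three_state.total_receptors(three_state.initial_state()) == 1500


class TestInduction:
    def test_confined_to_target_spine(self, three_state):
        n0 = three_state.initial_state()
        n1 = apply_induction(three_state, n0, 1, ENZ_LTP)
        cyt1 = three_state.graph.spine_compartment(SPINE_CYTOSOL, 1)
        assert n1[three_state.idx(ENZ_LTP, cyt1.id)] == 100
        # nothing else changed
        diff = np.nonzero(n1 - n0)[0]
        assert diff.tolist() == [three_state.idx(ENZ_LTP, cyt1.id)]

    def test_unknown_spine_and_bad_copies(self, three_state):
        with pytest.raises(ValueError):
            apply_induction(three_state, three_state.initial_state(), 9, ENZ_LTP)
        with pytest.raises(ValueError):
            apply_induction(three_state, three_state.initial_state(), 1, ENZ_LTP, 0)

    def test_conversion_fast_and_complete(self, graph, params):
        """>=99% of the target PSD's scaffolds reach the LTP state within
        5 s of enzyme release (mean-field kinetics of the same channels)."""
        system = build_network(graph, params, "three_state")
        n0 = apply_induction(system, system.initial_state(), 1, ENZ_LTP)
        traj = integrate_meanfield(system, n0, duration=5.0, sample_dt=0.5)
        psd = graph.spine_compartment(PSD, 1)
        ltp = traj.counts[-1, system.idx("S_ltp", psd.id)]
        ltp_c = traj.counts[-1, system.idx("S_ltp.R", psd.id)]
        assert ltp + ltp_c >= 297.0

    def test_ltd_on_all_low_two_state_is_noop(self, graph, params):
        system = build_network(graph, params, ModelVariant("two_state",
                                                           two_state_high_fraction=0.0))
        n0 = apply_induction(system, system.initial_state(), 1, ENZ_LTD)
        traj = integrate_meanfield(system, n0, duration=2.0, sample_dt=0.5)
        psd = graph.spine_compartment(PSD, 1)
        hi = traj.counts[-1, system.idx("S_hi", psd.id)]
        hi_c = traj.counts[-1, system.idx("S_hi.R", psd.id)]
        assert hi + hi_c == pytest.approx(0.0, abs=1e-6)
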