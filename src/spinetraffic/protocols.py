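"""Named in-silico plasticity experiments.

Each protocol fixes the model variant, burn-in, duration, induction events
and replicate count for one figure-level experiment: LTP or LTD at 1-4
adjacent spines (observation window 10-180 s), sequential prior (t1 = 10 s)
plus posterior (t2 = 180 s) inductions over 330 s with analysis windows
dt1 = (10, 160) s and dt2 = (180, 330) s, the two-state-scaffold versions of
the sequential designs (50 s burn-in), and resting controls.  Replicate
counts follow the original experiments (5-12 stochastic repetitions).

``fixture_small`` is a deliberately reduced 2-spine model for fast tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

from .geometry import GeometryParams
from .network import (
    ModelVariant,
    ParameterSet,
    ReactionSystem,
    build_default_system,
    calibrated_parameters,
    ENZ_LTP,
    ENZ_LTD,
)
from .engine import Trajectory, simulate, integrate_meanfield

__all__ = [
    "InductionEvent",
    "Protocol",
    "make_protocol",
    "list_protocols",
    "run_protocol",
    "run_protocol_meanfield",
    "WINDOW_MAIN",
    "WINDOW_DT1",
    "WINDOW_DT2",
    "DEFAULT_BASE_SEED",
]

WINDOW_MAIN = (10.0, 180.0)   # induction -> end, single-induction designs
WINDOW_DT1 = (10.0, 160.0)    # prior induction window, sequential designs
WINDOW_DT2 = (180.0, 330.0)   # posterior induction window
DEFAULT_BASE_SEED = 20180709


@dataclass(frozen=True)
class InductionEvent:
    time: float
    spine_index: int
    enzyme: str  # "enzLTP" | "enzLTD"
    copies: int | None = None  # None -> ParameterSet.n_enzyme_released

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.enzyme not in (ENZ_LTP, ENZ_LTD):
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.copies is not None and self.copies <= 0:
            raise ValueError("copies must be > 0")


@dataclass(frozen=True)
class Protocol:
    name: str
    duration: float = 180.0
    burn_in: float = 30.0
    events: tuple[InductionEvent, ...] = ()
    variant: ModelVariant = ModelVariant("three_state")
    n_replicates: int = 5
    base_seed: int = DEFAULT_BASE_SEED
    boundary_mode: str = "reflective"
    geometry: GeometryParams | None = None
    params: ParameterSet | None = None  # None -> calibrated artifact
    benchmark_protocol: bool = True  # benchmark replicate-count rule (5-12) applies

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        for ev in self.events:
            if ev.time > self.duration:
                raise ValueError(f"event at {ev.time}s beyond duration {self.duration}s")
        if self.benchmark_protocol and not (5 <= self.n_replicates <= 12):
            raise ValueError("benchmark-reproduction protocols use 5-12 replicates")

    def seeds(self) -> list[int]:
        """Documented default replicate seeds.

        Derived from the base seed and the protocol name so that replicate
        noise is independent across protocols (a shared plain counter would
        reuse the same burn-in realizations everywhere)."""
        import hashlib

        h = int(hashlib.sha256(f"{self.base_seed}:{self.name}".encode())
                .hexdigest()[:8], 16) % (2 ** 31 - 4096)
        return [h + k for k in range(self.n_replicates)]

    def build_system(self) -> ReactionSystem:
        params = self.params if self.params is not None else calibrated_parameters()
        return build_default_system(
            params=params, variant=self.variant, geometry=self.geometry,
            boundary_mode=self.boundary_mode)


def _ltp_ltd(name_prefix: str, enzyme: str, spines: Sequence[int], n: int,
             **kw) -> Protocol:
    events = tuple(InductionEvent(10.0, s, enzyme) for s in spines)
    name = f"{name_prefix}_{''.join(map(str, spines))}"
    return Protocol(name=name, duration=180.0, burn_in=30.0, events=events,
                    n_replicates=n, **kw)


def _sequential(name: str, prior: Sequence[int], prior_enz: str,
                posterior: int, post_enz: str, n: int, *,
                two_state: bool = False) -> Protocol:
    events = tuple(InductionEvent(10.0, s, prior_enz) for s in prior)
    events += (InductionEvent(180.0, posterior, post_enz),)
    variant = ModelVariant("two_state") if two_state else ModelVariant("three_state")
    return Protocol(name=name, duration=330.0, burn_in=50.0 if two_state else 30.0,
                    events=events, variant=variant, n_replicates=n)


def _registry() -> dict[str, Callable[[], Protocol]]:
    reg: dict[str, Callable[[], Protocol]] = {}

    reg["control_rest"] = lambda: Protocol("control_rest", 180.0, 30.0, (), n_replicates=5)
    reg["control_rest_330"] = lambda: Protocol("control_rest_330", 330.0, 30.0, (),
                                               n_replicates=5)

    # LTP/LTD at 1-4 adjacent synapses (replicate counts as reported)
    ltp_n = {(1,): 6, (1, 2): 7, (1, 2, 3): 6, (1, 2, 3, 4): 8}
    ltd_n = {(1,): 5, (1, 2): 7, (1, 2, 3): 6, (1, 2, 3, 4): 7}
    for spines, n in ltp_n.items():
        reg[f"ltp_at_{''.join(map(str, spines))}"] = (
            lambda s=spines, n=n: _ltp_ltd("ltp_at", ENZ_LTP, s, n))
    for spines, n in ltd_n.items():
        reg[f"ltd_at_{''.join(map(str, spines))}"] = (
            lambda s=spines, n=n: _ltp_ltd("ltd_at", ENZ_LTD, s, n))

    # sequential prior (10 s) + posterior (180 s), all four sign combinations
    reg["seq_ltp12_ltp3"] = lambda: _sequential("seq_ltp12_ltp3", (1, 2), ENZ_LTP, 3, ENZ_LTP, 8)
    reg["seq_ltp123_ltp4"] = lambda: _sequential("seq_ltp123_ltp4", (1, 2, 3), ENZ_LTP, 4, ENZ_LTP, 12)
    reg["seq_ltd12_ltd3"] = lambda: _sequential("seq_ltd12_ltd3", (1, 2), ENZ_LTD, 3, ENZ_LTD, 8)
    reg["seq_ltd123_ltd4"] = lambda: _sequential("seq_ltd123_ltd4", (1, 2, 3), ENZ_LTD, 4, ENZ_LTD, 8)
    reg["seq_ltp12_ltd3"] = lambda: _sequential("seq_ltp12_ltd3", (1, 2), ENZ_LTP, 3, ENZ_LTD, 10)
    reg["seq_ltp123_ltd4"] = lambda: _sequential("seq_ltp123_ltd4", (1, 2, 3), ENZ_LTP, 4, ENZ_LTD, 11)
    reg["seq_ltd12_ltp3"] = lambda: _sequential("seq_ltd12_ltp3", (1, 2), ENZ_LTD, 3, ENZ_LTP, 8)
    reg["seq_ltd123_ltp4"] = lambda: _sequential("seq_ltd123_ltp4", (1, 2, 3), ENZ_LTD, 4, ENZ_LTP, 8)

    # single posterior induction without prior plasticity (sequential controls)
    reg["ctrl_post_ltp3"] = lambda: Protocol(
        "ctrl_post_ltp3", 330.0, 30.0, (InductionEvent(180.0, 3, ENZ_LTP),), n_replicates=5)
    reg["ctrl_post_ltd3"] = lambda: Protocol(
        "ctrl_post_ltd3", 330.0, 30.0, (InductionEvent(180.0, 3, ENZ_LTD),), n_replicates=5)

    # two-state scaffold variant (40% high-affinity basal mixture, 50 s burn-in)
    ts = ModelVariant("two_state")
    reg["ts_control_rest"] = lambda: Protocol("ts_control_rest", 330.0, 50.0, (),
                                              variant=ts, n_replicates=5)
    reg["ts_ltp_at_12"] = lambda: Protocol(
        "ts_ltp_at_12", 180.0, 50.0,
        tuple(InductionEvent(10.0, s, ENZ_LTP) for s in (1, 2)), variant=ts, n_replicates=5)
    reg["ts_ltd_at_12"] = lambda: Protocol(
        "ts_ltd_at_12", 180.0, 50.0,
        tuple(InductionEvent(10.0, s, ENZ_LTD) for s in (1, 2)), variant=ts, n_replicates=5)
    reg["ts_seq_ltp12_ltp3"] = lambda: _sequential("ts_seq_ltp12_ltp3", (1, 2), ENZ_LTP, 3, ENZ_LTP, 5, two_state=True)
    reg["ts_seq_ltd12_ltd3"] = lambda: _sequential("ts_seq_ltd12_ltd3", (1, 2), ENZ_LTD, 3, ENZ_LTD, 5, two_state=True)
    reg["ts_seq_ltp12_ltd3"] = lambda: _sequential("ts_seq_ltp12_ltd3", (1, 2), ENZ_LTP, 3, ENZ_LTD, 5, two_state=True)
    reg["ts_seq_ltd12_ltp3"] = lambda: _sequential("ts_seq_ltd12_ltp3", (1, 2), ENZ_LTD, 3, ENZ_LTP, 5, two_state=True)
    reg["ts_ctrl_post_ltp3"] = lambda: Protocol(
        "ts_ctrl_post_ltp3", 330.0, 50.0, (InductionEvent(180.0, 3, ENZ_LTP),),
        variant=ts, n_replicates=5)
    reg["ts_ctrl_post_ltd3"] = lambda: Protocol(
        "ts_ctrl_post_ltd3", 330.0, 50.0, (InductionEvent(180.0, 3, ENZ_LTD),),
        variant=ts, n_replicates=5)

    # continuous receptor flow through the lateral membranes
    reg["open_bath_rest"] = lambda: Protocol(
        "open_bath_rest", 180.0, 30.0, (), boundary_mode="open_bath", n_replicates=5)

    # reduced model for fast tests: 2 spines, 200 surface receptors, 60 s
    reg["fixture_small"] = lambda: Protocol(
        "fixture_small", 60.0, 10.0, (), n_replicates=3, benchmark_protocol=False,
        geometry=GeometryParams(n_spines=2),
        params=calibrated_parameters(
            n_ampar_surface=200, n_scaffold_per_psd=60, n_ampar_cyt_per_spine=20))
    return reg


_REGISTRY = None


def _get_registry() -> dict[str, Callable[[], Protocol]]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _registry()
    return _REGISTRY


def list_protocols() -> list[str]:
    return sorted(_get_registry())


def make_protocol(name: str, **overrides) -> Protocol:
    """Instantiate a registered protocol, optionally overriding its fields.

    Parameter-level overrides (``n_scaffold_per_psd``, ``k_b1``,
    ``n_ampar_surface``, ...) are applied to the protocol's ParameterSet;
    all other keys override Protocol fields.
    """
    reg = _get_registry()
    if name not in reg:
        raise KeyError(f"unknown protocol {name!r}; see list_protocols()")
    proto = reg[name]()
    param_keys = {f for f in ParameterSet.__dataclass_fields__}
    param_over = {k: v for k, v in overrides.items() if k in param_keys}
    proto_over = {k: v for k, v in overrides.items() if k not in param_keys}
    if param_over:
        base = proto.params if proto.params is not None else calibrated_parameters()
        proto_over["params"] = replace(base, **param_over)
    if proto_over:
        proto = replace(proto, **proto_over)
    return proto


def _events_tuple(proto: Protocol):
    return [(ev.time, ev.spine_index, ev.enzyme, ev.copies) for ev in proto.events]


def run_protocol(
    protocol: Protocol,
    seeds: Sequence[int] | None = None,
    method: str = "ssa",
    sample_dt: float = 0.5,
    system: ReactionSystem | None = None,
) -> list[Trajectory]:
    """One stochastic trajectory per seed (distinct seeds required)."""
    if seeds is None:
        seeds = protocol.seeds()
    seeds = list(seeds)
    if len(set(seeds)) != len(seeds):
        raise ValueError("replicate seeds must be distinct")
    if system is None:
        system = protocol.build_system()
    events = _events_tuple(protocol)
    return [
        simulate(system, duration=protocol.duration, seed=s, method=method,
                 sample_dt=sample_dt, burn_in=protocol.burn_in, events=events)
        for s in seeds
    ]


def run_protocol_meanfield(
    protocol: Protocol,
    sample_dt: float = 0.5,
    system: ReactionSystem | None = None,
) -> Trajectory:
    """Deterministic mean-field trajectory of a protocol (calibration oracle)."""
    if system is None:
        system = protocol.build_system()
    return integrate_meanfield(
        system, duration=protocol.duration, burn_in=protocol.burn_in,
        events=_events_tuple(protocol), sample_dt=sample_dt)
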