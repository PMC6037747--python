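"""Stochastic (SSA / tau-leap) and mean-field simulation of a ReactionSystem.

The exact solver is the Gillespie direct method, compiled with numba and
accelerated by a channel dependency graph so only affected propensities are
recomputed after each firing; channels are ordered by their initial
propensity so the linear selection scan stays short.  The approximate
solver is a fixed-step tau-leap with binomial draws on single-reactant
channels (which cannot overdraw their substrate) and Poisson draws on
bimolecular channels; any step that would drive a count negative is
rejected and retried at half the step, never clamped.

``integrate_meanfield`` integrates the mass-action ODEs of the same
channels and serves as the deterministic oracle for calibration and
cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .geometry import SPINE_CYTOSOL
from .network import ReactionSystem, apply_induction

__all__ = [
    "SimState",
    "Trajectory",
    "simulate",
    "integrate_meanfield",
    "sample_waiting_times",
    "compile_network",
]


@dataclass
class SimState:
    counts: np.ndarray
    time: float = 0.0


@dataclass
class CompiledNetwork:
    r1: np.ndarray
    r2: np.ndarray
    rate: np.ndarray
    s_ptr: np.ndarray
    s_idx: np.ndarray
    s_delta: np.ndarray
    dep_ptr: np.ndarray
    dep_idx: np.ndarray
    perm: np.ndarray  # compiled order -> original channel index


def compile_network(system: ReactionSystem) -> CompiledNetwork:
    chans = system.channels
    n_ch = len(chans)
    r1 = np.full(n_ch, -1, dtype=np.int64)
    r2 = np.full(n_ch, -1, dtype=np.int64)
    rate = np.zeros(n_ch)
    for c, ch in enumerate(chans):
        if len(ch.reactants) > 0:
            r1[c] = ch.reactants[0]
        if len(ch.reactants) > 1:
            r2[c] = ch.reactants[1]
        rate[c] = ch.rate

    # order channels by initial propensity (descending) to shorten the scan
    n0 = system.initial_state().astype(np.float64)
    a0 = np.empty(n_ch)
    for c in range(n_ch):
        if r1[c] < 0:
            a0[c] = rate[c]
        elif r2[c] < 0:
            a0[c] = rate[c] * max(n0[r1[c]], 1.0)
        else:
            a0[c] = rate[c] * max(n0[r1[c]], 1.0) * max(n0[r2[c]], 1.0)
    perm = np.argsort(-a0, kind="stable").astype(np.int64)

    r1, r2, rate = r1[perm], r2[perm], rate[perm]
    s_ptr = [0]
    s_idx: list[int] = []
    s_delta: list[int] = []
    for c in perm:
        for sp, d in chans[c].stoich:
            s_idx.append(sp)
            s_delta.append(d)
        s_ptr.append(len(s_idx))

    # dependency graph: after channel c fires, recompute channels whose
    # reactants include any species changed by c
    by_reactant: dict[int, set[int]] = {}
    for c in range(n_ch):
        for r in (r1[c], r2[c]):
            if r >= 0:
                by_reactant.setdefault(int(r), set()).add(c)
    dep_ptr = [0]
    dep_idx: list[int] = []
    for c in range(n_ch):
        dep: set[int] = set()
        for k in range(s_ptr[c], s_ptr[c + 1]):
            dep |= by_reactant.get(int(s_idx[k]), set())
        dep_idx.extend(sorted(dep))
        dep_ptr.append(len(dep_idx))

    return CompiledNetwork(
        r1=r1,
        r2=r2,
        rate=rate,
        s_ptr=np.array(s_ptr, dtype=np.int64),
        s_idx=np.array(s_idx, dtype=np.int64),
        s_delta=np.array(s_delta, dtype=np.int64),
        dep_ptr=np.array(dep_ptr, dtype=np.int64),
        dep_idx=np.array(dep_idx, dtype=np.int64),
        perm=perm,
    )


@njit(cache=True)
def _propensity(c, n, r1, r2, rate):
    if r1[c] < 0:
        return rate[c]
    if r2[c] < 0:
        return rate[c] * n[r1[c]]
    return rate[c] * n[r1[c]] * n[r2[c]]


@njit(cache=True)
def _ssa_kernel(n, r1, r2, rate, s_ptr, s_idx, s_delta, dep_ptr, dep_idx,
                t0, t_end, sample_times, out, si, seed, wait_out):
    """Gillespie direct method on integer counts ``n`` (modified in place).

    Records ``out[k] = n`` at each ``sample_times[k]`` passed; returns the
    updated sample cursor.  ``wait_out`` (may be empty) receives the first
    waiting times for distributional tests.
    """
    np.random.seed(seed)
    n_ch = r1.size
    a = np.empty(n_ch)
    a_sum = 0.0
    for c in range(n_ch):
        a[c] = _propensity(c, n, r1, r2, rate)
        a_sum += a[c]
    t = t0
    n_samples = sample_times.size
    events = 0
    n_wait = wait_out.size
    while True:
        if a_sum <= 1e-300:
            while si < n_samples and sample_times[si] <= t_end + 1e-12:
                for j in range(n.size):
                    out[si, j] = n[j]
                si += 1
            break
        dt = -math.log(np.random.random()) / a_sum
        t_next = t + dt
        if events < n_wait:
            wait_out[events] = dt
        bound = t_next if t_next < t_end else t_end + 1e-12
        while si < n_samples and sample_times[si] <= bound:
            for j in range(n.size):
                out[si, j] = n[j]
            si += 1
        if t_next >= t_end:
            break
        t = t_next
        u = np.random.random() * a_sum
        acc = 0.0
        c = n_ch - 1
        for k in range(n_ch):
            acc += a[k]
            if u <= acc:
                c = k
                break
        for k in range(s_ptr[c], s_ptr[c + 1]):
            n[s_idx[k]] += s_delta[k]
        for k in range(dep_ptr[c], dep_ptr[c + 1]):
            d = dep_idx[k]
            a_sum -= a[d]
            a[d] = _propensity(d, n, r1, r2, rate)
            a_sum += a[d]
        events += 1
        if n_wait > 0 and events >= n_wait:
            break
        if events % 4_000_000 == 0:  # refresh accumulated float drift
            a_sum = 0.0
            for k in range(n_ch):
                a_sum += a[k]
    return si, events


@njit(cache=True)
def _tau_kernel(n, r1, r2, rate, s_ptr, s_idx, s_delta,
                t0, t_end, dt_max, sample_times, out, si, seed):
    """Fixed-step tau-leap with halving on negativity (never clamps)."""
    np.random.seed(seed)
    n_ch = r1.size
    n_sp = n.size
    n_samples = sample_times.size
    t = t0
    draws = np.empty(n_ch, dtype=np.int64)
    trial = np.empty(n_sp, dtype=np.int64)
    while si < n_samples and sample_times[si] <= t + 1e-12:
        for j in range(n_sp):
            out[si, j] = n[j]
        si += 1
    while t < t_end - 1e-12:
        dt = dt_max
        if t + dt > t_end:
            dt = t_end - t
        ok = False
        for _attempt in range(60):
            for j in range(n_sp):
                trial[j] = n[j]
            for c in range(n_ch):
                if r1[c] < 0:
                    draws[c] = np.random.poisson(rate[c] * dt)
                elif r2[c] < 0:
                    nr = n[r1[c]]
                    if nr <= 0:
                        draws[c] = 0
                    else:
                        p = 1.0 - math.exp(-rate[c] * dt)
                        draws[c] = np.random.binomial(nr, p)
                else:
                    a = rate[c] * n[r1[c]] * n[r2[c]]
                    draws[c] = np.random.poisson(a * dt) if a > 0 else 0
            for c in range(n_ch):
                if draws[c] > 0:
                    for k in range(s_ptr[c], s_ptr[c + 1]):
                        trial[s_idx[k]] += s_delta[k] * draws[c]
            neg = False
            for j in range(n_sp):
                if trial[j] < 0:
                    neg = True
                    break
            if not neg:
                ok = True
                break
            dt *= 0.5
        if not ok:
            return -1, si  # signal failure instead of silently clamping
        for j in range(n_sp):
            n[j] = trial[j]
        t += dt
        while si < n_samples and sample_times[si] <= t + 1e-12:
            for j in range(n_sp):
                out[si, j] = n[j]
            si += 1
    return 0, si


@dataclass
class Trajectory:
    """Time-sampled copy numbers for one replicate (burn-in already removed)."""

    times: np.ndarray
    counts: np.ndarray  # shape (n_times, n_species)
    system: ReactionSystem
    seed: int
    method: str = "ssa"
    burn_in: float = 0.0

    def value(self, species: str, comp_id: str) -> np.ndarray:
        return self.counts[:, self.system.idx(species, comp_id)]

    def synaptic_series(self, spine_index: int) -> np.ndarray:
        idx = self.system.synaptic_indices(spine_index)
        return self.counts[:, idx].sum(axis=1)

    def total_receptor_series(self) -> np.ndarray:
        return self.counts @ self.system.receptor_load()

    def to_frame(self):
        import pandas as pd

        names = self.system.species_names
        recs = []
        for k, (sp, comp) in enumerate(names):
            recs.append(pd.DataFrame({
                "time": self.times,
                "species": sp,
                "compartment": comp,
                "count": self.counts[:, k],
            }))
        return pd.concat(recs, ignore_index=True)


def _segment_seed(seed: int, segment: int) -> int:
    return int((np.uint64(seed) * np.uint64(1000003) + np.uint64(7919 * (segment + 1)))
               % np.uint64(2 ** 31))


def simulate(
    system: ReactionSystem,
    initial: SimState | np.ndarray | None = None,
    duration: float = 60.0,
    seed: int = 0,
    method: str = "ssa",
    sample_dt: float = 0.5,
    burn_in: float = 0.0,
    events: Sequence[tuple[float, int, str, int | None]] = (),
    tau_dt: float = 1e-3,
) -> Trajectory:
    """Run one stochastic replicate and return its sampled trajectory.

    ``events`` are ``(time, spine_index, enzyme, copies)`` inductions on the
    post-burn-in clock; the burn-in interval is simulated but discarded and
    the returned times start at 0.  Identical inputs give bit-identical
    trajectories.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if method not in ("ssa", "tau_leap"):
        raise ValueError(f"unknown method {method!r}")
    if method == "tau_leap" and tau_dt > 0.010 + 1e-12:
        raise ValueError("tau_leap step must be <= 10 ms")
    if initial is None:
        counts = system.initial_state()
    elif isinstance(initial, SimState):
        counts = np.array(initial.counts, dtype=np.int64, copy=True)
    else:
        counts = np.array(initial, dtype=np.int64, copy=True)
    if counts.min() < 0:
        raise ValueError("initial counts must be nonnegative")

    cn = system.compiled()
    n_steps = int(round(duration / sample_dt))
    rel_times = np.arange(n_steps + 1) * sample_dt
    sample_times = burn_in + rel_times
    out = np.zeros((sample_times.size, system.n_species), dtype=np.int64)

    ev = sorted(events, key=lambda e: e[0])
    for e in ev:
        if not (0.0 <= e[0] <= duration):
            raise ValueError(f"event time {e[0]} outside [0, {duration}]")
    boundaries = [burn_in + e[0] for e in ev] + [burn_in + duration]

    t_cur = 0.0
    si = 0
    empty_wait = np.empty(0)
    for seg, t_stop in enumerate(boundaries):
        seg_seed = _segment_seed(seed, seg)
        if t_stop > t_cur:
            if method == "ssa":
                si, _ = _ssa_kernel(
                    counts, cn.r1, cn.r2, cn.rate, cn.s_ptr, cn.s_idx, cn.s_delta,
                    cn.dep_ptr, cn.dep_idx, t_cur, t_stop, sample_times, out, si,
                    seg_seed, empty_wait)
            else:
                status, si = _tau_kernel(
                    counts, cn.r1, cn.r2, cn.rate, cn.s_ptr, cn.s_idx, cn.s_delta,
                    t_cur, t_stop, tau_dt, sample_times, out, si, seg_seed)
                if status != 0:
                    raise RuntimeError(
                        "tau-leap could not find a nonnegative step; "
                        "reduce tau_dt or use method='ssa'")
            t_cur = t_stop
        if seg < len(ev):
            _t, spine, enzyme, copies = ev[seg]
            counts = apply_induction(system, counts, spine, enzyme, copies)

    # any samples exactly at the final boundary not yet written
    while si < sample_times.size:
        out[si] = counts
        si += 1

    return Trajectory(
        times=rel_times,
        counts=out,
        system=system,
        seed=seed,
        method=method,
        burn_in=burn_in,
    )


def sample_waiting_times(
    system: ReactionSystem,
    initial: np.ndarray | None = None,
    n_events: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """First ``n_events`` SSA waiting times (for exactness tests)."""
    counts = (system.initial_state() if initial is None
              else np.array(initial, dtype=np.int64, copy=True))
    cn = system.compiled()
    wait = np.zeros(n_events)
    sample_times = np.empty(0)
    out = np.zeros((0, system.n_species), dtype=np.int64)
    _ssa_kernel(
        counts, cn.r1, cn.r2, cn.rate, cn.s_ptr, cn.s_idx, cn.s_delta,
        cn.dep_ptr, cn.dep_idx, 0.0, np.inf, sample_times, out, 0,
        _segment_seed(seed, 0), wait)
    return wait


def _rhs_factory(system: ReactionSystem):
    cn = system.compiled()
    n_ch = cn.r1.size
    n_sp = system.n_species
    S = np.zeros((n_sp, n_ch))
    for c in range(n_ch):
        for k in range(cn.s_ptr[c], cn.s_ptr[c + 1]):
            S[cn.s_idx[k], c] += cn.s_delta[k]
    r1, r2, rate = cn.r1, cn.r2, cn.rate
    uni = (r1 >= 0) & (r2 < 0)
    bi = r2 >= 0
    zero = r1 < 0

    def rhs(_t, y):
        a = np.zeros(n_ch)
        a[zero] = rate[zero]
        a[uni] = rate[uni] * y[r1[uni]]
        a[bi] = rate[bi] * y[r1[bi]] * y[r2[bi]]
        return S @ a

    return rhs


def integrate_meanfield(
    system: ReactionSystem,
    initial: np.ndarray | None = None,
    duration: float = 60.0,
    burn_in: float = 0.0,
    events: Sequence[tuple[float, int, str, int | None]] = (),
    sample_dt: float = 0.5,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> Trajectory:
    """Mass-action mean-field ODE trajectory of the same reaction channels."""
    y = (system.initial_state() if initial is None
         else np.array(initial, dtype=float, copy=True)).astype(float)
    rhs = _rhs_factory(system)
    n_steps = int(round(duration / sample_dt))
    rel_times = np.arange(n_steps + 1) * sample_dt
    sample_times = burn_in + rel_times
    ev = sorted(events, key=lambda e: e[0])
    boundaries = [burn_in + e[0] for e in ev] + [burn_in + duration]
    out = np.zeros((sample_times.size, system.n_species))
    t_cur = 0.0
    si = 0
    for seg, t_stop in enumerate(boundaries):
        if t_stop > t_cur + 1e-12:
            in_seg = sample_times[(sample_times >= t_cur - 1e-9) & (sample_times <= t_stop + 1e-9)]
            t_eval = np.unique(np.append(in_seg, t_stop))
            sol = solve_ivp(rhs, (t_cur, t_stop), y, method="LSODA",
                            t_eval=t_eval, rtol=rtol, atol=atol)
            if not sol.success:
                raise RuntimeError(f"mean-field integration failed: {sol.message}")
            for j in range(sol.t.size):
                if si < sample_times.size and abs(sol.t[j] - sample_times[si]) < 1e-6:
                    out[si] = sol.y[:, j]
                    si += 1
            y = sol.y[:, -1]
            t_cur = t_stop
        if seg < len(ev):
            _t, spine, enzyme, copies = ev[seg]
            if copies is None:
                copies = system.params.n_enzyme_released
            cyt = system.graph.spine_compartment(SPINE_CYTOSOL, spine)
            y[system.idx(enzyme, cyt.id)] += copies
    while si < sample_times.size:
        out[si] = y
        si += 1
    return Trajectory(times=rel_times, counts=out, system=system, seed=-1,
                      method="meanfield", burn_in=burn_in)
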