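"""Calibration of the trafficking rate constants and analytic oracles.

The scaffold-binding constants (``k_f1``, ``k_b1``), copy numbers and
geometry are fixed model inputs, but the four EEP trafficking rates
(``k_f2``, ``k_b2``, ``k_f3``, ``k_b3``) are only constrained indirectly:
the resting cytosolic pool must hold around 100 receptors per spine, the
resting synaptic population 100-120 receptors per PSD, and the calibrated
kinetics must reproduce the reported homo- and heterosynaptic percent
changes.  ``calibrate`` fits these rates on the mean-field oracle
(derivative-free Nelder-Mead from a fixed start, in log space) and the
result is frozen into a JSON artifact shipped with the package, so tests
and analyses never re-run the fit.

``equilibrium_solve`` is the closed-form single-PSD binding equilibrium used
throughout the tests as an independent oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import optimize

from .network import ParameterSet, calibrated_parameters, R_CYT
from .geometry import SPINE_CYTOSOL, PSD
from . import reference
from .analysis import percent_change

__all__ = [
    "CalibrationTarget",
    "equilibrium_solve",
    "default_targets",
    "calibrate",
    "predict_benchmarks",
    "write_artifact",
    "load_report",
]

FREE_PARAMS = ("k_f2", "k_b2", "k_f3", "k_b3")


@dataclass(frozen=True)
class CalibrationTarget:
    name: str          # observable name (rest_* or a reference benchmark name)
    target_value: float
    tolerance: float

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


def equilibrium_solve(
    n_scaffold: float, n_free_local: float, area: float, k_f1: float, k_b1: float
) -> float:
    """Equilibrium number of scaffold.AMPAR complexes in one closed PSD.

    Mass action with surface-density scaling,
    ``(k_f1/A) * (S_tot - C) * (R_tot - C) = k_b1 * C``, solved for the
    unique root ``C`` in ``[0, min(S_tot, R_tot)]``.
    """
    if n_scaffold < 0 or n_free_local < 0 or area <= 0 or k_f1 <= 0 or k_b1 < 0:
        raise ValueError("inputs must be positive (k_b1 may be 0)")
    m = k_b1 * area / k_f1
    b = n_scaffold + n_free_local + m
    disc = b * b - 4.0 * n_scaffold * n_free_local
    assert disc >= 0.0, "binding equilibrium discriminant negative"
    # smaller quadratic root, written cancellation-free for large b
    c = 2.0 * n_scaffold * n_free_local / (b + math.sqrt(disc))
    hi = min(n_scaffold, n_free_local)
    assert -1e-9 <= c <= hi + 1e-9, "no admissible equilibrium root"
    return float(min(max(c, 0.0), hi))


def default_targets() -> list[CalibrationTarget]:
    """Printed constraints used to pin down the trafficking rates."""
    return [
        CalibrationTarget("rest_cyt_per_spine", 100.0, 10.0),
        CalibrationTarget("rest_synaptic_per_psd", 110.0, 10.0),
        CalibrationTarget("ltp1_psd1", 119.0, 6.8),
        CalibrationTarget("ltp12_psd3_mag", 15.8, 3.7),
        CalibrationTarget("ltp1234_psd5_mag", 29.4, 5.35),
        CalibrationTarget("ltd1234_psd5", 24.8, 7.8),
    ]


# -- mean-field observable computation --------------------------------------

def _total_propensity(system, y: np.ndarray) -> float:
    cn = system.compiled()
    a = 0.0
    for c in range(cn.r1.size):
        if cn.r1[c] < 0:
            a += cn.rate[c]
        elif cn.r2[c] < 0:
            a += cn.rate[c] * y[cn.r1[c]]
        else:
            a += cn.rate[c] * y[cn.r1[c]] * y[cn.r2[c]]
    return float(a)


def _rest_observables(params: ParameterSet) -> dict[str, float]:
    from .protocols import make_protocol, run_protocol_meanfield

    proto = make_protocol("control_rest", params=params)
    traj = run_protocol_meanfield(proto)
    system = traj.system
    cyts = [system.idx(R_CYT, c.id) for c in system.graph.of_kind(SPINE_CYTOSOL)]
    rest_cyt = float(traj.counts[-1, cyts].mean())
    syn = np.mean([traj.synaptic_series(s)[-1] for s in system.spine_indices()])
    return {
        "rest_cyt_per_spine": rest_cyt,
        "rest_synaptic_per_psd": float(syn),
        "rest_event_rate": _total_propensity(system, traj.counts[-1]),
    }


def _benchmark_value(traj, bench: reference.Benchmark) -> float:
    if bench.window is None:
        system = traj.system
        mask = traj.times >= traj.times[-1] - 30.0
        vals = [traj.counts[mask][:, system.synaptic_indices(s)].sum(axis=1).mean()
                for s in system.spine_indices()]
        return float(np.mean(vals))
    pc = percent_change(traj, bench.psd, bench.window[0], bench.window[1]).value
    return float(-pc if bench.magnitude else pc)


def compute_observables(params: ParameterSet, names: list[str]) -> dict[str, float]:
    """Mean-field values of the named observables (one ODE run per protocol)."""
    from .protocols import make_protocol, run_protocol_meanfield

    out: dict[str, float] = {}
    rest_names = [n for n in names if n.startswith("rest_") and n not in reference.BENCHMARKS]
    if rest_names:
        rest = _rest_observables(params)
        out.update({n: rest[n] for n in rest_names})
    bench_names = [n for n in names if n in reference.BENCHMARKS]
    by_proto: dict[str, list[reference.Benchmark]] = {}
    for n in bench_names:
        b = reference.BENCHMARKS[n]
        by_proto.setdefault(b.protocol, []).append(b)
    for proto_name, benches in by_proto.items():
        proto = make_protocol(proto_name, params=params)
        traj = run_protocol_meanfield(proto)
        for b in benches:
            out[b.name] = _benchmark_value(traj, b)
    return out


def predict_benchmarks(params: ParameterSet | None = None,
                       names: list[str] | None = None) -> dict[str, float]:
    """Mean-field predictions of the reference benchmarks for a parameter set."""
    p = params if params is not None else calibrated_parameters()
    if names is None:
        names = list(reference.BENCHMARKS)
    return compute_observables(p, names)


# -- fitting -----------------------------------------------------------------

def default_soft_targets() -> list[CalibrationTarget]:
    """Additional printed values that steer the fit but, being known surrogate
    bias directions, do not gate feasibility."""
    return [
        CalibrationTarget("seq_ltp12_ltp3_dt2", 137.0, 6.0),
        CalibrationTarget("ctrl_post_ltp3_dt2", 117.0, 6.0),
        CalibrationTarget("ltp123_psd1", 96.3, 8.0),
        CalibrationTarget("ltd12_psd3", 13.3, 5.5),
    ]


def calibrate(
    targets: list[CalibrationTarget] | None = None,
    free_params: tuple[str, ...] = FREE_PARAMS,
    base: ParameterSet | None = None,
    x0: dict[str, float] | None = None,
    maxiter: int = 250,
    full_report: bool = True,
    soft_targets: list[CalibrationTarget] | None = None,
) -> tuple[ParameterSet, dict]:
    """Fit the free trafficking rates to the calibration targets.

    Runs Nelder-Mead in log10 space on the mean-field oracle from a fixed
    starting point.  Returns the fitted :class:`ParameterSet` and a report
    with achieved values per target, a feasibility flag, and (if
    ``full_report``) mean-field predictions for every reference benchmark
    with a ``within_1std`` surrogate-bias flag.
    """
    if targets is None:
        targets = default_targets()
        if soft_targets is None:
            soft_targets = default_soft_targets()
    soft_targets = soft_targets or []
    if base is None:
        base = ParameterSet()
    names = [t.name for t in targets]
    soft_names = [t.name for t in soft_targets]

    def with_params(x: np.ndarray) -> ParameterSet:
        vals = {k: float(10.0 ** xi) for k, xi in zip(free_params, x)}
        return replace(base, **vals)

    # among kinetically equivalent fits prefer the least stiff one: cap the
    # rates and softly penalize the resting total event rate of the SSA
    bounds = {"k_f2": (1e-4, 50.0), "k_b2": (1e-4, 5000.0),
              "k_f3": (1e-4, 200.0), "k_b3": (1e-4, 100.0)}
    eval_names = list(dict.fromkeys(names + soft_names + ["rest_event_rate"]))

    def objective(x: np.ndarray) -> float:
        for k, xi in zip(free_params, x):
            lo, hi = bounds.get(k, (1e-4, 1e4))
            if not (math.log10(lo) - 1e-9 <= xi <= math.log10(hi) + 1e-9):
                return 1e6 + float(np.sum(x ** 2))
        p = with_params(x)
        try:
            obs = compute_observables(p, eval_names)
        except Exception:
            return 1e6
        cost = float(sum(((obs[t.name] - t.target_value) / t.tolerance) ** 2
                         for t in targets))
        cost += 0.5 * float(sum(((obs[t.name] - t.target_value) / t.tolerance) ** 2
                                for t in soft_targets))
        cost += max(0.0, (obs["rest_event_rate"] - 1.8e5) / 3e4) ** 2
        return cost

    start = {"k_f2": 0.05, "k_b2": 0.5, "k_f3": 1.0, "k_b3": 0.1}
    if x0:
        start.update(x0)
    if free_params:
        x_init = np.array([math.log10(start[k]) for k in free_params])
        res = optimize.minimize(objective, x_init, method="Nelder-Mead",
                                options={"maxiter": maxiter, "xatol": 1e-3,
                                         "fatol": 1e-4})
        fitted = with_params(res.x)
    else:
        fitted = base
    achieved = compute_observables(fitted, names)
    target_rows = []
    feasible = True
    for t in targets:
        resid = (achieved[t.name] - t.target_value) / t.tolerance
        ok = abs(resid) <= 1.0
        feasible &= ok
        target_rows.append({
            "name": t.name, "target": t.target_value, "tolerance": t.tolerance,
            "achieved": achieved[t.name], "within_tolerance": ok,
        })
    report: dict = {"feasible": feasible, "targets": target_rows}
    if full_report:
        report["benchmarks"] = benchmark_report(fitted)
    return fitted, report


def _verification_seeds(protocol_name: str, n: int) -> list[int]:
    import hashlib

    h = int(hashlib.sha256(f"calibration-verify:{protocol_name}".encode())
            .hexdigest()[:8], 16) % (2 ** 31 - 64)
    return [h + k for k in range(n)]


def benchmark_report(params: ParameterSet, n_verify: int = 12) -> list[dict]:
    """Mean-field prediction plus stochastic verification for every benchmark.

    The ``within_1std`` flag is False (surrogate bias documented, validation
    widens to two STD) when either oracle — the mean-field prediction or the
    stochastic verification mean (``n_verify`` replicates on a dedicated
    seed list) — departs from the reported mean by more than one STD.
    """
    from .protocols import make_protocol, run_protocol
    from .analysis import percent_changes
    from .sweeps import binding_only_parameters, rest_synaptic_count

    preds = predict_benchmarks(params)
    by_proto: dict[str, list[reference.Benchmark]] = {}
    for b in reference.BENCHMARKS.values():
        if b.window is not None:
            by_proto.setdefault(b.protocol, []).append(b)
    stoch: dict[str, tuple[float, float]] = {}
    for proto_name, benches in by_proto.items():
        proto = make_protocol(proto_name, params=params)
        trajs = run_protocol(proto, seeds=_verification_seeds(proto_name, n_verify))
        for b in benches:
            vals = percent_changes(trajs, b.psd, b.window)
            if b.magnitude:
                vals = -vals
            stoch[b.name] = (float(np.mean(vals)),
                             float(np.std(vals, ddof=1) / np.sqrt(len(vals))))
    rest = reference.BENCHMARKS["rest_synaptic_count"]
    rest_val = rest_synaptic_count(
        binding_only_parameters(D_free=params.D_free), method="ssa",
        seeds=tuple(_verification_seeds("rest_binding_only", 5)))
    stoch[rest.name] = (rest_val, None)

    rows = []
    for name, b in reference.BENCHMARKS.items():
        est, sem = stoch[name]
        if b.band is not None:
            ok = (b.band[0] <= est <= b.band[1]) and (b.band[0] <= preds[name] <= b.band[1])
        else:
            # bias is documented when either oracle (mean-field or verified
            # stochastic mean) departs by more than the reported STD
            ok = abs(est - b.mean) <= b.std and abs(preds[name] - b.mean) <= b.std
        rows.append({
            "name": name, "reported_mean": b.mean, "reported_std": b.std,
            "band": list(b.band) if b.band else None,
            "meanfield_prediction": preds[name],
            "stochastic_mean": est, "stochastic_sem": sem,
            "within_1std": ok,
        })
    return rows


def write_artifact(params: ParameterSet, report: dict, path: str | Path) -> None:
    payload = {
        "note": "calibrated trafficking rates; regenerate with spinetraffic.calibration.calibrate",
        "parameters": {k: getattr(params, k) for k in FREE_PARAMS + ("D_free",)},
        "report": report,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_report() -> dict:
    """Report stored alongside the shipped calibrated-parameter artifact."""
    from importlib import resources

    with resources.files("spinetraffic.data").joinpath("calibrated_params.json").open() as fh:
        return json.load(fh)["report"]


def biased_benchmarks() -> set[str]:
    """Benchmarks whose calibrated mean-field prediction sits outside the
    reported 1-STD interval (documented surrogate bias; validation widens to
    2 STD for these)."""
    report = load_report()
    rows = report.get("benchmarks", [])
    return {r["name"] for r in rows if not r["within_1std"]}
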