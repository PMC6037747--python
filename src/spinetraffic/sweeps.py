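"""Parameter sweeps of the resting synaptic receptor number.

The binding-only configuration (no endo/exocytosis, no cytosolic pools)
reproduces the constitutive-trafficking sweeps: resting synaptic AMPARs as
a function of the scaffold copy number per PSD, of the scaffold-receptor
dissociation rate ``k_b1``, and of the number of surface receptors
released.  Sweeps run on the mean-field oracle by default (the trends are
deterministic); ``method='ssa'`` gives the stochastic version.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import ParameterSet, build_default_system
from .engine import integrate_meanfield, simulate

__all__ = ["binding_only_parameters", "rest_synaptic_count", "sweep"]

SWEEP_AXES = {
    "scaffolds": ("n_scaffold_per_psd", (50, 100, 200, 300, 400)),
    "k_b1": ("k_b1", (10.0, 50.0, 100.0, 500.0, 1000.0)),
    "surface_receptors": ("n_ampar_surface", (1000, 1500, 2000, 2500)),
}


def binding_only_parameters(**overrides) -> ParameterSet:
    """Scaffold-binding model only: trafficking rates and cytosolic pools off."""
    base = dict(k_f2=0.0, k_b2=0.0, k_f3=0.0, k_b3=0.0, n_ampar_cyt_per_spine=0)
    base.update(overrides)
    return ParameterSet(**base)


def rest_synaptic_count(
    params: ParameterSet,
    duration: float = 60.0,
    burn_in: float = 30.0,
    method: str = "meanfield",
    seeds: tuple[int, ...] = (1, 2, 3),
) -> float:
    """Mean resting synaptic AMPARs per PSD, averaged over the last 30 s."""
    system = build_default_system(params=params)
    if method == "meanfield":
        trajs = [integrate_meanfield(system, duration=duration, burn_in=burn_in)]
    else:
        trajs = [simulate(system, duration=duration, seed=s, burn_in=burn_in,
                          method=method) for s in seeds]
    vals = []
    for tr in trajs:
        mask = tr.times >= tr.times[-1] - 30.0
        for s in system.spine_indices():
            vals.append(tr.synaptic_series(s)[mask].mean())
    return float(np.mean(vals))


def sweep(axis: str, values=None, method: str = "meanfield",
          seeds: tuple[int, ...] = (1, 2, 3)) -> pd.DataFrame:
    """Sweep one axis of the binding-only model; returns value vs rest count."""
    if axis not in SWEEP_AXES:
        raise KeyError(f"unknown sweep axis {axis!r}; options: {sorted(SWEEP_AXES)}")
    field, defaults = SWEEP_AXES[axis]
    values = list(defaults if values is None else values)
    rows = []
    for v in values:
        params = binding_only_parameters(**{field: v})
        rows.append({axis: v, "rest_synaptic_per_psd":
                     rest_synaptic_count(params, method=method, seeds=seeds)})
    return pd.DataFrame(rows)
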