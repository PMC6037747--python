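"""Run configuration, validation and output manifests.

A run configuration (YAML or JSON) names a registered protocol and may
override geometry fields, rate constants/copy numbers, seeds, the solver
and the output directory.  Unknown keys are rejected.  Every run directory
receives a manifest (protocol, overrides, seeds, parameter hash, package
version) sufficient to re-execute the run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__ as _pkg_version
from .geometry import GeometryParams
from .protocols import Protocol, make_protocol
from .engine import Trajectory

__all__ = ["GeometryConfig", "ParameterConfig", "RunConfig", "load_config",
           "config_to_protocol", "write_run_outputs"]


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dendrite_length: float | None = None
    dendrite_diameter: float | None = None
    n_spines: int | None = None
    neck_length: float | None = None
    neck_diameter: float | None = None
    head_diameter: float | None = None
    psd_diameter: float | None = None
    ez_outer_diameter: float | None = None
    shaft_segments: int | None = None
    spine_positions: list[float] | None = None


class ParameterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_f1: float | None = None
    k_b1: float | None = None
    k_f2: float | None = None
    k_b2: float | None = None
    k_f3: float | None = None
    k_b3: float | None = None
    k_phos: float | None = None
    D_free: float | None = None
    n_ampar_surface: int | None = None
    n_ampar_cyt_per_spine: int | None = None
    n_scaffold_per_psd: int | None = None
    n_eep_per_ez: int | None = None
    n_enzyme_released: int | None = None


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    protocol: str
    geometry: GeometryConfig | None = None
    parameters: ParameterConfig | None = None
    seeds: list[int] | None = None
    n_replicates: int | None = None
    method: Literal["ssa", "tau_leap"] = "ssa"
    sample_dt: float = 0.5
    out_dir: str = "runs"


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return RunConfig.model_validate(data)


def config_to_protocol(cfg: RunConfig) -> Protocol:
    overrides: dict[str, Any] = {}
    if cfg.parameters is not None:
        overrides.update({k: v for k, v in cfg.parameters.model_dump().items()
                          if v is not None})
    proto = make_protocol(cfg.protocol, **overrides)
    if cfg.geometry is not None:
        geo_over = {k: v for k, v in cfg.geometry.model_dump().items() if v is not None}
        if geo_over:
            base = proto.geometry or GeometryParams()
            merged = {**asdict(base), **geo_over}
            from dataclasses import replace
            proto = replace(proto, geometry=GeometryParams(**merged))
    if cfg.n_replicates is not None:
        from dataclasses import replace
        proto = replace(proto, n_replicates=cfg.n_replicates)
    return proto


def _params_hash(proto: Protocol) -> str:
    from .network import calibrated_parameters

    params = proto.params if proto.params is not None else calibrated_parameters()
    payload = json.dumps({"params": asdict(params),
                          "geometry": asdict(proto.geometry) if proto.geometry else None},
                         sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_run_outputs(out_dir: str | Path, proto: Protocol,
                      trajs: list[Trajectory], summary: pd.DataFrame | None = None) -> Path:
    """Write per-replicate synaptic time courses, optional summary and manifest."""
    out = Path(out_dir) / proto.name
    out.mkdir(parents=True, exist_ok=True)
    for tr in trajs:
        rows = {"time": tr.times}
        for s in tr.system.spine_indices():
            rows[f"psd{s}"] = tr.synaptic_series(s)
        pd.DataFrame(rows).to_csv(out / f"synaptic_seed{tr.seed}.csv", index=False)
    if summary is not None:
        summary.to_csv(out / "summary.csv", index=False)
    manifest = {
        "package_version": _pkg_version,
        "protocol": proto.name,
        "duration": proto.duration,
        "burn_in": proto.burn_in,
        "variant": proto.variant.name,
        "boundary_mode": proto.boundary_mode,
        "events": [asdict(ev) for ev in proto.events],
        "seeds": [tr.seed for tr in trajs],
        "method": trajs[0].method if trajs else None,
        "params_hash": _params_hash(proto),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
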