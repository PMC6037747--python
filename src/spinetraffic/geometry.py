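"""Compartmental surrogate of a spiny dendritic segment.

The membrane of a short dendrite (cylinder) carrying mushroom spines is
discretized into well-mixed compartments: shaft rings, spine necks, spine
heads, a perisynaptic endocytic-zone (EZ) annulus and a postsynaptic-density
(PSD) disc per spine, plus one well-mixed cytosolic pool per spine.  Lateral
diffusion of membrane molecules becomes hopping between adjacent compartments
at rates given by the standard finite-volume discretization of 2-D diffusion,

    k(from -> to) = D * w / (A_from * h),

with ``w`` the shared boundary length, ``A_from`` the source area and ``h``
the distance between compartment centres.  Using the same ``w`` and ``h`` for
both directions makes every coupling satisfy detailed balance
(``k_fwd * A_from == k_rev * A_to``), so a freely diffusing molecule
equilibrates to an occupancy proportional to compartment area.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
__all__ = [
    "GeometryParams",
    "Compartment",
    "Coupling",
    "CompartmentGraph",
    "build_dendrite_model",
    "hop_rate",
]

# membrane compartment kinds; SPINE_CYTOSOL is the single volume kind
PSD = "PSD"
EZ = "EZ"
HEAD_MEMBRANE = "HEAD_MEMBRANE"
NECK_MEMBRANE = "NECK_MEMBRANE"
SHAFT_MEMBRANE = "SHAFT_MEMBRANE"
SPINE_CYTOSOL = "SPINE_CYTOSOL"

MEMBRANE_KINDS = (PSD, EZ, HEAD_MEMBRANE, NECK_MEMBRANE, SHAFT_MEMBRANE)


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the dendritic segment, all lengths in micrometres.

    Defaults follow the modelled CA1 segment: a 2 um x 0.5 um dendrite with
    five spines (0.25 um x 0.2 um necks, 0.5 um heads with a flat top acting
    as the PSD).  The PSD/EZ diameters and spine spacing are not constrained
    by the source measurements and are exposed here for calibration.
    """

    dendrite_length: float = 2.0
    dendrite_diameter: float = 0.5
    n_spines: int = 5
    neck_length: float = 0.25
    neck_diameter: float = 0.2
    head_diameter: float = 0.5
    psd_diameter: float = 0.3
    ez_outer_diameter: float = 0.4
    shaft_segments: int = 10
    spine_positions: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.spine_positions is None:
            # evenly spaced along the shaft, away from the reflective ends
            n = self.n_spines
            pos = tuple(
                round(self.dendrite_length * (i + 1) / (n + 1), 6) for i in range(n)
            )
            object.__setattr__(self, "spine_positions", pos)
        else:
            object.__setattr__(self, "spine_positions", tuple(self.spine_positions))
        for name in (
            "dendrite_length",
            "dendrite_diameter",
            "neck_length",
            "neck_diameter",
            "head_diameter",
            "psd_diameter",
            "ez_outer_diameter",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_spines < 1:
            raise ValueError("n_spines must be >= 1")
        if self.shaft_segments < 1:
            raise ValueError("shaft_segments must be >= 1")
        if not (self.psd_diameter < self.ez_outer_diameter < self.head_diameter):
            raise ValueError("require psd_diameter < ez_outer_diameter < head_diameter")
        if len(self.spine_positions) != self.n_spines:
            raise ValueError("spine_positions length must equal n_spines")
        if list(self.spine_positions) != sorted(set(self.spine_positions)):
            raise ValueError("spine_positions must be strictly increasing")
        if self.spine_positions[0] < 0 or self.spine_positions[-1] > self.dendrite_length:
            raise ValueError("spine_positions must lie within [0, dendrite_length]")

    # -- derived areas ------------------------------------------------------
    @property
    def psd_area(self) -> float:
        return math.pi * (self.psd_diameter / 2.0) ** 2

    @property
    def ez_area(self) -> float:
        return math.pi * ((self.ez_outer_diameter / 2.0) ** 2 - (self.psd_diameter / 2.0) ** 2)

    @property
    def head_area(self) -> float:
        """Spherical head surface minus the cap replaced by the flat PSD+EZ top."""
        r = self.head_diameter / 2.0
        r_top = self.ez_outer_diameter / 2.0
        cap_height = r - math.sqrt(max(r * r - r_top * r_top, 0.0))
        return 4.0 * math.pi * r * r - 2.0 * math.pi * r * cap_height

    @property
    def neck_area(self) -> float:
        return math.pi * self.neck_diameter * self.neck_length

    @property
    def shaft_area(self) -> float:
        return math.pi * self.dendrite_diameter * self.dendrite_length

    @property
    def spine_volume(self) -> float:
        r = self.head_diameter / 2.0
        return 4.0 / 3.0 * math.pi * r ** 3

    @property
    def total_membrane_area(self) -> float:
        return self.shaft_area + self.n_spines * (
            self.neck_area + self.head_area + self.ez_area + self.psd_area
        )


@dataclass(frozen=True)
class Compartment:
    id: str
    kind: str
    spine_index: int | None = None  # 1-based; None for shaft
    area: float = 0.0  # um^2, membrane kinds
    volume: float = 0.0  # um^3, cytosol kind

    def __post_init__(self):
        if self.kind in MEMBRANE_KINDS and self.area <= 0:
            raise ValueError(f"membrane compartment {self.id} must have area > 0")
        if self.kind == SPINE_CYTOSOL and self.volume <= 0:
            raise ValueError(f"cytosol compartment {self.id} must have volume > 0")


@dataclass(frozen=True)
class Coupling:
    """Bidirectional diffusive coupling between two membrane compartments."""

    from_id: str
    to_id: str
    hop_rate_fwd: float  # 1/s, per molecule, from -> to
    hop_rate_rev: float  # 1/s, per molecule, to -> from

    def __post_init__(self):
        if self.hop_rate_fwd < 0 or self.hop_rate_rev < 0:
            raise ValueError("hop rates must be >= 0")


@dataclass
class CompartmentGraph:
    compartments: dict[str, Compartment]
    couplings: list[Coupling]
    boundary_mode: str = "reflective"  # or "open_bath"
    # per terminal shaft segment: (compartment id, per-molecule exit rate 1/s)
    bath_couplings: list[tuple[str, float]] = field(default_factory=list)
    params: GeometryParams | None = None

    def area(self, comp_id: str) -> float:
        return self.compartments[comp_id].area

    def membrane_ids(self) -> list[str]:
        return [c.id for c in self.compartments.values() if c.kind in MEMBRANE_KINDS]

    def of_kind(self, kind: str) -> list[Compartment]:
        return [c for c in self.compartments.values() if c.kind == kind]

    def spine_compartment(self, kind: str, spine_index: int) -> Compartment:
        for c in self.compartments.values():
            if c.kind == kind and c.spine_index == spine_index:
                return c
        raise KeyError(f"no {kind} compartment for spine {spine_index}")

    def total_membrane_area(self) -> float:
        return sum(c.area for c in self.compartments.values() if c.kind in MEMBRANE_KINDS)

    def is_membrane_connected(self) -> bool:
        """BFS over couplings restricted to membrane compartments."""
        ids = set(self.membrane_ids())
        if not ids:
            return True
        adj: dict[str, set[str]] = {i: set() for i in ids}
        for cp in self.couplings:
            if cp.from_id in ids and cp.to_id in ids:
                adj[cp.from_id].add(cp.to_id)
                adj[cp.to_id].add(cp.from_id)
        seen = set()
        stack = [next(iter(ids))]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(adj[u] - seen)
        return seen == ids

    def to_json(self) -> str:
        return json.dumps(
            {
                "boundary_mode": self.boundary_mode,
                "compartments": [asdict(c) for c in self.compartments.values()],
                "couplings": [asdict(c) for c in self.couplings],
                "bath_couplings": list(self.bath_couplings),
            },
            indent=2,
        )


def hop_rate(D: float, boundary_length: float, area_from: float, center_distance: float) -> float:
    """Per-molecule hop rate ``D*w/(A*h)`` of the finite-volume diffusion stencil."""
    for name, v in (
        ("D", D),
        ("boundary_length", boundary_length),
        ("area_from", area_from),
        ("center_distance", center_distance),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    return D * boundary_length / (area_from * center_distance)


def _couple(a: Compartment, b: Compartment, D: float, w: float, h: float) -> Coupling:
    return Coupling(a.id, b.id, hop_rate(D, w, a.area, h), hop_rate(D, w, b.area, h))


def build_dendrite_model(
    params: GeometryParams | None = None,
    *,
    D_free: float = 0.1,
    boundary_mode: str = "reflective",
) -> CompartmentGraph:
    """Build the compartment graph for the dendritic segment.

    ``D_free`` (um^2/s) sets the hop rates of the free-receptor diffusion
    stencil; reaction propensities are attached later by the network builder.
    With the default 5 spines and 10 shaft rings the graph has
    5*4 membrane + 10 shaft + 5 cytosol = 40 compartments.
    """
    p = params or GeometryParams()
    if boundary_mode not in ("reflective", "open_bath"):
        raise ValueError(f"unknown boundary_mode {boundary_mode!r}")

    seg_len = p.dendrite_length / p.shaft_segments
    seg_area = p.shaft_area / p.shaft_segments
    comps: dict[str, Compartment] = {}
    for i in range(p.shaft_segments):
        comps[f"shaft_{i}"] = Compartment(f"shaft_{i}", SHAFT_MEMBRANE, None, area=seg_area)

    # spine attachment: each spine claims one shaft ring
    attach: dict[int, int] = {}
    for s, pos in enumerate(p.spine_positions, start=1):
        seg = min(int(pos / seg_len), p.shaft_segments - 1)
        if seg in attach.values():
            raise ValueError(
                f"spine {s} at {pos} um overlaps another spine's attachment ring; "
                "increase shaft_segments or separate spine_positions"
            )
        attach[s] = seg

    # the flat PSD+EZ top must fit on the sphere and leave curved head membrane
    if p.ez_outer_diameter >= p.head_diameter or p.head_area <= 0:
        raise ValueError("PSD+EZ cap does not fit on the spine head")

    for s in range(1, p.n_spines + 1):
        comps[f"neck_{s}"] = Compartment(f"neck_{s}", NECK_MEMBRANE, s, area=p.neck_area)
        comps[f"head_{s}"] = Compartment(f"head_{s}", HEAD_MEMBRANE, s, area=p.head_area)
        comps[f"ez_{s}"] = Compartment(f"ez_{s}", EZ, s, area=p.ez_area)
        comps[f"psd_{s}"] = Compartment(f"psd_{s}", PSD, s, area=p.psd_area)
        comps[f"cyt_{s}"] = Compartment(f"cyt_{s}", SPINE_CYTOSOL, s, volume=p.spine_volume)

    # characteristic in-path lengths of each compartment kind (um); these set
    # kinetic timescales only, not equilibria (which depend on areas alone)
    ell_shaft = seg_len
    ell_neck = p.neck_length
    ell_head = math.pi * p.head_diameter / 4.0  # ~ half great-circle arc
    ell_ez = (p.ez_outer_diameter - p.psd_diameter) / 2.0
    ell_psd = p.psd_diameter / 2.0

    couplings: list[Coupling] = []
    circ_dend = math.pi * p.dendrite_diameter
    circ_neck = math.pi * p.neck_diameter
    circ_ez_outer = math.pi * p.ez_outer_diameter
    circ_psd = math.pi * p.psd_diameter

    for i in range(p.shaft_segments - 1):
        couplings.append(
            _couple(comps[f"shaft_{i}"], comps[f"shaft_{i+1}"], D_free, circ_dend, ell_shaft)
        )
    for s in range(1, p.n_spines + 1):
        seg = attach[s]
        couplings.append(
            _couple(comps[f"shaft_{seg}"], comps[f"neck_{s}"], D_free, circ_neck,
                    0.5 * (ell_shaft + ell_neck))
        )
        couplings.append(
            _couple(comps[f"neck_{s}"], comps[f"head_{s}"], D_free, circ_neck,
                    0.5 * (ell_neck + ell_head))
        )
        couplings.append(
            _couple(comps[f"head_{s}"], comps[f"ez_{s}"], D_free, circ_ez_outer,
                    0.5 * (ell_head + ell_ez))
        )
        couplings.append(
            _couple(comps[f"ez_{s}"], comps[f"psd_{s}"], D_free, circ_psd,
                    0.5 * (ell_ez + ell_psd))
        )

    bath: list[tuple[str, float]] = []
    if boundary_mode == "open_bath":
        # exchange with an external bath through the two lateral cross-sections,
        # at the same stencil rate as an additional shaft ring
        k_out = hop_rate(D_free, circ_dend, seg_area, ell_shaft)
        bath = [("shaft_0", k_out), (f"shaft_{p.shaft_segments - 1}", k_out)]

    graph = CompartmentGraph(
        compartments=comps,
        couplings=couplings,
        boundary_mode=boundary_mode,
        bath_couplings=bath,
        params=p,
    )
    assert graph.is_membrane_connected()
    return graph
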