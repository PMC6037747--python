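"""Species, reaction channels and propensity rules for AMPAR trafficking.

The model couples four processes on the compartment graph:

* **Scaffold binding** — at each PSD, immobile scaffold molecules trap free
  receptors, ``scaffold + AMPAR_free <-> scaffold.AMPAR`` with second-order
  association ``k_f1`` (um^2 molecule^-1 s^-1, scaled by the PSD area) and
  first-order dissociation ``k_b1``.  The scaffold's phosphorylation state
  sets the dissociation rate: the LTP state binds 10-fold more tightly
  (``k_b1/10``), the LTD state 10-fold more weakly (``10*k_b1``).
* **Endo/exocytosis** — a single endocytic/exocytic enzyme (EEP, 10 copies
  per EZ) cycles receptors between the EZ membrane and the spine's cytosolic
  pool through an explicit EEP.AMPAR intermediate: encounter ``k_f2``,
  release ``k_b2``, internalization ``k_f3``, externalization ``k_b3``.
* **Plasticity induction** — generic cytosolic enzymes (enzLTP/enzLTD),
  released into one spine, convert that PSD's scaffolds (free or complexed)
  by mass action at ``k_phos``, fast enough to complete in well under a
  second.  In the three-state variant basal scaffolds convert to LTP or LTD
  states; in the two-state variant enzLTP converts low->high affinity and
  enzLTD high->low, starting from a 40/60 high/low basal mixture.
* **Lateral diffusion** — free receptors hop between membrane compartments;
  scaffolds (any state) stay at their PSD and EEP stays in its EZ.

Receptor totals are conserved exactly in reflective mode, and per-PSD
scaffold totals are conserved always.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .geometry import (
    CompartmentGraph,
    GeometryParams,
    build_dendrite_model,
    PSD,
    EZ,
    SPINE_CYTOSOL,
)

__all__ = [
    "ParameterSet",
    "ModelVariant",
    "ReactionChannel",
    "ReactionSystem",
    "build_network",
    "build_default_system",
    "apply_induction",
    "calibrated_parameters",
]

ENZ_LTP = "enzLTP"
ENZ_LTD = "enzLTD"


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants and copy numbers.

    ``k_f1``/``k_b1`` and all copy numbers are fixed model constants.  The
    trafficking rates (``k_f2``, ``k_b2``, ``k_f3``, ``k_b3``) and ``D_free``
    carry plain placeholder defaults here; analyses should load the fitted
    values with :func:`calibrated_parameters`, which reads the calibration
    artifact shipped in ``spinetraffic/data``.
    """

    k_f1: float = 1.0          # um^2 molecule^-1 s^-1, scaffold-receptor association
    k_b1: float = 100.0        # s^-1, dissociation from basal scaffolds
    k_f2: float = 0.05         # um^2 molecule^-1 s^-1, EEP-receptor encounter
    k_b2: float = 0.5          # s^-1, EEP.AMPAR release without transport
    k_f3: float = 1.0          # s^-1, internalization from the EEP.AMPAR intermediate
    k_b3: float = 0.1          # s^-1, externalization from the EEP.AMPAR_cyt intermediate
    k_phos: float = 0.01       # um^2 molecule^-1 s^-1, enzyme-scaffold conversion
    D_free: float = 0.1        # um^2/s, lateral diffusion of free receptors
    n_ampar_surface: int = 1000
    n_ampar_cyt_per_spine: int = 100
    n_scaffold_per_psd: int = 300
    n_eep_per_ez: int = 10
    n_enzyme_released: int = 100

    def __post_init__(self):
        for name in ("k_f1", "k_b1", "k_f2", "k_b2", "k_f3", "k_b3", "k_phos", "D_free"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "n_ampar_surface",
            "n_ampar_cyt_per_spine",
            "n_scaffold_per_psd",
            "n_eep_per_ez",
            "n_enzyme_released",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # the 10-fold affinity shifts are identities, not free parameters
    @property
    def k_b1_LTP(self) -> float:
        return self.k_b1 / 10.0

    @property
    def k_b1_LTD(self) -> float:
        return self.k_b1 * 10.0


def calibrated_parameters(**overrides) -> ParameterSet:
    """Load the calibrated :class:`ParameterSet` artifact shipped with the package."""
    from importlib import resources

    with resources.files("spinetraffic.data").joinpath("calibrated_params.json").open() as fh:
        payload = json.load(fh)
    values = payload["parameters"]
    values.update(overrides)
    return ParameterSet(**values)


@dataclass(frozen=True)
class ModelVariant:
    name: str = "three_state"  # or "two_state"
    two_state_high_fraction: float = 0.40

    def __post_init__(self):
        if self.name not in ("three_state", "two_state"):
            raise ValueError(f"unknown variant {self.name!r}")
        if not (0.0 <= self.two_state_high_fraction <= 1.0):
            raise ValueError("two_state_high_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ReactionChannel:
    """One reaction channel; ``rate`` already folds in any area scaling.

    Propensity: ``rate * n[reactants[0]]`` (unimolecular),
    ``rate * n[r0] * n[r1]`` (bimolecular), or ``rate`` (zero-order influx).
    ``stoich`` maps species index -> integer change.
    """

    name: str
    reactants: tuple[int, ...]
    stoich: tuple[tuple[int, int], ...]
    rate: float


# species short names used in the index
R_SURF = "R"          # free receptor on a membrane compartment
R_CYT = "Rc"          # cytosolic receptor
EEP_FREE = "EEP"
EEP_R = "EEP.R"       # EEP bound to a surface receptor
EEP_RC = "EEP.Rc"     # EEP bound to a cytosolic receptor
SCAFFOLD_STATES = {
    "three_state": ("S_basal", "S_ltp", "S_ltd"),
    "two_state": ("S_hi", "S_lo"),
}
# dissociation rate of each scaffold state, as a multiple of k_b1
_STATE_KB_FACTOR = {
    "S_basal": 1.0,
    "S_ltp": 0.1,
    "S_ltd": 10.0,
    "S_hi": 0.1,
    "S_lo": 10.0,
}
# receptors carried by one molecule of each species
_RECEPTOR_LOAD = {
    R_SURF: 1,
    R_CYT: 1,
    EEP_R: 1,
    EEP_RC: 1,
    ENZ_LTP: 0,
    ENZ_LTD: 0,
    EEP_FREE: 0,
}


def _complex_name(state: str) -> str:
    return state + ".R"


class ReactionSystem:
    """Flattened (species, compartment) state space plus reaction channels."""

    def __init__(
        self,
        graph: CompartmentGraph,
        params: ParameterSet,
        variant: ModelVariant,
    ):
        self.graph = graph
        self.params = params
        self.variant = variant
        self._index: dict[tuple[str, str], int] = {}
        self.species_names: list[tuple[str, str]] = []
        self.channels: list[ReactionChannel] = []
        self._compiled = None
        self._build()

    # -- index bookkeeping --------------------------------------------------
    def _add_species(self, species: str, comp_id: str) -> int:
        key = (species, comp_id)
        if key not in self._index:
            self._index[key] = len(self.species_names)
            self.species_names.append(key)
        return self._index[key]

    def idx(self, species: str, comp_id: str) -> int:
        return self._index[(species, comp_id)]

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def scaffold_states(self) -> tuple[str, ...]:
        return SCAFFOLD_STATES[self.variant.name]

    def spine_indices(self) -> list[int]:
        return sorted(c.spine_index for c in self.graph.of_kind(PSD))

    # -- construction -------------------------------------------------------
    def _build(self) -> None:
        g, p = self.graph, self.params
        states = self.scaffold_states

        # species: free receptor everywhere on the membrane
        for comp_id in g.membrane_ids():
            self._add_species(R_SURF, comp_id)
        for psd in g.of_kind(PSD):
            for st in states:
                self._add_species(st, psd.id)
                self._add_species(_complex_name(st), psd.id)
        for ez in g.of_kind(EZ):
            self._add_species(EEP_FREE, ez.id)
            self._add_species(EEP_R, ez.id)
            self._add_species(EEP_RC, ez.id)
        for cyt in g.of_kind(SPINE_CYTOSOL):
            self._add_species(R_CYT, cyt.id)
            self._add_species(ENZ_LTP, cyt.id)
            self._add_species(ENZ_LTD, cyt.id)

        ch = self.channels

        # diffusion of free receptors along every coupling (fwd + rev)
        for cp in g.couplings:
            i, j = self.idx(R_SURF, cp.from_id), self.idx(R_SURF, cp.to_id)
            ch.append(ReactionChannel(
                f"hop:{cp.from_id}->{cp.to_id}", (i,), ((i, -1), (j, +1)), cp.hop_rate_fwd))
            ch.append(ReactionChannel(
                f"hop:{cp.to_id}->{cp.from_id}", (j,), ((j, -1), (i, +1)), cp.hop_rate_rev))

        # open-bath exchange: bath density fixed at the initial mean density
        if g.boundary_mode == "open_bath":
            rho_bath = p.n_ampar_surface / g.total_membrane_area()
            for comp_id, k_out in g.bath_couplings:
                i = self.idx(R_SURF, comp_id)
                ch.append(ReactionChannel(
                    f"bath_out:{comp_id}", (i,), ((i, -1),), k_out))
                influx = k_out * rho_bath * g.area(comp_id)
                ch.append(ReactionChannel(
                    f"bath_in:{comp_id}", (), ((i, +1),), influx))

        # scaffold binding at each PSD, one channel family per scaffold state
        for psd in g.of_kind(PSD):
            r = self.idx(R_SURF, psd.id)
            for st in states:
                s = self.idx(st, psd.id)
                c = self.idx(_complex_name(st), psd.id)
                ch.append(ReactionChannel(
                    f"bind:{st}@{psd.id}", (s, r),
                    ((s, -1), (r, -1), (c, +1)), p.k_f1 / psd.area))
                ch.append(ReactionChannel(
                    f"unbind:{st}@{psd.id}", (c,),
                    ((c, -1), (s, +1), (r, +1)), p.k_b1 * _STATE_KB_FACTOR[st]))

        # EEP trafficking cycle per spine
        for s_i in self.spine_indices():
            ez = self.graph.spine_compartment(EZ, s_i)
            cyt = self.graph.spine_compartment(SPINE_CYTOSOL, s_i)
            r = self.idx(R_SURF, ez.id)
            e = self.idx(EEP_FREE, ez.id)
            er = self.idx(EEP_R, ez.id)
            erc = self.idx(EEP_RC, ez.id)
            rc = self.idx(R_CYT, cyt.id)
            kk = p.k_f2 / ez.area
            ch.append(ReactionChannel(
                f"eep_catch_surf@{ez.id}", (r, e), ((r, -1), (e, -1), (er, +1)), kk))
            ch.append(ReactionChannel(
                f"eep_release_surf@{ez.id}", (er,), ((er, -1), (r, +1), (e, +1)), p.k_b2))
            ch.append(ReactionChannel(
                f"internalize@{ez.id}", (er,), ((er, -1), (rc, +1), (e, +1)), p.k_f3))
            ch.append(ReactionChannel(
                f"eep_catch_cyt@{ez.id}", (rc, e), ((rc, -1), (e, -1), (erc, +1)), kk))
            ch.append(ReactionChannel(
                f"eep_release_cyt@{ez.id}", (erc,), ((erc, -1), (rc, +1), (e, +1)), p.k_b2))
            ch.append(ReactionChannel(
                f"externalize@{ez.id}", (erc,), ((erc, -1), (r, +1), (e, +1)), p.k_b3))

        # enzyme-driven scaffold state conversion, confined to the spine's PSD
        conversions = {
            "three_state": ((ENZ_LTP, "S_basal", "S_ltp"), (ENZ_LTD, "S_basal", "S_ltd")),
            "two_state": ((ENZ_LTP, "S_lo", "S_hi"), (ENZ_LTD, "S_hi", "S_lo")),
        }[self.variant.name]
        for s_i in self.spine_indices():
            psd = self.graph.spine_compartment(PSD, s_i)
            cyt = self.graph.spine_compartment(SPINE_CYTOSOL, s_i)
            kk = p.k_phos / psd.area
            for enz, src, dst in conversions:
                e = self.idx(enz, cyt.id)
                for a, b in ((src, dst), (_complex_name(src), _complex_name(dst))):
                    ai, bi = self.idx(a, psd.id), self.idx(b, psd.id)
                    ch.append(ReactionChannel(
                        f"phos:{a}->{b}@{psd.id}", (e, ai), ((ai, -1), (bi, +1)), kk))

    # -- initial condition --------------------------------------------------
    def initial_state(self) -> np.ndarray:
        """Deterministic initial counts: receptors spread over the membrane in
        proportion to compartment area (largest-remainder rounding), cytosolic
        pools and scaffolds at their stated copy numbers."""
        n = np.zeros(self.n_species, dtype=np.int64)
        p = self.params
        mem = self.graph.membrane_ids()
        areas = np.array([self.graph.area(m) for m in mem])
        quota = p.n_ampar_surface * areas / areas.sum()
        base = np.floor(quota).astype(np.int64)
        rem = p.n_ampar_surface - int(base.sum())
        order = np.argsort(-(quota - base))
        base[order[:rem]] += 1
        for m, c in zip(mem, base):
            n[self.idx(R_SURF, m)] = c

        for psd in self.graph.of_kind(PSD):
            if self.variant.name == "three_state":
                n[self.idx("S_basal", psd.id)] = p.n_scaffold_per_psd
            else:
                hi = int(round(self.variant.two_state_high_fraction * p.n_scaffold_per_psd))
                n[self.idx("S_hi", psd.id)] = hi
                n[self.idx("S_lo", psd.id)] = p.n_scaffold_per_psd - hi
        for ez in self.graph.of_kind(EZ):
            n[self.idx(EEP_FREE, ez.id)] = p.n_eep_per_ez
        for cyt in self.graph.of_kind(SPINE_CYTOSOL):
            n[self.idx(R_CYT, cyt.id)] = p.n_ampar_cyt_per_spine
        return n

    # -- bookkeeping helpers ------------------------------------------------
    def receptor_load(self) -> np.ndarray:
        """Receptors carried per molecule of each species (for conservation)."""
        load = np.zeros(self.n_species, dtype=np.int64)
        for k, (sp, _comp) in enumerate(self.species_names):
            if sp in _RECEPTOR_LOAD:
                load[k] = _RECEPTOR_LOAD[sp]
            elif sp.endswith(".R"):
                load[k] = 1  # scaffold.AMPAR complexes
        return load

    def scaffold_load(self) -> np.ndarray:
        load = np.zeros(self.n_species, dtype=np.int64)
        states = set(self.scaffold_states)
        for k, (sp, _comp) in enumerate(self.species_names):
            base = sp[:-2] if sp.endswith(".R") else sp
            if base in states:
                load[k] = 1
        return load

    def total_receptors(self, counts: np.ndarray) -> int:
        return int(np.asarray(counts) @ self.receptor_load())

    def synaptic_indices(self, spine_index: int) -> list[int]:
        """Indices counting toward the synaptic AMPAR population of one PSD
        (free receptors on the PSD plus all scaffold.AMPAR complexes)."""
        psd = self.graph.spine_compartment(PSD, spine_index)
        out = [self.idx(R_SURF, psd.id)]
        out += [self.idx(_complex_name(st), psd.id) for st in self.scaffold_states]
        return out

    def scaffold_total(self, counts: np.ndarray, spine_index: int) -> int:
        psd = self.graph.spine_compartment(PSD, spine_index)
        tot = 0
        for st in self.scaffold_states:
            tot += counts[self.idx(st, psd.id)] + counts[self.idx(_complex_name(st), psd.id)]
        return int(tot)

    # -- engine compilation --------------------------------------------------
    def compiled(self):
        if self._compiled is None:
            from .engine import compile_network

            self._compiled = compile_network(self)
        return self._compiled

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant": asdict(self.variant),
                "parameters": asdict(self.params),
                "species": [list(k) for k in self.species_names],
                "channels": [
                    {
                        "name": c.name,
                        "reactants": list(c.reactants),
                        "stoich": [list(s) for s in c.stoich],
                        "rate": c.rate,
                    }
                    for c in self.channels
                ],
            },
            indent=2,
        )


def build_network(
    graph: CompartmentGraph,
    params: ParameterSet,
    variant: ModelVariant | str = "three_state",
) -> ReactionSystem:
    """Assemble the :class:`ReactionSystem` for a compartment graph."""
    if isinstance(variant, str):
        variant = ModelVariant(name=variant)
    return ReactionSystem(graph, params, variant)


def build_default_system(
    params: ParameterSet | None = None,
    variant: ModelVariant | str = "three_state",
    geometry: GeometryParams | None = None,
    boundary_mode: str = "reflective",
) -> ReactionSystem:
    """Default 5-spine system; loads calibrated parameters when none given."""
    p = params if params is not None else calibrated_parameters()
    graph = build_dendrite_model(geometry, D_free=p.D_free, boundary_mode=boundary_mode)
    return build_network(graph, p, variant)


def apply_induction(
    system: ReactionSystem,
    counts: np.ndarray,
    spine_index: int,
    enzyme: str,
    n_copies: int | None = None,
) -> np.ndarray:
    """Release plasticity-enzyme copies into one spine's cytosol.

    Returns a new counts vector; the scaffold conversion itself then proceeds
    by the mass-action phosphorylation channels of the system.
    """
    if enzyme not in (ENZ_LTP, ENZ_LTD):
        raise ValueError(f"unknown enzyme {enzyme!r}")
    if n_copies is None:
        n_copies = system.params.n_enzyme_released
    if n_copies <= 0:
        raise ValueError("n_copies must be > 0")
    if spine_index not in system.spine_indices():
        raise ValueError(f"no spine {spine_index} in this model")
    cyt = system.graph.spine_compartment(SPINE_CYTOSOL, spine_index)
    out = np.array(counts, dtype=np.int64, copy=True)
    out[system.idx(enzyme, cyt.id)] += n_copies
    return out
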