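"""Hippo-pathway shuttling models for the YAP/TAZ effectors.

Two reaction-network topologies are implemented, differing only in where the
effector is (de)phosphorylated:

* ``canonical`` — phosphorylation and dephosphorylation happen exclusively in
  the cytoplasm; only the unphosphorylated form ``U`` crosses the nuclear
  membrane (in both directions), and the phosphorylated form ``P`` is confined
  to the cytoplasm.
* ``alternative`` — ``U`` is imported into the nucleus, phosphorylated *inside*
  the nucleus, and the phosphorylated form ``P`` is exported back to the
  cytoplasm, where it is dephosphorylated again.  Both forms may occupy both
  compartments.

All reactions are first order; membrane transport is a first-order flux
density (permeability, µm/s, times the source-side concentration).  A
cytoplasmic zeroth-order synthesis of ``U`` and first-order degradation of
both forms give the open system a unique nontrivial steady state.

The module also provides a well-mixed (compartment ODE) steady state used as
an independent oracle for the spatial solver: removing diffusion turns each
topology into a small linear ODE system whose steady state is a linear solve.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "CYTOPLASM",
    "NUCLEUS",
    "TOPOLOGIES",
    "DEFAULT_BOUNDS",
    "DEFAULT_PARAMS",
    "Species",
    "VolumeReaction",
    "MembraneTransport",
    "Synthesis",
    "ReactionNetwork",
    "KineticParameters",
    "WellMixedSteadyState",
    "NoSteadyStateError",
    "UndefinedRatioError",
    "build_topology",
    "phospho_ratio",
    "wellmixed_steady_state",
]

CYTOPLASM = "cytoplasm"
NUCLEUS = "nucleus"
COMPARTMENTS = (CYTOPLASM, NUCLEUS)
TOPOLOGIES = ("canonical", "alternative")


class NoSteadyStateError(RuntimeError):
    """The compartment ODE system has no finite steady state."""


class UndefinedRatioError(ValueError):
    """The phosphorylation/dephosphorylation ratio is undefined."""


@dataclass(frozen=True)
class Species:
    """A model species (``U`` unphosphorylated or ``P`` phosphorylated)."""

    name: str
    allowed_compartments: tuple[str, ...]

    def allowed_in(self, compartment: str) -> bool:
        return compartment in self.allowed_compartments


@dataclass(frozen=True)
class VolumeReaction:
    """First-order volume reaction ``substrate -> product`` (product ``None``
    means degradation) confined to one compartment; ``rate`` names the
    kinetic-parameter field holding the rate constant (1/s)."""

    compartment: str
    substrate: str
    product: str | None
    rate: str


@dataclass(frozen=True)
class MembraneTransport:
    """First-order transport of ``species`` across a membrane.

    ``rate`` names a permeability field (µm/s); the flux density is
    permeability × concentration on the ``source`` side.
    """

    membrane: str  # "nuclear" (the cell is closed: no plasma-membrane flux)
    species: str
    source: str
    dest: str
    rate: str


@dataclass(frozen=True)
class Synthesis:
    """Zeroth-order source of ``species`` in ``compartment`` (conc/s)."""

    compartment: str
    species: str
    rate: str


@dataclass(frozen=True)
class ReactionNetwork:
    topology_kind: str
    species: tuple[Species, ...]
    volume_reactions: tuple[VolumeReaction, ...]
    membrane_transports: tuple[MembraneTransport, ...]
    synthesis: tuple[Synthesis, ...]

    def species_named(self, name: str) -> Species:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(name)

    def validate(self) -> None:
        """Check the structural invariants of the topology."""
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        for rxn in self.volume_reactions:
            if rxn.compartment not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {rxn.compartment!r}")
            if not self.species_named(rxn.substrate).allowed_in(rxn.compartment):
                raise ValueError(
                    f"substrate {rxn.substrate} not allowed in {rxn.compartment}"
                )
            if rxn.product is not None and not self.species_named(
                rxn.product
            ).allowed_in(rxn.compartment):
                raise ValueError(
                    f"product {rxn.product} not allowed in {rxn.compartment}"
                )
        for tr in self.membrane_transports:
            if tr.membrane != "nuclear":
                raise ValueError("only nuclear-membrane transport is allowed "
                                 "(the cell is closed)")
            if {tr.source, tr.dest} != {CYTOPLASM, NUCLEUS}:
                raise ValueError("nuclear transport must connect cytoplasm and nucleus")
            sp = self.species_named(tr.species)
            if not (sp.allowed_in(tr.source) and sp.allowed_in(tr.dest)):
                raise ValueError(
                    f"transported species {tr.species} must be allowed on both sides"
                )
        for syn in self.synthesis:
            if not self.species_named(syn.species).allowed_in(syn.compartment):
                raise ValueError("synthesized species not allowed in its compartment")
        if self.topology_kind == "canonical":
            if any(r.compartment == NUCLEUS for r in self.volume_reactions):
                raise ValueError("canonical topology admits no nuclear reactions")
            if self.species_named("P").allowed_in(NUCLEUS):
                raise ValueError("canonical P is confined to the cytoplasm")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "topology_kind": self.topology_kind,
            "species": [asdict(sp) | {"allowed_compartments":
                                      list(sp.allowed_compartments)}
                        for sp in self.species],
            "volume_reactions": [asdict(r) for r in self.volume_reactions],
            "membrane_transports": [asdict(t) for t in self.membrane_transports],
            "synthesis": [asdict(s) for s in self.synthesis],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReactionNetwork":
        net = cls(
            topology_kind=d["topology_kind"],
            species=tuple(
                Species(s["name"], tuple(s["allowed_compartments"]))
                for s in d["species"]
            ),
            volume_reactions=tuple(
                VolumeReaction(**r) for r in d["volume_reactions"]
            ),
            membrane_transports=tuple(
                MembraneTransport(**t) for t in d["membrane_transports"]
            ),
            synthesis=tuple(Synthesis(**s) for s in d["synthesis"]),
        )
        net.validate()
        return net

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ReactionNetwork":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants, permeabilities and diffusion coefficients.

    Units: first-order rates 1/s; membrane permeabilities µm/s; synthesis
    conc/s; diffusion µm²/s.  ``k_phos`` acts in the nucleus under the
    alternative topology and in the cytoplasm under the canonical one.
    """

    k_phos: float = 0.17
    k_dephos_nuc: float = 1.0
    k_dephos_cyt: float = 0.02
    k_import: float = 0.8
    k_export: float = 2.0
    k_syn: float = 0.05
    k_deg: float = 0.05
    d_u: float = 2.0
    d_p: float = 2.0

    def __post_init__(self) -> None:
        for name, value in self.to_dict().items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.d_u <= 0 or self.d_p <= 0:
            raise ValueError("diffusion coefficients must be strictly positive")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def rate(self, symbol: str) -> float:
        return getattr(self, symbol)

    def diffusion(self, species_name: str) -> float:
        return self.d_u if species_name == "U" else self.d_p

    def replace(self, **kwargs: float) -> "KineticParameters":
        return replace(self, **kwargs)

    def with_ratio(self, r: float) -> "KineticParameters":
        """Set ``k_phos = r * k_dephos_nuc`` leaving everything else fixed."""
        if r < 0:
            raise ValueError("ratio must be >= 0")
        return self.replace(k_phos=r * self.k_dephos_nuc)

    def check_bounds(self, bounds: Mapping[str, tuple[float, float]]) -> None:
        for name, (lo, hi) in bounds.items():
            v = self.rate(name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")


#: Default parameter bounds (user-overridable): first-order rates 1e-4–1 s⁻¹,
#: permeabilities 1e-3–10 µm/s, diffusion 0.1–30 µm²/s.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_phos": (1e-4, 1.0),
    "k_dephos_nuc": (1e-4, 1.0),
    "k_dephos_cyt": (1e-4, 1.0),
    "k_syn": (1e-4, 1.0),
    "k_deg": (1e-4, 1.0),
    "k_import": (1e-3, 10.0),
    "k_export": (1e-3, 10.0),
    "d_u": (0.1, 30.0),
    "d_p": (0.1, 30.0),
}

#: Reference parameter set used by the synthetic-target studies.
DEFAULT_PARAMS = KineticParameters()


def build_topology(kind: str) -> ReactionNetwork:
    """Construct one of the two validated Hippo topologies.

    ``canonical`` keeps all (de)phosphorylation in the cytoplasm with P
    excluded from the nucleus; ``alternative`` phosphorylates in the nucleus
    and exports P.  Deterministic; raises ``ValueError`` for unknown kinds.
    """
    if kind == "canonical":
        net = ReactionNetwork(
            topology_kind="canonical",
            species=(
                Species("U", (CYTOPLASM, NUCLEUS)),
                Species("P", (CYTOPLASM,)),
            ),
            volume_reactions=(
                VolumeReaction(CYTOPLASM, "U", "P", "k_phos"),
                VolumeReaction(CYTOPLASM, "P", "U", "k_dephos_cyt"),
                VolumeReaction(CYTOPLASM, "U", None, "k_deg"),
                VolumeReaction(CYTOPLASM, "P", None, "k_deg"),
            ),
            membrane_transports=(
                MembraneTransport("nuclear", "U", CYTOPLASM, NUCLEUS, "k_import"),
                MembraneTransport("nuclear", "U", NUCLEUS, CYTOPLASM, "k_export"),
            ),
            synthesis=(Synthesis(CYTOPLASM, "U", "k_syn"),),
        )
    elif kind == "alternative":
        net = ReactionNetwork(
            topology_kind="alternative",
            species=(
                Species("U", (CYTOPLASM, NUCLEUS)),
                Species("P", (CYTOPLASM, NUCLEUS)),
            ),
            volume_reactions=(
                VolumeReaction(NUCLEUS, "U", "P", "k_phos"),
                VolumeReaction(NUCLEUS, "P", "U", "k_dephos_nuc"),
                VolumeReaction(CYTOPLASM, "P", "U", "k_dephos_cyt"),
                VolumeReaction(CYTOPLASM, "U", None, "k_deg"),
                VolumeReaction(CYTOPLASM, "P", None, "k_deg"),
            ),
            membrane_transports=(
                MembraneTransport("nuclear", "U", CYTOPLASM, NUCLEUS, "k_import"),
                MembraneTransport("nuclear", "P", NUCLEUS, CYTOPLASM, "k_export"),
            ),
            synthesis=(Synthesis(CYTOPLASM, "U", "k_syn"),),
        )
    else:
        raise ValueError(
            f"unknown topology {kind!r}: expected 'canonical' or 'alternative'"
        )
    net.validate()
    return net


def phospho_ratio(params: KineticParameters) -> float:
    """Nuclear phosphorylation/dephosphorylation ratio r = k_phos / k_dephos_nuc."""
    if params.k_dephos_nuc <= 0:
        raise UndefinedRatioError(
            "phospho ratio undefined: k_dephos_nuc must be > 0"
        )
    return params.k_phos / params.k_dephos_nuc


@dataclass
class WellMixedSteadyState:
    """Steady state of the diffusion-free compartment ODE system."""

    concentrations: dict[tuple[str, str], float]  # (species, compartment)
    ncr: float
    ncr_diverged: bool = False

    def conc(self, species: str, compartment: str) -> float:
        return self.concentrations.get((species, compartment), 0.0)


def compartment_ode_system(
    network: ReactionNetwork,
    params: KineticParameters,
    volumes: Mapping[str, float],
    membrane_area: float,
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray]:
    """Linear compartment ODE ``dx/dt = A x + b`` over (species, compartment)
    states; transport scales with membrane_area / destination volume."""
    if membrane_area <= 0 or any(v <= 0 for v in volumes.values()):
        raise ValueError("volumes and membrane area must be > 0")
    states = [
        (sp.name, comp)
        for sp in network.species
        for comp in COMPARTMENTS
        if sp.allowed_in(comp)
    ]
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    A = np.zeros((n, n))
    b = np.zeros(n)
    for rxn in network.volume_reactions:
        i = idx[(rxn.substrate, rxn.compartment)]
        k = params.rate(rxn.rate)
        A[i, i] -= k
        if rxn.product is not None:
            A[idx[(rxn.product, rxn.compartment)], i] += k
    for tr in network.membrane_transports:
        k = params.rate(tr.rate)
        i_src = idx[(tr.species, tr.source)]
        i_dst = idx[(tr.species, tr.dest)]
        A[i_src, i_src] -= k * membrane_area / volumes[tr.source]
        A[i_dst, i_src] += k * membrane_area / volumes[tr.dest]
    for syn in network.synthesis:
        b[idx[(syn.species, syn.compartment)]] += params.rate(syn.rate)
    return states, A, b


def wellmixed_steady_state(
    network: ReactionNetwork,
    params: KineticParameters,
    volumes: Mapping[str, float],
    membrane_area: float,
    total_amount: float | None = None,
) -> WellMixedSteadyState:
    """Steady state of the well-mixed compartment model.

    For an open system (degradation balancing synthesis) the steady state is
    the unique solution of the linear system.  For a closed, mass-conserving
    system (``k_syn = k_deg = 0``) the steady state lies in the nullspace of
    the rate matrix and is scaled to ``total_amount`` (default: one unit of
    concentration filling the cytoplasm, matching the solver's default
    initial condition).
    """
    states, A, b = compartment_ode_system(network, params, volumes, membrane_area)
    n = len(states)
    rank = np.linalg.matrix_rank(A, tol=1e-12 * max(1.0, float(np.abs(A).max())))
    if rank == n:
        x = np.linalg.solve(A, -b)
        if (x < -1e-9 * max(1.0, float(np.abs(x).max()))).any():
            raise NoSteadyStateError("steady state has negative concentrations")
    elif not np.any(b):
        # conserved total mass: steady state is the (unique) nullspace ray
        from scipy.linalg import null_space

        ns = null_space(A, rcond=1e-12)
        if ns.shape[1] != 1:
            raise NoSteadyStateError(
                f"nullspace dimension {ns.shape[1]} != 1: steady state not unique"
            )
        v = ns[:, 0]
        if v.sum() < 0:
            v = -v
        if (v < -1e-9).any():
            raise NoSteadyStateError("nullspace steady state is not non-negative")
        v = np.clip(v, 0.0, None)
        if total_amount is None:
            total_amount = volumes[CYTOPLASM]  # conc 1 filling the cytoplasm
        mass = sum(v[i] * volumes[comp] for i, (_, comp) in enumerate(states))
        x = v * (total_amount / mass)
    else:
        raise NoSteadyStateError(
            "rate matrix is singular with a nonzero source "
            "(e.g. k_deg = 0 with k_syn > 0): no finite steady state"
        )
    conc = {state: float(val) for state, val in zip(states, x)}
    nuc = sum(v for (sp, comp), v in conc.items() if comp == NUCLEUS)
    cyt = sum(v for (sp, comp), v in conc.items() if comp == CYTOPLASM)
    if cyt <= 1e-12 * max(nuc, 1.0):
        return WellMixedSteadyState(conc, math.inf, ncr_diverged=True)
    return WellMixedSteadyState(conc, nuc / cyt)
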