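"""Explicit FTCS reaction-diffusion solver on a compartment label grid.

The spatial model couples, per species, diffusion *within* each allowed
compartment (zero-flux at all compartment boundaries), first-order volume
reactions, zeroth-order synthesis, and first-order permeability fluxes across
the nuclear-membrane pixel faces.  Because every term is linear, the explicit
Forward-Time Centered-Space update

    c(t + dt) = c(t) + dt * (M c(t) + s)

is assembled once per (geometry, network, parameters) as a sparse operator
``M`` plus source ``s`` over the stacked species grids, and stepped by sparse
matrix-vector products.  The arithmetic is identical to the textbook stencil
loop (4-neighbour Laplacian, pairwise conservative fluxes); the assembly is
just a vectorization.

Steady state is declared when the maximum concentration rate of change drops
below a tolerance, by default 1e-6 of the mean initial concentration per
second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import CompartmentGeometry
from .model import COMPARTMENTS, KineticParameters, ReactionNetwork

__all__ = [
    "ConcentrationFields",
    "SimulationResult",
    "FtcsOperator",
    "stable_timestep",
    "ftcs_step",
    "simulate_to_steady_state",
    "total_fluorescence_image",
    "compartment_means",
    "simulated_ncr",
]


@dataclass
class ConcentrationFields:
    """Per-species 2D concentration arrays at simulated time ``t`` (s)."""

    fields: dict[str, np.ndarray]
    time: float = 0.0

    def copy(self) -> "ConcentrationFields":
        return ConcentrationFields(
            {k: v.copy() for k, v in self.fields.items()}, self.time
        )

    def validate(self, geometry: CompartmentGeometry, network: ReactionNetwork) -> None:
        for sp_ in network.species:
            arr = self.fields[sp_.name]
            if arr.shape != geometry.shape:
                raise ValueError("field shape does not match geometry")
            if (arr < 0).any():
                raise ValueError(f"negative concentrations in species {sp_.name}")
            allowed = np.zeros(geometry.shape, bool)
            for comp in sp_.allowed_compartments:
                allowed |= geometry.mask(comp)
            if arr[~allowed].any():
                raise ValueError(
                    f"species {sp_.name} has nonzero concentration outside its "
                    "allowed compartments"
                )


@dataclass
class SimulationResult:
    fields: ConcentrationFields
    steady_state_reached: bool
    final_rate_norm: float  # max |dc/dt| over pixels and species, conc/s
    elapsed_time: float
    dt_used: float
    n_steps: int
    tol: float


def _first_order_load(
    network: ReactionNetwork, params: KineticParameters, pixel_size: float
) -> float:
    """Largest total first-order loss rate acting on any (species, compartment),
    membrane permeabilities counted as k/pixel_size."""
    load: dict[tuple[str, str], float] = {}
    for rxn in network.volume_reactions:
        key = (rxn.substrate, rxn.compartment)
        load[key] = load.get(key, 0.0) + params.rate(rxn.rate)
    for tr in network.membrane_transports:
        key = (tr.species, tr.source)
        load[key] = load.get(key, 0.0) + params.rate(tr.rate) / pixel_size
    return max(load.values(), default=0.0)


def stable_timestep(
    params: KineticParameters,
    pixel_size: float,
    safety: float = 0.5,
    network: ReactionNetwork | None = None,
) -> float:
    """Largest stable FTCS time step.

    dt = safety * pixel_size^2 / (4 D_max), further reduced to safety / k_max
    when the fastest total first-order rate k_max would otherwise violate
    dt * k_max <= safety.  With ``network`` given, k_max is the largest total
    loss rate on any species/compartment (permeabilities as k/pixel_size);
    without it, the conservative sum of all first-order rate constants plus
    (k_import + k_export)/pixel_size is used.  The default safety of 0.5
    keeps the explicit update non-negativity-preserving even when both the
    diffusion and the reaction bound are active.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if not 0 < safety <= 1:
        raise ValueError("safety must be in (0, 1]")
    d_max = max(params.d_u, params.d_p)
    dt = safety * pixel_size**2 / (4.0 * d_max)
    if network is not None:
        k_max = _first_order_load(network, params, pixel_size)
    else:
        k_max = (
            params.k_phos
            + params.k_dephos_nuc
            + params.k_dephos_cyt
            + params.k_deg
            + (params.k_import + params.k_export) / pixel_size
        )
    if k_max > 0:
        dt = min(dt, safety / k_max)
    return dt


class FtcsOperator:
    """Sparse assembly of the FTCS right-hand side dc/dt = M c + s."""

    def __init__(
        self,
        geometry: CompartmentGeometry,
        network: ReactionNetwork,
        params: KineticParameters,
    ) -> None:
        self.geometry = geometry
        self.network = network
        self.params = params
        self.species_names = [s.name for s in network.species]
        h, w = geometry.shape
        self.n_px = h * w
        n = self.n_px * len(self.species_names)
        h_um = geometry.pixel_size
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []

        def add(r: np.ndarray, c: np.ndarray, v: np.ndarray) -> None:
            rows.append(np.asarray(r, dtype=np.int64))
            cols.append(np.asarray(c, dtype=np.int64))
            vals.append(np.asarray(v, dtype=np.float64))

        sp_index = {name: i for i, name in enumerate(self.species_names)}
        lab = geometry.label_map
        flat = np.arange(self.n_px).reshape(h, w)

        # diffusion: conservative pairwise fluxes within each compartment
        for species in network.species:
            off = sp_index[species.name] * self.n_px
            d = params.diffusion(species.name) / h_um**2
            for comp in species.allowed_compartments:
                m = geometry.mask(comp)
                for sl_p, sl_q in (
                    ((slice(None, -1), slice(None)), (slice(1, None), slice(None))),
                    ((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
                ):
                    both = m[sl_p] & m[sl_q]
                    p = flat[sl_p][both] + off
                    q = flat[sl_q][both] + off
                    ones = np.full(p.size, d)
                    add(p, q, ones)
                    add(q, p, ones)
                    add(p, p, -ones)
                    add(q, q, -ones)

        # first-order volume reactions
        comp_pixels = {comp: flat[geometry.mask(comp)] for comp in COMPARTMENTS}
        for rxn in network.volume_reactions:
            k = params.rate(rxn.rate)
            if k == 0:
                continue
            px = comp_pixels[rxn.compartment]
            sub = px + sp_index[rxn.substrate] * self.n_px
            add(sub, sub, np.full(px.size, -k))
            if rxn.product is not None:
                prod = px + sp_index[rxn.product] * self.n_px
                add(prod, sub, np.full(px.size, k))

        # nuclear-membrane transport: flux density k * c_source across each
        # face of length h, over pixel area h^2 -> rate k/h on both pixels
        faces = geometry.nuclear_membrane_faces  # (cyt, nuc) pairs
        side = {"cytoplasm": faces[:, 0], "nucleus": faces[:, 1]}
        for tr in network.membrane_transports:
            k = params.rate(tr.rate) / h_um
            if k == 0:
                continue
            off = sp_index[tr.species] * self.n_px
            src = side[tr.source] + off
            dst = side[tr.dest] + off
            add(src, src, np.full(src.size, -k))
            add(dst, src, np.full(src.size, k))

        self.matrix = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()

        self.source = np.zeros(n)
        for syn in network.synthesis:
            px = comp_pixels[syn.compartment] + sp_index[syn.species] * self.n_px
            self.source[px] += params.rate(syn.rate)

        self.max_stable_dt = stable_timestep(
            params, h_um, safety=1.0, network=network
        )

    # state packing ------------------------------------------------------

    def pack(self, fields: ConcentrationFields) -> np.ndarray:
        return np.concatenate(
            [fields.fields[name].ravel() for name in self.species_names]
        )

    def unpack(self, state: np.ndarray, time: float) -> ConcentrationFields:
        h, w = self.geometry.shape
        return ConcentrationFields(
            {
                name: state[i * self.n_px : (i + 1) * self.n_px].reshape(h, w).copy()
                for i, name in enumerate(self.species_names)
            },
            time,
        )

    def rate(self, state: np.ndarray) -> np.ndarray:
        return self.matrix @ state + self.source

    def uniform_cytoplasmic_init(self, value: float = 1.0) -> ConcentrationFields:
        """Default initial condition: all protein unphosphorylated, uniform
        in the cytoplasm."""
        h, w = self.geometry.shape
        fields = {name: np.zeros((h, w)) for name in self.species_names}
        fields["U"][self.geometry.mask("cytoplasm")] = value
        return ConcentrationFields(fields, 0.0)


def ftcs_step(
    fields: ConcentrationFields,
    geometry: CompartmentGeometry,
    network: ReactionNetwork,
    params: KineticParameters,
    dt: float,
    operator: FtcsOperator | None = None,
) -> ConcentrationFields:
    """One explicit FTCS step; refuses dt above the stability bound."""
    op = operator or FtcsOperator(geometry, network, params)
    if dt > op.max_stable_dt * (1 + 1e-12):
        raise ValueError(
            f"dt={dt} exceeds the FTCS stability bound {op.max_stable_dt}"
        )
    state = op.pack(fields)
    state = state + dt * op.rate(state)
    return op.unpack(state, fields.time + dt)


def simulate_to_steady_state(
    geometry: CompartmentGeometry,
    network: ReactionNetwork,
    params: KineticParameters,
    init: ConcentrationFields | float = 1.0,
    tol: float | None = None,
    t_max: float = 5000.0,
    dt: float | None = None,
    safety: float = 0.5,
    check_every: int = 25,
) -> SimulationResult:
    """March FTCS until max |dc/dt| <= tol or ``t_max`` is reached.

    ``init`` may be a ConcentrationFields or a scalar, meaning a uniform
    cytoplasmic concentration of unphosphorylated protein.  ``tol`` defaults
    to 1e-6 of the mean initial cell concentration per second.  Reaching
    ``t_max`` without convergence is reported via the flag, not an exception.
    """
    op = FtcsOperator(geometry, network, params)
    if isinstance(init, ConcentrationFields):
        init.validate(geometry, network)
        state = op.pack(init)
    else:
        state = op.pack(op.uniform_cytoplasmic_init(float(init)))
    if dt is None:
        dt = stable_timestep(params, geometry.pixel_size, safety, network)
    elif dt > op.max_stable_dt * (1 + 1e-12):
        raise ValueError(f"dt={dt} exceeds the FTCS stability bound")
    if tol is None:
        n_cell = max(int(geometry.cell_mask.sum()), 1)
        mean0 = state.sum() / (n_cell * len(op.species_names))
        tol = 1e-6 * max(mean0, 1e-30)
    if tol <= 0:
        raise ValueError("tol must be > 0")

    t = 0.0
    n_steps = 0
    rate_norm = float(np.abs(op.rate(state)).max())
    steady = rate_norm <= tol
    while not steady and t < t_max:
        for _ in range(check_every):
            r = op.rate(state)
            state += dt * r
            t += dt
            n_steps += 1
            if t >= t_max:
                break
        rate_norm = float(np.abs(r).max())
        steady = rate_norm <= tol
    return SimulationResult(
        fields=op.unpack(state, t),
        steady_state_reached=bool(steady),
        final_rate_norm=rate_norm,
        elapsed_time=t,
        dt_used=dt,
        n_steps=n_steps,
        tol=tol,
    )


def total_fluorescence_image(fields: ConcentrationFields) -> np.ndarray:
    """Per-pixel sum over all forms of the effector (the fluorescent tag
    labels U and P alike), zero on the exterior by construction."""
    arrays = list(fields.fields.values())
    out = np.zeros_like(arrays[0])
    for a in arrays:
        out = out + a
    return out


def compartment_means(
    image: np.ndarray, geometry: CompartmentGeometry
) -> dict[str, float]:
    return {
        comp: float(image[geometry.mask(comp)].mean())
        for comp in ("cytoplasm", "nucleus")
        if geometry.mask(comp).any()
    }


def simulated_ncr(fields: ConcentrationFields, geometry: CompartmentGeometry) -> float:
    """Nuclear/cytoplasmic ratio of the total-effector image."""
    means = compartment_means(total_fluorescence_image(fields), geometry)
    if means.get("cytoplasm", 0.0) <= 0:
        return float("inf")
    return means["nucleus"] / means["cytoplasm"]
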