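"""FTCS solver: stability bound, conservation, diffusion accuracy, limits."""

import numpy as np
import pytest

from hipposhuttle.geometry import CYTOPLASM_LABEL, CompartmentGeometry
from hipposhuttle.model import KineticParameters, build_topology, wellmixed_steady_state
from hipposhuttle.pde import (
    ConcentrationFields,
    FtcsOperator,
    compartment_means,
    ftcs_step,
    simulate_to_steady_state,
    simulated_ncr,
    stable_timestep,
    total_fluorescence_image,
)
from hipposhuttle.synth import single_cell_geometry


def all_cytoplasm_geometry(size: int, pixel_size: float = 1.0) -> CompartmentGeometry:
    """A plain diffusive box (no nucleus) for pure-diffusion checks."""
    return CompartmentGeometry(
        np.full((size, size), CYTOPLASM_LABEL, dtype=np.int8), pixel_size
    )


def zero_rate_params(**overrides) -> KineticParameters:
    base = dict(
        k_phos=0.0, k_dephos_nuc=0.0, k_dephos_cyt=0.0, k_import=0.0,
        k_export=0.0, k_syn=0.0, k_deg=0.0, d_u=1.0, d_p=1.0,
    )
    base.update(overrides)
    return KineticParameters(**base)


class TestStableTimestep:
    def test_cfl_formula(self):
        p = zero_rate_params(d_u=1.0, d_p=1.0)
        assert stable_timestep(p, 1.0, safety=1.0) == pytest.approx(0.25)

    def test_rate_limited(self):
        p = zero_rate_params(k_phos=10.0)
        assert stable_timestep(p, 1.0, safety=0.5) == pytest.approx(0.05)

    def test_quadratic_scaling_in_pixel_size(self):
        p = zero_rate_params()
        assert stable_timestep(p, 2.0, safety=1.0) == pytest.approx(
            4 * stable_timestep(p, 1.0, safety=1.0)
        )

    def test_rejects_bad_pixel_size(self):
        with pytest.raises(ValueError):
            stable_timestep(zero_rate_params(), 0.0)


class TestFtcsStep:
    def test_uniform_field_is_a_fixed_point(self, geo64, alt_net):
        p = zero_rate_params(d_u=2.0, d_p=2.0)
        op = FtcsOperator(geo64, alt_net, p)
        fields = op.uniform_cytoplasmic_init(3.0)
        fields.fields["U"][geo64.mask("nucleus")] = 3.0
        dt = stable_timestep(p, geo64.pixel_size)
        out = ftcs_step(fields, geo64, alt_net, p, dt, operator=op)
        assert np.array_equal(out.fields["U"], fields.fields["U"])

    def test_diffusion_conserves_mass_per_step(self, geo64, alt_net):
        p = zero_rate_params(d_u=2.0, d_p=2.0)
        op = FtcsOperator(geo64, alt_net, p)
        rng = np.random.default_rng(0)
        fields = op.uniform_cytoplasmic_init(0.0)
        cyt = geo64.mask("cytoplasm")
        fields.fields["U"][cyt] = rng.uniform(0.5, 2.0, cyt.sum())
        dt = stable_timestep(p, geo64.pixel_size)
        before = fields.fields["U"].sum()
        out = ftcs_step(fields, geo64, alt_net, p, dt, operator=op)
        assert out.fields["U"].sum() == pytest.approx(before, rel=1e-12)

    def test_refuses_unstable_dt(self, geo64, alt_net, params):
        op = FtcsOperator(geo64, alt_net, params)
        fields = op.uniform_cytoplasmic_init()
        with pytest.raises(ValueError, match="stability"):
            ftcs_step(fields, geo64, alt_net, params, 10 * op.max_stable_dt,
                      operator=op)

    def test_point_source_matches_heat_kernel(self):
        # Gaussian initial condition: the exact solution stays Gaussian with
        # variance sigma0^2 + 2 D t
        size, d, sigma0, t_end = 96, 1.5, 3.0, 40.0
        geo = all_cytoplasm_geometry(size)
        net = build_topology("alternative")
        p = zero_rate_params(d_u=d, d_p=d)
        op = FtcsOperator(geo, net, p)
        rr, cc = np.mgrid[0:size, 0:size].astype(float)
        c0 = (size - 1) / 2
        r2 = (rr - c0) ** 2 + (cc - c0) ** 2
        fields = op.uniform_cytoplasmic_init(0.0)
        fields.fields["U"] = np.exp(-r2 / (2 * sigma0**2))
        dt = stable_timestep(p, 1.0, safety=0.5)
        n_steps = int(round(t_end / dt))
        state = op.pack(fields)
        for _ in range(n_steps):
            state += dt * op.rate(state)
        got = op.unpack(state, n_steps * dt).fields["U"]
        sig2 = sigma0**2 + 2 * d * (n_steps * dt)
        expected = (sigma0**2 / sig2) * np.exp(-r2 / (2 * sig2))
        core = r2 < (2.5**2 * sig2)  # away from boundaries, above noise floor
        rel = np.abs(got[core] - expected[core]) / expected[core].max()
        assert rel.max() < 0.02


class TestSimulateToSteadyState:
    def test_all_rates_zero_uniform_init_is_steady_immediately(self, geo64):
        net = build_topology("alternative")
        p = zero_rate_params(d_u=1.0, d_p=1.0)
        res = simulate_to_steady_state(geo64, net, p, init=1.0, t_max=100.0)
        assert res.steady_state_reached
        assert res.n_steps == 0
        assert res.final_rate_norm == 0.0

    def test_result_independent_of_initial_condition(self, geo64, alt_net, params):
        res_a = simulate_to_steady_state(geo64, alt_net, params, init=1.0)
        op = FtcsOperator(geo64, alt_net, params)
        other = op.uniform_cytoplasmic_init(0.2)
        other.fields["U"][geo64.mask("nucleus")] = 2.0
        res_b = simulate_to_steady_state(geo64, alt_net, params, init=other)
        img_a = total_fluorescence_image(res_a.fields)
        img_b = total_fluorescence_image(res_b.fields)
        assert res_a.steady_state_reached and res_b.steady_state_reached
        assert np.allclose(img_a, img_b, rtol=0, atol=1e-3 * img_a.max())

    def test_result_independent_of_timestep(self, geo64, alt_net, params):
        dt_ref = stable_timestep(params, geo64.pixel_size, 0.5, alt_net)
        res_a = simulate_to_steady_state(geo64, alt_net, params, dt=dt_ref)
        res_b = simulate_to_steady_state(geo64, alt_net, params, dt=dt_ref / 2)
        ncr_a = simulated_ncr(res_a.fields, geo64)
        ncr_b = simulated_ncr(res_b.fields, geo64)
        assert ncr_a == pytest.approx(ncr_b, rel=0.01)

    def test_nonconvergence_sets_flag_instead_of_raising(self, geo64, alt_net, params):
        res = simulate_to_steady_state(geo64, alt_net, params, t_max=1.0)
        assert not res.steady_state_reached
        assert res.final_rate_norm > res.tol

    def test_canonical_p_never_enters_the_nucleus(self, geo64, can_net, params):
        res = simulate_to_steady_state(geo64, can_net, params)
        assert not res.fields.fields["P"][geo64.mask("nucleus")].any()

    def test_mass_conservation_without_sources(self, alt_net):
        geo = single_cell_geometry(32, 1.24, 15.0, 6.0)
        p = KineticParameters(k_syn=0.0, k_deg=0.0)
        op = FtcsOperator(geo, alt_net, p)
        state = op.pack(op.uniform_cytoplasmic_init(1.0))
        dt = stable_timestep(p, geo.pixel_size, 0.5, alt_net)
        total0 = state.sum()
        for _ in range(100_000):
            state += dt * op.rate(state)
        assert state.sum() == pytest.approx(total0, rel=1e-8)
        assert (state >= 0).all()

    def test_wellmixed_limit_error_decreases_with_diffusion(self, alt_net):
        geo = single_cell_geometry(32, 1.24, 15.0, 6.0)
        ref = wellmixed_steady_state(
            alt_net, KineticParameters(),
            geo.compartment_volumes(), geo.nuclear_membrane_length(),
        )
        errors = []
        for d in (1.0, 2.0, 4.0):
            p = KineticParameters(d_u=d, d_p=d)
            res = simulate_to_steady_state(geo, alt_net, p)
            assert res.steady_state_reached
            errors.append(abs(simulated_ncr(res.fields, geo) - ref.ncr) / ref.ncr)
        assert errors[0] > errors[1] > errors[2]

    def test_grid_refinement_changes_means_by_under_2_percent(self, alt_net):
        # smooth regime: diffusion fast enough that the one-pixel membrane
        # boundary layer stays mild (the membrane flux is first-order in h)
        p = KineticParameters(d_u=10.0, d_p=10.0)
        means = []
        for size, px in ((48, 1.6), (96, 0.8)):
            geo = single_cell_geometry(size, px, 30.0, 12.0)
            res = simulate_to_steady_state(geo, alt_net, p)
            assert res.steady_state_reached
            img = total_fluorescence_image(res.fields)
            means.append(compartment_means(img, geo))
        for comp in ("cytoplasm", "nucleus"):
            assert means[0][comp] == pytest.approx(means[1][comp], rel=0.02)


class TestTotalFluorescence:
    def test_reduces_to_u_when_p_is_zero(self, geo64, alt_net):
        op = FtcsOperator(geo64, alt_net, zero_rate_params())
        fields = op.uniform_cytoplasmic_init(1.7)
        assert np.array_equal(
            total_fluorescence_image(fields), fields.fields["U"]
        )

    def test_sums_both_forms(self, geo64, alt_net):
        op = FtcsOperator(geo64, alt_net, zero_rate_params())
        fields = op.uniform_cytoplasmic_init(1.0)
        fields.fields["P"] = fields.fields["U"].copy()
        img = total_fluorescence_image(fields)
        assert np.all(img[geo64.mask("cytoplasm")] == 2.0)
        assert np.all(img[geo64.mask("exterior")] == 0.0)

    def test_low_ratio_steady_state_is_nuclear_enriched_with_outward_gradient(
        self, geo64, alt_net, params
    ):
        res = simulate_to_steady_state(geo64, alt_net, params.with_ratio(0.17))
        img = total_fluorescence_image(res.fields)
        means = compartment_means(img, geo64)
        assert means["nucleus"] > means["cytoplasm"]
        # radial profile decreases outward from the nuclear envelope
        c0 = (geo64.height - 1) / 2
        rr, cc = np.mgrid[0 : geo64.height, 0 : geo64.width].astype(float)
        radius = np.hypot(rr - c0, cc - c0) * geo64.pixel_size
        cyt = geo64.mask("cytoplasm")
        inner = cyt & (radius < 18.0)
        outer = cyt & (radius > 24.0)
        assert img[inner].mean() > img[outer].mean()
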