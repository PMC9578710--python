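"""Normalization, residuals, the two-term cost, PSO, and the ratio scan."""

import numpy as np
import pytest

from hipposhuttle.fitting import (
    TargetImage,
    fit_cost,
    normalize_to_max,
    particle_swarm_fit,
    pso_minimize,
    ratio_scan,
    residual_image,
    summarized_residual,
)
from hipposhuttle.model import KineticParameters
from hipposhuttle.pde import simulate_to_steady_state, total_fluorescence_image
from hipposhuttle.synth import single_cell_geometry


@pytest.fixture(scope="module")
def geo48():
    return single_cell_geometry(48, 1.24, 22.0, 9.0)


@pytest.fixture(scope="module")
def self_target(geo48, alt_net, params):
    sim = simulate_to_steady_state(geo48, alt_net, params)
    assert sim.steady_state_reached
    return TargetImage.from_raw(total_fluorescence_image(sim.fields), geo48)


class TestNormalizeToMax:
    def test_constant_image_maps_to_one(self):
        assert np.all(normalize_to_max(np.full((4, 4), 7.0)) == 1.0)

    def test_scales_by_maximum(self):
        img = np.zeros((3, 3))
        img[0, 0], img[1, 1] = 200.0, 50.0
        out = normalize_to_max(img)
        assert out[0, 0] == 1.0 and out[1, 1] == 0.25

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        img = normalize_to_max(rng.uniform(size=(8, 8)))
        assert np.array_equal(normalize_to_max(img), img)

    def test_all_zero_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = normalize_to_max(np.zeros((4, 4)))
        assert np.all(out == 0)

    def test_rejects_negative_pixels(self):
        with pytest.raises(ValueError, match="negative"):
            normalize_to_max(np.array([[-1.0, 2.0]]))


class TestResiduals:
    def test_identical_images_zero_residual(self, geo48, self_target):
        res = residual_image(self_target, self_target, geo48)
        assert np.all(res == 0)
        assert summarized_residual(self_target, self_target, geo48) == 0.0

    def test_zero_simulation_returns_target(self, geo48, self_target):
        res = residual_image(self_target, np.zeros(geo48.shape), geo48)
        cell = geo48.cell_mask
        assert np.array_equal(res[cell], self_target.intensity[cell])
        assert np.all(res[~cell] == 0)

    def test_constant_residual_mean_square(self, geo48):
        cell = geo48.cell_mask
        target = np.zeros(geo48.shape)
        target[cell] = 0.6
        sim = np.zeros(geo48.shape)
        sim[cell] = 0.5
        assert summarized_residual(target, sim, geo48) == pytest.approx(0.01)

    def test_shape_mismatch_rejected(self, geo48):
        with pytest.raises(ValueError):
            residual_image(np.zeros((8, 8)), np.zeros((9, 9)), geo48)

    def test_nuclear_halo_target_vs_flat_model_gives_positive_envelope_ring(
        self, geo48
    ):
        # target bright just outside the nuclear envelope, model flat:
        # the model under-predicts there, so residuals are positive
        c0 = (geo48.height - 1) / 2
        rr, cc = np.mgrid[0 : geo48.height, 0 : geo48.width].astype(float)
        radius = np.hypot(rr - c0, cc - c0) * geo48.pixel_size
        ring = geo48.mask("cytoplasm") & (radius < 13.0)
        target = np.zeros(geo48.shape)
        target[geo48.cell_mask] = 0.4
        target[ring] = 1.0
        flat = np.zeros(geo48.shape)
        flat[geo48.cell_mask] = 0.4
        res = residual_image(target, flat, geo48)
        assert (res[ring] > 0).all()
        assert res[geo48.cell_mask & ~ring].max() == pytest.approx(0.0, abs=1e-12)


class TestFitCost:
    def test_self_fit_cost_is_nearly_zero(self, geo48, alt_net, params, self_target):
        cost = fit_cost(params, self_target, geo48, alt_net)
        assert cost <= 1e-6

    def test_nonconverged_snapshot_pays_steady_state_penalty(
        self, geo48, alt_net, params, self_target
    ):
        converged = fit_cost(params, self_target, geo48, alt_net)
        truncated = fit_cost(
            params, self_target, geo48, alt_net, sim_kwargs={"t_max": 3.0}
        )
        assert truncated > 10 * max(converged, 1e-12)

    def test_local_identifiability_around_truth(
        self, geo48, alt_net, params, self_target
    ):
        cost_true = fit_cost(params, self_target, geo48, alt_net)
        cost_pert = fit_cost(
            params.replace(k_phos=2 * params.k_phos),
            self_target, geo48, alt_net,
        )
        assert cost_true < cost_pert

    def test_invalid_weights_rejected(self, geo48, alt_net, params, self_target):
        with pytest.raises(ValueError):
            fit_cost(params, self_target, geo48, alt_net,
                     weights={"w_img": 0.0, "w_ss": 0.0})


class TestParticleSwarm:
    def test_sphere_minimum_recovered(self):
        x, f, trace = pso_minimize(
            lambda v: float(np.sum((v - 0.3) ** 2)),
            [(-2, 2)] * 3, n_particles=20, n_iterations=200, seed=5,
        )
        assert np.allclose(x, 0.3, atol=1e-3)
        assert f < 1e-3

    def test_trace_is_non_increasing(self):
        _, _, trace = pso_minimize(
            lambda v: float(np.cos(3 * v[0]) + v[0] ** 2),
            [(-4, 4)], n_particles=8, n_iterations=60, seed=1,
        )
        assert (np.diff(trace) <= 0).all()

    def test_seeded_runs_are_bit_identical(self):
        runs = [
            pso_minimize(
                lambda v: float(np.sum(v**2)), [(-1, 2)] * 4,
                n_particles=10, n_iterations=30, seed=42,
            )
            for _ in range(2)
        ]
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]
        assert np.array_equal(runs[0][2], runs[1][2])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pso_minimize(lambda v: 0.0, [], n_particles=5, n_iterations=5)
        with pytest.raises(ValueError):
            pso_minimize(lambda v: 0.0, [(0, 1)], n_particles=1, n_iterations=5)

    def test_seeded_fit_is_deterministic(self, geo48, alt_net, params, self_target):
        bounds = {"k_phos": (0.01, 1.0), "k_import": (0.05, 5.0)}
        kw = dict(
            base_params=params, n_particles=4, n_iterations=3, seed=9,
            sim_kwargs={"t_max": 200.0},
        )
        a = particle_swarm_fit(self_target, geo48, alt_net, bounds, **kw)
        b = particle_swarm_fit(self_target, geo48, alt_net, bounds, **kw)
        assert a.best_cost == b.best_cost
        assert a.best_params == b.best_params
        assert np.array_equal(a.cost_trace, b.cost_trace)
        assert np.array_equal(a.residual, b.residual)
        assert (np.diff(a.cost_trace) <= 0).all()
        assert a.best_cost == a.cost_trace[-1]


class TestRatioScan:
    def test_generating_ratio_has_minimal_residual(
        self, geo48, alt_net, params, self_target
    ):
        r_true = params.k_phos / params.k_dephos_nuc
        scan = ratio_scan(
            self_target, geo48, params, [r_true / 3, r_true, 3 * r_true]
        )
        assert scan["converged"].all()
        best = scan.loc[scan["summarized_residual"].idxmin(), "ratio"]
        assert best == pytest.approx(r_true)

    def test_simulated_ncr_non_increasing_in_ratio(self, geo48, params, self_target):
        scan = ratio_scan(self_target, geo48, params, [0.05, 0.17, 0.4, 0.75])
        ncr = scan["ncr_sim"].to_numpy()
        assert (np.diff(ncr) <= 1e-9).all()

    def test_rejects_non_positive_ratios(self, geo48, params, self_target):
        with pytest.raises(ValueError):
            ratio_scan(self_target, geo48, params, [0.2, -0.1])
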