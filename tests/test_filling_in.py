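import numpy as np
import pytest
from scipy import ndimage

from chromafill.filling_in import (
    FillinProblem,
    fill_ratio,
    fillin_direct,
    fillin_iterative,
    fillin_snn,
    poisson_residual,
)
from chromafill.nef_core import EnsembleSpec
from chromafill.receptive_fields import LAPLACIAN_KERNEL
from chromafill.stimuli import SquareStimulusSpec, make_square, square_mask
from chromafill.colorspace import rgb_to_opponent
from chromafill.receptive_fields import compute_channels, GaussianKernelSpec


class TestProblemValidation:
    def test_non_finite_source_rejected(self):
        src = np.zeros((8, 8))
        src[3, 3] = np.nan
        with pytest.raises(ValueError):
            FillinProblem(source=src)

    def test_large_tau_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            FillinProblem(source=np.zeros((8, 8)), tau=0.3)

    def test_unknown_boundary_rejected(self):
        with pytest.raises(ValueError):
            FillinProblem(source=np.zeros((8, 8)), boundary="periodic")


class TestIterative:
    def test_zero_source_stays_zero(self):
        res = fillin_iterative(FillinProblem(source=np.zeros((10, 10))), mode="snapshot", n_steps=50)
        assert np.array_equal(res.surface, np.zeros((10, 10)))
        assert res.iterations == 50

    def test_fixed_point_recovers_laplacian_preimage(self, smooth_plane):
        # source built by the printed (positive-center) kernel; the diffusion
        # iteration must regenerate the original plane under Dirichlet-0
        src = ndimage.convolve(smooth_plane, LAPLACIAN_KERNEL, mode="nearest")
        res = fillin_iterative(FillinProblem(source=src), tol=1e-6)
        assert res.converged
        assert np.max(np.abs(res.surface - smooth_plane)) <= 1e-3

    def test_linearity_at_equal_step_counts(self, rng):
        s1 = rng.standard_normal((16, 16))
        s2 = rng.standard_normal((16, 16))
        sol = lambda s: fillin_iterative(
            FillinProblem(source=s), mode="snapshot", n_steps=40
        ).surface
        assert np.allclose(sol(s1 + s2), sol(s1) + sol(s2), atol=1e-10)

    def test_monotone_center_filling_in_snapshot_mode(self):
        spec = SquareStimulusSpec(canvas=(40, 40), side=12)
        ch = compute_channels(rgb_to_opponent(make_square(spec)), GaussianKernelSpec(11, 3.0))
        problem = FillinProblem(source=ch.do_rg)
        centers = [
            fillin_iterative(problem, mode="snapshot", n_steps=n).surface[20, 20]
            for n in (10, 50, 100, 300, 800)
        ]
        assert np.all(np.diff(centers) >= -1e-12)

    def test_stability_with_default_tau_on_bounded_source(self, rng):
        src = rng.uniform(-1, 1, size=(20, 20))
        res = fillin_iterative(FillinProblem(source=src), mode="snapshot", n_steps=3000)
        assert np.max(np.abs(res.surface)) < 1e3

    def test_residual_is_recomputable(self, rng):
        problem = FillinProblem(source=rng.standard_normal((12, 12)))
        res = fillin_iterative(problem, mode="snapshot", n_steps=25)
        assert res.residual == pytest.approx(poisson_residual(res.surface, problem))
        assert not res.converged


class TestDirect:
    def test_zero_source_gives_zero_surface(self):
        for boundary in ("dirichlet", "neumann"):
            res = fillin_direct(FillinProblem(source=np.zeros((10, 10)), boundary=boundary))
            assert np.allclose(res.surface, 0.0, atol=1e-12)
            assert res.residual <= 1e-9

    def test_oracle_equivalence_with_iterative(self, rng):
        for boundary in ("dirichlet", "neumann"):
            src = rng.standard_normal((24, 24))
            problem = FillinProblem(source=src, boundary=boundary)
            it = fillin_iterative(problem, tol=1e-6)
            dr = fillin_direct(problem)
            assert np.max(np.abs(it.surface - dr.surface)) <= 1e-4

    def test_neumann_solution_is_zero_mean_and_flagged(self, rng):
        res = fillin_direct(FillinProblem(source=rng.standard_normal((14, 14)), boundary="neumann"))
        assert res.projected
        assert abs(res.surface.mean()) <= 1e-9

    def test_centered_impulse_has_fourfold_symmetry(self):
        src = np.zeros((17, 17))
        src[8, 8] = 1.0
        surf = fillin_direct(FillinProblem(source=src)).surface
        assert np.allclose(surf, surf[::-1, :], atol=1e-10)
        assert np.allclose(surf, surf[:, ::-1], atol=1e-10)
        assert np.allclose(surf, surf.T, atol=1e-10)

    def test_direct_residual_tiny(self, rng):
        res = fillin_direct(FillinProblem(source=rng.standard_normal((20, 20))))
        assert res.residual <= 1e-9


class TestSpikingBackend:
    def test_zero_source_decodes_near_zero(self):
        res = fillin_snn(
            FillinProblem(source=np.zeros((10, 10))),
            ensemble_spec=EnsembleSpec(n_neurons=20, radius=0.6, seed=0),
            run_time=0.5,
        )
        assert np.max(np.abs(res.surface)) <= 0.05

    def test_agrees_with_converged_iterative_on_red_square(self, red_square_channels):
        problem = FillinProblem(source=red_square_channels.do_rg)
        ref = fillin_iterative(problem, tol=1e-6)
        snn = fillin_snn(
            problem,
            ensemble_spec=EnsembleSpec(n_neurons=20, radius=0.6, seed=42),
            run_time=1.0,
        )
        dyn = np.ptp(ref.surface)
        rmse = np.sqrt(np.mean((snn.surface - ref.surface) ** 2))
        assert rmse <= 0.05 * dyn
        assert not snn.converged  # spiking never claims an exact steady state

    def test_short_run_time_warns(self):
        with pytest.warns(UserWarning, match="run_time"):
            fillin_snn(
                FillinProblem(source=np.zeros((6, 6))),
                ensemble_spec=EnsembleSpec(n_neurons=5, radius=1.0, seed=0),
                run_time=0.02,
            )


class TestFillRatio:
    def test_constant_surface_gives_ratio_one(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        assert fill_ratio(np.ones((30, 30)), mask) == pytest.approx(1.0)

    def test_edge_band_only_surface_gives_ratio_zero(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True
        surface = np.zeros((40, 40))
        band = mask & ~ndimage.binary_erosion(mask, iterations=2)
        surface[band] = 1.0
        assert fill_ratio(surface, mask) == pytest.approx(0.0)

    def test_converged_small_square_is_filled(self):
        spec = SquareStimulusSpec(canvas=(40, 40), side=5)
        ch = compute_channels(rgb_to_opponent(make_square(spec)), GaussianKernelSpec(11, 3.0))
        res = fillin_iterative(FillinProblem(source=ch.do_rg), tol=1e-6)
        assert fill_ratio(res, square_mask(spec)) >= 0.8

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fill_ratio(np.zeros((5, 5)), np.zeros((5, 5), dtype=bool))


def test_snapshot_and_converge_agree_in_the_long_step_limit(smooth_plane):
    src = ndimage.convolve(smooth_plane, LAPLACIAN_KERNEL, mode="nearest")
    problem = FillinProblem(source=src)
    long_snap = fillin_iterative(problem, mode="snapshot", n_steps=20000)
    conv = fillin_iterative(problem, tol=1e-6)
    assert np.max(np.abs(long_snap.surface - conv.surface)) <= 1e-3
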