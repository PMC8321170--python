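"""Active-surface energy, descent and level-set machinery vs. brute-force oracles."""

import numpy as np
import pytest

from petas3d.active_surface import (
    ASParams,
    SurfaceState,
    ball_offsets,
    ball_sum,
    evolve_step,
    local_intensity_means,
    local_mean_fields,
    prior_fields,
    reinitialize,
    segment,
    signed_distance,
    smoothed_dirac,
    total_energy,
)
from petas3d.da_classifier import ClassMaps
from petas3d.tissue_sampling import BACKGROUND, BORDER_LINE, LESION
from petas3d.volume_io import BinaryMask, Grid3D, SUVVolume

from oracles import oracle_local_means, oracle_prior_at, oracle_total_energy


def make_maps(grid, labels):
    return ClassMaps.from_labels(grid, labels)


def random_maps(grid, rng):
    labels = rng.integers(0, 3, size=grid.shape)
    return make_maps(grid, labels)


class TestBallStencil:
    def test_symmetric_and_contains_origin(self):
        offs = ball_offsets(3)
        s = {tuple(o) for o in offs}
        assert (0, 0, 0) in s
        assert all(tuple(-np.array(o)) in s for o in s)

    def test_ball_sum_matches_offset_loop(self, rng):
        f = rng.random((7, 6, 5))
        got = ball_sum(f, 2)
        for x in [(0, 0, 0), (3, 3, 2), (6, 5, 4), (1, 4, 2)]:
            exp = sum(
                f[tuple(np.asarray(x) + o)]
                for o in ball_offsets(2)
                if all(0 <= (np.asarray(x) + o)[a] < f.shape[a] for a in range(3))
            )
            assert got[x] == pytest.approx(exp, rel=1e-12)

    def test_global_shortcut_when_ball_covers_grid(self, rng):
        f = rng.random((4, 4, 4))
        got = ball_sum(f, 10)
        assert np.allclose(got, f.sum())


class TestPriorFields:
    def test_all_lesion(self):
        g = Grid3D((6, 6, 6), (1, 1, 1))
        maps = make_maps(g, np.full(g.shape, LESION))
        p_in, p_out = prior_fields(maps, 2)
        assert np.allclose(p_in, 1.0) and np.allclose(p_out, 0.0)

    def test_all_border_line_applies_no_penalty(self):
        g = Grid3D((6, 6, 6), (1, 1, 1))
        maps = make_maps(g, np.full(g.shape, BORDER_LINE))
        p_in, p_out = prior_fields(maps, 2)
        assert not p_in.any() and not p_out.any()

    def test_random_maps_match_bruteforce(self, rng):
        g = Grid3D((7, 6, 5), (1, 1, 1))
        maps = random_maps(g, rng)
        p_in, p_out = prior_fields(maps, 2)
        for x in [(0, 0, 0), (3, 3, 2), (6, 5, 4), (2, 1, 3)]:
            e_in, e_out = oracle_prior_at(maps, 2, x)
            assert p_in[x] == pytest.approx(e_in, rel=1e-12)
            assert p_out[x] == pytest.approx(e_out, rel=1e-12)


class TestLocalMeans:
    def test_piecewise_constant_on_true_boundary(self, clean_sphere):
        vol, gold = clean_sphere
        phi = signed_distance(gold.bool)
        band = np.argwhere(np.abs(phi) < 1.5)
        for x in map(tuple, band[:: max(1, len(band) // 10)]):
            u, v = local_intensity_means(phi, vol.values, x, 3)
            assert u == pytest.approx(8.0)
            assert v == pytest.approx(1.0)

    def test_uniform_image(self):
        phi = np.fromfunction(lambda i, j, k: i - 3.5, (8, 8, 8))
        suv = np.full((8, 8, 8), 2.5)
        u, v = local_intensity_means(phi, suv, (3, 4, 4), 3)
        assert u == v == 2.5

    def test_random_image_matches_bruteforce(self, rng):
        phi = rng.normal(size=(8, 8, 8))
        suv = rng.random((8, 8, 8)) * 4
        for x in [(0, 0, 0), (4, 4, 4), (7, 7, 7), (2, 6, 1)]:
            u, v = local_intensity_means(phi, suv, x, 2)
            eu, ev = oracle_local_means(phi, suv, x, 2)
            assert u == pytest.approx(eu, rel=1e-12)
            assert v == pytest.approx(ev, rel=1e-12)

    def test_field_version_agrees_with_pointwise(self, rng):
        phi = rng.normal(size=(7, 7, 7))
        suv = rng.random((7, 7, 7))
        uf, vf = local_mean_fields(phi, suv, 2)
        for x in [(0, 3, 6), (3, 3, 3), (6, 0, 2)]:
            u, v = local_intensity_means(phi, suv, x, 2)
            assert uf[x] == pytest.approx(u, rel=1e-12)
            assert vf[x] == pytest.approx(v, rel=1e-12)


class TestTotalEnergy:
    def test_matches_bruteforce_triple_loop(self, rng):
        g = Grid3D((9, 9, 9), (1, 1, 1))
        suv = rng.random(g.shape) * 5
        maps = random_maps(g, rng)
        inside = np.zeros(g.shape, dtype=bool)
        inside[3:6, 3:6, 3:6] = True
        phi = signed_distance(inside)
        params = ASParams(lam=0.3, l=2, alpha=0.0)
        ours = total_energy(phi, suv, maps, params)
        oracle = oracle_total_energy(phi, suv, maps, params)
        assert ours == pytest.approx(oracle, rel=1e-9)

    def test_lambda0_boundary_on_piecewise_constant_is_zero(self, clean_sphere):
        vol, gold = clean_sphere
        phi = signed_distance(gold.bool)
        maps = make_maps(gold.grid, np.full(gold.grid.shape, BORDER_LINE))
        e = total_energy(phi, vol.values, maps, ASParams(lam=0.0, l=3, alpha=0.0))
        assert e == pytest.approx(0.0, abs=1e-9)

    def test_lambda1_all_border_is_zero(self, rng):
        g = Grid3D((8, 8, 8), (1, 1, 1))
        maps = make_maps(g, np.full(g.shape, BORDER_LINE))
        inside = np.zeros(g.shape, dtype=bool)
        inside[2:6, 2:6, 2:6] = True
        phi = signed_distance(inside)
        e = total_energy(phi, rng.random(g.shape), maps, ASParams(lam=1.0, alpha=0.0))
        assert e == pytest.approx(0.0, abs=1e-12)


class TestEvolveStep:
    def test_stationary_on_uniform_image_without_curvature(self):
        g = Grid3D((10, 10, 10), (1, 1, 1))
        inside = np.zeros(g.shape, dtype=bool)
        inside[3:7, 3:7, 3:7] = True
        phi = signed_distance(inside)
        maps = make_maps(g, np.full(g.shape, BORDER_LINE))
        suv = np.full(g.shape, 2.0)
        state = evolve_step(
            SurfaceState(phi=phi.copy()), suv, maps, ASParams(lam=0.0, alpha=0.0)
        )
        np.testing.assert_array_equal(state.phi, phi)

    def test_speed_sign_moves_lesionlike_voxel_inside(self, clean_sphere):
        # a band voxel whose value matches the interior mean and whose local
        # classification is lesion must see its phi decrease
        vol, gold = clean_sphere
        inside = np.zeros(gold.grid.shape, dtype=bool)
        inside[12:20, 12:20, 12:20] = True  # under-segmented init inside the sphere
        phi = signed_distance(inside)
        maps = make_maps(gold.grid, np.where(gold.bool, LESION, BACKGROUND))
        state = evolve_step(SurfaceState(phi=phi.copy()), vol.values, maps, ASParams(alpha=0.0))
        probe = np.abs(phi) < 1.0
        tumor_band = probe & gold.bool & (vol.values == 8.0)
        assert (state.phi[tumor_band] <= phi[tumor_band]).all()
        assert (state.phi[tumor_band] < phi[tumor_band]).any()


class TestReinitialize:
    def test_plane_distance_field_is_fixed_point(self):
        phi = np.fromfunction(lambda i, j, k: i - 5.5, (12, 12, 12))
        out = reinitialize(phi, iterations=20)
        np.testing.assert_allclose(out, phi, atol=1e-3)

    def test_doubled_distance_rescaled_to_unit_gradient(self):
        phi = 2.0 * np.fromfunction(lambda i, j, k: i - 5.5, (12, 12, 12))
        out = reinitialize(phi, iterations=40)
        gi = np.diff(out, axis=0)
        band = np.abs(out[:-1]) < 4
        assert np.all(np.abs(gi[band] - 1.0) < 0.2)

    def test_band_gradient_bound_for_smooth_field(self):
        # warped sphere field; the band excludes the skeleton kink at the center
        phi0 = np.fromfunction(
            lambda i, j, k: np.sqrt((i - 11.5) ** 2 + (j - 11.5) ** 2 + (k - 11.5) ** 2) - 7,
            (24, 24, 24),
        )
        phi = reinitialize(0.5 * phi0 + 0.3 * np.sin(phi0), iterations=40)
        gx, gy, gz = np.gradient(phi)
        g = np.sqrt(gx**2 + gy**2 + gz**2)
        band = (np.abs(phi) < 2.5) & (np.abs(phi) > 1)
        assert np.all((g[band] > 0.8) & (g[band] < 1.2))

    def test_zero_level_set_does_not_move(self):
        # subcell fix: sign pattern of a smooth signed-distance field survives,
        # even when the field arrives scaled
        phi0 = np.fromfunction(
            lambda i, j, k: np.sqrt((i - 11.5) ** 2 + (j - 11.5) ** 2 + (k - 11.5) ** 2) - 7,
            (24, 24, 24),
        )
        for scale in (1.0, 2.0):
            out = reinitialize(scale * phi0, iterations=20)
            assert ((out < 0) == (phi0 < 0)).all()

    def test_single_sign_rejected(self):
        with pytest.raises(ValueError):
            reinitialize(np.ones((4, 4, 4)))


class TestSegment:
    def test_clean_sphere_with_oracle_maps_recovers_gold(self, clean_sphere):
        vol, gold = clean_sphere
        maps = make_maps(gold.grid, np.where(gold.bool, LESION, BACKGROUND))
        inside = np.zeros(gold.grid.shape, dtype=bool)
        inside[12:20, 12:20, 12:20] = True
        phi0 = signed_distance(inside)
        mask, hist = segment(vol, maps, phi0, ASParams())
        inter = (mask.bool & gold.bool).sum()
        dsc = 2 * inter / (mask.count() + gold.count())
        assert dsc >= 0.95
        assert hist["converged"]

    def test_prior_only_gold_maps_reaches_gold(self):
        # clinically sized sphere: the ball-averaged prior biases the boundary
        # inward by ~l^2/2R voxels, negligible only when R >> l
        from petas3d.phantom import PhantomSpec, generate_phantom

        spec = PhantomSpec(
            grid=Grid3D((64, 64, 64), (1.0, 1.0, 1.0)),
            radius_mm=25.0, noise_sigma=0.0, psf_fwhm_mm=0.0, seed=0,
        )
        vol, gold = generate_phantom(spec)
        maps = make_maps(gold.grid, np.where(gold.bool, LESION, BACKGROUND))
        inside = np.zeros(gold.grid.shape, dtype=bool)
        inside[20:44, 20:44, 20:44] = True
        phi0 = signed_distance(inside)
        mask, hist = segment(vol, maps, phi0, ASParams(lam=1.0))
        inter = (mask.bool & gold.bool).sum()
        dsc = 2 * inter / (mask.count() + gold.count())
        assert dsc >= 0.98

    def test_optimal_init_converges_immediately_and_unchanged(self, clean_sphere):
        vol, gold = clean_sphere
        phi0 = signed_distance(gold.bool)
        maps = make_maps(gold.grid, np.full(gold.grid.shape, BORDER_LINE))
        params = ASParams(lam=0.0, alpha=0.0)
        mask, hist = segment(vol, maps, phi0, params)
        assert hist["converged"]
        assert hist["iterations"] <= params.conv_window
        np.testing.assert_array_equal(mask.values, gold.values)

    def test_seeded_run_bit_reproducible(self, clean_sphere):
        vol, gold = clean_sphere
        maps = make_maps(gold.grid, np.where(gold.bool, LESION, BACKGROUND))
        inside = np.zeros(gold.grid.shape, dtype=bool)
        inside[12:20, 12:20, 12:20] = True
        phi0 = signed_distance(inside)
        m1, h1 = segment(vol, maps, phi0, ASParams())
        m2, h2 = segment(vol, maps, phi0, ASParams())
        np.testing.assert_array_equal(m1.values, m2.values)
        assert h1["energy"] == h2["energy"]

    def test_empty_interior_init_rejected(self, clean_sphere):
        vol, gold = clean_sphere
        maps = make_maps(gold.grid, np.full(gold.grid.shape, BORDER_LINE))
        with pytest.raises(ValueError):
            segment(vol, maps, np.ones(gold.grid.shape), ASParams())


def test_smoothed_dirac_shape_and_support():
    phi = np.linspace(-3, 3, 121).reshape(11, 11, 1)
    d = smoothed_dirac(phi, 1.5)
    assert d.max() == pytest.approx(1 / 1.5, rel=1e-6)
    assert (d[np.abs(phi) >= 1.5] == 0).all()
    assert (d[np.abs(phi) < 1.5] > 0).all()
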