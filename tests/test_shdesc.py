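"""Spherical-harmonics basis, depth maps and the rotation-invariant
descriptor."""

import numpy as np
import pytest
from scipy.special import lpmv

from shpcvm import (Atom, Molecule, build_depth_map, compute_sh_descriptor,
                    degree_norms, normalize_pose, real_spherical_harmonic,
                    sh_coefficients, slm_normalization)
from shpcvm.datasets import make_toy_molecule
from shpcvm.shdesc import (DepthMap, DescriptorConfig, SHCoefficients,
                           quadrature_weights)
from .conftest import random_rotation, rotate_molecule


def grid(B):
    thetas = np.pi * (2 * np.arange(2 * B) + 1) / (4 * B)
    phis = np.pi * np.arange(2 * B) / B
    return np.meshgrid(thetas, phis, indexing="ij")


class TestBasis:
    def test_normalization_constant_values(self):
        # direct evaluation of sqrt((2l+1)(l−m)!/(4π(l+m)!)) with exact
        # big-integer factorials
        import math
        for l, m in [(0, 0), (1, 0), (2, 1), (5, 3), (10, 10), (40, 25)]:
            exact = math.sqrt((2 * l + 1) * math.factorial(l - m)
                              / (4 * math.pi * math.factorial(l + m)))
            assert slm_normalization(l, m) == pytest.approx(exact, rel=1e-12)
        assert slm_normalization(0, 0) == pytest.approx(0.2820948, abs=1e-7)
        assert slm_normalization(1, 0) == pytest.approx(0.4886025, abs=1e-7)

    def test_order_exceeding_degree_rejected(self):
        with pytest.raises(ValueError):
            slm_normalization(2, 3)
        with pytest.raises(ValueError):
            real_spherical_harmonic(2, 3, 0.1, 0.1)

    def test_y00_constant_and_y10_pole(self):
        assert real_spherical_harmonic(0, 0, 0.7, 1.3) == pytest.approx(
            0.2820948, abs=1e-7)
        assert real_spherical_harmonic(0, 0, 2.1, 5.9) == pytest.approx(
            0.2820948, abs=1e-7)
        assert real_spherical_harmonic(1, 0, 0.0, 2.0) == pytest.approx(
            0.4886025, abs=1e-7)

    @pytest.mark.parametrize("l,m", [(1, 1), (2, -1), (3, 2), (6, -6), (8, 5)])
    def test_matches_legendre_closed_form(self, l, m):
        # independent route: scipy lpmv with the Condon–Shortley phase
        # stripped, times the explicit normalization
        theta, phi = 0.9, 2.4
        mm = abs(m)
        P = (-1) ** mm * lpmv(mm, l, np.cos(theta))
        S = slm_normalization(l, mm)
        if m > 0:
            ref = np.sqrt(2) * S * np.cos(m * phi) * P
        elif m < 0:
            ref = np.sqrt(2) * S * np.sin(mm * phi) * P
        else:
            ref = S * P
        got = real_spherical_harmonic(l, m, theta, phi)
        assert got == pytest.approx(ref, abs=1e-12)

    def test_orthonormality_under_quadrature(self):
        # Gram matrix of all basis functions with l ≤ 6 on a B = 32 grid
        B, L = 32, 6
        tt, pp = grid(B)
        w = np.repeat(quadrature_weights(B)[:, None], 2 * B, axis=1).ravel()
        Y = np.array([real_spherical_harmonic(l, m, tt, pp).ravel()
                      for l in range(L + 1) for m in range(-l, l + 1)])
        G = (Y * w) @ Y.T
        assert np.abs(G - np.eye(len(G))).max() < 1e-9

    def test_high_degree_values_stay_finite(self):
        tt, pp = grid(16)
        v = real_spherical_harmonic(63, 63, tt, pp)
        assert np.all(np.isfinite(v))


class TestDepthMap:
    def test_single_sphere_gives_constant_one(self, single_atom):
        dm = build_depth_map(normalize_pose(single_atom), bandwidth=8)
        np.testing.assert_allclose(dm.values, 1.0, atol=1e-12)

    def test_rays_missing_all_atoms_give_zero(self):
        # thin dumbbell along x: polar (±z) rays pass far from both spheres
        atoms = (Atom("C", np.array([2.0, 0.0, 0.0]), 0.5),
                 Atom("C", np.array([-2.0, 0.0, 0.0]), 0.5))
        mol = normalize_pose(Molecule(id="m", atoms=atoms))
        dm = build_depth_map(mol, bandwidth=16)
        assert (dm.values[0] == 0.0).all()   # θ ≈ 0 rows miss everything
        assert (dm.values[-1] == 0.0).all()  # θ ≈ π likewise
        assert dm.values.max() > 0.9

    def test_dumbbell_polar_exceeds_equatorial(self, dumbbell):
        dm = build_depth_map(dumbbell, bandwidth=16)
        polar = dm.values[0, 0]
        equatorial = dm.values[len(dm.values) // 2, 0]
        assert polar > equatorial

    def test_ray_agrees_with_analytic_intersection(self, dumbbell):
        # closed-form oracle for the farthest ray–sphere hit along +z
        dm = build_depth_map(dumbbell, bandwidth=16)
        c = dumbbell.atoms[0].coords[2]
        r = dumbbell.atoms[0].vdw_radius
        theta0 = dm.thetas[0]
        uc = np.cos(theta0) * c
        expected = uc + np.sqrt(uc**2 - c**2 + r**2)
        assert dm.values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_voxel_mode_agrees_with_ray_mode(self, dumbbell):
        G = 64
        d_ray = build_depth_map(dumbbell, bandwidth=16, mode="ray")
        d_vox = build_depth_map(dumbbell, bandwidth=16, mode="voxel",
                                voxel_resolution=G)
        assert np.abs(d_ray.values - d_vox.values).max() <= 2.0 / G

    def test_unnormalized_molecule_rejected(self, single_atom):
        with pytest.raises(ValueError, match="normalized"):
            build_depth_map(single_atom, bandwidth=8)

    def test_inverse_variant_complements_extent(self, dumbbell):
        d1 = build_depth_map(dumbbell, bandwidth=8, depth_variant="extent")
        d2 = build_depth_map(dumbbell, bandwidth=8, depth_variant="inverse")
        np.testing.assert_allclose(d1.values + d2.values, 1.0, atol=1e-12)


class TestCoefficients:
    def test_recovers_pure_harmonic(self):
        # f = y_2^1 fed through the transform returns the unit coefficient
        B = 32
        tt, pp = grid(B)
        f = real_spherical_harmonic(2, 1, tt, pp)
        co = sh_coefficients(f, l_max=8)
        assert co[(2, 1)] == pytest.approx(1.0, abs=1e-3)
        others = [abs(v) for k, v in co.c.items() if k != (2, 1)]
        assert max(others) <= 1e-3

    def test_constant_map_projects_onto_y00(self):
        B = 32
        dm = DepthMap(values=np.ones((2 * B, 2 * B)), bandwidth=B)
        co = sh_coefficients(dm, l_max=8)
        assert co[(0, 0)] == pytest.approx(np.sqrt(4 * np.pi), abs=1e-3)
        assert max(abs(v) for k, v in co.c.items() if k != (0, 0)) <= 1e-3

    def test_zero_map_gives_zero_coefficients(self):
        dm = DepthMap(values=np.zeros((16, 16)), bandwidth=8)
        co = sh_coefficients(dm, l_max=4)
        assert all(v == 0.0 for v in co.c.values())

    def test_aliasing_rejected(self):
        dm = DepthMap(values=np.ones((16, 16)), bandwidth=8)
        with pytest.raises(ValueError, match="alias"):
            sh_coefficients(dm, l_max=8)

    def test_parseval_on_bandlimited_map(self):
        # energy of a band-limited function equals the sum of squared
        # coefficients (quadrature is exact for these degrees)
        B = 16
        tt, pp = grid(B)
        f = (0.4 * real_spherical_harmonic(0, 0, tt, pp)
             + 0.3 * real_spherical_harmonic(3, -2, tt, pp)
             + 0.2 * real_spherical_harmonic(5, 4, tt, pp))
        co = sh_coefficients(f, l_max=B - 1)
        energy_coeff = sum(v**2 for v in co.c.values())
        w = quadrature_weights(B)[:, None]
        energy_quad = float(np.sum(f**2 * w))
        assert energy_coeff == pytest.approx(energy_quad, rel=1e-2)


class TestInvariantVector:
    def test_pythagorean_norms(self):
        c = {(l, m): 0.0 for l in range(3) for m in range(-l, l + 1)}
        c[(1, -1)] = 3.0
        c[(1, 0)] = 4.0
        v = degree_norms(SHCoefficients(l_max=2, c=c))
        assert v.norms[1] == pytest.approx(5.0)
        assert v.norms[0] == 0.0 and v.norms[2] == 0.0

    def test_zero_coefficients_zero_norms(self):
        c = {(l, m): 0.0 for l in range(4) for m in range(-l, l + 1)}
        v = degree_norms(SHCoefficients(l_max=3, c=c))
        assert np.all(v.norms == 0.0)


class TestDescriptorPipeline:
    CFG = DescriptorConfig(bandwidth=32, l_max=15)

    def test_deterministic(self):
        mol = make_toy_molecule("compact", 10, 0.1, seed=5)
        v1 = compute_sh_descriptor(mol, self.CFG).norms
        v2 = compute_sh_descriptor(mol, self.CFG).norms
        np.testing.assert_array_equal(v1, v2)

    def test_single_atom_is_spherically_symmetric(self, single_atom):
        v = compute_sh_descriptor(single_atom, self.CFG).norms
        assert v[0] > 0
        assert np.all(v[1:] / v[0] < 1e-2)

    def test_translation_invariance(self):
        mol = make_toy_molecule("elongated", 8, 0.05, seed=2)
        shifted = Molecule(id="s", atoms=tuple(
            Atom(a.element, a.coords + np.array([5.0, -3.0, 2.0]),
                 a.vdw_radius) for a in mol.atoms))
        v1 = compute_sh_descriptor(mol, self.CFG).norms
        v2 = compute_sh_descriptor(shifted, self.CFG).norms
        np.testing.assert_allclose(v1, v2, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(100 + seed)
        mol = make_toy_molecule("compact", 12, 0.1, seed=seed)
        rot = rotate_molecule(mol, random_rotation(rng))
        v1 = compute_sh_descriptor(mol, self.CFG).norms
        v2 = compute_sh_descriptor(rot, self.CFG).norms
        rel = np.linalg.norm(v1 - v2) / np.linalg.norm(v1)
        assert rel < 1e-2

    def test_descriptor_length_is_lmax_plus_one(self):
        mol = make_toy_molecule("compact", 6, 0.1, seed=1)
        v = compute_sh_descriptor(mol, DescriptorConfig(bandwidth=16, l_max=9))
        assert len(v.norms) == 10
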