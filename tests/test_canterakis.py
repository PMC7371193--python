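"""Cayley-Klein rotations, moment-space rotation law and normalization."""

import numpy as np
import pytest

from zershape.basis import count_indices, nl_pairs
from zershape.canterakis import (
    CayleyKleinRotation,
    DegenerateNormalizationError,
    cn_invariant,
    composite_cn,
    random_rotation,
    rotate_moments,
    rotation_matrix,
    solve_normalization,
    wigner_block,
)
from zershape.volume import rasterize, unit_sphere_frame
from zershape.zernike import MomentSet, compute_moments, descriptor_3dzd, modify_moments

from conftest import moments_of


def random_moments(order_max, seed=0):
    """Random moment set with the conjugation symmetry of a real density."""
    rng = np.random.default_rng(seed)
    values = rng.normal(size=count_indices(order_max)) * (
        1.0 + 1j * rng.normal(size=count_indices(order_max)))
    mom = MomentSet(order_max, values)
    pos = 0
    for n, l in nl_pairs(order_max):
        mom.values[pos] = mom.values[pos].real  # m = 0 must be real
        pos += l + 1
    return mom


class TestRotationMatrix:
    def test_identity(self):
        np.testing.assert_allclose(
            rotation_matrix(CayleyKleinRotation.identity()), np.eye(3), atol=1e-14)

    def test_b_equals_one_is_a_half_turn(self):
        # (a, b) = (0, 1): trace -1 (180 degree rotation), proper
        R = rotation_matrix(CayleyKleinRotation(0.0j, 1.0 + 0.0j))
        assert np.trace(R) == pytest.approx(-1.0)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_random_rotation_is_proper_orthogonal(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            R = rotation_matrix(random_rotation(rng))
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0)

    def test_unnormalized_parameters_rejected(self):
        with pytest.raises(ValueError):
            CayleyKleinRotation(1.0 + 0j, 1.0 + 0j)


class TestRotateMoments:
    def test_identity_rotation_is_noop(self):
        mom = random_moments(10)
        out = rotate_moments(mom, CayleyKleinRotation.identity())
        np.testing.assert_allclose(out.values, mom.values, atol=1e-12)

    def test_norms_preserved_per_nl(self):
        mom = random_moments(12, seed=3)
        rot = random_rotation(np.random.default_rng(4))
        out = rotate_moments(mom, rot)
        for n, l in nl_pairs(12):
            assert out.norm_nl(n, l) == pytest.approx(mom.norm_nl(n, l), abs=1e-10)

    def test_composition_consistency(self):
        mom = random_moments(8, seed=7)
        rng = np.random.default_rng(8)
        r1, r2 = random_rotation(rng), random_rotation(rng)
        twice = rotate_moments(rotate_moments(mom, r1), r2)
        once = rotate_moments(mom, r1.compose(r2))
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)
        # and the real-space matrices compose the same way
        np.testing.assert_allclose(
            rotation_matrix(r1.compose(r2)),
            rotation_matrix(r2) @ rotation_matrix(r1), atol=1e-12)

    def test_five_term_expansion_for_222(self):
        """The degree-2 rotated moment equals its explicit five-term
        expansion a^4 w222 - a^3 b* w221 + a^2 b*^2 w220 + a b*^3 w221*
        + b*^4 w222* in the modified gauge, for random moments and
        rotations."""
        mom = random_moments(6, seed=11)
        modified = modify_moments(mom)
        rng = np.random.default_rng(12)
        for _ in range(10):
            rot = random_rotation(rng)
            a, bc = rot.a, np.conj(rot.b)
            w = {m: modified.get(2, 2, m) for m in (0, 1, 2)}
            expected = (a**4 * w[2] - a**3 * bc * w[1] + a**2 * bc**2 * w[0]
                        + a * bc**3 * np.conj(w[1]) + bc**4 * np.conj(w[2]))
            rotated = modify_moments(rotate_moments(mom, rot))
            assert rotated.get(2, 2, 2) == pytest.approx(expected, abs=1e-12)

    def test_wigner_blocks_unitary(self):
        rot = random_rotation(np.random.default_rng(13))
        for l in (1, 5, 20):
            M = wigner_block(l, rot)
            np.testing.assert_allclose(M @ M.conj().T, np.eye(2 * l + 1),
                                       atol=1e-11)

    def test_conjugation_symmetry_preserved(self):
        """Rotating a real-density moment set keeps m=0 entries real (the
        full symmetry is implied by unitarity plus this check)."""
        mom = random_moments(10, seed=14)
        out = rotate_moments(mom, random_rotation(np.random.default_rng(15)))
        pos = 0
        for n, l in nl_pairs(10):
            assert abs(out.values[pos].imag) < 1e-10
            pos += l + 1


class TestRealSpaceOracle:
    def test_moment_rotation_matches_rotated_cloud(self, blob_atoms, blob_moments):
        """Central commutativity oracle: rotating in moment space equals
        recomputing moments from the rotated point cloud."""
        rng = np.random.default_rng(21)
        rot = random_rotation(rng)
        R = rotation_matrix(rot)
        rotated_atoms = blob_atoms.transformed(rotation=R)
        vol = rasterize(rotated_atoms, 0.5)
        mom_direct = compute_moments(vol, unit_sphere_frame(rotated_atoms), 20)
        mom_pred = rotate_moments(blob_moments, rot)
        rel = (np.linalg.norm(mom_pred.values - mom_direct.values)
               / np.linalg.norm(blob_moments.values))
        assert rel < 0.02

    def test_3dzd_rotation_invariance(self, blob_atoms, blob_moments):
        rng = np.random.default_rng(22)
        R = rotation_matrix(random_rotation(rng))
        mom_rot = moments_of(blob_atoms.transformed(rotation=R))
        d0, d1 = descriptor_3dzd(blob_moments), descriptor_3dzd(mom_rot)
        assert np.linalg.norm(d0 - d1) / np.linalg.norm(d0) < 0.02


class TestSolveNormalization:
    def test_generic_moments_give_eight_solutions(self):
        modified = modify_moments(random_moments(6, seed=31))
        sols = solve_normalization(modified, 2, (2, 2))
        assert len(sols.rotations) == 8
        scale = np.abs(modified.vector_nl(2, 2)).max()
        assert sols.residuals.max() < 1e-8 * scale

    def test_odd_order_constraint_gives_twelve_solutions(self):
        modified = modify_moments(random_moments(6, seed=32))
        sols = solve_normalization(modified, 3, (3, 3))
        assert len(sols.rotations) == 12  # 6 roots x 2 gauge solutions
        scale = np.abs(modified.vector_nl(3, 3)).max()
        assert sols.residuals.max() < 1e-8 * scale

    def test_t_zero_root_when_constraint_already_satisfied(self):
        mom = random_moments(6, seed=33)
        pos = 0
        for n, l in nl_pairs(6):
            if (n, l) == (2, 2):
                mom.values[pos + 2] = 0.0  # Omega_222 = 0
            pos += l + 1
        modified = modify_moments(mom)
        # constant coefficient of the quartic vanishes -> t = 0 among roots;
        # the corresponding rotation is about z only (|b| in {0, 1} branch)
        sols = solve_normalization(modified, 2, (2, 2))
        scale = np.abs(modified.vector_nl(2, 2)).max()
        assert sols.residuals.max() < 1e-8 * scale

    def test_residuals_by_back_substitution(self):
        """Independent check: applying each returned rotation via the full
        moment-rotation law drives the constrained moment below 1e-8 of
        scale."""
        mom = random_moments(8, seed=34)
        modified = modify_moments(mom)
        sols = solve_normalization(modified, 4, (2, 2))
        scale = np.abs(modified.vector_nl(4, 2)).max()
        for rot in sols.rotations:
            rotated = modify_moments(rotate_moments(mom, rot))
            assert abs(rotated.get(4, 2, 2)) < 1e-8 * scale

    def test_gauge_re_b_positive(self):
        modified = modify_moments(random_moments(6, seed=35))
        sols = solve_normalization(modified, 2, (2, 2))
        for rot in sols.rotations:
            assert rot.b.real > 0

    def test_degenerate_all_zero_constraint_raises(self):
        mom = random_moments(6, seed=36)
        pos = 0
        for n, l in nl_pairs(6):
            if (n, l) == (2, 2):
                mom.values[pos:pos + 3] = 0.0
            pos += l + 1
        with pytest.raises(DegenerateNormalizationError):
            solve_normalization(modify_moments(mom), 2, (2, 2))


class TestCNInvariant:
    def test_length_946_at_order_20(self, blob_moments):
        cn = cn_invariant(blob_moments, 2)
        assert cn.values.shape == (946,)
        assert np.all(cn.values >= 0)

    def test_composite_length_3784(self, blob_moments):
        assert composite_cn(blob_moments).shape == (3784,)

    def test_single_order_composite(self, blob_moments):
        vec = composite_cn(blob_moments, orders=[2])
        np.testing.assert_array_equal(vec, cn_invariant(blob_moments, 2).values)

    @pytest.mark.parametrize("order", [2, 3, 4, 5])
    def test_rotation_invariance(self, blob_atoms, blob_moments, order):
        rng = np.random.default_rng(40 + order)
        R = rotation_matrix(random_rotation(rng))
        mom_rot = moments_of(blob_atoms.transformed(rotation=R))
        cn0 = cn_invariant(blob_moments, order).values
        cn1 = cn_invariant(mom_rot, order).values
        assert np.linalg.norm(cn0 - cn1) / np.linalg.norm(cn0) < 0.02

    def test_pure_dc_moments_are_rotation_inert(self):
        values = np.zeros(count_indices(6), dtype=complex)
        values[0] = 2.5
        mom = MomentSet(6, values)
        cn = cn_invariant(mom, 2)  # degenerate: falls back to magnitudes
        assert cn.degenerate
        assert cn.values[0] == pytest.approx(2.5)
        assert np.all(cn.values[1:] == 0)

    def test_standard_position_is_a_fixed_point(self, blob_moments):
        """Re-normalizing an already-normalized moment set changes the CN
        magnitudes below tolerance."""
        modified = modify_moments(blob_moments)
        sols = solve_normalization(modified, 2, (2, 2))
        standard = rotate_moments(blob_moments, sols.rotations[0])
        cn_once = cn_invariant(blob_moments, 2).values
        cn_twice = cn_invariant(standard, 2).values
        assert np.linalg.norm(cn_once - cn_twice) / np.linalg.norm(cn_once) < 1e-6
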