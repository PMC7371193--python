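"""Moment-space structure superposition via Canterakis normalizations.

Alignment needs no atom correspondences: each structure is rotated to the
standard position induced by a Canterakis normalization, and structures
sharing a standard position are superposed by construction.  For a pair (or
a set) of structures, all candidate normalizations (orders 2-5, every
polynomial solution) are enumerated and the combination minimizing the
relative moment distance is kept, so the number of alignment operations
grows linearly with the number of structures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .canterakis import (
    CayleyKleinRotation,
    DegenerateNormalizationError,
    rotate_moments,
    rotation_matrix,
    solve_normalization,
    constraint_for_order,
)
from .descriptors import DescriptorConfig
from .structure import RepresentativeAtomSet
from .volume import rasterize, unit_sphere_frame
from .zernike import MomentSet, compute_moments, modify_moments

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentDescriptor",
    "RigidTransform",
    "alignment_descriptor",
    "moment_pair_distance",
    "optimal_normalization",
    "superpose",
    "ALIGNMENT_ORDER_MAX",
]

#: expansion order of the alignment descriptor; low orders suffice for
#: orienting a density and keep candidate enumeration cheap
ALIGNMENT_ORDER_MAX = 6


@dataclass
class AlignmentDescriptor:
    """Complete moments to order 6 plus the center of mass.

    The center of mass is carried separately because the unit-ball scaling
    discards absolute position and size.
    """

    moments: MomentSet
    center_of_mass: np.ndarray

    def __post_init__(self):
        self.center_of_mass = np.asarray(self.center_of_mass, dtype=float)
        if self.moments.order_max != ALIGNMENT_ORDER_MAX:
            raise ValueError(f"alignment moments must be order {ALIGNMENT_ORDER_MAX}")
        if not np.all(np.isfinite(self.center_of_mass)):
            raise ValueError("center of mass must be finite")


@dataclass
class RigidTransform:
    """x -> rotation @ x + translation, with a proper orthogonal rotation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if np.abs(self.rotation @ self.rotation.T - np.eye(3)).max() > 1e-6:
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation is improper")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        out = np.eye(4)
        out[:3, :3] = self.rotation
        out[:3, 3] = self.translation
        return out

    def to_json(self) -> str:
        return json.dumps({"matrix": self.matrix().tolist()})


def alignment_descriptor(atoms: RepresentativeAtomSet,
                         config: DescriptorConfig | None = None) -> AlignmentDescriptor:
    """Order-6 moments in the structure's unit-sphere frame, plus its COM."""
    grid_width = config.grid_width if config is not None else None
    volume = rasterize(atoms, grid_width)
    frame = unit_sphere_frame(atoms)
    moments = compute_moments(volume, frame, ALIGNMENT_ORDER_MAX)
    return AlignmentDescriptor(moments=moments, center_of_mass=atoms.center_of_mass())


def moment_pair_distance(m1: MomentSet, m2: MomentSet) -> float:
    """Relative moment difference summed over the full index lattice.

    ``sum_nlm |O1 - O2| / (|O1| + |O2| + 1)`` including negative m (whose
    terms duplicate the positive-m ones by conjugation symmetry).  Zero iff
    the moment sets coincide; symmetric in its arguments.
    """
    if m1.order_max != m2.order_max:
        raise ValueError("order mismatch between moment sets")
    total = 0.0
    pos = 0
    for n in range(m1.order_max + 1):
        for l in range(n % 2, n + 1, 2):
            v1 = m1.values[pos:pos + l + 1]
            v2 = m2.values[pos:pos + l + 1]
            terms = np.abs(v1 - v2) / (np.abs(v1) + np.abs(v2) + 1.0)
            # m = 0 counts once, each m > 0 twice (for -m)
            total += terms[0] + 2.0 * terms[1:].sum()
            pos += l + 1
    return float(total)


def candidate_normalizations(moments: MomentSet, orders=(2, 3, 4, 5)) -> dict:
    """All normalization rotations per order; degenerate orders are skipped
    (falling back to whatever orders remain).

    The residual z-phase is fixed through a degree-1 moment whose choice is
    immaterial for descriptors but matters here; near-symmetric shapes can
    have all degree-1 vectors at noise level, so solutions for every
    available second-constraint order are enumerated ("testing all
    possibilities") and near-duplicates merged.
    """
    modified = modify_moments(moments)
    out = {}
    second_orders = [n2 for n2 in (3, 5) if n2 <= moments.order_max] or [None]
    for n in orders:
        if n > moments.order_max:
            continue
        rotations = []
        for n2 in second_orders:
            try:
                sols = solve_normalization(modified, n, constraint_for_order(n),
                                           second_order=n2)
            except DegenerateNormalizationError:
                logger.info("order-%d normalization degenerate; skipped", n)
                break
            for rot in sols.rotations:
                # (a, b) and (-a, -b) induce the same rotation
                if all(min(abs(rot.a - r.a) + abs(rot.b - r.b),
                           abs(rot.a + r.a) + abs(rot.b + r.b)) > 1e-9
                       for r in rotations):
                    rotations.append(rot)
        if rotations:
            out[n] = rotations
    return out


def optimal_normalization(s1: AlignmentDescriptor, s2: AlignmentDescriptor,
                          orders=(2, 3, 4, 5)):
    """Pick the pair of standard-position rotations minimizing the moment
    distance.

    Every solution of every normalization order of each structure is a
    candidate; candidates are compared within the same order.  Ties are
    broken toward the lowest order and first-found solution.  Returns
    ``(rot1, rot2, distance, order)``.
    """
    cands1 = candidate_normalizations(s1.moments, orders)
    cands2 = candidate_normalizations(s2.moments, orders)
    best = None
    for n in sorted(set(cands1) & set(cands2)):
        rotated1 = [(r, rotate_moments(s1.moments, r)) for r in cands1[n]]
        rotated2 = [(r, rotate_moments(s2.moments, r)) for r in cands2[n]]
        for r1, m1 in rotated1:
            for r2, m2 in rotated2:
                d = moment_pair_distance(m1, m2)
                if best is None or d < best[2] - 1e-12:
                    best = (r1, r2, d, n)
    if best is None:
        # all normalizations degenerate for at least one structure: fall
        # back to identity (arbitrary common frame), flagged
        logger.warning("all candidate normalizations degenerate; identity fallback")
        ident = CayleyKleinRotation.identity()
        return ident, ident, moment_pair_distance(s1.moments, s2.moments), 0
    return best


def _transform_between(rot_i: CayleyKleinRotation, com_i: np.ndarray,
                       rot_ref: CayleyKleinRotation, com_ref: np.ndarray) -> RigidTransform:
    """Map structure i onto the frame of the reference structure.

    Both objects are first rotated (about their centers of mass) to the
    shared standard position; the reference rotation is then undone and the
    centers of mass are matched.
    """
    Ri = rotation_matrix(rot_i)
    Rr = rotation_matrix(rot_ref)
    rot = Rr.T @ Ri
    return RigidTransform(rotation=rot, translation=com_ref - rot @ com_i)


def superpose(structures: list[AlignmentDescriptor], target: int = 0,
              orders=(2, 3, 4, 5)) -> list[RigidTransform]:
    """Align an arbitrary number of structures in linear time.

    Each structure is normalized to the standard position independently; per
    normalization order the candidate combination minimizing the sum of
    moment distances to the target's candidate is selected, and all
    structures are then expressed in the target's original frame (target
    receives the identity transform).
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    ref = structures[target]
    cands_ref = candidate_normalizations(ref.moments, orders)
    others = [s for k, s in enumerate(structures) if k != target]
    cands_oth = [candidate_normalizations(s.moments, orders) for s in others]

    best = None  # (total_d, rot_ref, rotations_for_others, order)
    for n in sorted(cands_ref):
        if not all(n in c for c in cands_oth):
            continue
        rot_oth = [[(r, rotate_moments(s.moments, r)) for r in c[n]]
                   for s, c in zip(others, cands_oth)]
        for r_ref in cands_ref[n]:
            m_ref = rotate_moments(ref.moments, r_ref)
            total, picks = 0.0, []
            for cand_list in rot_oth:
                d_best, r_best = None, None
                for r, m in cand_list:
                    d = moment_pair_distance(m_ref, m)
                    if d_best is None or d < d_best - 1e-12:
                        d_best, r_best = d, r
                total += d_best
                picks.append(r_best)
            if best is None or total < best[0] - 1e-12:
                best = (total, r_ref, picks, n)

    if best is None:
        logger.warning("superposition fell back to identity normalization")
        ident = CayleyKleinRotation.identity()
        best = (np.inf, ident, [ident] * len(others), 0)

    _, r_ref, picks, order = best
    logger.info("superpose: normalization order %d selected", order)
    transforms, k = [], 0
    for idx in range(len(structures)):
        if idx == target:
            transforms.append(RigidTransform(np.eye(3), np.zeros(3)))
        else:
            transforms.append(
                _transform_between(picks[k], structures[idx].center_of_mass,
                                   r_ref, ref.center_of_mass)
            )
            k += 1
    return transforms
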