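"""Canterakis-norm machinery: moment-space rotations and normalization.

A 3D rotation is carried by its Cayley-Klein parameters (a, b), two complex
numbers with |a|^2 + |b|^2 = 1 (the top row of an SU(2) matrix).  In the
modified-moment gauge the rotation of a degree-l coefficient vector is the
coefficient map of the polynomial substitution

    sum_mu  W_l[m, mu] Omega^_nl,mu,
    W_l[m, mu] = [zeta^(l+m)] (a zeta + b)^(l+mu) (-b* zeta + a*)^(l-mu)

whose top row (m = l) gives the classical five-term expansion for l = 2.
Driving a chosen moment (Omega^R)_{n,l,l} to zero therefore reduces to a
degree-2l complex polynomial in t = a/b*; fixing the residual z-rotation by
Im{(Omega^R)_{n',1,1}} = 0 adds a real quadratic in s = Im{b}/Re{b}.  All
solutions are enumerated; their rotated-moment magnitudes, averaged, are the
CN rotation invariants.

Sign conventions: the real-space matrix returned by :func:`rotation_matrix`
is the rotation actually induced on a density by the moment transformation
above (verified against recomputing moments from rotated point clouds).  It
agrees with the classical Cayley-Klein matrix up to a fixed relabelling of
the x/y axes (a change of axis convention, not of the group structure);
identity, trace and determinant are unaffected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import lgamma

import numpy as np

from .basis import nl_pairs
from .zernike import ModifiedMomentSet, MomentSet, modify_moments

logger = logging.getLogger(__name__)

__all__ = [
    "CayleyKleinRotation",
    "NormalizationSolutionSet",
    "CNInvariantVector",
    "DegenerateNormalizationError",
    "rotation_matrix",
    "wigner_block",
    "rotate_moments",
    "solve_normalization",
    "cn_invariant",
    "composite_cn",
    "random_rotation",
]

_UNITY_TOL = 1e-9


class DegenerateNormalizationError(RuntimeError):
    """All coefficients of the normalization polynomial vanish (the shape is
    rotationally degenerate for the chosen constraint)."""


@dataclass(frozen=True)
class CayleyKleinRotation:
    """(a, b) pair encoding an element of SO(3) via SU(2)."""

    a: complex
    b: complex

    def __post_init__(self):
        norm = abs(self.a) ** 2 + abs(self.b) ** 2
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"|a|^2 + |b|^2 = {norm} is not 1")
        # renormalize residual rounding
        s = 1.0 / np.sqrt(norm)
        object.__setattr__(self, "a", complex(self.a) * s)
        object.__setattr__(self, "b", complex(self.b) * s)

    @classmethod
    def identity(cls) -> "CayleyKleinRotation":
        return cls(1.0 + 0.0j, 0.0j)

    def inverse(self) -> "CayleyKleinRotation":
        return CayleyKleinRotation(np.conj(self.a), -self.b)

    def compose(self, then: "CayleyKleinRotation") -> "CayleyKleinRotation":
        """Rotation equivalent to applying ``self`` first, ``then`` second."""
        u1 = np.array([[self.a, self.b], [-np.conj(self.b), np.conj(self.a)]])
        u2 = np.array([[then.a, then.b], [-np.conj(then.b), np.conj(then.a)]])
        u = u1 @ u2
        return CayleyKleinRotation(u[0, 0], u[0, 1])


def random_rotation(rng) -> CayleyKleinRotation:
    """Haar-uniform random rotation (4D Gaussian on the unit quaternion)."""
    v = rng.normal(size=4)
    v /= np.linalg.norm(v)
    return CayleyKleinRotation(complex(v[0], v[1]), complex(v[2], v[3]))


def _classical_matrix(a: complex, b: complex) -> np.ndarray:
    ab = a * b
    abc = a * np.conj(b)
    s2 = a * a + b * b
    d2 = a * a - b * b
    return np.array([
        [s2.real, -d2.imag, 2 * ab.imag],
        [s2.imag, d2.real, -2 * ab.real],
        [2 * abc.imag, 2 * abc.real, abs(a) ** 2 - abs(b) ** 2],
    ])


_AXIS_PERM = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])


def rotation_matrix(rot: CayleyKleinRotation) -> np.ndarray:
    """Proper rotation matrix induced on real-space coordinates.

    ``rotate_moments(compute_moments(f), rot)`` equals (to quadrature
    accuracy) the moments of the density ``f`` actively rotated by this
    matrix.  (1, 0) maps to the identity.
    """
    norm = abs(rot.a) ** 2 + abs(rot.b) ** 2
    if abs(norm - 1.0) > _UNITY_TOL:
        raise ValueError("Cayley-Klein parameters are not normalized")
    return _AXIS_PERM @ _classical_matrix(rot.a, rot.b).T @ _AXIS_PERM.T


def _log_c(l: int) -> np.ndarray:
    """log c_lm over m = -l..l, up to the common (2l+1)/l! factor."""
    return np.array([0.5 * (lgamma(l + m + 1) + lgamma(l - m + 1))
                     for m in range(-l, l + 1)])


def _w_block(l: int, a: complex, b: complex) -> np.ndarray:
    """Rotation matrix on modified-moment vectors (columns mu, rows m)."""
    W = np.zeros((2 * l + 1, 2 * l + 1), dtype=complex)
    p1 = np.array([b, a], dtype=complex)
    p2 = np.array([np.conj(a), -np.conj(b)], dtype=complex)
    for col, mu in enumerate(range(-l, l + 1)):
        poly = np.array([1.0 + 0.0j])
        for _ in range(l + mu):
            poly = np.convolve(poly, p1)
        for _ in range(l - mu):
            poly = np.convolve(poly, p2)
        W[:, col] = poly
    return W


def wigner_block(l: int, rot: CayleyKleinRotation) -> np.ndarray:
    """Unitary (2l+1)x(2l+1) rotation matrix on unmodified moment vectors."""
    lc = _log_c(l)
    return np.exp(lc[:, None] - lc[None, :]) * _w_block(l, rot.a, rot.b)


def rotate_moments(moments: MomentSet, rot: CayleyKleinRotation) -> MomentSet:
    """Rotate a full moment set in moment space.

    Per-(n, l) vector norms are preserved exactly (the blocks are unitary);
    composing two rotations equals rotating by the composed rotation.
    """
    blocks = {l: wigner_block(l, rot) for l in
              sorted({l for _, l in nl_pairs(moments.order_max)})}
    out = np.empty_like(moments.values)
    pos = 0
    for n, l in nl_pairs(moments.order_max):
        v = moments.vector_nl(n, l)
        w = blocks[l] @ v
        out[pos:pos + l + 1] = w[l:]  # keep m >= 0
        pos += l + 1
    return MomentSet(moments.order_max, out, moments.frame)


@dataclass
class NormalizationSolutionSet:
    """All rotations driving the constrained moment to zero."""

    rotations: list
    constrained_index: tuple
    residuals: np.ndarray
    degenerate: bool = False


def _second_constraint_order(modified: ModifiedMomentSet) -> int | None:
    """Odd order n' whose (n', 1) vector is most informative for fixing the
    in-plane degree of freedom."""
    best, best_norm = None, 0.0
    for n2 in (3, 5, 7, 1):
        if n2 > modified.order_max:
            continue
        norm = modified.norm_nl(n2, 1)
        if norm > best_norm:
            best, best_norm = n2, norm
    return best


def solve_normalization(modified: ModifiedMomentSet, n: int,
                        constraint: tuple[int, int],
                        second_order: int | None = None) -> NormalizationSolutionSet:
    """Solve the order-n normalization system.

    ``constraint = (l, m)`` with m = l (the package normalizes against the
    extremal-m moment, (2, 2) for even orders and (3, 3) for odd ones).
    Roots t of the degree-2l polynomial with coefficients
    ``(-1)^(l-mu) Omega^_{n,l,mu}`` fix two degrees of freedom; each t admits
    two values of s = Im{b}/Re{b} from the quadratic second constraint
    ``Im{(Omega^R)_{n',1,1}} = 0``.  Re{b} > 0 holds for every returned
    solution by construction of the recovery formulas.
    """
    l, m = constraint
    if m != l:
        raise ValueError("only extremal constraints (l, l) are supported")
    if (n - l) % 2 != 0 or l > n:
        raise ValueError(f"constraint l={l} invalid for order n={n}")

    v = modified.vector_nl(n, l)  # mu = -l .. l
    signs = np.array([(-1.0) ** (l - mu) for mu in range(-l, l + 1)])
    coeffs_asc = signs * v  # coefficient of t^(l+mu)
    scale = float(np.abs(modified.values).max()) or 1.0
    mag = np.abs(coeffs_asc)
    if mag.max() < 1e-9 * scale:
        raise DegenerateNormalizationError(
            f"normalization polynomial vanishes for order {n}, constraint {constraint}"
        )

    # deflate numerically-zero leading coefficients; each trimmed
    # coefficient is a root at infinity, i.e. b = 0: a pure z-rotation that
    # already satisfies the first constraint (the input is in standard
    # position for it).  These sit on the gauge boundary Re{b} = 0 and are
    # restored explicitly below.
    desc = coeffs_asc[::-1].copy()
    lead_tol = 1e-12 * mag.max()
    first = int(np.argmax(np.abs(desc) > lead_tol))
    desc = desc[first:]
    if desc.size < 2:
        raise DegenerateNormalizationError(
            f"normalization polynomial is constant for order {n}"
        )
    roots_t = np.roots(desc)

    if second_order is not None and second_order <= modified.order_max:
        n2 = second_order
    else:
        n2 = _second_constraint_order(modified)
    rotations, residuals = [], []
    for _ in range(first):
        # z-rotation solutions: a = e^{i theta/2}, b = 0; the second
        # constraint Im{a^2 * Omega^_{n2,1,1}} = 0 fixes theta two ways
        if n2 is not None and abs(modified.get(n2, 1, 1)) > 1e-13 * scale:
            theta = -np.angle(modified.get(n2, 1, 1))
        else:
            theta = 0.0
        for th in (theta, theta + np.pi):
            rot = CayleyKleinRotation(np.exp(0.5j * th), 0.0j)
            W = _w_block(l, rot.a, rot.b)
            residuals.append(abs(W[2 * l] @ v))
            rotations.append(rot)
    for t in roots_t:
        if n2 is not None:
            om11 = modified.get(n2, 1, 1)
            om10 = modified.get(n2, 1, 0)
            K = t * t * om11 - t * om10 - np.conj(om11)
        else:
            K = 0.0
        boundary = False
        if abs(K) < 1e-13 * scale:
            s_values = [0.0]  # second constraint vacuous; z-phase free
        elif abs(K.imag) < 1e-13 * abs(K):
            # quadratic degenerates to s * (s Im{K} + 2 Re{K}) = 0: one root
            # at s = 0 and one at infinity, i.e. Re{b} = 0 (gauge boundary,
            # kept explicitly)
            s_values = [0.0]
            boundary = True
        else:
            s_values = [(-K.real + abs(K)) / K.imag, (-K.real - abs(K)) / K.imag]
        candidates = []
        for s in s_values:
            rho = 1.0 / np.sqrt((1.0 + abs(t) ** 2) * (1.0 + s * s))
            candidates.append(rho * complex(1.0, s))
        if boundary:
            candidates.append(1j / np.sqrt(1.0 + abs(t) ** 2))
        for b in candidates:
            a = t * np.conj(b)
            rot = CayleyKleinRotation(a, b)
            W = _w_block(l, rot.a, rot.b)
            residuals.append(abs(W[2 * l] @ v))
            rotations.append(rot)

    return NormalizationSolutionSet(
        rotations=rotations,
        constrained_index=(n, l, l),
        residuals=np.array(residuals),
    )


@dataclass
class CNInvariantVector:
    """Rotation-invariant moment magnitudes from one normalization order."""

    order: int
    values: np.ndarray
    degenerate: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def constraint_for_order(n: int) -> tuple[int, int]:
    """(2, 2) for even normalization orders, (3, 3) for odd ones."""
    return (2, 2) if n % 2 == 0 else (3, 3)


def cn_invariant(moments: MomentSet, n: int) -> CNInvariantVector:
    """Canterakis-norm invariants of normalization order n.

    Every solution rotation is applied to the full moment set; complex
    magnitudes per (n, l, m >= 0) are averaged across solutions.  The result
    does not depend on the residual z-phase (magnitudes are blind to it), so
    only the first-constraint solutions matter.  If the normalization is
    degenerate the unrotated magnitudes are returned with a flag.
    """
    if n > moments.order_max:
        raise ValueError("normalization order exceeds order_max")
    constraint = constraint_for_order(n)
    modified = modify_moments(moments)
    try:
        sols = solve_normalization(modified, n, constraint)
    except DegenerateNormalizationError:
        logger.warning("degenerate normalization at order %d; using unrotated magnitudes", n)
        return CNInvariantVector(n, np.abs(moments.values), degenerate=True)
    acc = np.zeros(moments.values.shape)
    for rot in sols.rotations:
        acc += np.abs(rotate_moments(moments, rot).values)
    return CNInvariantVector(n, acc / len(sols.rotations))


def composite_cn(moments: MomentSet, orders=(2, 3, 4, 5)) -> np.ndarray:
    """Concatenated CN invariants in ascending order of n.

    Default orders 2-5 at order_max 20 give 4 x 946 = 3784 components.
    """
    return np.concatenate([cn_invariant(moments, n).values for n in sorted(orders)])
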