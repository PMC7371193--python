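"""3D Zernike polynomial basis on the unit ball.

The basis functions are ``Z_nlm(x) = R_nl(|x|) Y_lm(x/|x|)`` with

* ``R_nl(r) = sqrt(2n+3) * r**l * P_k^(0, l+1/2)(2 r**2 - 1)``, ``k = (n-l)/2``,
  orthonormal on [0, 1] with weight ``r**2`` (Jacobi-polynomial form of the
  radial Zernike polynomials);
* ``Y_lm`` the orthonormal complex spherical harmonics with the
  Condon-Shortley phase, so that for a real-valued density the moments obey
  ``Omega_{n,l,-m} = (-1)**m * conj(Omega_{n,l,m})``.

Index convention used throughout the package: moments are stored for
``0 <= n <= N``, ``0 <= l <= n`` with ``n - l`` even, and ``0 <= m <= l``
(negative ``m`` implied by conjugation symmetry), ordered lexicographically
by ``(n, l, m)``.

The hot loops (moment accumulation and reconstruction) are JIT-compiled with
numba; the recurrence coefficient tables are precomputed in numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "moment_indices",
    "count_indices",
    "nl_pairs",
    "accumulate_moments",
    "evaluate_expansion",
    "sph_harm_table",
    "radial_table",
]


def moment_indices(order_max: int) -> list[tuple[int, int, int]]:
    """Canonical (n, l, m>=0) index list up to ``order_max``."""
    if order_max < 0:
        raise ValueError("order_max must be >= 0")
    return [
        (n, l, m)
        for n in range(order_max + 1)
        for l in range(n % 2, n + 1, 2)
        for m in range(l + 1)
    ]


def nl_pairs(order_max: int) -> list[tuple[int, int]]:
    """Valid (n, l) pairs up to ``order_max`` (lexicographic)."""
    if order_max < 0:
        raise ValueError("order_max must be >= 0")
    return [(n, l) for n in range(order_max + 1) for l in range(n % 2, n + 1, 2)]


def count_indices(order_max: int, with_m: bool = True) -> int:
    """Number of stored moment indices.

    ``with_m=True`` counts (n, l, m>=0) triples (946 for order 20),
    ``with_m=False`` counts (n, l) pairs (121 for order 20).
    """
    if with_m:
        return len(moment_indices(order_max))
    return len(nl_pairs(order_max))


# ---------------------------------------------------------------------------
# recurrence coefficient tables
# ---------------------------------------------------------------------------


def _legendre_coeffs(lmax: int):
    """Coefficients for the normalized associated-Legendre recursion."""
    a = np.zeros((lmax + 1, lmax + 1))
    b = np.zeros((lmax + 1, lmax + 1))
    for m in range(lmax + 1):
        for l in range(m + 2, lmax + 1):
            a[l, m] = np.sqrt((4.0 * l * l - 1.0) / (l * l - m * m))
            b[l, m] = np.sqrt(((l - 1.0) ** 2 - m * m) / (4.0 * (l - 1.0) ** 2 - 1.0))
    return a, b


def _jacobi_coeffs(lmax: int):
    """Coefficients for the Jacobi P_k^(0, l+1/2) three-term recursion.

    P_k = (c1*x + c2) * P_{k-1} + c3 * P_{k-2} evaluated at x = 2 r^2 - 1.
    """
    kmax = lmax // 2
    c1 = np.zeros((lmax + 1, kmax + 1))
    c2 = np.zeros((lmax + 1, kmax + 1))
    c3 = np.zeros((lmax + 1, kmax + 1))
    for l in range(lmax + 1):
        beta = l + 0.5
        for k in range(1, kmax + 1):
            if k == 1:
                # P_1^(0,b)(x) = (b/2 + 1) x + (-b/2)
                c1[l, k] = beta / 2.0 + 1.0
                c2[l, k] = -beta / 2.0
                c3[l, k] = 0.0
            else:
                s = 2.0 * k + beta  # 2k + alpha + beta with alpha = 0
                den = 2.0 * k * (k + beta) * (s - 2.0)
                c1[l, k] = (s - 1.0) * s * (s - 2.0) / den
                c2[l, k] = -(s - 1.0) * beta * beta / den
                c3[l, k] = -2.0 * (k - 1.0) * (k + beta - 1.0) * s / den
    return c1, c2, c3


def _index_offsets(order_max: int) -> np.ndarray:
    """offset[n, l] = flat index of (n, l, 0) in the canonical ordering."""
    off = np.full((order_max + 1, order_max + 1), -1, dtype=np.int64)
    pos = 0
    for n in range(order_max + 1):
        for l in range(n % 2, n + 1, 2):
            off[n, l] = pos
            pos += l + 1
    return off


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _moment_kernel(
    x, y, z, w, order_max, la, lb, c1, c2, c3, offsets, out
):  # pragma: no cover - exercised through accumulate_moments
    lmax = order_max
    kmax = lmax // 2
    sq4pi = np.sqrt(1.0 / (4.0 * np.pi))
    P = np.zeros((lmax + 1, lmax + 1))
    J = np.zeros((lmax + 1, kmax + 1))
    em = np.zeros(lmax + 1, dtype=np.complex128)
    rl = np.zeros(lmax + 1)
    for i in range(x.shape[0]):
        r2 = x[i] * x[i] + y[i] * y[i] + z[i] * z[i]
        r = np.sqrt(r2)
        if r > 0.0:
            ct = z[i] / r
        else:
            ct = 1.0
        st = np.sqrt(max(0.0, 1.0 - ct * ct))
        phi = np.arctan2(y[i], x[i])
        # normalized associated Legendre (Condon-Shortley embedded)
        P[0, 0] = sq4pi
        for m in range(1, lmax + 1):
            P[m, m] = -np.sqrt((2.0 * m + 1.0) / (2.0 * m)) * st * P[m - 1, m - 1]
        for m in range(lmax):
            P[m + 1, m] = np.sqrt(2.0 * m + 3.0) * ct * P[m, m]
        for m in range(lmax + 1):
            for l in range(m + 2, lmax + 1):
                P[l, m] = la[l, m] * (ct * P[l - 1, m] - lb[l, m] * P[l - 2, m])
        # e^{-i m phi} table (conjugated harmonics enter the projection)
        em[0] = 1.0 + 0.0j
        e1 = complex(np.cos(phi), -np.sin(phi))
        for m in range(1, lmax + 1):
            em[m] = em[m - 1] * e1
        # Jacobi values at 2 r^2 - 1 and powers of r
        xj = 2.0 * r2 - 1.0
        rl[0] = 1.0
        for l in range(1, lmax + 1):
            rl[l] = rl[l - 1] * r
        for l in range(lmax + 1):
            J[l, 0] = 1.0
            for k in range(1, kmax + 1):
                if k == 1:
                    J[l, 1] = c1[l, 1] * xj + c2[l, 1]
                else:
                    J[l, k] = (c1[l, k] * xj + c2[l, k]) * J[l, k - 1] + c3[l, k] * J[l, k - 2]
        # accumulate
        wi = w[i]
        for n in range(lmax + 1):
            for l in range(n % 2, n + 1, 2):
                k = (n - l) // 2
                rad = np.sqrt(2.0 * n + 3.0) * rl[l] * J[l, k] * wi
                base = offsets[n, l]
                for m in range(l + 1):
                    out[base + m] += rad * P[l, m] * em[m]


@njit(cache=True)
def _reconstruct_kernel(
    x, y, z, coef, order_max, la, lb, c1, c2, c3, offsets, out
):  # pragma: no cover - exercised through evaluate_expansion
    lmax = order_max
    kmax = lmax // 2
    sq4pi = np.sqrt(1.0 / (4.0 * np.pi))
    P = np.zeros((lmax + 1, lmax + 1))
    J = np.zeros((lmax + 1, kmax + 1))
    em = np.zeros(lmax + 1, dtype=np.complex128)
    rl = np.zeros(lmax + 1)
    for i in range(x.shape[0]):
        r2 = x[i] * x[i] + y[i] * y[i] + z[i] * z[i]
        r = np.sqrt(r2)
        if r > 0.0:
            ct = z[i] / r
        else:
            ct = 1.0
        st = np.sqrt(max(0.0, 1.0 - ct * ct))
        phi = np.arctan2(y[i], x[i])
        P[0, 0] = sq4pi
        for m in range(1, lmax + 1):
            P[m, m] = -np.sqrt((2.0 * m + 1.0) / (2.0 * m)) * st * P[m - 1, m - 1]
        for m in range(lmax):
            P[m + 1, m] = np.sqrt(2.0 * m + 3.0) * ct * P[m, m]
        for m in range(lmax + 1):
            for l in range(m + 2, lmax + 1):
                P[l, m] = la[l, m] * (ct * P[l - 1, m] - lb[l, m] * P[l - 2, m])
        em[0] = 1.0 + 0.0j
        e1 = complex(np.cos(phi), np.sin(phi))
        for m in range(1, lmax + 1):
            em[m] = em[m - 1] * e1
        xj = 2.0 * r2 - 1.0
        rl[0] = 1.0
        for l in range(1, lmax + 1):
            rl[l] = rl[l - 1] * r
        for l in range(lmax + 1):
            J[l, 0] = 1.0
            for k in range(1, kmax + 1):
                if k == 1:
                    J[l, 1] = c1[l, 1] * xj + c2[l, 1]
                else:
                    J[l, k] = (c1[l, k] * xj + c2[l, k]) * J[l, k - 1] + c3[l, k] * J[l, k - 2]
        acc = 0.0 + 0.0j
        for n in range(lmax + 1):
            for l in range(n % 2, n + 1, 2):
                k = (n - l) // 2
                rad = np.sqrt(2.0 * n + 3.0) * rl[l] * J[l, k]
                base = offsets[n, l]
                # m = 0 term plus m > 0 pairs (negative m via conjugation)
                acc += coef[base] * rad * P[l, 0]
                for m in range(1, l + 1):
                    t = coef[base + m] * rad * P[l, m] * em[m]
                    acc += t + np.conj(t)
        out[i] = acc


class _Tables:
    """Cached recurrence coefficient tables per order_max."""

    _cache: dict[int, tuple] = {}

    @classmethod
    def get(cls, order_max: int):
        if order_max not in cls._cache:
            la, lb = _legendre_coeffs(order_max)
            c1, c2, c3 = _jacobi_coeffs(order_max)
            off = _index_offsets(order_max)
            cls._cache[order_max] = (la, lb, c1, c2, c3, off)
        return cls._cache[order_max]


def accumulate_moments(points: np.ndarray, weights: np.ndarray, order_max: int) -> np.ndarray:
    """Project weighted points onto the Zernike basis.

    Returns the complex vector ``sum_i w_i * conj(Z_nlm(p_i))`` over the
    canonical (n, l, m>=0) index list.  Points must lie in the unit ball;
    weights carry the quadrature volume element.
    """
    la, lb, c1, c2, c3, off = _Tables.get(order_max)
    out = np.zeros(count_indices(order_max), dtype=np.complex128)
    pts = np.ascontiguousarray(points, dtype=np.float64)
    _moment_kernel(
        pts[:, 0], pts[:, 1], pts[:, 2],
        np.ascontiguousarray(weights, dtype=np.float64),
        order_max, la, lb, c1, c2, c3, off, out,
    )
    return out


def evaluate_expansion(points: np.ndarray, coefficients: np.ndarray, order_max: int) -> np.ndarray:
    """Evaluate ``f(x) = sum Omega_nlm Z_nlm(x)`` at unit-ball points.

    Negative-m terms are included through the conjugation symmetry of real
    densities, so the result's imaginary part is zero up to rounding.
    """
    la, lb, c1, c2, c3, off = _Tables.get(order_max)
    pts = np.ascontiguousarray(points, dtype=np.float64)
    out = np.zeros(pts.shape[0], dtype=np.complex128)
    _reconstruct_kernel(
        pts[:, 0], pts[:, 1], pts[:, 2],
        np.ascontiguousarray(coefficients, dtype=np.complex128),
        order_max, la, lb, c1, c2, c3, off, out,
    )
    return out


# ---------------------------------------------------------------------------
# reference (numpy) evaluation, used by tests as an independent slow path
# ---------------------------------------------------------------------------


def sph_harm_table(lmax: int, theta: np.ndarray, phi: np.ndarray) -> dict:
    """Orthonormal Y_lm (Condon-Shortley) for 0 <= m <= l <= lmax."""
    ct, st = np.cos(theta), np.sin(theta)
    P = {(0, 0): np.full(np.shape(theta), np.sqrt(1 / (4 * np.pi)))}
    for m in range(1, lmax + 1):
        P[(m, m)] = -np.sqrt((2 * m + 1) / (2 * m)) * st * P[(m - 1, m - 1)]
    for m in range(lmax):
        P[(m + 1, m)] = np.sqrt(2 * m + 3) * ct * P[(m, m)]
    la, lb = _legendre_coeffs(lmax)
    for m in range(lmax + 1):
        for l in range(m + 2, lmax + 1):
            P[(l, m)] = la[l, m] * (ct * P[(l - 1, m)] - lb[l, m] * P[(l - 2, m)])
    return {(l, m): P[(l, m)] * np.exp(1j * m * phi) for (l, m) in P}


def radial_table(order_max: int, r: np.ndarray) -> dict:
    """Radial polynomials R_nl(r) for all valid (n, l), numpy path."""
    from scipy.special import eval_jacobi

    out = {}
    for n, l in nl_pairs(order_max):
        k = (n - l) // 2
        out[(n, l)] = np.sqrt(2 * n + 3) * r**l * eval_jacobi(k, 0, l + 0.5, 2 * r**2 - 1)
    return out
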