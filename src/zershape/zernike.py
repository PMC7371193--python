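"""3D Zernike moments of density volumes.

``compute_moments`` projects a rasterized density, mapped into the unit
ball, onto the orthonormal Zernike basis by midpoint (voxel-center)
quadrature.  ``descriptor_3dzd`` collapses the moments to the classical
rotation invariants (per-(n, l) vector norms); ``reconstruct`` evaluates the
truncated expansion back onto a grid.

Modified moments divide each coefficient by

    c_lm = sqrt((2l+1) (l+m)! (l-m)! / l!)

which makes the Cayley-Klein rotation law of :mod:`zershape.canterakis` a
plain polynomial-coefficient transformation.  (Without the square root the
induced transformation fails to be unitary; see docs/methods.md.)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import lgamma, exp

import numpy as np

from . import basis
from .basis import count_indices, moment_indices, nl_pairs
from .volume import UnitSphereFrame, VolumeGrid

__all__ = [
    "MomentSet",
    "ModifiedMomentSet",
    "compute_moments",
    "reconstruct",
    "descriptor_3dzd",
    "modify_moments",
    "unmodify_moments",
    "c_factor",
    "count_indices",
]


def c_factor(l: int, m: int) -> float:
    """Modification factor c_lm > 0 (independent of the sign of m)."""
    m = abs(m)
    return exp(0.5 * (np.log(2 * l + 1) + lgamma(l + m + 1) + lgamma(l - m + 1) - lgamma(l + 1)))


@dataclass
class _MomentBase:
    order_max: int
    values: np.ndarray
    frame: UnitSphereFrame | None = None
    _offsets: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.complex128)
        expected = count_indices(self.order_max, with_m=True)
        if self.values.shape != (expected,):
            raise ValueError(
                f"expected {expected} coefficients for order {self.order_max}, "
                f"got {self.values.shape}"
            )
        pos = 0
        for n, l in nl_pairs(self.order_max):
            self._offsets[(n, l)] = pos
            pos += l + 1

    def get(self, n: int, l: int, m: int) -> complex:
        """Coefficient at (n, l, m); negative m through conjugation symmetry."""
        base = self._offsets[(n, l)]
        if m >= 0:
            return complex(self.values[base + m])
        return (-1) ** (-m) * np.conj(complex(self.values[base - m]))

    def vector_nl(self, n: int, l: int) -> np.ndarray:
        """Full (2l+1)-vector over m = -l..l."""
        return np.array([self.get(n, l, m) for m in range(-l, l + 1)])

    def norm_nl(self, n: int, l: int) -> float:
        return float(np.linalg.norm(self.vector_nl(n, l)))

    def copy(self):
        return type(self)(self.order_max, self.values.copy(), self.frame)


class MomentSet(_MomentBase):
    """Complex 3D Zernike coefficients Omega_nlm up to ``order_max``.

    Stored for m >= 0 only; Omega_{n,l,-m} = (-1)^m conj(Omega_{n,l,m}) for
    the real densities this package produces.  946 coefficients at order 20.
    """

    def to_json(self, path=None) -> str:
        """Serialize as a documented JSON layout (index triples + re/im)."""
        payload = {
            "order_max": self.order_max,
            "indices": moment_indices(self.order_max),
            "real": self.values.real.tolist(),
            "imag": self.values.imag.tolist(),
        }
        if self.frame is not None:
            payload["frame"] = {
                "center": self.frame.center.tolist(),
                "scale": self.frame.scale,
            }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MomentSet":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        values = np.array(payload["real"]) + 1j * np.array(payload["imag"])
        frame = None
        if "frame" in payload:
            frame = UnitSphereFrame(np.array(payload["frame"]["center"]),
                                    payload["frame"]["scale"])
        return cls(payload["order_max"], values, frame)


class ModifiedMomentSet(_MomentBase):
    """Moments divided elementwise by c_lm (the rotation-ready gauge)."""


def _c_vector(order_max: int) -> np.ndarray:
    return np.array([c_factor(l, m) for (_, l, m) in moment_indices(order_max)])


def modify_moments(moments: MomentSet) -> ModifiedMomentSet:
    """Elementwise division by c_lm."""
    return ModifiedMomentSet(moments.order_max,
                             moments.values / _c_vector(moments.order_max),
                             moments.frame)


def unmodify_moments(modified: ModifiedMomentSet) -> MomentSet:
    """Inverse of :func:`modify_moments`; round trip is the identity."""
    return MomentSet(modified.order_max,
                     modified.values * _c_vector(modified.order_max),
                     modified.frame)


def compute_moments(volume: VolumeGrid, frame: UnitSphereFrame,
                    order_max: int) -> MomentSet:
    """Project a density volume onto the Zernike basis.

    The volume is mapped through ``frame`` into the unit ball; voxels whose
    center falls outside the ball are ignored.  Quadrature weight per voxel
    is ``density * (grid_width * scale)^3``.
    """
    if order_max < 0:
        raise ValueError("order_max must be >= 0")
    if volume.values.size == 0:
        raise ValueError("empty volume")
    centers = volume.voxel_centers()
    u = frame.to_unit(centers)
    vals = volume.values.ravel()
    inside = (np.einsum("ij,ij->i", u, u) < 1.0) & (vals != 0.0)
    weights = vals[inside] * (volume.grid_width * frame.scale) ** 3
    coeffs = basis.accumulate_moments(u[inside], weights, order_max)
    return MomentSet(order_max, coeffs, frame)


def reconstruct(moments: MomentSet, grid_shape) -> VolumeGrid:
    """Partial sum of the basis expansion on a unit-ball grid.

    The returned grid spans [-1, 1]^3 in scaled coordinates (grid_width in
    those units); values outside the unit ball are zero.  The imaginary
    residue of the summation is discarded; it vanishes up to rounding
    because of the conjugation symmetry.
    """
    shape = tuple(int(s) for s in np.broadcast_to(grid_shape, (3,)))
    widths = 2.0 / np.asarray(shape)
    axes = [-1.0 + (np.arange(s) + 0.5) * w for s, w in zip(shape, widths)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    inside = np.einsum("ij,ij->i", pts, pts) < 1.0
    out = np.zeros(pts.shape[0])
    vals = basis.evaluate_expansion(pts[inside], moments.values, moments.order_max)
    out[inside] = vals.real
    # clip tiny negative overshoot of the truncated expansion
    return VolumeGrid(
        values=np.clip(out.reshape(shape), 0.0, None),
        grid_width=float(widths[0]),
        origin=np.array([-1.0, -1.0, -1.0]),
        center_of_mass=np.zeros(3),
        gyration_radius=1.0,
    )


def reconstruction_values(moments: MomentSet, points: np.ndarray) -> np.ndarray:
    """Raw (signed, complex) expansion values at arbitrary unit-ball points."""
    return basis.evaluate_expansion(np.asarray(points, dtype=float),
                                    moments.values, moments.order_max)


def descriptor_3dzd(moments: MomentSet) -> np.ndarray:
    """Classical 3DZD invariants F_nl = ||Omega_nl||, one per (n, l).

    Each (2l+1)-vector (negative m reconstructed by conjugation symmetry) is
    collapsed to its Euclidean norm; length 121 at order 20.  The invariants
    of one order do not mix into any other order.
    """
    return np.array([moments.norm_nl(n, l) for n, l in nl_pairs(moments.order_max)])
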