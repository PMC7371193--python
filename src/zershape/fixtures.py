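"""Deterministic synthetic shapes, conformers and retrieval benchmarks.

Everything downstream of structure parsing can be exercised without any
external file: the generators below produce labeled point clouds that mimic
the statistical design of an assemblies benchmark - a set of mutually
distinct base shapes, each expanded into a class of smoothly deformed
conformers.  The deformations are low-frequency sinusoidal displacement
fields (a cheap stand-in for normal-mode conformer sampling that preserves
the within-class smooth-deformation structure without an elastic-network
dependency).

Same spec + seed always gives a bitwise-identical point set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import RepresentativeAtomSet

__all__ = ["ShapeSpec", "make_shape", "make_conformer", "make_benchmark",
           "SHAPE_KINDS"]

SHAPE_KINDS = ("helix_bundle", "ring_cn", "dumbbell", "slab", "random_blob")

#: Distinctness floor for benchmark base shapes: minimum allowed mean
#: relativized geometric-feature difference (the same per-component form the
#: composite distance uses on GEO features).  Plays the role of a ceiling on
#: density correlation between classes: pairs below the floor are
#: near-duplicates and are rejection-sampled away.
DISTINCTNESS_FLOOR = 0.02


@dataclass(frozen=True)
class ShapeSpec:
    """Recipe for one deterministic point cloud."""

    kind: str
    n_points: int = 120
    size: float = 12.0  # characteristic radius, A
    symmetry_order: int = 6  # ring_cn only
    seed: int = 0
    cluster_scale: float | None = None  # ring_cn subunit width, A (None: seeded draw)
    params: tuple = field(default_factory=tuple)  # kind-specific extras


def _round_pdb(coords: np.ndarray) -> np.ndarray:
    """Round to PDB coordinate precision so file round trips are exact."""
    return np.round(coords, 3)


def make_shape(spec: ShapeSpec) -> RepresentativeAtomSet:
    """Deterministic point cloud for a shape spec, unit masses.

    ``ring_cn`` has exact C_n symmetry (one seeded cluster replicated by
    rotation); ``helix_bundle`` is chiral and asymmetric.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.size
    if spec.kind == "helix_bundle":
        n_helices = int(rng.integers(2, 5))
        turns = float(rng.uniform(3.0, 6.0))
        per = max(spec.n_points // n_helices, 4)
        pts = []
        for h in range(n_helices):
            t = np.linspace(0, turns * np.pi, per)
            phase = 2 * np.pi * h / n_helices
            axis_r = 0.45 * s
            helix_r = 0.18 * s * (1.0 + 0.25 * h)  # break symmetry
            x = axis_r * np.cos(phase) + helix_r * np.cos(t + h)
            y = axis_r * np.sin(phase) + helix_r * np.sin(t + h)
            z = np.linspace(-0.8 * s, 0.8 * s, per) * (1.0 - 0.1 * h)
            pts.append(np.stack([x, y, z], axis=1))
        coords = np.concatenate(pts)
    elif spec.kind == "ring_cn":
        n = spec.symmetry_order
        per = max(spec.n_points // n, 3)
        cscale = (spec.cluster_scale if spec.cluster_scale is not None
                  else float(rng.uniform(0.08, 0.2)) * s)
        cluster = rng.normal(scale=cscale, size=(per, 3)) + np.array([s, 0.0, 0.0])
        blocks = []
        for k in range(n):
            ang = 2 * np.pi * k / n
            c, si = np.cos(ang), np.sin(ang)
            R = np.array([[c, -si, 0], [si, c, 0], [0, 0, 1.0]])
            blocks.append(cluster @ R.T)
        coords = np.concatenate(blocks)
    elif spec.kind == "dumbbell":
        half = spec.n_points // 2
        sep = float(rng.uniform(0.8, 1.3)) * s
        lobe_scale = float(rng.uniform(0.25, 0.45)) * s
        lobe1 = rng.normal(scale=lobe_scale, size=(half, 3))
        lobe2 = rng.normal(scale=lobe_scale * float(rng.uniform(0.6, 1.0)),
                           size=(spec.n_points - half, 3))
        coords = np.concatenate([
            lobe1 + np.array([-sep, 0.0, 0.0]),
            lobe2 + np.array([sep, 0.0, 0.0]),
        ])
    elif spec.kind == "slab":
        thickness = float(rng.uniform(0.1, 0.3))
        coords = np.stack([
            rng.uniform(-s, s, spec.n_points),
            rng.uniform(-0.8 * s, 0.8 * s, spec.n_points),
            rng.uniform(-thickness * s, thickness * s, spec.n_points),
        ], axis=1)
    elif spec.kind == "random_blob":
        aniso = np.array([1.0, rng.uniform(0.5, 0.9), rng.uniform(0.3, 0.6)]) * 0.5 * s
        coords = rng.normal(size=(spec.n_points, 3)) * aniso
    else:
        raise ValueError(f"unknown shape kind {spec.kind!r}")
    coords = _round_pdb(coords)
    labels = [("A", i + 1, "ALA") for i in range(len(coords))]
    return RepresentativeAtomSet(coords, np.ones(len(coords)), labels,
                                 source_id=f"{spec.kind}-{spec.seed}")


def _displacement_field(coords: np.ndarray, seed: int, n_modes: int = 3) -> np.ndarray:
    """Unit-RMS low-frequency sinusoidal displacement field.

    Wavelengths are of the order of the cloud extent, so neighbor distances
    change smoothly.  If the field RMS collapses (degenerate phases) the
    modes are re-drawn deterministically.
    """
    rng = np.random.default_rng(seed)
    extent = max(np.ptp(coords, axis=0).max(), 1e-6)
    for _ in range(10):
        raw = np.zeros_like(coords)
        for _mode in range(n_modes):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            wavevec = rng.normal(size=3)
            wavevec *= 2 * np.pi / (extent * rng.uniform(1.0, 2.0)) / np.linalg.norm(wavevec)
            phase = rng.uniform(0, 2 * np.pi)
            raw += np.sin(coords @ wavevec + phase)[:, None] * direction
        rms = np.sqrt(np.mean(np.sum(raw**2, axis=1)))
        if rms > 0.3 * np.sqrt(n_modes):
            return raw / rms
    return raw / max(rms, 1e-9)


def make_conformer(base: RepresentativeAtomSet, amplitude: float,
                   seed: int = 0) -> RepresentativeAtomSet:
    """Smoothly deformed copy of a point cloud.

    The displacement field is fixed by (base coordinates, seed) and scaled
    linearly by ``amplitude`` (A RMS displacement), so the RMSD to the base
    grows exactly linearly with amplitude and amplitude 0 returns the base
    unchanged.  Per-point displacement is bounded by ~10x the amplitude
    (field maximum over field RMS is bounded by construction).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return RepresentativeAtomSet(base.coordinates.copy(), base.masses.copy(),
                                     list(base.labels), base.source_id)
    field_ = _displacement_field(base.coordinates, seed)
    coords = _round_pdb(base.coordinates + amplitude * field_)
    return RepresentativeAtomSet(coords, base.masses.copy(), list(base.labels),
                                 source_id=f"{base.source_id}-conf{seed}")


def _quick_signature(atoms: RepresentativeAtomSet) -> np.ndarray:
    """Geometric feature vector used for distinctness screening."""
    from .descriptors import geo_descriptor

    return geo_descriptor(atoms).values


def _signature_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean relativized per-feature difference (GEO term of the composite
    distance with uniform weights)."""
    return float(np.mean(np.abs(a - b) / (1.0 + np.abs(a) + np.abs(b))))


def make_benchmark(n_classes: int, n_members: int, base_kinds=SHAPE_KINDS,
                   amplitude: float = 1.0, seed: int = 0,
                   n_points: int = 120):
    """Labeled conformer benchmark.

    ``n_classes`` distinct base shapes (rejection-sampled so that any two
    differ by at least :data:`DISTINCTNESS_FLOOR` in normalized geometric
    signature - the stand-in for a density-correlation ceiling between
    classes), each expanded to ``n_members`` structures: the base plus
    smoothly deformed conformers of the given RMS amplitude.

    Returns ``(structures, labels)`` with labels[i] the class index.
    """
    if n_classes < 2 or n_members < 2:
        raise ValueError("need n_classes >= 2 and n_members >= 2")
    rng = np.random.default_rng(seed)
    bases, signatures = [], []
    attempts = 0
    while len(bases) < n_classes:
        attempts += 1
        if attempts > 60 * n_classes:
            raise RuntimeError(
                "cannot satisfy the distinctness floor; use fewer classes"
            )
        kind = base_kinds[len(bases) % len(base_kinds)]
        spec = ShapeSpec(
            kind=kind,
            n_points=n_points,
            size=float(rng.uniform(8.0, 16.0)),
            symmetry_order=int(rng.integers(3, 13)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        shape = make_shape(spec)
        sig = _quick_signature(shape)
        if all(_signature_distance(sig, s) >= DISTINCTNESS_FLOOR
               for s in signatures):
            bases.append(shape)
            signatures.append(sig)
    structures, labels = [], []
    for c, base in enumerate(bases):
        structures.append(base)
        labels.append(c)
        for k in range(n_members - 1):
            conf_seed = int(rng.integers(0, 2**31 - 1))
            structures.append(make_conformer(base, amplitude, conf_seed))
            labels.append(c)
    return structures, np.array(labels)
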