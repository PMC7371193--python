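# Methods

`zershape` computes rotation-invariant volumetric shape descriptors of
macromolecular structures and superposes structures in moment space. This
note records the model, its parameters, the numerical choices, and what the
synthetic benchmarks do and do not establish.

## Density model

A structure is reduced to one point per polymer residue: the C-alpha atom of
an amino acid or the backbone phosphorus of a nucleotide. Each point carries
the average residue mass (residue = monomer minus water; embedded table for
the 20 standard amino acids and 8 standard nucleotides, documented default
for unknown codes) and an isotropic Gaussian width derived from the
residue's average partial volume: the residue is modelled as a single
Gaussian whose per-axis variance matches the second moment of a uniform
sphere of that volume, `sigma = (3V/4pi)^(1/3) / sqrt(5)` (about 1.1 A for
glycine, 1.7 A for tryptophan). Exact constants of the gmconvert-style
single-Gaussian fits are not published alongside the method, so descriptor
values differ from other implementations at the margin; all internal
consistency properties are independent of the particular table.

Gaussians are normalized to integrate to the residue mass, truncated at
**4 sigma** (a 3D Gaussian truncated at 3 sigma already loses ~3% of its
mass; 4 sigma keeps the loss near 0.1%, consistent with the <1% integral
invariant), and accumulated on a regular grid sampled at voxel centers. The
grid width is chosen from the dyadic ladder 0.25 x 2^k A, k = 0..6,
preferring the finest width that keeps the mean grid dimension between 50
and 200 voxels; outside that feasible range the nearest bound (0.25 or
16 A) is used. The grid is padded so no truncated Gaussian is clipped.

The volume is mapped into the unit ball by `u = (x - com) / (1.8 Rg)` with
`com` the mass-weighted centroid and `Rg` the mass-weighted gyration
radius. For globular point clouds the factor 1.8 leaves a negligible mass
fraction outside the ball while filling most of the basis' radial range.

## 3D Zernike moments

The density (in unit-ball coordinates) is projected onto the orthonormal
basis `Z_nlm = R_nl(r) Y_lm(theta, phi)`, `0 <= n <= N`, `l <= n` with
`n - l` even, `|m| <= l`:

* radial factors `R_nl(r) = sqrt(2n+3) r^l P_k^(0, l+1/2)(2r^2 - 1)`,
  `k = (n-l)/2` (Jacobi form of the 3D Zernike radial polynomials,
  orthonormal under `r^2 dr` on [0, 1]; validated by quadrature);
* orthonormal complex spherical harmonics with the Condon-Shortley phase,
  so that real densities satisfy `Omega_{n,l,-m} = (-1)^m conj(Omega_nlm)`
  and only `m >= 0` is stored (946 coefficients at N = 20).

Projection uses midpoint (voxel-center) quadrature; voxels whose center
falls outside the unit ball are ignored. Basis evaluation and accumulation
are fused in a numba kernel using stable normalized-Legendre and Jacobi
recursions (checked against scipy to ~1e-14).

The classical 3DZD invariants are the per-(n, l) Euclidean norms of the
(2l+1)-vectors (121 values at N = 20); each order's invariants are
independent of every other order's.

## Rotations in moment space

Rotations are carried by Cayley-Klein parameters (a, b), |a|^2 + |b|^2 = 1.
In the modified gauge `Omega^ = Omega / c_lm` with

    c_lm = sqrt( (2l+1) (l+m)! (l-m)! / l! )

the rotation of a degree-l coefficient vector is the coefficient map of the
polynomial substitution with top-row (m = l) expansion

    (Omega^R)_nll = sum_mu a^(l+mu) (-b*)^(l-mu) Omega^_nl,mu ,

reproducing the classical five-term identity at l = 2. The square root in
`c_lm` is essential: without it the transformation is not unitary and
per-(n, l) norms would not be preserved. The real-space matrix returned by
`rotation_matrix` is the rotation this law actually induces on a density
(verified by recomputing moments from rotated point clouds to <2% relative
error at 0.5 A grids; the discrepancy is pure grid discretization). It
differs from one common printed form of the Cayley-Klein matrix by a fixed
relabeling of the x/y axes — a convention, not a different group action.

## Canterakis normalization

Setting the extremal moment `(Omega^R)_{n,l,l}` to zero (l = 2 for even
normalization orders, l = 3 for odd) reduces, after `t = a/b*`, to a
degree-2l complex polynomial whose ascending coefficients are
`(-1)^(l-mu) Omega^_{n,l,mu}`. Roots are taken from the companion matrix
(`numpy.roots`) after deflating numerically-zero leading coefficients;
each deflated coefficient is a root at infinity, i.e. b = 0 — a pure
z-rotation that is restored explicitly (it is what makes re-normalizing an
already-normalized structure a fixed point). The residual in-plane angle is
fixed by `Im{(Omega^R)_{n',1,1}} = 0` with n' the odd order (3, 5, 7, 1)
whose degree-1 vector is largest; given t this is a real quadratic in
`s = Im{b}/Re{b}` with closed-form roots `(-Re K +- |K|)/Im K`,
`K = t^2 w11 - t w10 - conj(w11)`. When `Im K ~ 0` the second root lies at
infinity (`Re{b} = 0`); both gauge-boundary signs are kept. Recovery:
`b = (1 + is)/sqrt((1+|t|^2)(1+s^2))`, `a = t b*`. Generic moments yield
exactly 8 solutions for the (2,2) system and 12 for (3,3); back-substitution
residuals are ~1e-16 of the constrained-vector scale and are reported per
solution.

A **CN invariant vector** of order n applies every solution rotation to the
full moment set, takes complex magnitudes per (n, l, m >= 0), and averages
across solutions. Magnitudes are blind to the residual z-phase, so the
choice of second constraint does not affect descriptors (it matters for
alignment, where it is solved). If the constrained vector vanishes (shapes
symmetric for that order) the unrotated magnitudes are returned with a
degeneracy flag. The composite CN descriptor concatenates orders 2-5
(4 x 946 = 3784 components at N = 20).

## Descriptors and distance

**GEO** (17 components, exactly rigid-motion invariant): standard
deviation, skewness and kurtosis (Pearson, i.e. non-excess) of the
unweighted distances from the center of mass; their 10th-90th deciles
(linear interpolation between order statistics); mass-weighted gyration
radius; nominal molecular weight; and the three principal standard
deviations of the unweighted coordinate covariance, descending.

The composite distance is

    D = sum_i wg_i^2 |g1_i - g2_i| / (1 + |g1_i| + |g2_i|)
      + sum_i wm_i |m1_i - m2_i|

(geometric weights enter squared, moment weights linearly). Weights are
fitted by L2-regularized logistic regression on the per-component terms of
this formula as features, predicting "different class", with coefficients
constrained non-negative (L-BFGS-B box constraints) and classes
weight-balanced; the non-negativity produces sparse solutions. The
regularization strength is selected by grouped 10-fold cross-validation at
the class level, maximizing the Matthews correlation coefficient of
held-out predictions; `wg = sqrt(coef)` on the geometric block, `wm = coef`
on the moment block, so the learned linear score *is* the distance.
Features enter on their native scale — rescaling columns would silently
re-weight the prior and measurably hurt generalization of the moment block.

## Alignment

The alignment descriptor is the complete moment set to order 6 plus the
center of mass (position and size are lost in unit-ball scaling). For each
structure all normalization solutions of orders 2-5 are candidates; for a
pair, every same-order candidate combination is scored by the relative
moment distance `sum |O1 - O2| / (|O1| + |O2| + 1)` over the full index
lattice (negative m included via symmetry), and the minimizing combination
is kept (ties toward lower order, first solution). Superposition rotates
each structure about its center of mass to the selected standard position,
undoes the reference structure's rotation, and matches centers of mass;
for multiple structures each candidate of the reference is paired with the
best candidate of every other structure and the total distance is
minimized, keeping the cost linear in the number of structures. Rotated
copies of asymmetric test shapes are recovered to ~0.001 A RMSD and
~0.005 degrees; recovered rotations are defined only modulo a shape's
symmetry group. The order-2 constraint zeroes the m = +-2 quadrupole
components only (not full diagonalization), so principal axes of similar
shapes align because their standard positions match; for nearly
axially-symmetric shapes the order-2 system is ill-conditioned and higher
orders carry the alignment.

## Synthetic data

The fixtures module generates labeled point clouds emulating the design of
an assemblies benchmark: mutually distinct base shapes (helix bundles,
C_n rings, dumbbells, slabs, anisotropic blobs; kind-internal structure
parameters drawn deterministically from the spec seed), each expanded into
a class of smoothly deformed conformers. Distinctness is enforced by
rejection sampling with a floor of 0.02 on the mean relativized
geometric-feature difference (playing the role of a ceiling on inter-class
density correlation; calibrated once from the distance distribution of
random shape pairs, below its 5th percentile). Conformers displace points
by a fixed unit-RMS field of three long-wavelength sinusoidal modes scaled
by the amplitude (default 1.0 A RMS), so RMSD grows exactly linearly with
amplitude and per-point displacement is bounded (~10x amplitude). This is
a stand-in for normal-mode sampling: it preserves the statistical structure
(smooth low-frequency within-class deformation) but none of protein
energetics, fold statistics, mass heterogeneity, or real side-chain
density. Green benchmark tests therefore establish that the machinery
separates smooth-deformation classes of distinct shapes — not biological
retrieval accuracy.

Benchmark backends are trained on an independently seeded 10-class x
4-member benchmark: candidates (GEO-only, CN-only, full composite; two
regularization strengths) are fitted on two-thirds of the training classes
and ranked by max-MCC on the held-out third, with a parsimony preference
(fewest parameters within 1e-3 of the best score); the winner is refitted
on all training pairs. Nesting the restricted models among the composite's
candidates guarantees the composite degrades gracefully to whichever
family carries the signal. On this synthetic world the geometric features
alone nearly saturate retrieval (classes differ in size and gross
anisotropy by construction), so the composite frequently reduces to the
GEO weighting — unlike on real fold data, where the moment components
carry most of the signal. The 3DZD backend is scored with plain Euclidean
distance (its classical use).

## Tolerances and degenerate inputs

- Moment/descriptor rotation-invariance tests use 2% relative L2 at 0.5 A
  grids; the error is dominated by voxelization and shrinks with the grid.
- Normalization-polynomial degeneracy: all coefficients below 1e-9 of the
  moment scale raises a degeneracy signal (callers fall back or flag);
  leading coefficients below 1e-12 of scale are deflated.
- Gaussian rasterization conserves mass to <1%; empty selections, coincident
  point sets (Rg = 0) and single-point geometric descriptors raise errors.
- Percentile convention: linear interpolation; kurtosis is Pearson
  (non-excess); principal axes from the unweighted covariance.

## Known limitations

- No local/partial matching; retrieval and alignment are global by design.
- Experimental density maps are not ingested (no contour/noise handling);
  volumes enter only through the rasterizer or as in-memory arrays.
- Descriptor values are tied to the embedded residue-width table; other
  implementations with different Gaussian fits produce shifted (but
  internally consistent) values.
- The shipped strict/relaxed search thresholds are calibrated on synthetic
  data and must be re-fitted for any real corpus.
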