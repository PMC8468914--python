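# Methods

This note documents the models, numerical choices and limitations of
`capsrom`: a space–time–parameter reduced-order model (ROM) of a
deformable capsule flowing along a square-section microchannel, trained on
a snapshot database and queried at arbitrary admissible parameter pairs
`theta = (Ca, beta)` with `Ca` the capillary number and `beta = a/l` the
confinement ratio.

## Problem setting and admissible domain

The physical problem is an inertialess fluid–structure interaction: a
capsule of radius `a`, enclosed by a Neo-Hookean membrane of surface shear
modulus `Gs` (area modulus `Ks = 3 Gs`), is advected by square-duct
Poiseuille flow of mean velocity `V`. Times are non-dimensionalized by the
shear rate `V/l`, lengths by `a`. The parameter box is
`Ca in [0.005, 0.2]`, `beta in [0.75, 1.2]`; above a critical capillary
number the membrane strain-softens and never reaches a steady shape. The
published boundary of that region is a figure, not a table, so the package
uses a stated synthetic stand-in, `Ca <= 0.27 - 0.125 beta`, chosen to
reproduce the qualitative trend (decreasing with confinement). It is a
property of the synthetic study only and is exposed as a replaceable
callable.

The duct profile is the classical odd-harmonic Fourier series with walls
at `x, y = +/- l/2`. Transcriptions of its closed-form normalization are
error-prone, so the implementation renormalizes the truncated series by its
*exact* term-wise mean, `sum (2/n^4)(1 - 2 tanh(n pi/2)/(n pi))`, which
enforces the defining property — the cross-sectional mean equals `V` — at
any truncation (51 odd harmonics by default; the profile is then converged
far below double precision away from the corners). Note that some
descriptions of the same geometry call `2l` the duct width; the code
follows the series' own scaling and never silently rescales.

## The synthetic full-order surrogate

No public capsule-flow snapshot database exists, so the pipeline is built
and validated against a kinematic surrogate that generates displacement and
velocity snapshots in closed form:

```
u(X, t) = (1 - e^(-t/tau)) [ (F - I) X + c g(X_z) e_z ] + U_c t e_z
F = diag(1 - q, 1 - q, (1 - q)^-2),   q   = q0 Ca beta
tau = tau0 / (1 + Ca),                c   = c0 Ca beta^2
g(X_z) = max(0, -X_z)^2,              U_c = duct centerline speed (V = 1)
```

with `v` the exact analytic time derivative. Defaults `q0 = 1.2`,
`tau0 = 0.8`, `c0 = 0.35` keep the deformation amplitude physical
(`q < 0.18` over the admissible domain) and reach steady state well before
the final time, as capsules in this regime do. The ingredients emulate the
features the ROM must capture: relaxation toward a parameter-dependent
steady shape, faster relaxation at higher `Ca`, a parachute-like rear
flattening growing with `Ca` and confinement, and steady translation.
`det F = 1`, so the deformation is volume-preserving exactly.

What the surrogate does *not* emulate: genuine membrane mechanics (no
force balance; tensions are available only as a post-processing law),
hydrodynamic wall interaction, shape-dependent translation speed (the
centerline speed is parameter-independent here), mesh-scale spatial
complexity (the fields are spatially low-rank by construction), and noise.
Consequently, passing tests demonstrate the correctness and stability of
the reduction machinery — not the physical fidelity one would obtain from
a boundary-integral/finite-element database, whose singular-value spectra
decay far more slowly.

Smoothness in `theta` is a hard requirement of the diffuse-approximation
stage, and the high-confinement pre-deformation protocol (spherical rest
shape below `beta = 0.95`, transverse semi-axes squeezed to `0.9 l` at or
above it) is discontinuous in `beta`. The package therefore evaluates the
learned fields on the shared spherical reference mesh for every
configuration — keeping the datacube infinitely smooth in `theta` — and
composes the pre-deformed reference purely geometrically at reconstruction
time, `x = X_ref(beta) + u`. The jump never enters any learned quantity.

## Offline stage

Each field's parametric stack (`3NxNt x Nc`) and spatial stack
(`3Nx x NtNc`) is decomposed; only the right modes of the former and the
left modes of the latter are needed, so each is computed from the
eigendecomposition of the smaller Gram matrix (`Nc x Nc`, resp.
`3Nx x 3Nx`). This is exact and deterministic — not a randomized or
iterative sketch — and roughly four times faster than a full LAPACK SVD of
the stacked matrix at validation scale. Modes whose singular values sit
below the square root of machine precision relative to the leading one
lose directional accuracy in this route (as they carry no information in
any route); they remain exactly orthonormal, and the coefficient matrices
project the data onto them, so downstream results are unaffected. The
standalone `truncated_svd` used everywhere else is a true LAPACK SVD.

SVD sign indeterminacy is removed by forcing the largest-magnitude entry of
every mode to be positive, making the whole offline stage bit-reproducible.
Relative information content is reported as *captured* energy
(`RIC(K) -> 1` as `K -> r`); the tail `1 - RIC(K)` drives tolerance-based
truncation. Default truncation ranks are 40/40 (displacement space /
parameter) and 50/50 (velocity), the reference operating point; a
tail-energy tolerance of `1e-7` is available as the alternative mode.

A two-rectangle parameter-domain clustering (split at `Ca = 0.10`, overlap
band 0.02, nearest-centroid assignment inside the band, lower id on ties)
is implemented but disabled by default (`n_clusters = 1`). Clustering
exists to cap memory at production database sizes; at desk scale it is
unnecessary, and a hard cluster edge inside the domain degrades
diffuse-approximation neighborhoods near the split. Enable it with
`n_clusters = 2` when memory requires it.

## Diffuse approximation

Both interpolation problems use the same engine: weighted least squares
with the compactly supported Wendland kernel `w(d) = 2d^3 - 3d^2 + 1` on
`[0, 1]` and a low-order polynomial basis.

*Parameter space.* Neighborhoods are ellipses in the anisotropic metric
`sqrt(dCa^2 + r~^2 dbeta^2)` with `r~ = 1.9`, reflecting the different
physical scales of the two axes. The support radius is set to the distance
of the `(M+1)`-th nearest sample so that all `M = 12` selected samples
carry strictly positive weight. The default basis is the full quadratic
(`m = 6`). Fits are performed in query-centered coordinates scaled by the
support radius — an affine change of variables that leaves every
prediction of a polynomial fit identical while keeping the normal matrix
well conditioned (raw monomials of `(Ca, beta)` over a 0.05-wide
neighborhood are catastrophically collinear). The solver works on the
square-root-weighted system with an orthogonal factorization; with zero
ridge it reproduces the closed-form normal-equation solution to 1e-10, and
a rank-deficient system (locally aligned samples) raises a conditioning
error rather than returning garbage. A scale-aware ridge
(`1e-12 tr(P^T W P)/m`) is on by default for robustness at domain corners.

*Time axis (manifold learning).* The velocity coordinates are regressed on
order-0/1 monomials of the displacement coordinates with temporal Wendland
weights of radius `2 dt` — so at most three snapshots support each fit,
while the regressor dimension is `mu + 1 = 11`. The system is generically
rank-deficient *by design of the reference parameters*; it is solved by
the minimum-norm least-squares solution after centering the non-constant
regressors by their kernel-weighted mean. Centering decouples the
intercept (constant data then loads entirely on it, with exactly zero
slope coefficients) and makes the fitted manifold interpolate the reduced
data at snapshot times to machine precision. If fewer than two snapshots
fall inside the window — which happens at `t = 0`, before the first
snapshot — the window is doubled until two do.

## Online stage and integration

Local bases are the leading `mu = mv = 10` left singular vectors of the
pseudo-snapshot matrices (ranks clamp with a warning when the matrices are
lower rank). The reduced dynamics

```
alpha^{i+1} = alpha^i + dt_rom Q xi^i,    Q = Phi_q^T Gamma_q
```

is stepped explicitly with `dt_rom = dt/2` by default (`dt` the snapshot
step; the reference configuration leaves the ROM step free). Initialization
is `alpha^0 = 0` and `xi^0` from the manifold evaluated at `t = 0` with
`alpha = 0`. Manifold coefficients are fitted lazily at each ROM time (a
moving window), not precomputed. A non-finite state aborts with the step
index; across the validation sweep the reduced energy stays bounded by the
data amplitude (asserted in tests with a hard ceiling).

The explicit update contributes an `O(dt_rom)` error during the
deformation transient that vanishes as the capsule reaches steady state
(the translation mode, with constant velocity coordinate, is integrated
exactly). Halving `dt_rom` roughly halves the transient error; at
`dt/16` the error floor of the diffuse-approximation reconstruction
(~3e-4 capsule radii on the validation database) is reached.

## Validation

Shape error is the modified Hausdorff distance — the maximum of the two
directed mean nearest-point distances — between predicted and reference
node sets, normalized by the capsule radius. Nearest neighbors use a k-d
tree and match the brute-force double loop exactly (no approximate
search).

The leave-one-out study removes each design configuration, rebuilds the
offline model from the rest, predicts the withheld parameter and scores
`d_MH/a` at times 1, 2, 4 and 8. The default validation database uses a
level-3 mesh (642 nodes), a 65-point design (`Ca` step 0.025 plus the
0.005 column, `beta` step 0.05) and 50 snapshots of step 0.2 — sizes
chosen so the full sweep completes in a few minutes while exercising every
stage at the reference parameter settings. Design points missing any of
their four Cartesian grid neighbors are classed as boundary points.

Measured behaviour on this database: interior-point mean error ~0.15% of
the capsule radius (well below the 1% acceptance bound), and the worst
errors over the design occur at boundary points, where one-sided
neighborhoods degrade the diffuse approximation. One caveat is stated
openly: the *class means* of boundary vs interior errors are confounded by
the surrogate's deformation-amplitude distribution — `q = q0 Ca beta`
peaks at interior points adjacent to the steady-state boundary, and the
transient integration error scales with `q` — so with the default ROM step
the interior mean can slightly exceed the boundary mean even though the
pure reconstruction error (integration switched off) is larger at the
boundary, as expected. The boundary effect is therefore asserted on the
worst-case location (the maximum error sits on the design boundary), which
is robust across ROM steps.

## Known limitations

- The surrogate's spatial rank is small; truncation-rank studies on it say
  nothing about the ranks a boundary-integral database would need.
- Error estimates are empirical (leave-one-out); there is no a-posteriori
  error bound on an individual online query.
- Query parameters must lie inside the admissible sampled region;
  extrapolation beyond the design is not guarded against beyond the
  admissibility check.
- The explicit update inherits a step-size/accuracy trade-off during the
  transient; no adaptive or higher-order ROM stepping is provided.
- Meshes are closed triangulated spheres by construction; imported meshes
  are validated only structurally (closedness is not re-checked on read).
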