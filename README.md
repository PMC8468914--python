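# capsrom

Data-driven, space–time–parameter reduced-order modeling of a deformable
microcapsule flowing along a square-section microchannel.

Micrometric capsules — liquid drops protected by a thin hyperelastic
membrane — are candidate drug-delivery vehicles. Their dynamics in a
channel of comparable size is a three-dimensional fluid–structure
interaction problem governed by two dimensionless numbers: the capillary
number `Ca = mu V / Gs` (viscous over membrane-elastic forces) and the
confinement ratio `beta = a / l` (capsule radius over channel half-width).
High-fidelity solvers take hours per configuration; `capsrom` builds a
reduced-order model (ROM) that, after an offline compression of a snapshot
database, predicts the full three-dimensional shape evolution at *any*
admissible `(Ca, a/l)` in milliseconds.

## The method

Given a datacube of nodal displacements `u` and velocities `v` over space
(3Nx degrees of freedom), time (Nt snapshots) and parameter (Nc design
configurations), the pipeline is:

**Offline.** Two rearrangements of the datacube are decomposed per field
`r in {u, v}`: the parametric stack `S_r (3NxNt x Nc)` yields discrete
parameter modes `Psi_r` (right singular vectors), the spatial stack
`T_r (3Nx x NtNc)` yields spatial modes `Phi_r`. Both are truncated by rank
or by relative information content `RIC(K) = sum_{k<=K} s_k^2 / sum s_k^2`,
and per-snapshot coefficient matrices

```
A(t_i) = Phi_u^T  u(., t_i, .)  Psi_u        (and B(t_i) for velocity)
```

compress the database to `Nt` small matrices.

**Online**, at a query `theta_q = (Ca, a/l)`:

1. *Diffuse approximation* (a moving-least-squares variant) interpolates the
   rows of `Psi_r` at `theta_q`: the `M = 12` nearest design samples in the
   anisotropic metric `sqrt(dCa^2 + r~^2 dbeta^2)` (anisotropy `r~ = 1.9`)
   are weighted by the Wendland kernel `w(d) = 2d^3 - 3d^2 + 1` and a local
   quadratic is fitted, giving coordinates `psi_u, psi_v`.
2. Pseudo-snapshots `U(theta_q)[:, i] = Phi_u A(t_i) psi_u` (and `V`) are
   assembled, and their SVDs give small local bases `Phi_q (mu = 10)` and
   `Gamma_q (mv = 10)`.
3. The displacement-to-velocity manifold `xi = M(t, alpha)` is learned from
   the reduced data cloud `alpha_D = Phi_q^T U`, `xi_D = Gamma_q^T V` by
   temporal diffuse approximation: at each time, a weighted fit of `xi` on
   `(1, alpha)` with Wendland weights of radius `2 dt`.
4. The low-order dynamical system is stepped explicitly with
   `Q = Phi_q^T Gamma_q`:

   ```
   alpha^{i+1} = alpha^i + dt_rom * Q xi^i,     xi^{i+1} = p(alpha^{i+1})^T a_k(t_{i+1})
   ```

   and shapes are reconstructed as `x = X_ref(beta) + Phi_q alpha(t)`.

Accuracy is scored with the modified Hausdorff distance between predicted
and reference surfaces, `d_MH(F, G) = max` of the two directed *mean*
nearest-point distances, normalized by the capsule radius.

Because no public capsule-flow snapshot database exists, the package ships
a synthetic full-order surrogate (`capsrom.surrogate`): a smooth, kinematic
snapshot generator with exponential relaxation toward a
parameter-dependent deformed shape, a parachute-like rear flattening and
steady translation at the duct centerline velocity. It defines the study
conditions for every test; see `docs/methods.md` for what it does and does
not emulate.

## Worked example

`examples/offline_online_demo.py` builds a coarse database (level-2 mesh,
79 design points, 40 snapshots), compresses it, and queries the ROM at
`theta = (0.11, 0.92)`, a parameter *not* in the design:

```
design of experiment: 79 admissible (Ca, a/l) samples
database: Nx=162, Nt=40, Nc=79 (3,071,520 stored doubles)
offline stage: global ranks {'k_u_x': 20, 'k_u_c': 20, 'k_v_x': 25, 'k_v_c': 25}
online stage at theta=(0.11, 0.92): 400 explicit steps, local ranks mu=8, mv=8

  t     |alpha|     d_MH/a vs truth
    1     26.798     0.223 %
    2     53.477     0.220 %
    4    106.821     0.190 %
    8    213.531     0.185 %
```

The trajectory norm grows linearly because the capsule translates down the
channel at the centerline speed (~2.096 mean velocities); the shape error
against the withheld synthetic truth stays near 0.2% of the capsule radius
through the deformation transient and at steady state.

The other examples cover mesh generation and I/O
(`build_capsule_mesh.py`), the duct-flow profile and Neo-Hookean membrane
tensions (`duct_flow_and_membrane.py`), and a leave-one-out error map
(`leave_one_out_validation.py`). A thin CLI wraps the same stages:

```sh
capsrom mesh --level 4 --out mesh.ply
capsrom build-db --config cfg.toml --out db/
capsrom offline  --config cfg.toml --db db/ --out model/
capsrom query    --config cfg.toml --model model/ --ca 0.10 --beta 0.90 --out traj/
capsrom validate --config cfg.toml --db db/ --out report/
capsrom run-all  --config cfg.toml --out run/        # all four stages + manifest
```

Databases persist as little-endian float64 arrays (`u.bin`, `v.bin`,
C order, node-major with (x, y, z) within node) plus `manifest.json`.

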