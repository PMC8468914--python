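"""Physical utility formulas: square-duct Poiseuille flow and Neo-Hookean
membrane tensions.

The duct profile drives the capsule translation in the synthetic database;
its mean over the cross-section is exactly the nominal velocity V by
construction.  The Neo-Hookean law maps principal surface stretches to
principal Cauchy tensions (zero in the undeformed state); it is the
constitutive model of the capsule membrane and is provided for
post-processing reconstructed shapes.
"""

import numpy as np

from capsrom import nh_tensions, poiseuille_square_velocity

center = poiseuille_square_velocity(0.0, 0.0, V=1.0)
print(f"centerline velocity for unit mean: {center:.4f} (peak/mean ratio of a square duct)")
print(f"velocity at the wall:              {poiseuille_square_velocity(0.5, 0.2):.1e}")

# Quadrature check that the cross-sectional mean equals V.
nodes, w = np.polynomial.legendre.leggauss(128)
x, wq = 0.5 * nodes, 0.5 * w
vals = poiseuille_square_velocity(x[:, None], x[None, :], V=1.0)
print(f"cross-sectional mean (quadrature): {float(wq @ vals @ wq):.12f}")

print()
for lam in (1.0, 1.2, 1.5):
    t1, t2 = nh_tensions(lam, lam, Gs=1.0)
    print(f"equibiaxial stretch {lam:.1f}: tension {float(t1):+.4f} Gs per unit length")
t1, t2 = nh_tensions(1.4, 0.9, Gs=1.0)
print(f"anisotropic stretch (1.4, 0.9): tau1={float(t1):+.4f} Gs, tau2={float(t2):+.4f} Gs")
print("(the under-stretched direction carries far less tension)")
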