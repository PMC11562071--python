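"""Unrelaxed torsional scans, curve fits, and 1D DVR eigenvalues.

Scans the methyl and backbone torsions of toy butane rigidly, fits the
methyl curve with A sin(3 phi - phi0) + a and the backbone curve with an
even polynomial in (theta - pi), classifies the stationary points, and
solves the 1D torsional Schroedinger equation on the fitted methyl curve.
"""

import numpy as np

import pipchain as pc
from pipchain.conformational_analysis import (chain_rotating_set,
                                              classify_stationary_points,
                                              dihedral, dvr_levels,
                                              fit_torsion,
                                              reduced_rotational_constant,
                                              scan_energies, scan_geometries)

ff = pc.ToyFF(4, pc.ToyFFParams(lj_enabled=False))
g0 = pc.build_alkane(4)
angles = np.linspace(0, 2 * np.pi, 73, endpoint=False)

# methyl torsion: rotate the C4 methyl hydrogens about the C3-C4 bond
methyl = scan_energies(ff, scan_geometries(g0, (2, 3), [11, 12, 13], angles))
fit3 = fit_torsion(methyl.angles, methyl.energies_cm, "threefold")
print("methyl torsion  A sin(3 phi - phi0) + a:")
print(f"  amplitude {fit3.params['amplitude']:.1f} cm^-1, "
      f"phi0 {fit3.params['phi0']:.3f} rad, offset "
      f"{fit3.params['offset']:.1f} cm^-1, residual RMS "
      f"{fit3.residual_rms:.2e}")
print(f"  barrier (2A) = {2 * fit3.params['amplitude']:.0f} cm^-1")

B = reduced_rotational_constant(g0, (2, 3), [11, 12, 13])
grid = np.linspace(0, 2 * np.pi, 201, endpoint=False)
levels = dvr_levels(fit3.predict(grid) - fit3.predict(grid).min(), B)
print(f"  rotational constant B = {B:.3f} cm^-1")
print("  lowest torsional levels (cm^-1):",
      " ".join(f"{v:.1f}" for v in levels[:6]))

# backbone torsion about C2-C3: the full far side rotates
backbone = scan_energies(ff, scan_geometries(
    g0, (1, 2), chain_rotating_set(4, (1, 2)), angles))
phi = np.array([dihedral(g, 0, 1, 2, 3) for g in backbone.geometries])
order = np.argsort(phi)
fit_even = fit_torsion(phi[order], backbone.energies_cm[order], "even_poly")
points = classify_stationary_points(fit_even)
print("\nbackbone torsion, even-polynomial fit, stationary points "
      "(angle rad, energy cm^-1):")
for label in ("GM", "LM", "TS1", "TS2"):
    for a, e in points[label]:
        print(f"  {label:3s} at {a:5.3f}: {e:8.1f}")
print("GM is the anti (zigzag) conformation; LM the gauche wells; TS1 the "
      "anti/gauche saddle; TS2 the cis barrier to free rotation.")
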