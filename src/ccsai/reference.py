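"""Deterministic low-dimensional reference results for validation.

These helpers compute free energies by direct numerical quadrature of
configuration integrals — a route entirely independent of the sampling
engine and the MBAR estimator, usable as an oracle at desk scale.

The canonical test case is a *trap pair*: two neutral LJ particles held
near the origin by an isotropic harmonic trap ``U_trap = k (r1^2 + r2^2)``
(no bond, so the pair interacts through LJ).  Annihilating the second
particle by serial atom insertion has the exact dimensionless free energy
difference

    f_off - f_on = ln(Z_on / Z_off)

with both configuration integrals reduced to three dimensions
(r1, r2, cos gamma) by the trap's spherical symmetry.
"""

from __future__ import annotations

import math

import numpy as np

from .common_core import CommonCoreMap, XParams
from .molecular_model import AtomRecord, build_system
from .sampling import KB

__all__ = [
    "trap_pair_system",
    "trap_pair_map",
    "trap_pair_quadrature_df",
    "harmonic_ratio_exact_df",
]


def trap_pair_system(epsilon: float = 0.3, sigma: float = 1.6,
                     trap_k: float = 0.5):
    """Two unbonded LJ particles in a harmonic trap."""
    atoms = [
        AtomRecord(0, "Ar", "P0", 0.0, epsilon, sigma),
        AtomRecord(1, "Ar", "P1", 0.0, epsilon, sigma),
    ]
    coords = np.array([[-1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    return build_system(atoms, [], [], label="trap_pair",
                        coordinates=coords, trap_k=trap_k)


def trap_pair_map() -> CommonCoreMap:
    """Identity map designating particle 1 as the junction to annihilate.

    With ``XParams(0, 0, 0)`` the single vdw stage of the generated path
    turns particle 1 into a true dummy (full annihilation)."""
    return CommonCoreMap(
        pairs=((0, 0), (1, 1)),
        cc_atoms_a=frozenset({0, 1}), cc_atoms_b=frozenset({0, 1}),
        dummy_region_a=frozenset(), dummy_region_b=frozenset(),
        label_a="trap_pair", label_b="trap_pair",
        junction_a=1, junction_b=1, template_a=1, template_b=1,
        x_params=XParams(0.0, 0.0, 0.0),
    )


def trap_pair_quadrature_df(epsilon: float = 0.3, sigma: float = 1.6,
                            trap_k: float = 0.5, temperature: float = 303.15,
                            n_radial: int = 240, n_angular: int = 120,
                            r_max: float = 6.0) -> float:
    """Dimensionless f(annihilated) - f(interacting) by Gauss-Legendre
    quadrature of both configuration integrals."""
    beta = 1.0 / (KB * temperature)
    xr, wr = np.polynomial.legendre.leggauss(n_radial)
    r = 0.5 * r_max * (xr + 1.0)
    wr = wr * 0.5 * r_max
    xc, wc = np.polynomial.legendre.leggauss(n_angular)
    r1 = r[:, None, None]
    r2 = r[None, :, None]
    c = xc[None, None, :]
    d = np.sqrt(np.maximum(r1**2 + r2**2 - 2.0 * r1 * r2 * c, 1e-12))
    sr6 = (sigma / d) ** 6
    v_lj = 4.0 * epsilon * (sr6 * sr6 - sr6)
    weight = (wr[:, None, None] * r1**2) * (wr[None, :, None] * r2**2) \
        * wc[None, None, :]
    z_on = 8.0 * math.pi**2 * float(np.sum(
        weight * np.exp(-beta * (trap_k * (r1**2 + r2**2) + v_lj))))
    single = float(np.sum(wr * r**2 * np.exp(-beta * trap_k * r**2)))
    z_off = (4.0 * math.pi * single) ** 2
    return math.log(z_on / z_off)


def harmonic_ratio_exact_df(k0: float, k1: float) -> float:
    """Exact dimensionless free energy difference between two harmonic
    wells ``U = k x^2``: half the log of the spring-constant ratio per
    coordinate."""
    return 0.5 * math.log(k1 / k0)
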