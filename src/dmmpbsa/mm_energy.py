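"""Intermolecular molecular-mechanics energies with docking-engine conventions.

Shifted Coulomb and switched Lennard-Jones interactions between receptor and
peptide atoms: an 8.5 A cutoff with the X-PLOR/CNS shift function on the
electrostatics and X-PLOR switching between 6.5 and 8.5 A on the van der Waals
term.  Only receptor-peptide pairs are summed; in the rigid end-point convention
the intramolecular (bonded) energies cancel in the binding difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .model_io import Structure

__all__ = ["NonbondedParams", "MMEnergy", "coulomb_shifted", "lj_switched", "intermolecular_mm"]

#: Coulomb constant e^2/(4 pi eps0) in kJ mol^-1 A e^-2
COULOMB_CONSTANT = 1389.354


@dataclass(frozen=True)
class NonbondedParams:
    """Cutoff scheme for the nonbonded pair sum.

    ``dielectric`` is the relative permittivity of the MM Coulomb term (1 by
    the explicit-water refinement convention); the implicit-solvent screening
    lives entirely in the Poisson-Boltzmann polar term.
    """

    cutoff: float = 8.5
    switch_on: float = 6.5
    dielectric: float = 1.0
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self) -> None:
        if not (0 < self.switch_on < self.cutoff):
            raise ValueError(f"need 0 < switch_on < cutoff, got {self.switch_on}, {self.cutoff}")
        if self.dielectric < 1:
            raise ValueError(f"dielectric must be >= 1, got {self.dielectric}")


@dataclass(frozen=True)
class MMEnergy:
    e_coul: float  # kJ/mol
    e_lj: float    # kJ/mol

    def __post_init__(self) -> None:
        if not (math.isfinite(self.e_coul) and math.isfinite(self.e_lj)):
            raise ValueError("MM energies must be finite")


def coulomb_shifted(q1, q2, r, params: NonbondedParams = NonbondedParams()):
    """Shifted Coulomb energy C q1 q2/(eps r) * (1 - (r/r_c)^2)^2, 0 beyond r_c.

    The shift factor makes the energy and its first derivative vanish at the
    cutoff.  Accepts scalars or broadcastable arrays; r must be positive.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("interatomic distance must be > 0")
    rc = params.cutoff
    shift = np.where(r < rc, (1.0 - (r / rc) ** 2) ** 2, 0.0)
    e = params.coulomb_constant * np.asarray(q1) * np.asarray(q2) / (params.dielectric * r) * shift
    return float(e) if e.ndim == 0 else e


def switch_factor(r, params: NonbondedParams = NonbondedParams()):
    """X-PLOR switching function S(r): 1 below switch_on, 0 beyond cutoff.

    S(r) = (rc^2 - r^2)^2 (rc^2 + 2 r^2 - 3 ron^2) / (rc^2 - ron^2)^3 on the
    switching window; cubic in r^2, continuously differentiable at both ends.
    """
    r = np.asarray(r, dtype=float)
    rc2, ron2 = params.cutoff**2, params.switch_on**2
    r2 = r**2
    s = (rc2 - r2) ** 2 * (rc2 + 2.0 * r2 - 3.0 * ron2) / (rc2 - ron2) ** 3
    s = np.where(r2 <= ron2, 1.0, np.where(r2 >= rc2, 0.0, s))
    return float(s) if s.ndim == 0 else s


def lj_switched(sigma, epsilon, r, params: NonbondedParams = NonbondedParams()):
    """Switched Lennard-Jones energy 4 eps [(sig/r)^12 - (sig/r)^6] * S(r)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("interatomic distance must be > 0")
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("LJ sigma must be >= 0")
    epsilon = np.asarray(epsilon, dtype=float)
    if np.any(epsilon < 0):
        raise ValueError("LJ epsilon must be >= 0")
    sr6 = (sigma / r) ** 6
    e = 4.0 * epsilon * (sr6**2 - sr6) * switch_factor(r, params)
    return float(e) if e.ndim == 0 else e


def intermolecular_mm(
    receptor: Structure, peptide: Structure, params: NonbondedParams = NonbondedParams()
) -> MMEnergy:
    """Pairwise receptor-peptide Coulomb and LJ energies (kJ/mol).

    Vectorised over the full receptor x peptide distance matrix; pairs beyond
    the cutoff contribute exactly zero.  LJ cross parameters use geometric-mean
    combination for both sigma and epsilon (OPLS convention).
    """
    sig_r, eps_r = receptor.lj_params()
    sig_p, eps_p = peptide.lj_params()
    d = cdist(receptor.coords, peptide.coords)
    if np.any(d <= 0):
        raise ValueError("receptor and peptide share an atom position (zero distance)")
    within = d < params.cutoff
    if not np.any(within):
        return MMEnergy(0.0, 0.0)
    qq = np.outer(receptor.charges, peptide.charges)
    e_coul = float(np.sum(coulomb_shifted(qq[within], 1.0, d[within], params)))
    sig = np.sqrt(np.outer(sig_r, sig_p))
    eps = np.sqrt(np.outer(eps_r, eps_p))
    e_lj = float(np.sum(lj_switched(sig[within], eps[within], d[within], params)))
    return MMEnergy(e_coul, e_lj)
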