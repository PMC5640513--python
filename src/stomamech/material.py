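"""Transversely isotropic Veronda-Westmann hyperelasticity for the guard-cell wall.

The wall is modeled as an isotropic polysaccharide matrix reinforced by a
single family of stiff cellulose microfibrils (CMFs) wound circumferentially
around the guard-cell tube.  The matrix follows the Veronda-Westmann form

    W_m = C1 (exp(C2 (I1 - 3)) - 1) - (C1 C2 / 2) (I2 - 3)

on the deviatoric invariants, the fibers a piecewise toe/linear law specified
through lambda * W_f'(lambda):

    lambda W_f'(lambda) = 0                              lambda <= 1
                        = C3 (exp(C4 (lambda - 1)) - 1)  1 < lambda < lambda*
                        = C5 lambda + C6                 lambda >= lambda*

with C6 solved for stress continuity at the straightening stretch lambda*.
Fibers carry no compression.  Near-incompressibility is imposed with a
volumetric penalty U(J) = K/2 (ln J)^2.

Units: stresses and moduli in MPa, lengths cancel (the energy is per unit
reference volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expi

__all__ = [
    "MaterialParams",
    "DeformationState",
    "strain_invariants",
    "strain_energy",
    "cauchy_stress",
    "fiber_energy",
    "fiber_stress_scale",
]


class InvertedElementError(ValueError):
    """det F <= 0: the deformation maps material onto itself."""


@dataclass(frozen=True)
class MaterialParams:
    """Veronda-Westmann matrix + circumferential fiber parameters.

    The shipped defaults are *calibration* values: they were chosen so that
    the baseline guard-cell model reproduces the qualitative aperture-pressure
    landmarks (opening near 1.3 MPa, plateau above 5 MPa) and are not
    literature measurements.
    """

    c1: float = 1.0       # MPa, matrix exponential scale
    c2: float = 3.0       # -, matrix exponent
    c3: float = 0.5       # MPa, fiber toe scale
    c4: float = 5.0       # -, fiber toe exponent
    c5: float = 50.0      # MPa, fiber post-straightening modulus
    lam_star: float = 1.05  # -, fiber straightening stretch
    k_bulk: float = field(default=None)  # MPa, volumetric penalty; default 50*c1

    def __post_init__(self):
        if self.k_bulk is None:
            object.__setattr__(self, "k_bulk", 50.0 * self.c1)
        if not (self.c1 > 0 and self.k_bulk > 0):
            raise ValueError("C1 and K_bulk must be positive")
        if not (self.c2 > 0 and self.c4 > 0):
            raise ValueError("C2 and C4 must be positive")
        if self.c3 < 0 or self.c5 < 0:
            raise ValueError("C3 and C5 must be non-negative")
        if self.lam_star < 1.0:
            raise ValueError("lambda* must be >= 1")

    @property
    def c6(self) -> float:
        """Continuity constant of the linear fiber branch at lambda*."""
        return (self.c3 * (np.exp(self.c4 * (self.lam_star - 1.0)) - 1.0)
                - self.c5 * self.lam_star)

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialParams":
        keys = {"c1", "c2", "c3", "c4", "c5", "lam_star", "k_bulk"}
        return cls(**{k: float(v) for k, v in d.items() if k in keys})


@dataclass
class DeformationState:
    """A deformation gradient plus the reference fiber direction.

    Invariants (I1, I2 deviatoric, fiber stretch lambda = |F a0|, J = det F)
    are computed on construction.
    """

    F: np.ndarray
    a0: np.ndarray

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        self.a0 = np.asarray(self.a0, dtype=float)
        if self.F.shape != (3, 3):
            raise ValueError("F must be 3x3")
        if not np.isclose(np.linalg.norm(self.a0), 1.0, atol=1e-8):
            raise ValueError("a0 must be a unit vector")
        self.I1, self.I2, self.lam, self.J = strain_invariants(self.F, self.a0)


def strain_invariants(F: np.ndarray, a0: np.ndarray):
    """Kinematic invariants (I1, I2, lambda, J).

    I1 and I2 are the first two invariants of the deviatoric right
    Cauchy-Green tensor C_bar = J^(-2/3) F^T F; lambda = |F a0| is the total
    fiber stretch; J = det F.
    """
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise InvertedElementError(f"det F = {J:.3g} <= 0")
    C = F.T @ F
    Cbar = J ** (-2.0 / 3.0) * C
    I1 = float(np.trace(Cbar))
    I2 = 0.5 * (I1 ** 2 - float(np.trace(Cbar @ Cbar)))
    lam = float(np.linalg.norm(F @ np.asarray(a0, dtype=float)))
    return I1, I2, lam, J


# -- fiber law helpers (shared with the membrane solver; vectorized in lambda)

def fiber_stress_scale(lam, p: MaterialParams):
    """lambda * W_f'(lambda): the fiber stress magnitude scale (MPa)."""
    lam = np.asarray(lam, dtype=float)
    out = np.zeros_like(lam)
    toe = (lam > 1.0) & (lam < p.lam_star)
    lin = lam >= p.lam_star
    if p.c3 > 0.0:
        out = np.where(toe, p.c3 * (np.exp(p.c4 * (lam - 1.0)) - 1.0), out)
    if p.c5 > 0.0 or p.c3 > 0.0:
        out = np.where(lin, p.c5 * lam + p.c6, out)
    return out


def fiber_energy(lam, p: MaterialParams):
    """Fiber strain energy W_f(lambda) per unit reference volume (MPa).

    The toe integral of C3 (exp(C4 (s-1)) - 1) / s is expressed with the
    exponential integral Ei.
    """
    lam = np.asarray(lam, dtype=float)
    out = np.zeros_like(lam)
    if p.c3 == 0.0 and p.c5 == 0.0:
        return out if out.ndim else float(out)

    def toe_energy(x):
        return p.c3 * (np.exp(-p.c4) * (expi(p.c4 * x) - expi(p.c4))
                       - np.log(x))

    ls = p.lam_star
    toe = (lam > 1.0) & (lam < ls)
    lin = lam >= ls
    if np.any(toe):
        out = np.where(toe, toe_energy(np.where(toe, lam, 1.0)), out)
    if np.any(lin):
        w_star = toe_energy(ls) if ls > 1.0 else 0.0
        lam_safe = np.where(lin, lam, ls)
        out = np.where(lin, w_star + p.c5 * (lam_safe - ls)
                       + p.c6 * np.log(lam_safe / ls), out)
    return out if out.ndim else float(out)


def strain_energy(state: DeformationState, p: MaterialParams) -> float:
    """Strain-energy density W (MPa) at a deformation state."""
    I1, I2, lam, J = state.I1, state.I2, state.lam, state.J
    w_matrix = (p.c1 * (np.exp(p.c2 * (I1 - 3.0)) - 1.0)
                - 0.5 * p.c1 * p.c2 * (I2 - 3.0))
    w_vol = 0.5 * p.k_bulk * np.log(J) ** 2
    return float(w_matrix + fiber_energy(lam, p) + w_vol)


def _dev(t: np.ndarray) -> np.ndarray:
    return t - np.trace(t) / 3.0 * np.eye(3)


def cauchy_stress(state: DeformationState, p: MaterialParams) -> np.ndarray:
    """Cauchy stress tensor (MPa), symmetric, zero at the identity.

    Standard push-forward of the uncoupled deviatoric/volumetric split:
    sigma = (2/J) dev[(W1 + I1 W2) b_bar - W2 b_bar^2]
          + (lambda W_f'(lambda) / J) a_hat (x) a_hat
          + K ln J / J I
    with b_bar = J^(-2/3) F F^T and a_hat the deformed fiber direction.
    """
    F, a0 = state.F, state.a0
    J = state.J
    bbar = J ** (-2.0 / 3.0) * (F @ F.T)
    I1 = state.I1
    W1 = p.c1 * p.c2 * np.exp(p.c2 * (I1 - 3.0))
    W2 = -0.5 * p.c1 * p.c2
    sig = (2.0 / J) * _dev((W1 + I1 * W2) * bbar - W2 * (bbar @ bbar))
    lam = state.lam
    if lam > 1.0 and (p.c3 > 0.0 or p.c5 > 0.0):
        a = F @ a0 / lam
        sig = sig + (fiber_stress_scale(lam, p) / J) * np.outer(a, a)
    sig = sig + (p.k_bulk * np.log(J) / J) * np.eye(3)
    return 0.5 * (sig + sig.T)
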