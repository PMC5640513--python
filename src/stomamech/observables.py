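"""Measured quantities of the stomatal model: aperture, lengths, opening
threshold, effective (von-Mises-type) strain/stress scalars, and the
theoretical maximum pore area.

Aperture is the transverse (y) gap between the two deformed ventral walls,
measured where the equatorial ring crosses the long-axis midplane (x ~ 0);
for the undeformed elliptical pore this is the pore width at its widest
point, matching how apertures are measured on micrographs.  Complex length
is the long-axis extent over all nodes; pore length the long-axis extent of
the deformed ventral pore rim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SurfaceMesh
from .solver import EquilibriumState

__all__ = [
    "ApertureCurve",
    "measure_dimensions",
    "opening_threshold",
    "effective_measures",
    "theoretical_max_aperture",
    "curve_from_states",
    "plateau_onset",
]


@dataclass
class ApertureCurve:
    """Aperture/length observables along a pressurization path."""

    p_gc: np.ndarray           # MPa, strictly increasing
    aperture: np.ndarray       # um
    complex_length: np.ndarray  # um
    pore_length: np.ndarray    # um
    p_epi_max: float = 0.5     # MPa, end of the co-ramp phase

    def __post_init__(self):
        self.p_gc = np.asarray(self.p_gc, float)
        self.aperture = np.asarray(self.aperture, float)
        self.complex_length = np.asarray(self.complex_length, float)
        self.pore_length = np.asarray(self.pore_length, float)
        n = len(self.p_gc)
        if not (len(self.aperture) == len(self.complex_length)
                == len(self.pore_length) == n):
            raise ValueError("curve arrays must have equal length")
        if n and np.any(np.diff(self.p_gc) <= 0):
            raise ValueError("P_gc must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "P_gc_MPa": self.p_gc,
            "aperture_um": self.aperture,
            "complex_length_um": self.complex_length,
            "pore_length_um": self.pore_length,
        })

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def measure_dimensions(state: EquilibriumState, mesh: SurfaceMesh):
    """(aperture, complex_length, pore_length) in um for one state."""
    if not state.converged:
        raise ValueError("refusing to measure a non-converged state")
    x = mesh.nodes + state.u
    complex_length = float(x[:, 0].max() - x[:, 0].min())
    va = mesh.node_sets["ventral_equator_0"]
    vb = mesh.node_sets["ventral_equator_1"]
    pore_length = float(x[va][:, 0].max() - x[va][:, 0].min())
    # gap across the long-axis midplane (reference x ~ 0 on the ventral rim)
    mida = va[np.abs(mesh.nodes[va][:, 0]) < 1e-6]
    midb = vb[np.abs(mesh.nodes[vb][:, 0]) < 1e-6]
    if len(mida) == 0 or len(midb) == 0:
        raise ValueError("mesh has no ventral nodes on the long-axis midplane")
    gap = float(x[mida][:, 1].min() - x[midb][:, 1].max())
    # a closed pore has zero aperture; a (slightly) negative gap is just
    # residual contact-penalty penetration of the touching ventral walls
    aperture = max(gap, 0.0)
    return aperture, complex_length, pore_length


def curve_from_states(states, mesh: SurfaceMesh,
                      p_epi_max: float | None = None) -> ApertureCurve:
    rows = [measure_dimensions(s, mesh) for s in states]
    ap, cl, pl = (np.array(v) for v in zip(*rows))
    pe = max(s.p_epi for s in states) if p_epi_max is None else p_epi_max
    return ApertureCurve(np.array([s.p_gc for s in states]), ap, cl, pl,
                         p_epi_max=pe)


def opening_threshold(curve: ApertureCurve, epsilon: float | None = None):
    """Smallest P_gc at which the aperture exceeds its end-of-co-ramp value
    by epsilon (default: 1% of the total aperture gain), linearly
    interpolated.  Returns None when the stoma never opens."""
    if len(curve.p_gc) == 0:
        raise ValueError("empty curve")
    after = curve.p_gc >= curve.p_epi_max - 1e-12
    if not np.any(after):
        after = np.ones_like(curve.p_gc, bool)
    i0 = int(np.argmax(after))
    ap_ref = curve.aperture[i0]
    gain = float(curve.aperture.max() - ap_ref)
    if gain <= 0.0:
        return None
    eps = 0.01 * gain if epsilon is None else epsilon
    target = ap_ref + eps
    ap = curve.aperture
    for i in range(i0, len(ap)):
        if ap[i] > target:
            if i == 0:
                return float(curve.p_gc[0])
            p0, p1 = curve.p_gc[i - 1], curve.p_gc[i]
            a0, a1 = ap[i - 1], ap[i]
            if a1 == a0:
                return float(p1)
            return float(p0 + (target - a0) / (a1 - a0) * (p1 - p0))
    return None


def plateau_onset(curve: ApertureCurve, slope_fraction: float = 0.01):
    """First pressure after which the aperture gain per MPa stays below
    ``slope_fraction`` of the total gain; None if the curve never flattens."""
    ap, p = curve.aperture, curve.p_gc
    after = p >= curve.p_epi_max - 1e-12
    i0 = int(np.argmax(after))
    gain = float(ap.max() - ap[i0])
    if gain <= 0.0 or len(p) < 3:
        return None
    slopes = np.diff(ap) / np.diff(p)
    thresh = slope_fraction * gain
    below = slopes < thresh
    for i in range(i0, len(slopes)):
        if np.all(below[i:]):
            return float(p[i])
    return None


def effective_measures(state: EquilibriumState, cap_strain: bool = False):
    """Per-element effective (von-Mises-type) scalars.

    effective stress = sqrt(3/2 s:s) with s = dev(sigma);
    effective strain = sqrt(2/3 E':E') with E' = dev(E).
    The optional cap clamps the strain at 1 for plotting parity.
    """
    def dev(T):
        tr = np.trace(T, axis1=1, axis2=2)
        return T - tr[:, None, None] / 3.0 * np.eye(3)

    s = dev(state.cauchy)
    eff_stress = np.sqrt(1.5 * np.einsum("mij,mij->m", s, s))
    e = dev(state.green_strain)
    eff_strain = np.sqrt(np.maximum(
        2.0 / 3.0 * np.einsum("mij,mij->m", e, e), 0.0))
    if cap_strain:
        eff_strain = np.minimum(eff_strain, 1.0)
    return eff_strain, eff_stress


def theoretical_max_aperture(l: float) -> float:
    """Theoretical maximal pore area a_max = 0.25 pi l^2 (um^2) for a pore
    of fully open length l (um)."""
    if l < 0:
        raise ValueError("pore length must be non-negative")
    return 0.25 * np.pi * l * l
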