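"""Synthetic force-volume maps with known ground-truth stiffness patterns.

The generator emulates plasmolysed-leaf stomatal maps: a soft pavement-cell
background with stiff wall ridges laid out on the stomatal outline.  Stage
presets:

* ``gmc``    - guard mother cell: three wall ridges of equal modulus (the
  two outline walls and the new dividing wall along the long axis).
* ``young``  - two guard cells, inner and outer radial wall ridges of equal
  modulus, stiff polar caps.
* ``mature`` - inner radial wall stiffer than outer, stiff polar caps.

Preset moduli are chosen so the analysis pipeline recovers the study's
target statistics (e.g. a true diameter-transect gradient of
(10 - 6) MPa / 1.0 um = 4 MPa/um for the mature preset); they are synthetic
values, not measurements.  Because the tissue is plasmolysed, turgor makes
no contribution and the sample is treated as topography-free: stiffness
contrast alone generates the signal.

Forward model per pixel: pyramidal Hertz contact at the local modulus, run
up to the force setpoint (or to the maximum ramp depth, in which case the
pixel is flagged saturated), with cantilever bending included, plus
baseline tilt/offset, deflection noise and contact-point jitter.  Curves
are emitted uncalibrated (volts) so the full analysis chain is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .afm import AfmConfig, ForceMap

__all__ = [
    "GroundTruthPattern",
    "NoiseModel",
    "make_ground_truth",
    "simulate_force_map",
    "STAGE_PRESETS",
    "default_pose",
]

STAGE_PRESETS: Dict[str, dict] = {
    "mature": dict(E_bg=2.0, E_inner=10.0, E_outer=6.0, E_pole=12.0,
                   wall_separation_um=1.0),
    "young": dict(E_bg=2.0, E_inner=8.0, E_outer=8.0, E_pole=12.0,
                  wall_separation_um=1.0),
    "gmc": dict(E_bg=2.0, E_inner=8.0, E_outer=8.0, E_pole=None,
                wall_separation_um=1.0),
}


def default_pose(stage: str, map_size_um: float) -> dict:
    """Centered stoma pose; mature stomata are longer than wide, young ones
    nearly isodiametric, GMCs small."""
    c = 0.5 * map_size_um
    axes = {"mature": (12.0, 7.0), "young": (7.0, 6.0),
            "gmc": (4.0, 3.2)}[stage]
    return {"center": (c, c), "semi_axes": axes, "angle": 0.0}


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition noise; identical seed -> identical map."""

    deflection_noise_nN: float = 10.0   # 1% of the 1000 nN setpoint
    contact_jitter_nm: float = 5.0
    tilt_slope_nN_per_nm: float = 0.01  # baseline tilt drawn in +- this
    offset_nN: float = 20.0             # baseline offset drawn in +- this
    modulus_jitter_rel: float = 0.05    # per-pixel multiplicative SD
    seed: int = 0

    def __post_init__(self):
        for name in ("deflection_noise_nN", "contact_jitter_nm",
                     "tilt_slope_nN_per_nm", "offset_nN",
                     "modulus_jitter_rel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruthPattern:
    """Continuous 2-D apparent-modulus field for one stoma."""

    stage: str
    pose: dict
    E_bg: float
    E_inner: float
    E_outer: float
    E_pole: Optional[float]
    wall_separation_um: float = 1.0
    ridge_sigma_um: float = 0.30
    pole_sigma_um: float = 0.8
    field_size_um: float = 30.0
    _polylines: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.stage not in STAGE_PRESETS:
            raise ValueError(f"unknown stage {self.stage!r}")
        for v in (self.E_bg, self.E_inner, self.E_outer):
            if v is None or v <= 0:
                raise ValueError("moduli must be positive")
        if self.stage == "mature" and not self.E_inner > self.E_outer:
            raise ValueError("mature preset requires E_inner > E_outer")
        if self.stage == "young" and self.E_inner != self.E_outer:
            raise ValueError("young preset requires E_inner == E_outer")
        a, b = self.pose["semi_axes"]
        cx, cy = self.pose["center"]
        margin = max(a, b) + 3.0 * self.ridge_sigma_um
        if (cx - margin < 0 or cx + margin > self.field_size_um
                or cy - margin < 0 or cy + margin > self.field_size_um):
            raise ValueError("stoma outline extends outside the field")
        self._build_polylines()

    # -- geometry ----------------------------------------------------------
    def _frame(self):
        ang = float(self.pose.get("angle", 0.0))
        return np.cos(ang), np.sin(ang)

    def _to_world(self, u, v):
        """(u along long axis, v along short axis) -> map coordinates."""
        ca, sa = self._frame()
        cx, cy = self.pose["center"]
        return cx + u * ca - v * sa, cy + u * sa + v * ca

    def _build_polylines(self):
        a, b = self.pose["semi_axes"]
        t = np.linspace(0.0, 2.0 * np.pi, 512)
        self._polylines = []

        def ellipse(aa, bb, amp):
            u, v = aa * np.cos(t), bb * np.sin(t)
            x, y = self._to_world(u, v)
            self._polylines.append((np.stack([x, y], 1), amp))

        sep = self.wall_separation_um
        ellipse(a, b, self.E_outer - self.E_bg)                    # outer walls
        ellipse(max(a - sep, 0.5), max(b - sep, 0.5),
                self.E_inner - self.E_bg)                          # inner walls
        if self.stage == "gmc":
            # new dividing wall along the long axis through the center
            u = np.linspace(-0.85 * a, 0.85 * a, 256)
            x, y = self._to_world(u, np.zeros_like(u))
            self._polylines.append((np.stack([x, y], 1),
                                    self.E_inner - self.E_bg))
        self._poles = None
        if self.E_pole is not None:
            xs, ys = self._to_world(np.array([-a, a]), np.zeros(2))
            self._poles = np.stack([xs, ys], 1)

    # -- evaluation --------------------------------------------------------
    def modulus_at(self, x, y) -> np.ndarray:
        """Ground-truth modulus (MPa) at map coordinates (um).

        The field is the background plus the largest of the Gaussian ridge
        and polar-cap contributions, so preset peak values are attained
        exactly on the wall centerlines.
        """
        x = np.asarray(x, float).ravel()
        y = np.asarray(y, float).ravel()
        pts = np.stack([x, y], 1)
        bump = np.zeros(len(pts))
        for line, amp in self._polylines:
            d2 = ((pts[:, None, :] - line[None, :, :]) ** 2).sum(-1)
            dmin = np.sqrt(d2.min(axis=1))
            bump = np.maximum(bump,
                              amp * np.exp(-0.5 * (dmin / self.ridge_sigma_um) ** 2))
        if self._poles is not None:
            amp = self.E_pole - self.E_bg
            for p in self._poles:
                d = np.linalg.norm(pts - p[None, :], axis=1)
                bump = np.maximum(
                    bump, amp * np.exp(-0.5 * (d / self.pole_sigma_um) ** 2))
        return self.E_bg + bump

    def raster(self, n: int) -> np.ndarray:
        pitch = self.field_size_um / n
        c = (np.arange(n) + 0.5) * pitch
        X, Y = np.meshgrid(c, c)
        return self.modulus_at(X, Y).reshape(n, n)

    def true_gradient(self) -> float:
        """(E_inner - E_outer) / wall-peak separation, MPa/um."""
        return (self.E_inner - self.E_outer) / self.wall_separation_um


def make_ground_truth(stage: str, pose: dict | None = None,
                      field_size_um: float = 30.0,
                      **overrides) -> GroundTruthPattern:
    """Stage preset -> ground-truth pattern (overrides replace preset
    values; pose defaults to a centered stoma)."""
    if stage not in STAGE_PRESETS:
        raise ValueError(f"unknown stage {stage!r}")
    kw = dict(STAGE_PRESETS[stage])
    kw.update(overrides)
    pose = pose or default_pose(stage, field_size_um)
    return GroundTruthPattern(stage=stage, pose=pose,
                              field_size_um=field_size_um, **kw)


def simulate_force_map(pattern: GroundTruthPattern, cfg: AfmConfig,
                       noise: NoiseModel, n_samples: int = 256,
                       precontact_nm: float = 500.0,
                       max_indent_nm: float = 1000.0) -> ForceMap:
    """Forward-model a force-volume acquisition over the pattern.

    Each approach runs until the force setpoint; pixels that would need
    more than ``max_indent_nm`` of indentation stop there instead and are
    flagged saturated in the metadata.  Deterministic given ``noise.seed``.
    """
    if pattern.field_size_um < cfg.map_size_um:
        raise ValueError("pattern field does not cover the map area")
    rng = np.random.default_rng(noise.seed)
    n = cfg.grid
    pitch = cfg.map_size_um / n
    c = (np.arange(n) + 0.5) * pitch
    X, Y = np.meshgrid(c, c)
    E = pattern.modulus_at(X, Y).reshape(n, n)
    if noise.modulus_jitter_rel > 0:
        E = E * np.exp(noise.modulus_jitter_rel
                       * rng.standard_normal((n, n)))
    k = cfg.spring_constant
    ce = cfg.hertz_prefactor * E                     # nN / nm^2
    delta_set = np.sqrt(cfg.setpoint_nN / ce)
    saturated = delta_set > max_indent_nm
    delta_end = np.minimum(delta_set, max_indent_nm)
    f_end = ce * delta_end ** 2
    z0 = precontact_nm + noise.contact_jitter_nm * rng.standard_normal((n, n))
    z_end = z0 + delta_end + f_end / k
    z = np.linspace(0.0, 1.0, n_samples)[None, None, :] * z_end[..., None]
    zp = np.maximum(z - z0[..., None], 0.0)
    q = ce[..., None] / k
    delta = (np.sqrt(1.0 + 4.0 * q * zp) - 1.0) / (2.0 * q)
    F = ce[..., None] * delta ** 2
    tilt = noise.tilt_slope_nN_per_nm * rng.uniform(-1, 1, (n, n, 1))
    offset = noise.offset_nN * rng.uniform(-1, 1, (n, n, 1))
    F = F + tilt * z + offset
    if noise.deflection_noise_nN > 0:
        F = F + noise.deflection_noise_nN * rng.standard_normal(F.shape)
    volts = F / (cfg.sensitivity * k)
    return ForceMap(z=z, deflection=volts, size_um=cfg.map_size_um,
                    calibrated=False,
                    meta={"stage": pattern.stage,
                          "pose": dict(pattern.pose),
                          "seed": noise.seed,
                          "true_gradient": pattern.true_gradient(),
                          "saturated_fraction": float(saturated.mean())})
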