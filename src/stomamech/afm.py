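"""AFM force-volume analysis: from raw approach curves to apparent-modulus
maps, stomatal transect profiles, and the radial stiffness-gradient
statistic.

Per-pixel pipeline (approach curves only): calibrate (V -> nN) ->
baseline/tilt correction on the pre-contact segment -> contact-point
detection (noise-threshold crossing with parabolic refinement) ->
indentation computation (cantilever bending subtracted) -> Hertzian fit for
a four-sided pyramidal tip,

    F = (tan(theta) / sqrt(2)) * (E_a / (1 - nu^2)) * delta^2,

yielding the apparent modulus E_a per pixel.  E_a is "apparent" because the
half-space assumptions of contact mechanics do not hold on a structured
leaf surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.stats import mannwhitneyu

__all__ = [
    "AfmConfig",
    "ForceCurve",
    "ForceMap",
    "EaMap",
    "TransectProfile",
    "calibrate_curve",
    "correct_baseline_tilt",
    "detect_contact_point",
    "compute_indentation",
    "fit_hertz_pyramid",
    "process_force_map",
    "extract_transect",
    "gradient_statistic",
    "mann_whitney_u",
    "hertz_force",
]

# quality flags
GOOD = 0
NO_BASELINE = 1
NO_CONTACT = 2
BAD_FIT = 3
TOO_FEW_POINTS = 4


@dataclass(frozen=True)
class AfmConfig:
    """Acquisition and analysis settings (defaults follow the nominal
    stomatal mapping protocol: 45 N/m lever, 1000 nN setpoint, 100 um maps
    at 128 x 128 points, sharp pyramidal tip)."""

    spring_constant: float = 45.0      # N/m
    sensitivity: float = 20.0          # nm/V deflection sensitivity
    tip_half_angle_deg: float = 17.5   # pyramid face half-angle
    setpoint_nN: float = 1000.0
    poisson: float = 0.5
    map_size_um: float = 100.0
    grid: int = 128
    fit_window: tuple = (0.10, 1.00)   # fraction of max indentation fitted
    contact_threshold_sd: float = 5.0  # noise SDs for contact detection

    def __post_init__(self):
        if self.spring_constant <= 0 or self.sensitivity <= 0 \
                or self.setpoint_nN <= 0:
            raise ValueError("k, sensitivity and setpoint must be positive")
        if not (0.0 < self.tip_half_angle_deg < 90.0):
            raise ValueError("tip half-angle must be in (0, 90) degrees")
        if not (0.0 <= self.poisson <= 0.5):
            raise ValueError("Poisson ratio must be in [0, 0.5]")

    @property
    def tan_theta(self) -> float:
        return float(np.tan(np.radians(self.tip_half_angle_deg)))

    @property
    def hertz_prefactor(self) -> float:
        """c in F = c * E_a * delta^2, with F in nN, delta in nm, E_a MPa."""
        # MPa * nm^2 = 1e6 Pa * 1e-18 m^2 = 1e-12 N = 1e-3 nN
        return self.tan_theta / np.sqrt(2.0) / (1.0 - self.poisson ** 2) * 1e-3

    @classmethod
    def from_dict(cls, d: dict) -> "AfmConfig":
        names = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        kw = {k: v for k, v in d.items() if k in names}
        if "fit_window" in kw:
            kw["fit_window"] = tuple(kw["fit_window"])
        if "grid" in kw:
            kw["grid"] = int(kw["grid"])
        return cls(**kw)


def hertz_force(delta_nm, E_MPa, cfg: AfmConfig):
    """Forward pyramidal Hertz model: force (nN) at indentation (nm)."""
    d = np.maximum(np.asarray(delta_nm, float), 0.0)
    return cfg.hertz_prefactor * E_MPa * d * d


@dataclass
class ForceCurve:
    """One approach curve: piezo extension z (nm, increasing toward the
    sample) and deflection (V if uncalibrated, nN once calibrated)."""

    z: np.ndarray
    deflection: np.ndarray
    calibrated: bool = False
    corrected: bool = False
    precontact_n: Optional[int] = None   # samples identified as pre-contact

    def __post_init__(self):
        self.z = np.asarray(self.z, float)
        self.deflection = np.asarray(self.deflection, float)
        if self.z.shape != self.deflection.shape or self.z.ndim != 1:
            raise ValueError("z and deflection must be equal-length 1-D")
        if len(self.z) >= 2 and np.any(np.diff(self.z) <= 0):
            raise ValueError("approach z must be strictly monotone")


@dataclass
class ForceMap:
    """Grid of approach curves on a physical square region."""

    z: np.ndarray            # (ny, nx, ns) nm
    deflection: np.ndarray   # (ny, nx, ns) V or nN
    size_um: float
    calibrated: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def grid(self):
        return self.z.shape[:2]

    def pixel_coords(self):
        ny, nx = self.grid
        dy = self.size_um / ny
        y = (np.arange(ny) + 0.5) * dy
        x = (np.arange(nx) + 0.5) * (self.size_um / nx)
        return np.meshgrid(x, y)

    def curve(self, iy, ix) -> ForceCurve:
        return ForceCurve(self.z[iy, ix], self.deflection[iy, ix],
                          calibrated=self.calibrated)


@dataclass
class EaMap:
    """Apparent-modulus image with per-pixel diagnostics."""

    Ea: np.ndarray           # (ny, nx) MPa, nan where masked
    contact_z0: np.ndarray   # nm
    delta_max: np.ndarray    # nm
    residual_rms: np.ndarray  # nN
    flag: np.ndarray         # int, GOOD = 0
    size_um: float
    meta: dict = field(default_factory=dict)

    @property
    def good_fraction(self) -> float:
        return float(np.mean(self.flag == GOOD))

    def pixel_pitch(self) -> float:
        return self.size_um / self.Ea.shape[0]


@dataclass
class TransectProfile:
    """E_a sampled along a path across or around a stoma."""

    s: np.ndarray            # um, arc length, strictly increasing
    Ea: np.ndarray           # MPa
    kind: str                # "diameter" | "circumference"
    anchor: dict = field(default_factory=dict)

    def __post_init__(self):
        self.s = np.asarray(self.s, float)
        self.Ea = np.asarray(self.Ea, float)
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("arc-length positions must be strictly increasing")


# ---------------------------------------------------------------------------
# per-curve operations


def calibrate_curve(raw: ForceCurve, cfg: AfmConfig) -> ForceCurve:
    """Convert photodiode voltage to force: F (nN) = V * s (nm/V) * k (N/m).

    nm * N/m = 1e-9 m * N/m = nN, so the arithmetic is unit-true.
    """
    if raw.calibrated:
        return raw
    if cfg.sensitivity <= 0 or cfg.spring_constant <= 0:
        raise ValueError("missing calibration constants")
    force = raw.deflection * cfg.sensitivity * cfg.spring_constant
    return replace(raw, deflection=force, calibrated=True)


def _precontact_region(curve: ForceCurve, frac: float = 0.3):
    """Initial guess at the pre-contact segment: the first ``frac`` of the
    approach (refined iteratively during baseline correction)."""
    n = len(curve.z)
    m = max(int(frac * n), 8)
    if m >= n:
        return None
    return slice(0, m)


def correct_baseline_tilt(curve: ForceCurve) -> ForceCurve:
    """Remove the virtual-deflection baseline.

    A least-squares line is fitted on the pre-contact segment and
    subtracted from the whole curve.  The segment is found iteratively:
    starting from the leading 30% of the approach, the fit window is shrunk
    to just before the first sustained excursion above the fit-residual
    noise, so a contact that begins inside the initial window does not bias
    the line.
    """
    if not curve.calibrated:
        raise ValueError("calibrate before baseline correction")
    seg = _precontact_region(curve)
    if seg is None:
        raise ValueError("curve too short for baseline identification")
    z, f = curve.z, curve.deflection
    end = seg.stop
    for _ in range(6):
        m, b = np.polyfit(z[:end], f[:end], 1)
        resid = f - (m * z + b)
        r = resid[:end]
        sd = max(1.4826 * float(np.median(np.abs(r - np.median(r)))), 1e-12)
        # first sustained excursion: 3 consecutive residuals above 3 sigma
        above = resid > 3.0 * sd
        runs = above[:-2] & above[1:-1] & above[2:]
        hits = np.where(runs)[0]
        if len(hits) == 0:
            break
        crossing = int(hits[0])
        if crossing <= 10:
            raise ValueError("no identifiable pre-contact region")
        new_end = max(int(0.8 * crossing), 8)
        if new_end >= end:
            break
        end = new_end
    m, b = np.polyfit(z[:end], f[:end], 1)
    resid = f - (m * z + b)
    # a virtual-deflection tilt is gentle (well below ~0.1 nN/nm); a slope
    # approaching the contact stiffness scale means the curve was already
    # in contact at the first sample
    if abs(m) > 0.5:
        raise ValueError("no identifiable pre-contact region "
                         "(baseline slope looks like contact)")
    out = replace(curve, deflection=resid)
    out.corrected = True
    out.precontact_n = end
    return out


def detect_contact_point(curve: ForceCurve,
                         cfg: AfmConfig | None = None) -> Optional[float]:
    """Contact point z0 (nm): first sustained crossing of c-sigma above the
    baseline noise, refined by parabolic back-extrapolation of the initial
    contact rise (F ~ (z - z0)^2 for a pyramidal tip).

    Returns None (no-contact) when the force never exceeds the threshold.
    """
    if not curve.corrected:
        raise ValueError("correct baseline before contact detection")
    c = (cfg.contact_threshold_sd if cfg is not None else 5.0)
    seg = (slice(0, curve.precontact_n) if curve.precontact_n
           else _precontact_region(curve))
    noise = float(np.std(curve.deflection[seg]))
    thresh = max(c * noise, 1e-12)
    f = curve.deflection
    above = f > thresh
    # sustained: a run of samples above threshold that stays above until
    # the end of the approach (isolated noise spikes are rejected)
    run = np.convolve(above.astype(float), np.ones(5), mode="full")[4:] >= 5
    idx = None
    for i in np.where(above & run)[0]:
        if np.mean(f[i:] > thresh) > 0.9:
            idx = int(i)
            break
    if idx is None or idx == 0:
        return None
    # parabolic refinement: fit F = a (z - z0)^2 on the early contact rise,
    # restricted to low forces where cantilever bending is negligible
    zi, fi = curve.z, f
    # fit window: walk back from the detection index toward the noise floor
    # (the samples nearest the vertex carry the most position information)
    # and forward through the bulk of the contact rise
    j = idx
    while j > 0 and fi[j - 1] > 2.0 * noise:
        j -= 1
    upper = fi[idx] + max(0.9 * (fi[-1] - fi[idx]), 10.0 * noise)
    k = idx
    while k < len(fi) - 1 and fi[k] < upper:
        k += 1
    if k - j >= 4:
        # hinge-model fit: F = a * max(z' - z0, 0)^2 with the cantilever
        # bending subtracted from the piezo position (z' = z - F/k_c, which
        # makes the contact branch exactly quadratic).  All samples up to
        # the window top enter, so the sub-noise region near contact
        # contributes collectively; z0 is the SSE minimizer over a
        # candidate grid, refined parabolically.
        k_c = cfg.spring_constant if cfg is not None else 45.0
        ff = fi[:k + 1]
        zz = zi[:k + 1] - np.maximum(ff, 0.0) / k_c
        # candidates must bracket the contact point; the SSE valley is
        # smooth and unimodal, so a coarse grid over the whole pre-window
        # range plus parabolic refinement suffices
        lo = zi[0]
        hi = zi[idx]
        def grid_best(lo_, hi_, n):
            zs = np.linspace(lo_, hi_, n)
            q2 = np.maximum(zz[None, :] - zs[:, None], 0.0) ** 2
            s_fq = q2 @ ff
            s_qq = np.einsum("cn,cn->c", q2, q2)
            valid = (s_qq > 0) & (s_fq > 0)
            if not np.any(valid):
                return None
            gain = np.where(valid, s_fq ** 2 / np.where(s_qq > 0, s_qq, 1.0),
                            -np.inf)
            i = int(np.argmax(gain))
            z0_ = float(zs[i])
            if 0 < i < n - 1 and np.isfinite(gain[i - 1]) \
                    and np.isfinite(gain[i + 1]):
                y0, y1, y2 = gain[i - 1:i + 2]
                denom = y0 - 2.0 * y1 + y2
                if denom < 0:
                    z0_ += 0.5 * (y0 - y2) / denom * (zs[1] - zs[0])
            return z0_, zs[1] - zs[0]

        if hi > lo:
            out = grid_best(lo, hi, 60)
            if out is not None:
                z0, step = out
                fine = grid_best(z0 - 1.5 * step, z0 + 1.5 * step, 25)
                if fine is not None:
                    z0 = fine[0]
                if zi[0] <= z0 <= hi:
                    return float(z0)
    # fall back to linear interpolation of the threshold crossing
    z_lo, z_hi = zi[idx - 1], zi[idx]
    f_lo, f_hi = fi[idx - 1], fi[idx]
    if f_hi == f_lo:
        return float(z_hi)
    return float(z_lo + (thresh - f_lo) / (f_hi - f_lo) * (z_hi - z_lo))


def compute_indentation(curve: ForceCurve, cfg: AfmConfig, z0: float):
    """(delta, F) pairs past contact: delta = (z - z0) - F/k, keeping
    delta >= 0 (the cantilever bending F/k is subtracted from the piezo
    travel; F in nN, k in N/m, so F/k is in nm)."""
    if cfg.spring_constant <= 0:
        raise ValueError("spring constant must be positive")
    mask = curve.z >= z0
    F = curve.deflection[mask]
    delta = (curve.z[mask] - z0) - F / cfg.spring_constant
    keep = delta >= 0.0
    return delta[keep], F[keep]


def fit_hertz_pyramid(delta, F, cfg: AfmConfig):
    """Least-squares Hertz fit F = c E_a delta^2 over the configured depth
    window; returns (E_a MPa or nan, diagnostics dict)."""
    delta = np.asarray(delta, float)
    F = np.asarray(F, float)
    diag = {"residual_rms": np.nan, "n_points": len(delta),
            "flag": GOOD, "delta_max": float(delta.max()) if len(delta) else 0.0}
    if len(delta) < 10:
        diag["flag"] = TOO_FEW_POINTS
        return np.nan, diag
    dmax = delta.max()
    lo, hi = cfg.fit_window
    win = (delta >= lo * dmax) & (delta <= hi * dmax)
    d, f = delta[win], F[win]
    if len(d) < 10:
        diag["flag"] = TOO_FEW_POINTS
        return np.nan, diag
    x = d * d
    denom = float(np.dot(x, x))
    if denom <= 0:
        diag["flag"] = BAD_FIT
        return np.nan, diag
    c_hat = float(np.dot(x, f)) / denom       # F = c_hat * delta^2
    Ea = c_hat / cfg.hertz_prefactor
    resid = f - c_hat * x
    diag["residual_rms"] = float(np.sqrt(np.mean(resid ** 2)))
    if Ea <= 0 or not np.isfinite(Ea):
        diag["flag"] = BAD_FIT
        return np.nan, diag
    return Ea, diag


# ---------------------------------------------------------------------------
# map-level operations


def process_force_map(fmap: ForceMap, cfg: AfmConfig,
                      warn_threshold: float = 0.5) -> EaMap:
    """Run the per-curve pipeline over every pixel of a force map."""
    ny, nx = fmap.grid
    Ea = np.full((ny, nx), np.nan)
    z0map = np.full((ny, nx), np.nan)
    dmax = np.full((ny, nx), np.nan)
    rrms = np.full((ny, nx), np.nan)
    flag = np.zeros((ny, nx), np.int64)
    for iy in range(ny):
        for ix in range(nx):
            curve = fmap.curve(iy, ix)
            if not curve.calibrated:
                curve = calibrate_curve(curve, cfg)
            try:
                curve = correct_baseline_tilt(curve)
            except ValueError:
                flag[iy, ix] = NO_BASELINE
                continue
            z0 = detect_contact_point(curve, cfg)
            if z0 is None:
                flag[iy, ix] = NO_CONTACT
                continue
            delta, F = compute_indentation(curve, cfg, z0)
            ea, diag = fit_hertz_pyramid(delta, F, cfg)
            Ea[iy, ix] = ea
            z0map[iy, ix] = z0
            dmax[iy, ix] = diag["delta_max"]
            rrms[iy, ix] = diag["residual_rms"]
            flag[iy, ix] = diag["flag"]
    out = EaMap(Ea, z0map, dmax, rrms, flag, fmap.size_um,
                meta={**fmap.meta,
                      "hertz": "four-sided pyramid",
                      "tip_half_angle_deg": cfg.tip_half_angle_deg,
                      "poisson": cfg.poisson})
    if out.good_fraction < warn_threshold:
        out.meta["warning"] = (f"only {100 * out.good_fraction:.0f}% of "
                               "pixels produced a good fit")
    return out


def _bilinear(img: np.ndarray, xs, ys, pitch: float):
    """Bilinear sampling of a pixel-centered image at physical (x, y) um."""
    fx = np.asarray(xs) / pitch - 0.5
    fy = np.asarray(ys) / pitch - 0.5
    x0 = np.clip(np.floor(fx).astype(int), 0, img.shape[1] - 2)
    y0 = np.clip(np.floor(fy).astype(int), 0, img.shape[0] - 2)
    tx = np.clip(fx - x0, 0.0, 1.0)
    ty = np.clip(fy - y0, 0.0, 1.0)
    v00 = img[y0, x0]
    v01 = img[y0, x0 + 1]
    v10 = img[y0 + 1, x0]
    v11 = img[y0 + 1, x0 + 1]
    return ((1 - ty) * ((1 - tx) * v00 + tx * v01)
            + ty * ((1 - tx) * v10 + tx * v11))


def extract_transect(eamap: EaMap, pose: dict, kind: str = "diameter",
                     spacing_um: float = 0.05,
                     extend_um: float = 2.0) -> TransectProfile:
    """Sample E_a along a stomatal transect by bilinear interpolation.

    ``pose``: {"center": (x, y) um, "semi_axes": (a, b) um, "angle": rad}
    with a the long (pole-to-pole) semi-axis.  "diameter" is the straight
    segment through the center along the short axis, extended by
    ``extend_um`` beyond the outline on both sides; "circumference" is the
    closed outline ellipse starting at the equator (short-axis point).
    """
    cx, cy = pose["center"]
    a, b = pose["semi_axes"]
    ang = float(pose.get("angle", 0.0))
    ca, sa = np.cos(ang), np.sin(ang)
    pitch = eamap.pixel_pitch()
    if kind == "diameter":
        half = b + extend_um
        s = np.arange(-half, half + 0.5 * spacing_um, spacing_um)
        xs = cx - s * sa
        ys = cy + s * ca
        s_out = s - s[0]
    elif kind == "circumference":
        per = 2.0 * np.pi * np.sqrt(0.5 * (a * a + b * b))
        n = max(int(per / spacing_um), 64)
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=True)
        # start at the equator: short-axis point (t measured from it)
        ex = b * np.cos(t)
        ey_ = a * np.sin(t)
        # (ex, ey_) in the rotated frame where +y is the long axis
        xs = cx + ex * ca - ey_ * sa
        ys = cy + ex * sa + ey_ * ca
        ds = np.hypot(np.diff(xs), np.diff(ys))
        s_out = np.concatenate([[0.0], np.cumsum(ds)])
    else:
        raise ValueError(f"unknown transect kind {kind!r}")
    size = eamap.size_um
    if np.any(xs < 0) or np.any(xs > size) or np.any(ys < 0) or np.any(ys > size):
        raise ValueError("transect path exits the map")
    Ea = _bilinear(eamap.Ea, xs, ys, pitch)
    return TransectProfile(s_out, Ea, kind,
                           anchor={"pose": dict(pose), "spacing_um": spacing_um})


def _detect_wall_peaks(profile: TransectProfile,
                       min_separation_um: float = 0.5,
                       prominence_frac: float = 0.05,
                       smooth_um: float = 0.15):
    """Wall peaks: local maxima of the lightly smoothed profile with
    prominence >= 5% of the profile range and >= 0.5 um separation."""
    Ea = np.nan_to_num(profile.Ea, nan=float(np.nanmin(profile.Ea)))
    ds = float(np.mean(np.diff(profile.s)))
    sm = gaussian_filter1d(Ea, max(smooth_um / ds, 1e-6))
    rng = float(sm.max() - sm.min())
    if rng <= 0:
        return np.array([], int), {"prominences": np.array([])}
    peaks, props = find_peaks(sm, prominence=prominence_frac * rng,
                              distance=max(int(min_separation_um / ds), 1))
    return peaks, props


def _peak_height(profile: TransectProfile, idx: int,
                 window_um: float = 0.15) -> float:
    """Max raw E_a in a small window around a detected peak position."""
    ds = float(np.mean(np.diff(profile.s)))
    w = max(int(window_um / ds), 1)
    lo, hi = max(idx - w, 0), min(idx + w + 1, len(profile.Ea))
    return float(np.nanmax(profile.Ea[lo:hi]))


def gradient_statistic(profile: TransectProfile) -> Optional[float]:
    """Radial stiffness gradient (MPa/um) from a diameter transect.

    Per guard cell: (max E_a at the inner wall peak - max E_a at the outer
    wall peak) / distance between those peaks; the per-stoma value is the
    mean over the two guard cells.  Requires the four wall peaks
    (outer-A, inner-A, inner-B, outer-B); returns None when fewer than four
    peaks are detected (e.g. the three-walled GMC pattern).
    """
    if profile.kind != "diameter":
        raise ValueError("gradient statistic is defined on diameter transects")
    peaks, props = _detect_wall_peaks(profile)
    if len(peaks) < 4:
        return None
    if len(peaks) > 4:
        order = np.argsort(props["prominences"])[::-1][:4]
        peaks = np.sort(peaks[order])
    s = profile.s
    outer_a, inner_a, inner_b, outer_b = peaks
    grads = []
    for inner, outer in ((inner_a, outer_a), (inner_b, outer_b)):
        d = abs(s[inner] - s[outer])
        if d <= 0:
            return None
        grads.append((_peak_height(profile, inner)
                      - _peak_height(profile, outer)) / d)
    return float(np.mean(grads))


def mann_whitney_u(sample_a, sample_b):
    """Two-sided Mann-Whitney U (rank-sum) test: (U_a, p).

    Exact for small tie-free samples, tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    small = max(len(a), len(b)) <= 8
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
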