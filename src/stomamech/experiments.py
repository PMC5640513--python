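"""Orchestration of the simulation scenario matrix and the synthetic AFM
recovery study.

``run_scenario_matrix`` solves the five model variants (baseline, variable
wall thickness, VWT with the ventral wall +-10%, and baseline with fixed
poles) on one common load protocol and evaluates the qualitative ordering
claims between their aperture-pressure curves.  ``run_afm_study`` generates
stage-preset synthetic force maps (14 mature, 18 young by default),
processes them blind through the AFM pipeline, and reports the per-stoma
stiffness-gradient medians and their Mann-Whitney comparison.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .afm import (AfmConfig, extract_transect, gradient_statistic,
                  mann_whitney_u, process_force_map)
from .geometry import GeometryParams, build_geometry
from .material import MaterialParams
from .observables import (ApertureCurve, curve_from_states,
                          effective_measures, opening_threshold)
from .solver import BCVariant, LoadProtocol, solve_quasistatic
from .synthetic import NoiseModel, make_ground_truth, simulate_force_map

__all__ = ["run_scenario_matrix", "run_afm_study", "ScenarioResult",
           "AfmStudyResult", "VARIANTS", "scenario_variant"]

VARIANTS = ("baseline", "vwt", "vwt+10", "vwt-10", "fixed_poles")


def scenario_variant(name: str, base: GeometryParams):
    """(GeometryParams, BCVariant) for one named scenario."""
    if name == "baseline":
        return base.with_(cross_section_kind="circular", m_v=1.0), \
            BCVariant("baseline", "circular")
    if name == "vwt":
        return base.with_(cross_section_kind="rounded_triangular", m_v=1.0), \
            BCVariant("baseline", "VWT")
    if name == "vwt+10":
        return base.with_(cross_section_kind="rounded_triangular", m_v=1.1), \
            BCVariant("baseline", "VWT+10")
    if name == "vwt-10":
        return base.with_(cross_section_kind="rounded_triangular", m_v=0.9), \
            BCVariant("baseline", "VWT-10")
    if name == "fixed_poles":
        return base.with_(cross_section_kind="circular", m_v=1.0), \
            BCVariant("fixed_poles", "circular")
    raise ValueError(f"unknown variant {name!r}")


@dataclass
class ScenarioResult:
    curves: Dict[str, ApertureCurve]
    thresholds: Dict[str, Optional[float]]
    final_apertures: Dict[str, float]
    checks: Dict[str, bool]
    localization: Dict[str, float]
    failures: Dict[str, str] = field(default_factory=dict)

    def report(self) -> dict:
        return {
            "thresholds_MPa": self.thresholds,
            "final_apertures_um": self.final_apertures,
            "ordering_checks": self.checks,
            "localization": self.localization,
            "failures": self.failures,
        }


def _localization_metrics(states, mesh):
    """Effective-field localization at the final (fully pressurized) state.

    The radial-pattern claims (which wall carries the peak strain/stress)
    are evaluated on the mid-cell band (|x| <= a_p/2): near the pore ends
    the membrane formulation concentrates stress at the ventral contact
    corner where the walls peel apart, which is a contact artifact rather
    than the radial wall pattern the claims are about.  The polar share
    uses the whole tube.
    """
    tube = mesh.cell >= 0
    ventral = mesh.patch_mask("ventral")
    strain_fin, stress_fin = effective_measures(states[-1])
    xc = np.abs(mesh.element_centroids()[:, 0])
    midcell = tube & (xc <= 0.5 * mesh.params.a_p)
    polar_band = tube & (xc >= 0.6 * xc[tube].max())
    return {
        "max_strain_on_ventral": bool(
            ventral[np.argmax(np.where(midcell, strain_fin, -np.inf))]),
        "max_stress_on_ventral": bool(
            ventral[np.argmax(np.where(midcell, stress_fin, -np.inf))]),
        "ventral_max_stress": float(stress_fin[midcell & ventral].max()),
        "global_max_stress": float(stress_fin[midcell].max()),
        "polar_stress_share": float(
            stress_fin[polar_band].max() / stress_fin[tube].max()),
    }


def run_scenario_matrix(geometry: GeometryParams | None = None,
                        material: MaterialParams | None = None,
                        protocol: LoadProtocol | None = None,
                        variants=VARIANTS,
                        out_dir=None) -> ScenarioResult:
    """Solve all variants on the shared protocol and check the curve-level
    ordering claims; non-convergent variants are reported, not fatal."""
    geometry = geometry or GeometryParams(mesh_resolution=3000)
    material = material or MaterialParams()
    protocol = protocol or LoadProtocol()
    curves, thresholds, finals, failures, loc = {}, {}, {}, {}, {}
    for name in variants:
        gp, bc = scenario_variant(name, geometry)
        mesh = build_geometry(gp)
        try:
            states = solve_quasistatic(mesh, material, protocol, bc)
        except Exception as err:      # partial report on failure
            failures[name] = str(err)
            continue
        curve = curve_from_states(states, mesh, protocol.p_epi_max)
        curves[name] = curve
        thresholds[name] = opening_threshold(curve)
        finals[name] = float(curve.aperture[-1])
        if name in ("baseline", "vwt", "fixed_poles"):
            for k, v in _localization_metrics(states, mesh).items():
                loc[f"{name}.{k}"] = v
    checks = _ordering_checks(curves, thresholds, finals)
    res = ScenarioResult(curves, thresholds, finals, checks, loc, failures)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, c in curves.items():
            c.to_csv(out / f"curve_{name.replace('+', 'p').replace('-', 'm')}.csv")
        (out / "report.json").write_text(json.dumps(res.report(), indent=2,
                                                    default=str))
    return res


def _ordering_checks(curves, thresholds, finals) -> Dict[str, bool]:
    checks: Dict[str, bool] = {}

    def have(*names):
        return all(n in curves for n in names)

    if have("baseline", "fixed_poles"):
        tb, tf = thresholds.get("baseline"), thresholds.get("fixed_poles")
        checks["fixed_poles_opens_earlier"] = (
            tb is not None and tf is not None and tf < tb)
        checks["fixed_poles_larger_final"] = (
            finals["fixed_poles"] > finals["baseline"])
        cb, cf = curves["baseline"], curves["fixed_poles"]
        l0 = cf.complex_length[0]
        checks["fixed_poles_length_constant"] = bool(
            np.max(np.abs(cf.complex_length - l0)) < 1e-3 * l0)
        after1 = cb.p_gc > 1.0
        checks["baseline_length_increases"] = bool(
            cb.complex_length[after1][-1] > cb.complex_length[0])
    if have("baseline", "vwt"):
        cb, cv = curves["baseline"], curves["vwt"]
        gain = cb.aperture.max() - cb.aperture.min()
        low = (cb.p_gc > cb.p_epi_max) & (cb.p_gc <= 2.5)
        checks["vwt_larger_at_low_pressure"] = bool(
            np.max(cv.aperture[low] - cb.aperture[low]) > 0)
        checks["vwt_smaller_at_high_pressure"] = bool(
            cv.aperture[-1] < cb.aperture[-1])
    if have("vwt+10", "vwt-10", "vwt"):
        cp, cm = curves["vwt+10"], curves["vwt-10"]
        rng = curves["vwt"].aperture.max() - curves["vwt"].aperture.min()
        checks["vwt_pm10_within_2pct"] = bool(
            np.max(np.abs(cp.aperture - cm.aperture)) < 0.02 * rng
            if rng > 0 else False)
    return checks


# ---------------------------------------------------------------------------


@dataclass
class AfmStudyResult:
    gradients_mature: List[Optional[float]]
    gradients_young: List[Optional[float]]
    median_mature: float
    median_young: float
    mw_u: float
    mw_p: float
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        rows = ([("mature", i, g) for i, g in enumerate(self.gradients_mature)]
                + [("young", i, g) for i, g in enumerate(self.gradients_young)])
        return pd.DataFrame(rows, columns=["stage", "map_index",
                                           "gradient_MPa_per_um"])

    def report(self) -> dict:
        return {
            "median_gradient_mature_MPa_per_um": self.median_mature,
            "median_gradient_young_MPa_per_um": self.median_young,
            "mann_whitney_U": self.mw_u,
            "mann_whitney_p_two_sided": self.mw_p,
            "n_mature": len(self.gradients_mature),
            "n_young": len(self.gradients_young),
            "n_excluded": self.n_excluded,
        }


def _study_seeds(seed: int, n_mature: int, n_young: int):
    base = int(seed) * 10000
    return ([base + 100 + i for i in range(n_mature)],
            [base + 1 + i for i in range(n_young)])


def run_afm_study(seed: int = 1, n_mature: int = 14, n_young: int = 18,
                  cfg: AfmConfig | None = None,
                  noise_kwargs: dict | None = None,
                  out_dir=None) -> AfmStudyResult:
    """Generate + analyze the synthetic stage-comparison study.

    Maps are acquired as 128 x 128 zooms over a 30 um field centered on one
    stoma.  Per-map seeds derive from ``seed`` so the whole study is
    reproducible from a single integer.
    """
    cfg = cfg or AfmConfig(map_size_um=30.0)
    noise_kwargs = noise_kwargs or {}
    seeds_m, seeds_y = _study_seeds(seed, n_mature, n_young)

    def one(stage, s):
        pat = make_ground_truth(stage, field_size_um=cfg.map_size_um)
        fm = simulate_force_map(pat, cfg, NoiseModel(seed=s, **noise_kwargs))
        ea = process_force_map(fm, cfg)
        prof = extract_transect(ea, pat.pose, "diameter")
        return gradient_statistic(prof)

    gm = [one("mature", s) for s in seeds_m]
    gy = [one("young", s) for s in seeds_y]
    gm_ok = [g for g in gm if g is not None]
    gy_ok = [g for g in gy if g is not None]
    n_excluded = (len(gm) - len(gm_ok)) + (len(gy) - len(gy_ok))
    if gm_ok and gy_ok:
        U, p = mann_whitney_u(gm_ok, gy_ok)
    else:                       # degenerate study (e.g. unresolvable maps)
        U = p = float("nan")
    res = AfmStudyResult(gm, gy,
                         float(np.median(gm_ok)) if gm_ok else float("nan"),
                         float(np.median(gy_ok)) if gy_ok else float("nan"),
                         U, p, n_excluded)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        res.to_frame().to_csv(out / "gradients.csv", index=False)
        (out / "afm_study.json").write_text(
            json.dumps(res.report(), indent=2))
    return res


def run_manifest(config: dict) -> dict:
    """Reproducibility manifest: config hash + tolerances."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {"config_sha256": hashlib.sha256(blob).hexdigest(),
            "config": config}
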