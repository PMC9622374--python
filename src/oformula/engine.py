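"""Predicted refraction and IOL power selection by exact ray tracing.

For a candidate IOL power the pseudophakic eye is assembled (two-surface
cornea, thick IOL at the regression-predicted depth, image plane at the
segmented axial length) and the predicted spectacle refraction is the sphere
S, placed 12 mm in front of the cornea as an ideal thin lens, that minimises
the RMS geometric spot radius of a parallel hexapolar ray fan at the
photoreceptor plane.  The minimisation is a golden-section search (unimodal
objective) to 1e-4 D.  A closed-form paraxial vergence cascade provides an
independent small-pupil oracle: with a 0.2 mm pupil the exact search and the
cascade agree to better than 0.02 D.

Sign convention: a myopic eye needs negative spectacle power, so predicted
refraction decreases as IOL power increases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .biometry import (
    BiometryRecord,
    CalibrationConstants,
    corneal_geometry_from_record,
    segmented_axial_length,
)
from .elp import ELPCoefficients, elp_features, predict_iol_depth
from .eye import IOLDesign, IOLPowerEntry, build_pseudophakic_system
from .optics import OpticalSystem, hexapolar_fan, paraxial_power, trace_bundle

__all__ = [
    "TraceConfig",
    "RefractionTable",
    "EngineError",
    "predicted_refraction",
    "paraxial_refraction",
    "refraction_table",
    "select_power",
    "solve_equibiconvex_radius",
    "thick_lens_power",
]


class EngineError(RuntimeError):
    pass


@dataclass(frozen=True)
class TraceConfig:
    """Knobs of the exact-trace refraction search.

    pupil_diameter: entrance beam diameter at the cornea, mm (3.0 = photopic
    pupil; <= 0.2 behaves paraxially).  vertex_distance: spectacle plane to
    cornea, mm.  search_interval: spectacle sphere bracket, D.
    """

    pupil_diameter: float = 3.0
    vertex_distance: float = 12.0
    n_rings: int = 6
    search_interval: tuple = (-30.0, 30.0)
    focus_tol: float = 1e-4  # D

    def __post_init__(self):
        if self.pupil_diameter <= 0:
            raise ValueError("pupil_diameter must be positive")
        if self.vertex_distance < 0:
            raise ValueError("vertex_distance must be >= 0")


@dataclass(frozen=True)
class RefractionTable:
    """Per labeled IOL power, the predicted spectacle-plane refraction (D)."""

    powers: np.ndarray
    refractions: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.powers, dtype=float)
        r = np.asarray(self.refractions, dtype=float)
        if p.shape != r.shape or p.ndim != 1 or len(p) == 0:
            raise ValueError("powers and refractions must be equal-length 1-D arrays")
        object.__setattr__(self, "powers", p)
        object.__setattr__(self, "refractions", r)

    def __len__(self):
        return len(self.powers)


def _spectacle_spot_rms(system: OpticalSystem, sphere_d: float, cfg: TraceConfig) -> float:
    """RMS spot radius at the image plane with an ideal thin spectacle lens of
    ``sphere_d`` diopters ``vertex_distance`` mm before the cornea."""
    xy = hexapolar_fan(cfg.pupil_diameter, cfg.n_rings)
    z0 = system.surfaces[0].apex_z - cfg.vertex_distance
    origins = np.column_stack([xy[:, 0], xy[:, 1], np.full(len(xy), z0)])
    # ideal thin lens acting on transverse slopes: u' = u - h * S (S in 1/mm)
    s_per_mm = sphere_d / 1000.0
    slopes = -xy * s_per_mm  # incoming rays are parallel to the axis (u = 0)
    dirs = np.column_stack([slopes[:, 0], slopes[:, 1], np.ones(len(xy))])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pts = trace_bundle(system, origins, dirs)
    return float(np.sqrt(np.mean(pts[:, 0] ** 2 + pts[:, 1] ** 2)))


_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def predicted_refraction(system: OpticalSystem, cfg: TraceConfig = TraceConfig()) -> float:
    """Spectacle sphere (D) that best focuses the eye on its photoreceptor
    plane, by golden-section search of the RMS spot radius."""
    lo, hi = cfg.search_interval
    f = lambda s: _spectacle_spot_rms(system, s, cfg)
    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > cfg.focus_tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    s_star = 0.5 * (a + b)
    if min(abs(s_star - lo), abs(s_star - hi)) < 10 * cfg.focus_tol:
        raise EngineError("refraction search hit the bracket edge; eye outside +/-30 D")
    return s_star


def paraxial_refraction(system: OpticalSystem, vertex_distance: float = 12.0) -> float:
    """Closed-form Gaussian oracle: the spectacle sphere focusing the eye on
    its image plane, by backward vergence propagation (independent of the
    exact tracer — no ray is traced)."""
    last = system.surfaces[-1]
    d_img = system.image_z - last.apex_z  # mm, in image medium
    if d_img <= 0:
        raise ValueError("image plane must lie behind the last surface")
    v = 1000.0 * system.n_image / d_img  # required exit vergence, D
    for i in range(len(system.surfaces) - 1, -1, -1):
        s = system.surfaces[i]
        if i < len(system.surfaces) - 1:
            nxt = system.surfaces[i + 1]
            gap_m = (nxt.apex_z - s.apex_z) / 1000.0
            v = v / (1.0 + (gap_m / s.n_after) * v)  # backward translation
        v = v - s.power_diopters
    # back from the corneal vertex to the spectacle plane (air)
    vd_m = vertex_distance / 1000.0
    return v / (1.0 + vd_m * v)


def refraction_table(b: BiometryRecord, design: IOLDesign, coef: ELPCoefficients,
                     k: CalibrationConstants = CalibrationConstants(),
                     cfg: TraceConfig = TraceConfig(),
                     powers=None) -> RefractionTable:
    """Predicted refraction for every labeled power of ``design`` (or the
    subset ``powers``).  Enforces the physical monotone-myopization invariant:
    predicted refraction strictly decreases with IOL power."""
    entries = design.entries if powers is None else [design.entry_for(p) for p in powers]
    if not entries:
        raise EngineError("empty IOL design table")
    cornea = corneal_geometry_from_record(b)
    seg_al = segmented_axial_length(b, k)
    feats = elp_features(b, seg_al)
    iol_depth = predict_iol_depth(feats, coef)
    out_p, out_r = [], []
    for entry in entries:
        system = build_pseudophakic_system(cornea, entry, iol_depth, seg_al)
        out_p.append(entry.labeled_power)
        out_r.append(predicted_refraction(system, cfg))
    refr = np.asarray(out_r)
    if np.any(np.diff(refr) >= -1e-6):
        raise EngineError("refraction table is not strictly decreasing in IOL power")
    return RefractionTable(np.asarray(out_p), refr)


def select_power(table: RefractionTable, target: float):
    """Row minimising |predicted - target|; ties break toward the higher
    (more myopic) power.  Returns (labeled_power, predicted_refraction)."""
    if len(table) == 0:
        raise EngineError("empty refraction table")
    diff = np.abs(table.refractions - target)
    best = np.min(diff)
    idx = np.flatnonzero(diff <= best + 1e-9)
    i = idx[np.argmax(table.powers[idx])]
    return float(table.powers[i]), float(table.refractions[i])


def thick_lens_power(r_front: float, r_back: float, thickness: float,
                     n_lens: float, n_medium: float) -> float:
    """Gaussian power (D) of a thick lens immersed in ``n_medium``."""
    p1 = 0.0 if math.isinf(r_front) else 1000.0 * (n_lens - n_medium) / r_front
    p2 = 0.0 if math.isinf(r_back) else 1000.0 * (n_medium - n_lens) / r_back
    return p1 + p2 - (thickness / 1000.0 / n_lens) * p1 * p2


def solve_equibiconvex_radius(power: float, thickness: float, n_iol: float,
                              n_medium: float = 1.336) -> float:
    """Radius R of an equi-biconvex (or -biconcave) lens, front +R / back -R,
    whose Gaussian power in the medium equals ``power`` to 1e-6 D.

    Powers with magnitude below 1e-9 D return ``math.inf`` (planar)."""
    if abs(power) < 1e-9:
        return math.inf
    r_thin = 2000.0 * (n_iol - n_medium) / power  # thin-lens seed, mm
    f = lambda r: thick_lens_power(r, -r, thickness, n_iol, n_medium) - power
    lo, hi = sorted((0.25 * r_thin, 4.0 * r_thin))
    if f(lo) * f(hi) > 0:
        raise EngineError("no bracketing radius for the requested power")
    r = brentq(f, lo, hi, xtol=1e-10, rtol=1e-14)
    if abs(f(r)) > 1e-6:
        raise EngineError("equi-biconvex radius solve did not converge")
    return float(r)
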