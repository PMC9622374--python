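"""Segmented (sum-of-segments) axial length to the photoreceptor plane.

SS-OCT biometers display an ultrasound-compatible axial length computed with
a single composite group index (1.3496) and a linear device calibration
(0.9573 * AL + 1.3304).  Here that displayed value is decomposed back into an
optical path length and re-segmented: each ocular segment's geometric depth
is recovered with its own refractive index (cornea 1.376, aqueous 1.336,
lens 1.410 — or 1.450 for dense nuclear cataracts above LOCS III grade 3 —
and vitreous 1.338), yielding the distance from the anterior cornea to the
external limiting membrane used as the ray-tracing image plane.

The vitreous depth is obtained by subtracting the corneal, aqueous and lens
optical paths from the total optical path and dividing by the vitreous index.
The crystalline-lens geometric term converts the device-displayed lens
thickness with the ratio n_lens / 1.426, where 1.426 is the device's display
index for the lens segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "BiometryRecord",
    "CalibrationConstants",
    "FIELD_RANGES",
    "lens_geometric_thickness",
    "lens_index_for_grade",
    "segmented_axial_length",
    "corneal_geometry_from_record",
    "validate_record",
]

# plausibility ranges used by the CSV reader (mm except where noted)
FIELD_RANGES = {
    "al_display": (20.0, 31.0),
    "cct": (0.3, 0.8),
    "aqd": (1.2, 4.2),
    "lt": (3.0, 6.5),
    "ata_depth": (2.0, 4.5),
    "le_depth": (2.0, 5.5),
    "nuclear_grade": (1.0, 6.9),  # LOCS III
    "r_ant_steep": (5.0, 12.0),
    "r_ant_flat": (5.0, 12.0),
    "r_post_steep": (4.0, 10.0),
    "r_post_flat": (4.0, 10.0),
    "e_ant": (-1.5, 1.5),
    "e_post": (-1.5, 1.5),
}


@dataclass(frozen=True)
class BiometryRecord:
    """One eye's preoperative measurements (mm; grades LOCS III; powers D)."""

    al_display: float
    cct: float
    aqd: float
    lt: float
    ata_depth: float
    le_depth: float
    nuclear_grade: float
    r_ant_steep: float
    r_ant_flat: float
    r_post_steep: float
    r_post_flat: float
    e_ant: float = 0.0
    e_post: float = 0.0
    eye_id: str = ""
    postop_refraction_se: float | None = None
    measured_iol_depth: float | None = None
    implanted_power: float | None = None

    @property
    def r_anterior_mean(self) -> float:
        return 0.5 * (self.r_ant_steep + self.r_ant_flat)

    @property
    def r_posterior_mean(self) -> float:
        return 0.5 * (self.r_post_steep + self.r_post_flat)


@dataclass(frozen=True)
class CalibrationConstants:
    """Device and media constants for the axial-length segmentation."""

    composite_group_index: float = 1.3496
    al_slope: float = 0.9573
    al_offset: float = 1.3304       # mm
    lt_device_index: float = 1.426  # device display index for the lens segment
    n_cornea: float = 1.376
    n_aqueous: float = 1.336
    n_lens_normal: float = 1.410
    n_lens_dense: float = 1.450
    n_vitreous: float = 1.338
    el_offset: float = 0.0          # mm, ELM-to-RPE adjustment; signed
    grade_threshold: float = 3.0    # LOCS III nuclear grade

    def __post_init__(self):
        if not -0.2 <= self.el_offset <= 0.2:
            raise ValueError("el_offset outside [-0.2, 0.2] mm")


def lens_geometric_thickness(opl: float, n: float) -> float:
    """Geometric lens thickness (mm) from its optical path length: opl / n.

    A 6.0 mm optical path is 4.26 mm of lens at index 1.41 but only 4.14 mm
    at 1.45 (dense nuclear cataract) — a 0.12 mm difference, which is why the
    nuclear grade enters the axial-length segmentation at all.
    """
    if opl <= 0:
        raise ValueError("optical path length must be positive")
    if n <= 1:
        raise ValueError("refractive index must exceed 1")
    return opl / n


def lens_index_for_grade(nuclear_grade: float,
                         k: CalibrationConstants = CalibrationConstants()) -> float:
    """Crystalline-lens index by LOCS III nuclear grade: 1.450 strictly above
    grade 3, else 1.410 (the boundary grade 3.0 uses the normal index)."""
    lo, hi = FIELD_RANGES["nuclear_grade"]
    if not lo <= nuclear_grade <= hi:
        raise ValueError(f"nuclear grade {nuclear_grade} outside LOCS III range [{lo}, {hi}]")
    return k.n_lens_dense if nuclear_grade > k.grade_threshold else k.n_lens_normal


def segmented_axial_length(b: BiometryRecord,
                           k: CalibrationConstants = CalibrationConstants()) -> float:
    """Segmented axial length (mm) from anterior cornea to the photoreceptors.

    The displayed AL is converted to a total optical path length
    OPL = 1.3496 * (0.9573 * AL + 1.3304); the vitreous geometric depth is the
    optical path left after removing the corneal, aqueous and lens paths,
    divided by the vitreous index:

        V = (OPL - 1.376*CCT - 1.336*AQD - n_lens*LT) / 1.338

    and the result is CCT + AQD + LT * n_lens / 1.426 + V + el_offset, with
    n_lens switched to 1.450 for dense nuclear cataracts (grade > 3).
    """
    for name in ("cct", "aqd", "lt", "al_display"):
        if getattr(b, name) <= 0:
            raise ValueError(f"{name} must be positive")
    n_lens = lens_index_for_grade(b.nuclear_grade, k)
    opl_total = k.composite_group_index * (k.al_slope * b.al_display + k.al_offset)
    vitreous = (
        opl_total - k.n_cornea * b.cct - k.n_aqueous * b.aqd - n_lens * b.lt
    ) / k.n_vitreous
    if vitreous <= 0:
        raise ValueError("inconsistent biometry: nonpositive vitreous depth")
    return b.cct + b.aqd + b.lt * n_lens / k.lt_device_index + vitreous + k.el_offset


def corneal_geometry_from_record(b: BiometryRecord):
    """Spherical-equivalent corneal geometry: steep/flat radii are averaged."""
    from .eye import CornealGeometry

    return CornealGeometry(
        r_anterior=b.r_anterior_mean,
        r_posterior=b.r_posterior_mean,
        cct=b.cct,
        e_anterior=b.e_ant,
        e_posterior=b.e_post,
    )


def validate_record(b: BiometryRecord) -> list:
    """Plausibility diagnostics for one record (empty list = clean)."""
    issues = []
    for name, (lo, hi) in FIELD_RANGES.items():
        v = getattr(b, name)
        if v is None:
            continue
        if not lo <= v <= hi:
            issues.append(f"{name}={v} outside plausible range [{lo}, {hi}]")
    return issues
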