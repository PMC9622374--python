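"""Synthetic biometry cohorts, IOL design tables and ground-truth outcomes.

Nothing in this module comes from patients.  The cohort generator draws a
truncated multivariate normal whose per-field means, SDs and truncation
ranges default to a typical cataract-surgery population (axial length
24.31 +/- 1.54 mm, aqueous depth 2.69 +/- 0.41 mm, lens thickness
4.68 +/- 0.39 mm, ...), with an assumed correlation structure taken from the
biometry literature (long eyes have deeper chambers and thinner lenses).
Outcomes are generated by this package's own ray tracer: the "true"
postoperative IOL depth is the linear depth model plus Gaussian noise, the
"manifest" refraction is the exact-trace refraction at the true depth plus
measurement noise quantised to phoropter resolution.  That makes the whole
pipeline testable end to end — parameter recovery, round-trip closure — but
it cannot validate the depth model itself against real anatomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biometry import BiometryRecord, CalibrationConstants, segmented_axial_length
from .elp import DEFAULT_SYNTHETIC_COEFFICIENTS, ELPCoefficients, elp_features, predict_iol_depth
from .engine import (
    TraceConfig,
    paraxial_refraction,
    predicted_refraction,
    refraction_table,
    select_power,
    solve_equibiconvex_radius,
)
from .eye import IOLDesign, IOLPowerEntry, build_pseudophakic_system
from .biometry import corneal_geometry_from_record

__all__ = [
    "COHORT_FIELDS",
    "CohortParams",
    "OutcomeParams",
    "sample_cohort",
    "make_design_table",
    "simulate_outcomes",
    "cohort_to_frame",
]

# field order of the multivariate draw
COHORT_FIELDS = (
    "al_display", "cct", "aqd", "lt", "ata_depth", "le_depth", "nuclear_grade",
    "r_ant_steep", "r_ant_flat", "e_ant", "r_post_steep", "r_post_flat", "e_post",
)

_MEANS = {
    "al_display": 24.31, "cct": 0.545, "aqd": 2.69, "lt": 4.68,
    "ata_depth": 3.25, "le_depth": 4.14, "nuclear_grade": 2.2,
    "r_ant_steep": 7.61, "r_ant_flat": 7.72, "e_ant": 0.52,
    "r_post_steep": 6.26, "r_post_flat": 6.52, "e_post": 0.67,
}
_SDS = {
    "al_display": 1.54, "cct": 0.032, "aqd": 0.41, "lt": 0.39,
    "ata_depth": 0.21, "le_depth": 0.32, "nuclear_grade": 0.4,
    "r_ant_steep": 0.28, "r_ant_flat": 0.26, "e_ant": 0.19,
    "r_post_steep": 0.28, "r_post_flat": 0.26, "e_post": 0.14,
}
_RANGES = {
    "al_display": (21.33, 29.82), "cct": (0.449, 0.642), "aqd": (1.43, 3.74),
    "lt": (3.57, 5.86), "ata_depth": (2.45, 3.87), "le_depth": (2.53, 4.94),
    "nuclear_grade": (1.0, 5.0), "r_ant_steep": (6.84, 8.47),
    "r_ant_flat": (7.01, 8.71), "e_ant": (-0.40, 1.05),
    "r_post_steep": (5.40, 7.19), "r_post_flat": (5.86, 7.37),
    "e_post": (-0.12, 1.04),
}

# assumed biometric correlations (literature-informed; configurable)
_SPECIFIC_CORR = {
    ("al_display", "aqd"): 0.45,
    ("al_display", "lt"): -0.30,
    ("aqd", "lt"): -0.55,
    ("ata_depth", "aqd"): 0.50,
    ("le_depth", "aqd"): 0.60,
}
_BASE_CORR = 0.1


def _project_correlation(corr: np.ndarray, floor: float = 0.01) -> np.ndarray:
    """Nearest well-conditioned correlation matrix: clip eigenvalues at
    ``floor`` and rescale to a unit diagonal.  Changes entries by < 0.02."""
    w, v = np.linalg.eigh(corr)
    fixed = (v * np.maximum(w, floor)) @ v.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def default_correlation() -> np.ndarray:
    m = len(COHORT_FIELDS)
    corr = np.full((m, m), _BASE_CORR)
    np.fill_diagonal(corr, 1.0)
    for (fa, fb), rho in _SPECIFIC_CORR.items():
        i, j = COHORT_FIELDS.index(fa), COHORT_FIELDS.index(fb)
        corr[i, j] = corr[j, i] = rho
    # the nominal table is very slightly indefinite; project it
    return _project_correlation(corr)


@dataclass
class CohortParams:
    """Sampling parameters for a synthetic biometry cohort."""

    n: int = 400
    seed: int = 0
    means: dict = field(default_factory=lambda: dict(_MEANS))
    sds: dict = field(default_factory=lambda: dict(_SDS))
    ranges: dict = field(default_factory=lambda: dict(_RANGES))
    correlation: np.ndarray = field(default_factory=default_correlation)

    def __post_init__(self):
        self.correlation = np.asarray(self.correlation, dtype=float)
        m = len(COHORT_FIELDS)
        if self.correlation.shape != (m, m):
            raise ValueError(f"correlation matrix must be {m}x{m}")
        if np.linalg.eigvalsh(self.correlation).min() <= 0:
            raise ValueError("correlation matrix is not positive-definite")


@dataclass(frozen=True)
class OutcomeParams:
    """Ground-truth generation: true depth model, noise levels, quantisation."""

    true_elp_coefficients: ELPCoefficients = DEFAULT_SYNTHETIC_COEFFICIENTS
    elp_noise_sd: float = 0.11          # mm, depth prediction scatter
    refraction_noise_sd: float = 0.25   # D, manifest refraction noise
    refraction_quantum: float = 0.125   # D, phoropter step (0 disables)
    target_refraction: float = -0.25    # D, surgeon's aim

    def __post_init__(self):
        if self.elp_noise_sd < 0 or self.refraction_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


def sample_cohort(p: CohortParams) -> list:
    """Draw ``p.n`` biometry records from the truncated multivariate normal.

    Rejection sampling per record: out-of-range draws are redrawn, so sample
    moments track the targets (slightly shrunk by truncation).  Reproducible
    for a fixed seed.
    """
    if p.n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(p.seed)
    mu = np.array([p.means[f] for f in COHORT_FIELDS])
    sd = np.array([p.sds[f] for f in COHORT_FIELDS])
    lo = np.array([p.ranges[f][0] for f in COHORT_FIELDS])
    hi = np.array([p.ranges[f][1] for f in COHORT_FIELDS])
    chol = np.linalg.cholesky(p.correlation)
    rows = []
    while len(rows) < p.n:
        need = p.n - len(rows)
        z = rng.standard_normal((max(need * 2, 16), len(COHORT_FIELDS)))
        draws = mu + (z @ chol.T) * sd
        ok = np.all((draws >= lo) & (draws <= hi), axis=1)
        rows.extend(draws[ok][:need])
    records = []
    for i, row in enumerate(rows):
        vals = dict(zip(COHORT_FIELDS, row))
        records.append(BiometryRecord(eye_id=f"syn{i:04d}", **vals))
    return records


def make_design_table(p_min: float = 6.0, p_max: float = 28.5, step: float = 0.5,
                      n_iol: float = 1.55,
                      thickness_rule=lambda p: 0.55 + 0.015 * p,
                      name: str = "synthetic-equibiconvex") -> IOLDesign:
    """Equi-biconvex synthetic IOL design table (real IOL geometry is
    proprietary).  Centre thickness grows linearly with power by default."""
    if p_min >= p_max:
        raise ValueError("p_min must be below p_max")
    powers = np.round(np.arange(p_min, p_max + step / 2, step), 6)
    entries = []
    for p in powers:
        t = thickness_rule(p)
        r = solve_equibiconvex_radius(float(p), t, n_iol)
        entries.append(IOLPowerEntry(float(p), r, -r if not math.isinf(r) else math.inf,
                                     t, n_iol))
    return IOLDesign(name=name, entries=entries, power_step=step)


def _exact_refraction(record, entry, iol_depth, seg_al, cfg):
    cornea = corneal_geometry_from_record(record)
    system = build_pseudophakic_system(cornea, entry, iol_depth, seg_al)
    return predicted_refraction(system, cfg)


def _select_implant(record, design, pred_depth, seg_al, target, cfg, window=2):
    """Exact-trace power selection with a closed-form vergence pre-screen.

    The vergence cascade (monotone in power, paraxially exact) shortlists the
    candidate powers around the target; the exact trace then decides among
    the shortlist.  Same selection as scanning the full exact table, at a
    fraction of the cost.
    """
    cornea = corneal_geometry_from_record(record)
    approx = []
    for e in design.entries:
        system = build_pseudophakic_system(cornea, e, pred_depth, seg_al)
        approx.append(paraxial_refraction(system, cfg.vertex_distance))
    approx = np.asarray(approx)
    centre = int(np.argmin(np.abs(approx - target)))
    idx = range(max(0, centre - window), min(len(design.entries), centre + window + 1))
    best = None
    for i in idx:
        e = design.entries[i]
        refr = _exact_refraction(record, e, pred_depth, seg_al, cfg)
        key = (abs(refr - target), -e.labeled_power)
        if best is None or key < best[0]:
            best = (key, e, refr)
    return best[1], best[2]


def simulate_outcomes(cohort, design: IOLDesign, op: OutcomeParams = OutcomeParams(),
                      k: CalibrationConstants = CalibrationConstants(),
                      cfg: TraceConfig = TraceConfig(),
                      seed: int = 0) -> pd.DataFrame:
    """Generate postoperative ground truth for every eye of ``cohort``.

    Per eye: true IOL depth = linear depth model (true coefficients) +
    N(0, elp_noise_sd); implanted power selected toward the target using the
    noise-free predicted depth; true refraction = exact ray trace at the TRUE
    depth; manifest = true + N(0, refraction_noise_sd), quantised.  Returns a
    DataFrame with the biometry plus implanted_power, measured_iol_depth,
    postop_refraction_se and the latent true_refraction_se.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rec in cohort:
        seg_al = segmented_axial_length(rec, k)
        feats = elp_features(rec, seg_al)
        pred_depth = predict_iol_depth(feats, op.true_elp_coefficients)
        true_depth = pred_depth + rng.normal(0.0, op.elp_noise_sd) if op.elp_noise_sd > 0 \
            else pred_depth
        entry, _ = _select_implant(rec, design, pred_depth, seg_al,
                                   op.target_refraction, cfg)
        true_refr = _exact_refraction(rec, entry, true_depth, seg_al, cfg)
        manifest = true_refr
        if op.refraction_noise_sd > 0:
            manifest += rng.normal(0.0, op.refraction_noise_sd)
        if op.refraction_quantum > 0:
            manifest = round(manifest / op.refraction_quantum) * op.refraction_quantum
        row = {f: getattr(rec, f) for f in COHORT_FIELDS}
        row.update(
            eye_id=rec.eye_id,
            segmented_al=seg_al,
            implanted_power=entry.labeled_power,
            measured_iol_depth=true_depth,
            true_refraction_se=true_refr,
            postop_refraction_se=manifest,
        )
        rows.append(row)
    cols = ["eye_id", *COHORT_FIELDS, "segmented_al", "implanted_power",
            "measured_iol_depth", "true_refraction_se", "postop_refraction_se"]
    return pd.DataFrame(rows)[cols]


def cohort_to_frame(cohort) -> pd.DataFrame:
    """Biometry records as a CSV-ready DataFrame (reader-compatible columns)."""
    rows = []
    for rec in cohort:
        row = {"eye_id": rec.eye_id}
        row.update({f: getattr(rec, f) for f in COHORT_FIELDS})
        for opt in ("postop_refraction_se", "measured_iol_depth", "implanted_power"):
            v = getattr(rec, opt)
            if v is not None:
                row[opt] = v
        rows.append(row)
    return pd.DataFrame(rows)
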