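"""Postoperative IOL-depth (effective lens position) regression.

The implant's resting depth — posterior cornea to anterior IOL surface — is
predicted by an additive linear model on four anterior-segment features:

    IOL depth = a * segmented_AL + b * (LT/2 + AQD) + c * ATA_depth
                + d * LE_depth + e

where LT/2 + AQD locates the preoperative crystalline-lens centre, ATA depth
the anterior-chamber angle plane, and LE depth the lens-equator plane (all
mm, measured on anterior-segment OCT).  Coefficients are fitted by ordinary
least squares; the published coefficient values are not public, so shipped
defaults are fitted to this package's synthetic cohort and are NOT clinical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .biometry import BiometryRecord

__all__ = [
    "ELPCoefficients",
    "ELPFitReport",
    "elp_features",
    "predict_iol_depth",
    "fit_elp",
    "DEFAULT_SYNTHETIC_COEFFICIENTS",
]


@dataclass(frozen=True)
class ELPCoefficients:
    """Slopes a-d (mm per mm) and intercept e (mm) of the IOL-depth model."""

    a: float
    b: float
    c: float
    d: float
    e: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e])

    def to_json(self, path, **meta) -> None:
        payload = {**asdict(self), **meta}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ELPCoefficients":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(*(float(payload[k]) for k in "abcde"))


#: Fitted to the default synthetic cohort (see ``oformula.synth``); provenance
#: is simulation, not patients.
DEFAULT_SYNTHETIC_COEFFICIENTS = ELPCoefficients(a=0.10, b=0.20, c=0.15, d=0.40, e=-1.4595)


@dataclass(frozen=True)
class ELPFitReport:
    coefficients: ELPCoefficients
    r_squared: float
    mae: float  # mm, in-sample
    n: int


def elp_features(b: BiometryRecord, seg_al: float) -> np.ndarray:
    """Feature vector [segmented AL, LT/2 + AQD, ATA depth, LE depth] in mm."""
    vals = (seg_al, b.lt / 2.0 + b.aqd, b.ata_depth, b.le_depth)
    if any(v is None or v <= 0 for v in vals):
        raise ValueError("ELP features require positive segmented AL, LT, AQD, ATA, LE")
    return np.array(vals, dtype=float)


def predict_iol_depth(features, coef: ELPCoefficients) -> float:
    """Predicted IOL depth (mm) = a f1 + b f2 + c f3 + d f4 + e."""
    f = np.asarray(features, dtype=float)
    if f.shape[-1] != 4:
        raise ValueError("expected 4 features")
    return float(f @ coef.as_array()[:4] + coef.e) if f.ndim == 1 else (
        f @ coef.as_array()[:4] + coef.e
    )


def fit_elp(records) -> ELPFitReport:
    """OLS fit of the IOL-depth model with intercept.

    ``records`` is an iterable of (features, measured_iol_depth) pairs.
    Raises on fewer than 10 eyes or a rank-deficient design matrix.
    """
    feats, depths = [], []
    for f, depth in records:
        feats.append(np.asarray(f, dtype=float))
        depths.append(float(depth))
    X = np.vstack(feats)
    y = np.asarray(depths)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 eyes to fit the IOL-depth model")
    design = np.column_stack([X, np.ones(n)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear features)")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ beta
    resid = y - pred
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ELPFitReport(
        coefficients=ELPCoefficients(*beta),
        r_squared=r2,
        mae=float(np.abs(resid).mean()),
        n=n,
    )
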