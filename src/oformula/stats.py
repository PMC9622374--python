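"""Refractive prediction-error statistics and formula-comparison tests.

The prediction error for one eye is the postoperative manifest spherical
equivalent minus the formula-predicted refraction (D).  Summaries follow the
IOL-formula literature: mean error (ME), its sample SD (n-1), mean and median
absolute error (MAE/MedAE), and the percentages of eyes within +/-0.25,
+/-0.50 and +/-1.00 D (inclusive).  Zero-adjustment subtracts each formula's
mean error, removing the systematic offset a lens-constant choice absorbs.

SDs of paired formulas are compared with a paired percentile bootstrap on
the SD difference of zero-adjusted errors (the literature's heteroscedastic
test; its exact published procedure is not public, so the bootstrap is this
package's documented stand-in).  MedAE comparisons use the Friedman rank
test and the within-band counts use Cochran's Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PredictionErrorSet",
    "ErrorStats",
    "error_stats",
    "zero_adjust",
    "heteroscedastic_sd_test",
    "friedman_test",
    "cochran_q",
    "al_subgroup",
    "sample_size_two_group",
]


@dataclass(frozen=True)
class PredictionErrorSet:
    """Signed per-eye refraction prediction errors (D) for one formula."""

    errors: np.ndarray
    label: str = ""

    def __post_init__(self):
        e = np.asarray(self.errors, dtype=float).ravel()
        if e.size < 1:
            raise ValueError("need at least one error")
        if not np.all(np.isfinite(e)):
            raise ValueError("errors must be finite")
        object.__setattr__(self, "errors", e)

    @property
    def n(self) -> int:
        return self.errors.size


@dataclass(frozen=True)
class ErrorStats:
    me: float
    sd: float
    mae: float
    medae: float
    pct_025: float
    pct_050: float
    pct_100: float


def error_stats(e: PredictionErrorSet) -> ErrorStats:
    """ME, sample SD (n-1), MAE, MedAE and inclusive band percentages."""
    x = e.errors
    if x.size < 2:
        raise ValueError("SD needs at least two eyes")
    ab = np.abs(x)
    return ErrorStats(
        me=float(x.mean()),
        sd=float(x.std(ddof=1)),
        mae=float(ab.mean()),
        medae=float(np.median(ab)),
        pct_025=float(100.0 * np.mean(ab <= 0.25)),
        pct_050=float(100.0 * np.mean(ab <= 0.50)),
        pct_100=float(100.0 * np.mean(ab <= 1.00)),
    )


def zero_adjust(e: PredictionErrorSet) -> PredictionErrorSet:
    """Subtract the mean error (SD is untouched)."""
    return PredictionErrorSet(e.errors - e.errors.mean(), label=e.label)


def heteroscedastic_sd_test(a: PredictionErrorSet, b: PredictionErrorSet,
                            n_boot: int = 10_000, seed: int = 0) -> float:
    """Two-sided paired percentile bootstrap p-value for SD(a) = SD(b).

    The two error sets must be paired (same eyes, same order).  Eyes are
    resampled with replacement; the p-value is how extreme a zero SD
    difference is in the bootstrap distribution of SD(a*) - SD(b*)
    (zero-adjusted errors).  Deterministic for a fixed seed.
    """
    if a.n != b.n:
        raise ValueError("paired test requires equal-length error sets")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    xa = zero_adjust(a).errors
    xb = zero_adjust(b).errors
    n = xa.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    d = np.std(xa[idx], axis=1, ddof=1) - np.std(xb[idx], axis=1, ddof=1)
    p_lo = (np.count_nonzero(d <= 0) + 1) / (n_boot + 1)
    p_hi = (np.count_nonzero(d >= 0) + 1) / (n_boot + 1)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def friedman_test(abs_errors) -> tuple:
    """Friedman rank test across formulas (columns) on paired eyes (rows).

    Average ranks for ties and the standard tie correction; returns
    (chi-square statistic, p-value) with k-1 degrees of freedom.  Implemented
    directly so that k = 2 is allowed (scipy requires k >= 3; for k >= 3 the
    two agree).
    """
    x = np.asarray(abs_errors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 eyes and >= 2 formulas")
    n, k = x.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    rsum = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rsum ** 2) - 3.0 * n * (k + 1)
    # tie correction
    tie_term = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts ** 3 - counts))
    denom = 1.0 - tie_term / (n * k * (k * k - 1))
    if denom <= 0:  # every row fully tied
        return 0.0, 1.0
    stat /= denom
    return float(stat), float(sps.chi2.sf(stat, k - 1))


def cochran_q(success) -> tuple:
    """Cochran's Q for paired binary outcomes, eyes x formulas.

    Q = k(k-1) sum_j (G_j - Gbar)^2 / (k sum_i L_i - sum_i L_i^2), chi-square
    with k-1 df.  Rows where every formula agrees contribute nothing; reduces
    to the uncorrected McNemar chi-square at k = 2.
    """
    x = np.asarray(success)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 formulas")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("entries must be binary 0/1")
    x = x.astype(float)
    n, k = x.shape
    G = x.sum(axis=0)
    L = x.sum(axis=1)
    denom = k * L.sum() - float(L @ L)
    if denom == 0:  # all rows constant
        return 0.0, 1.0
    q = k * (k - 1) * float(np.sum((G - G.mean()) ** 2)) / denom
    return float(q), float(sps.chi2.sf(q, k - 1))


def al_subgroup(al_display: float) -> str:
    """Axial-length subgroup: short (<=22 mm), medium (>22 to <26), long (>=26)."""
    if al_display <= 0:
        raise ValueError("axial length must be positive")
    if al_display <= 22.0:
        return "short"
    if al_display >= 26.0:
        return "long"
    return "medium"


def sample_size_two_group(delta: float, sd: float, alpha: float = 0.05,
                          power: float = 0.80) -> int:
    """Total n (two equal groups) for a two-sided two-sample t-test to detect
    a mean difference ``delta`` with common SD ``sd``.

    Iterates the per-group n upward under the exact noncentral-t power
    function (df = 2n-2, noncentrality d*sqrt(n/2), d = delta/sd) and returns
    2 * n_per_group.  delta = 0.25 D with SD 0.5 D at alpha 0.05 / power 0.80
    gives 128 eyes.
    """
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    d = delta / sd
    for n_per in range(2, 100_000):
        df = 2 * n_per - 2
        nc = d * np.sqrt(n_per / 2.0)
        tcrit = sps.t.isf(alpha / 2.0, df)
        achieved = sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
        if achieved >= power:
            return 2 * n_per
    raise ValueError("required sample size exceeds iteration limit")
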