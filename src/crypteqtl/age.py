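"""Transcriptional-age estimation from a linear developmental ruler.

A "ruler" is a set of spots whose log2 expression changes linearly with
developmental time inside a declared window (canonically 41.5-72 h).
A sample's transcriptional age is the least-squares time at which the
ruler's linear predictions best match the sample's expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ParameterError, ValidationError
from .io_core import ExpressionMatrix

WINDOW_H = (41.5, 72.0)


@dataclass(frozen=True)
class RulerSpot:
    spot_id: str
    slope: float  # log2 expression change per hour
    intercept: float  # expression at the window midpoint
    neg_log10_p: float


def build_ruler(
    timecourse: ExpressionMatrix,
    ages_h: np.ndarray | None = None,
    min_neg_log10_p: float = 6.0,
    min_abs_slope_per_hour: float = 0.1,
    window_h: tuple[float, float] = WINDOW_H,
) -> list[RulerSpot]:
    """Regress every spot on sample age; keep strongly linear spots.

    Per spot, OLS of expression on hours within the window; spots are
    retained when -log10(p) exceeds ``min_neg_log10_p`` AND the absolute
    slope exceeds ``min_abs_slope_per_hour`` (both strict). The stored
    intercept is the fitted expression at the window midpoint.
    """
    if ages_h is None:
        if "age_h" not in timecourse.metadata.columns:
            raise ValidationError("time course metadata lacks an age_h column")
        ages_h = timecourse.metadata["age_h"].to_numpy(dtype=float)
    ages_h = np.asarray(ages_h, dtype=float)
    in_window = (ages_h >= window_h[0]) & (ages_h <= window_h[1])
    t = ages_h[in_window]
    if len(np.unique(t)) < 3:
        raise ParameterError("need >= 3 distinct time points inside the window")
    y = timecourse.values[:, in_window]
    mid = 0.5 * (window_h[0] + window_h[1])
    tc = t - t.mean()
    sxx = (tc**2).sum()
    slope = (y @ tc) / sxx
    mean_y = y.mean(axis=1)
    resid = y - (mean_y[:, None] + slope[:, None] * tc[None, :])
    df = len(t) - 2
    s2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(s2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tt = np.where(se > 0, slope / se, np.inf)
    p = np.clip(2.0 * stats.t.sf(np.abs(tt), df), 1e-300, 1.0)
    nlp = -np.log10(p)
    intercept_mid = mean_y + slope * (mid - t.mean())
    keep = (nlp > min_neg_log10_p) & (np.abs(slope) > min_abs_slope_per_hour)
    return [
        RulerSpot(
            spot_id=timecourse.spots[i],
            slope=float(slope[i]),
            intercept=float(intercept_mid[i]),
            neg_log10_p=float(nlp[i]),
        )
        for i in np.flatnonzero(keep)
    ]


def estimate_age(
    sample_expression: dict[str, float] | "np.ndarray",
    ruler: list[RulerSpot],
    window_h: tuple[float, float] = WINDOW_H,
    min_spots: int = 10,
) -> float:
    """Least-squares transcriptional age of one sample, in hours.

    Minimizing sum_i (y_i - (intercept_i + slope_i*(t - mid)))^2 over t
    gives the closed form

        t_hat = mid + sum_i slope_i * (y_i - intercept_i) / sum_i slope_i^2.
    """
    if isinstance(sample_expression, dict):
        pairs = [(r, sample_expression[r.spot_id]) for r in ruler
                 if r.spot_id in sample_expression]
    else:
        values = np.asarray(sample_expression, dtype=float)
        if len(values) != len(ruler):
            raise ValidationError("expression vector length != ruler length")
        pairs = list(zip(ruler, values))
    if len(pairs) < min_spots:
        raise ValidationError(
            f"only {len(pairs)} ruler spots overlap the sample (need >= {min_spots})"
        )
    slopes = np.array([r.slope for r, _ in pairs])
    resid = np.array([y - r.intercept for r, y in pairs])
    mid = 0.5 * (window_h[0] + window_h[1])
    return float(mid + (slopes @ resid) / (slopes @ slopes))


def relative_age(ages_h, method: str = "rank") -> np.ndarray:
    """Map predicted ages onto the standard normal distribution.

    ``method="rank"`` (default) applies the rank-based inverse-normal
    transform z = Phi^-1((rank - 0.5)/n); ``method="zscore"`` is the plain
    (x - mean)/sd standardization.
    """
    ages = np.asarray(ages_h, dtype=float)
    if len(ages) < 2 or np.all(ages == ages[0]):
        raise ParameterError("need >= 2 samples with distinct ages")
    if method == "rank":
        ranks = stats.rankdata(ages, method="average")
        return stats.norm.ppf((ranks - 0.5) / len(ages))
    if method == "zscore":
        return (ages - ages.mean()) / ages.std(ddof=1)
    raise ParameterError(f"unknown method {method!r}")


def correlate_age_with_phenotype(rel_age, phenotype) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of relative age vs a phenotype."""
    x = np.asarray(rel_age, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ParameterError("need >= 4 paired strains")
    if x.std() == 0 or y.std() == 0:
        raise ParameterError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
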