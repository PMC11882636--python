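"""Scalar derived statistics and data-hygiene rules.

Small, explicitly defined computations used across the study's figures:
limit-of-detection filtering of replicate metal measurements and Cu:Zn
stoichiometry, dopamine turnover (HVA/dopamine), the pS129 α-synuclein
proportion, enzyme activity per unit protein, neuron density and
percent-of-reference, interrater Cronbach's α, and the SPSS-style
3×IQR extreme-value exclusion rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ReplicateSet",
    "RatingMatrix",
    "lod_filter",
    "cu_zn_ratio",
    "turnover",
    "ps129_percent",
    "activity_per_unit",
    "neuron_density",
    "percent_of_reference",
    "cronbach_alpha",
    "exclude_outliers",
]


@dataclass
class ReplicateSet:
    """Paired (Cu, Zn) replicate measurements with per-channel LODs.

    Triplicate or quintuplicate measurements are typical; at least one
    replicate must survive LOD filtering for a ratio to be computable.
    """

    values: list[tuple[float, float]]  # (cu, zn) counts
    lod_cu: float
    lod_zn: float

    def __post_init__(self) -> None:
        if self.lod_cu <= 0 or self.lod_zn <= 0:
            raise ValueError("LODs must be > 0")


@dataclass
class RatingMatrix:
    """Raters × items score matrix for interrater reliability."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2D raters × items matrix")
        k, n = self.scores.shape
        if k < 2 or n < 2:
            raise ValueError("need >= 2 raters and >= 2 items")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


def lod_filter(values: Sequence[float], lod: float) -> list[float]:
    """Retain values strictly above 3 × the limit of detection.

    The boundary is exclusive: a value of exactly 3×LOD is dropped
    ("above 3 LOD").  An empty result flags the sample for exclusion.
    """
    if lod <= 0:
        raise ValueError("LOD must be > 0")
    retained = [v for v in values if v > 3.0 * lod]
    if not retained:
        warnings.warn("all replicates at or below 3×LOD; sample flagged for exclusion")
    return retained


def cu_zn_ratio(reps: ReplicateSet, method: str = "mean_of_ratios") -> tuple[float, float]:
    """Mean Cu:Zn ratio and sample sd over replicates.

    Replicates where either channel fails the 3×LOD rule are dropped; a
    replicate with zero Zn is excluded with a warning.  The default
    computes per-replicate ratios then their mean and sample sd (an sd of
    ratios requires per-replicate ratios); ``method="ratio_of_means"``
    instead divides the channel means (sd reported as nan).  Fully
    metallated SOD1 (two Cu and two Zn per dimer) gives ratio 1.
    """
    ratios = []
    cus, zns = [], []
    for cu, zn in reps.values:
        if cu <= 3.0 * reps.lod_cu or zn <= 3.0 * reps.lod_zn:
            continue
        if zn == 0:
            warnings.warn("replicate with zero Zn excluded from ratio")
            continue
        ratios.append(cu / zn)
        cus.append(cu)
        zns.append(zn)
    if not ratios:
        raise ValueError("no replicate survives LOD filtering on both channels")
    if method == "ratio_of_means":
        return float(np.mean(cus) / np.mean(zns)), float("nan")
    if method != "mean_of_ratios":
        raise ValueError(f"unknown method {method!r}")
    mean = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return mean, sd


def turnover(hva: float, dopamine: float) -> float:
    """Dopamine turnover: the ratio of HVA to dopamine."""
    if dopamine <= 0:
        raise ValueError("dopamine must be > 0")
    return hva / dopamine


def ps129_percent(ps129: float, total: float) -> float:
    """Proportion of α-synuclein phosphorylated at S129, as a percentage.

    Both inputs are concentrations per mg total protein; the result is
    100 × ps129 / total.
    """
    if total <= 0:
        raise ValueError("total α-synuclein must be > 0")
    return 100.0 * ps129 / total


def activity_per_unit(total_activity: float, sod1_level: float) -> float:
    """Enzymatic activity normalized to protein level (activity per unit)."""
    if sod1_level <= 0:
        raise ValueError("protein level must be > 0")
    return total_activity / sod1_level


def neuron_density(count: float, region_volume: float) -> float:
    """Neurons per unit region volume."""
    if region_volume <= 0:
        raise ValueError("region volume must be > 0")
    return count / region_volume


def percent_of_reference(density: float, reference_mean: float) -> float:
    """Density as a percentage of a reference (e.g. age-matched control) mean."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be > 0")
    return 100.0 * density / reference_mean


def cronbach_alpha(m: RatingMatrix | np.ndarray) -> float:
    """Cronbach's α as an interrater reliability of repeated counts.

    α = k/(k−1) × (1 − Σᵢ s²ᵢ / s²_T) with k raters, s²ᵢ the sample
    variance of rater i's scores over items and s²_T the sample variance
    of per-item totals.  α ≤ 1 always; α = 1 iff all raters' score
    vectors agree up to additive constants.  Zero total-score variance
    leaves α undefined.
    """
    if not isinstance(m, RatingMatrix):
        m = RatingMatrix(np.asarray(m))
    scores = m.scores
    k = scores.shape[0]
    rater_vars = scores.var(axis=1, ddof=1)
    total_var = scores.sum(axis=0).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance: alpha undefined")
    return float(k / (k - 1) * (1.0 - rater_vars.sum() / total_var))


def exclude_outliers(values: Sequence[float]) -> tuple[list[float], list[float]]:
    """SPSS-style extreme-value exclusion at 3 × the interquartile range.

    Quartiles use linear interpolation between order statistics; values
    ≥ Q3 + 3·IQR or ≤ Q1 − 3·IQR are excluded.  When IQR is 0 the fences
    collapse onto the quartiles and values equal to the fence are
    retained (all-equal data excludes nothing).  Fewer than four values
    make quartiles meaningless: the data pass through with a warning.

    Returns (retained, excluded), both in input order.  The rule is
    idempotent: re-applying it to the retained values excludes nothing
    further only if their quartile fences still cover them, which holds
    for a single pass by construction of the fences.
    """
    values = [float(v) for v in values]
    if len(values) < 4:
        warnings.warn("fewer than 4 values: outlier rule skipped")
        return list(values), []
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    if iqr == 0:
        retained = [v for v in values if lo <= v <= hi]
        excluded = [v for v in values if not (lo <= v <= hi)]
        return retained, excluded
    retained = [v for v in values if lo < v < hi]
    excluded = [v for v in values if not (lo < v < hi)]
    return retained, excluded
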