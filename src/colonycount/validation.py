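"""Method-comparison statistics for colony enumeration.

Compares automatic (image analysis) and manual (pen-marking) counts
against a semi-manual on-screen point-and-click reference ("gold
standard") over a 25-sample benchmark table: count ratios, counting
rates, variation coefficients, and an errors-in-variables straight-line
fit forced through the origin (two methods must agree as counts approach
zero).

Because several samples have zero standard deviation in one or both
directions, per-point errors cannot be used; instead an average relative
error (variation coefficient) is assigned per axis and the slope ``b``
of ``y = b·x`` is found by minimizing the effective-variance chi-square

    χ²(b) = Σᵢ (yᵢ − b·xᵢ)² / ((b·cv_x·xᵢ)² + (cv_y·yᵢ)²),

in which each residual is normalized by the combined x- and y-error
variance projected through the fitted line.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

_TABLE_RESOURCE = "table1.csv"


@dataclass(frozen=True)
class EnumerationRecord:
    """One benchmark sample: three-way enumeration of a single plate.

    Counts are full-plate equivalents (segment counts already scaled by
    6); rates are in counted colonies per second.  Means and standard
    deviations summarize three enumerations each; the automatic count has
    no spread because the parameterized pipeline is deterministic.
    """

    sample_id: int
    gold_rate_mean: float
    gold_rate_sd: float
    gold_count_mean: float
    gold_count_sd: float
    manual_rate_mean: float
    manual_rate_sd: float
    manual_count_mean: float
    manual_count_sd: float
    auto_count: int
    ratio_auto_gold: float
    ratio_manual_gold: float
    segments_per_plate: int

    def __post_init__(self) -> None:
        if self.segments_per_plate not in (1, 6):
            raise ValueError("segments_per_plate must be 1 or 6")
        for name in ("gold_count_mean", "gold_count_sd", "manual_count_mean",
                     "manual_count_sd", "auto_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RegressionResult:
    """Origin-constrained effective-variance fit ``y = slope·x``."""

    slope: float
    ci95_low: float
    ci95_high: float
    cv_x: float
    cv_y: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.ci95_low <= self.slope <= self.ci95_high:
            raise ValueError("slope must lie inside its confidence interval")


def load_table1(path: str | Path | None = None) -> list[EnumerationRecord]:
    """Load the packaged 25-sample benchmark table (or a CSV like it)."""
    if path is None:
        source = resources.files("colonycount.data") / _TABLE_RESOURCE
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    records: list[EnumerationRecord] = []
    reader = csv.DictReader(text.splitlines())
    for lineno, row in enumerate(reader, start=2):
        try:
            records.append(EnumerationRecord(
                sample_id=int(row["sample_id"]),
                gold_rate_mean=float(row["gold_rate_mean"]),
                gold_rate_sd=float(row["gold_rate_sd"]),
                gold_count_mean=float(row["gold_count_mean"]),
                gold_count_sd=float(row["gold_count_sd"]),
                manual_rate_mean=float(row["manual_rate_mean"]),
                manual_rate_sd=float(row["manual_rate_sd"]),
                manual_count_mean=float(row["manual_count_mean"]),
                manual_count_sd=float(row["manual_count_sd"]),
                auto_count=int(row["auto_count"]),
                ratio_auto_gold=float(row["ratio_auto_gold"]),
                ratio_manual_gold=float(row["ratio_manual_gold"]),
                segments_per_plate=int(row["segments_per_plate"]),
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed benchmark table at row {lineno}: "
                             f"{exc}") from exc
    return records


def mean_variation_coefficient(values: list[tuple[float, float]]) -> float:
    """Average of sd/mean over (mean, sd) pairs, as a percentage."""
    if not values:
        raise ValueError("values must be non-empty")
    cvs = []
    for mean, sd in values:
        if mean <= 0:
            raise ValueError("variation coefficient needs a positive mean")
        cvs.append(sd / mean)
    return 100.0 * float(np.mean(cvs))


def mean_rate(rates: list[float]) -> float:
    """Arithmetic mean of per-sample mean counting rates (counts/s)."""
    if not rates:
        raise ValueError("rates must be non-empty")
    return float(np.mean(rates))


def origin_regression(x, y, cv_x: float, cv_y: float) -> RegressionResult:
    """Fit ``y = b·x`` through the origin with assigned relative errors.

    Minimizes the effective-variance chi-square over ``b > 0`` (a single
    free parameter, solved by bounded scalar minimization to 1e-10).  The
    95 % interval is ``b ± 1.96·SE`` with the standard error taken from
    the curvature of the chi-square at its minimum (Δχ² = 1 rule).
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 2:
        raise ValueError("x and y must be equal-length 1-D with >= 2 points")
    if np.any(xa <= 0):
        raise ValueError("all x must be positive")
    if cv_x <= 0 or cv_y <= 0:
        raise ValueError("cv_x and cv_y must be positive")

    def chi2(b: float) -> float:
        return float(np.sum((ya - b * xa) ** 2
                            / ((b * cv_x * xa) ** 2 + (cv_y * ya) ** 2)))

    ratio = ya / xa
    hi = max(1.0, 10.0 * float(ratio.max()))
    res = minimize_scalar(chi2, bounds=(1e-9, hi), method="bounded",
                          options={"xatol": 1e-10, "maxiter": 10_000})
    if not res.success:
        raise RuntimeError(f"slope optimization failed: {res.message}")
    b = float(res.x)
    h = max(1e-6 * b, 1e-9)
    curv = (chi2(b + h) - 2.0 * chi2(b) + chi2(b - h)) / (h * h)
    if curv <= 0:
        raise RuntimeError("chi-square curvature non-positive at the minimum")
    se = float(np.sqrt(2.0 / curv))
    return RegressionResult(slope=b, ci95_low=b - 1.96 * se,
                            ci95_high=b + 1.96 * se, cv_x=cv_x, cv_y=cv_y,
                            n_points=int(xa.size))


def correction_factor(result: RegressionResult | float) -> float:
    """Multiplier that makes the compared method match the reference.

    Computed as the reciprocal of the slope *rounded to its reported
    precision* (3 decimals) — the factor a reader would derive from the
    printed slope — and itself rounded to 3 decimals.
    """
    slope = result.slope if isinstance(result, RegressionResult) else result
    if slope <= 0:
        raise ValueError("slope must be positive")
    return round(1.0 / round(slope, 3), 3)


def method_comparison(records: list[EnumerationRecord] | None = None) -> dict:
    """Full benchmark summary: slopes, CIs, factors, mean CVs and rates.

    Returns a flat dict of the headline numbers, rounded the way they
    are conventionally reported (slopes and factors to 3 decimals, CVs
    to whole percent, rates to 1 decimal).
    """
    if records is None:
        records = load_table1()
    x = np.array([r.gold_count_mean for r in records])
    y_auto = np.array([float(r.auto_count) for r in records])
    y_manual = np.array([r.manual_count_mean for r in records])
    fit_auto = origin_regression(x, y_auto, cv_x=0.01, cv_y=0.001)
    fit_manual = origin_regression(x, y_manual, cv_x=0.01, cv_y=0.05)
    return {
        "n_samples": len(records),
        "slope_auto": round(fit_auto.slope, 3),
        "slope_auto_ci95": (round(fit_auto.ci95_low, 3),
                            round(fit_auto.ci95_high, 3)),
        "slope_manual": round(fit_manual.slope, 3),
        "slope_manual_ci95": (round(fit_manual.ci95_low, 3),
                              round(fit_manual.ci95_high, 3)),
        "factor_auto": correction_factor(fit_auto),
        "factor_manual": correction_factor(fit_manual),
        "cv_gold_percent": round(mean_variation_coefficient(
            [(r.gold_count_mean, r.gold_count_sd) for r in records])),
        "cv_manual_percent": round(mean_variation_coefficient(
            [(r.manual_count_mean, r.manual_count_sd) for r in records])),
        "rate_gold": round(mean_rate([r.gold_rate_mean for r in records]), 1),
        "rate_manual": round(mean_rate(
            [r.manual_rate_mean for r in records]), 1),
    }
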