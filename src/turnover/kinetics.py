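"""Turnover kinetics: %old transformation, log-linear decay fits, half-lives.

The pulse-chase design labels the pre-existing proteome with heavy Lys/Arg
and chases with light medium, so for each peptide the heavy channel reads
"old" protein. With AR the new/old area ratio, the fraction of signal from
old protein is

    %old = 100 * 1 / (1 + AR).

Under first-order decay in non-dividing cells, ln(%old) is linear in chase
time t:

    ln(%old) = k t + a,      k < 0,

so each peptide timecourse is fit by ordinary least squares in log space.
Fits are kept only when they are informative (detected in at least
``min_timepoints`` timepoints, r^2 above ``min_r_squared``, negative
slope); the retained peptide slopes of a protein are averaged and
converted to a half-life

    T_1/2 = -ln(2) / k_mean.

A 0-3 day chase resolves half-lives well between about 1 and 8 days; the
``precision_flag`` marks estimates outside that window as imprecise
(decay too fast to be sampled, or slope too shallow to distinguish from
zero) rather than dropping them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DomainError
from .peptide_qc import QCConfig, QCReport, qc_filter
from .tables_io import PeptideObservation

__all__ = [
    "FitConfig",
    "PeptideTimecourse",
    "PeptideFit",
    "ProteinTurnover",
    "PipelineResult",
    "percent_old",
    "build_timecourses",
    "fit_peptide",
    "aggregate_protein",
    "run_pipeline",
    "median_turnover_curve",
    "half_life_from_slope",
]

FLAG_RELIABLE = "reliable"
FLAG_BELOW = "below_window"
FLAG_ABOVE = "above_window"


@dataclass(frozen=True)
class FitConfig:
    """Fit and aggregation settings (defaults as published)."""

    min_timepoints: int = 3
    min_r_squared: float = 0.8
    precision_window_days: tuple[float, float] = (1.0, 8.0)

    def __post_init__(self) -> None:
        if self.min_timepoints < 2:
            raise ConfigurationError("min_timepoints must be at least 2")
        low, high = self.precision_window_days
        if not 0 < low < high:
            raise ConfigurationError(
                f"precision window must satisfy 0 < low < high, got {low}, {high}"
            )


@dataclass(frozen=True)
class PeptideTimecourse:
    """%old of one peptide across chase timepoints (times strictly increasing)."""

    protein_id: str
    peptide_seq: str
    timepoints: tuple[float, ...]
    percent_old: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.percent_old) or not self.timepoints:
            raise DomainError("timecourse needs matching, non-empty point lists")
        if any(t2 <= t1 for t1, t2 in zip(self.timepoints, self.timepoints[1:])):
            raise DomainError("timepoints must be strictly increasing")
        if any(not (0 < p <= 100) for p in self.percent_old):
            raise DomainError("percent_old values must lie in (0, 100]")

    @property
    def n_points(self) -> int:
        return len(self.timepoints)


@dataclass(frozen=True)
class PeptideFit:
    """OLS fit of ln(%old) against time for one peptide."""

    protein_id: str
    peptide_seq: str
    slope_k: float
    intercept_a: float
    r_squared: float
    n_points: int
    passed: bool


@dataclass(frozen=True)
class ProteinTurnover:
    """Protein-level turnover estimate aggregated over passing peptide fits."""

    protein_id: str
    n_peptides_used: int
    mean_slope: float
    sd_slope: float
    sem_slope: float
    half_life_days: float
    precision_flag: str


@dataclass
class PipelineResult:
    """End-to-end pipeline output: protein estimates plus accounting."""

    proteins: list[ProteinTurnover]
    qc_report: QCReport
    summary: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "protein_id": p.protein_id,
                    "n_peptides_used": p.n_peptides_used,
                    "mean_slope_per_day": p.mean_slope,
                    "sd_slope": p.sd_slope,
                    "sem_slope": p.sem_slope,
                    "half_life_days": p.half_life_days,
                    "precision_flag": p.precision_flag,
                }
                for p in self.proteins
            ]
        )


def percent_old(area_ratio):
    """Transform an area ratio into the percentage of old protein.

    %old = 100 / (1 + AR); AR = 0 (no new protein detected) gives 100,
    AR = 1 gives 50. Accepts scalars or arrays; AR must be finite and
    non-negative.
    """
    ar = np.asarray(area_ratio, dtype=float)
    if np.any(~np.isfinite(ar)) or np.any(ar < 0):
        raise DomainError(f"area ratio must be finite and >= 0, got {area_ratio!r}")
    result = 100.0 / (1.0 + ar)
    return float(result) if np.isscalar(area_ratio) or result.ndim == 0 else result


def half_life_from_slope(slope: float) -> float:
    """T_1/2 = -ln(2)/k for a negative first-order decay slope (per day)."""
    if not (slope < 0 and math.isfinite(slope)):
        raise DomainError(f"half-life requires a finite negative slope, got {slope}")
    return -math.log(2.0) / slope


def build_timecourses(
    observations: Sequence[PeptideObservation],
) -> list[PeptideTimecourse]:
    """Group QC-retained observations into per-peptide %old timecourses.

    Duplicate timepoints within one peptide (e.g. the same peptide
    quantified in two charge states) are collapsed by the arithmetic mean
    of their %old values; points are sorted by time.
    """
    grouped: dict[tuple[str, str], dict[float, list[float]]] = {}
    order: list[tuple[str, str]] = []
    for obs in observations:
        key = (obs.protein_id, obs.peptide_seq)
        if key not in grouped:
            grouped[key] = {}
            order.append(key)
        grouped[key].setdefault(obs.timepoint, []).append(
            percent_old(obs.area_ratio)
        )
    timecourses = []
    for key in order:
        points = sorted(
            (t, float(np.mean(vals))) for t, vals in grouped[key].items()
        )
        timecourses.append(
            PeptideTimecourse(
                protein_id=key[0],
                peptide_seq=key[1],
                timepoints=tuple(t for t, _ in points),
                percent_old=tuple(p for _, p in points),
            )
        )
    return timecourses


def fit_peptide(tc: PeptideTimecourse, config: FitConfig | None = None) -> PeptideFit:
    """Fit ln(%old) = k t + a by ordinary least squares.

    r^2 is the squared sample correlation between ln(%old) and t. The fit
    passes when the peptide was seen at >= ``min_timepoints`` timepoints,
    r^2 exceeds ``min_r_squared`` and the slope is negative. Degenerate
    timecourses (a single point, or zero time variance after collapsing)
    are marked failed with undefined slope.
    """
    config = config or FitConfig()
    t = np.asarray(tc.timepoints, dtype=float)
    y = np.log(np.asarray(tc.percent_old, dtype=float))
    if tc.n_points < 2 or np.ptp(t) == 0:
        return PeptideFit(
            tc.protein_id, tc.peptide_seq,
            slope_k=math.nan, intercept_a=math.nan, r_squared=math.nan,
            n_points=tc.n_points, passed=False,
        )
    res = stats.linregress(t, y)
    r_squared = res.rvalue ** 2
    if not math.isfinite(r_squared):  # constant y: correlation undefined
        r_squared = 0.0
    passed = (
        tc.n_points >= config.min_timepoints
        and r_squared > config.min_r_squared
        and res.slope < 0
    )
    return PeptideFit(
        tc.protein_id, tc.peptide_seq,
        slope_k=float(res.slope), intercept_a=float(res.intercept),
        r_squared=float(r_squared), n_points=tc.n_points, passed=passed,
    )


def _flag(half_life: float, config: FitConfig) -> str:
    # relative epsilon so a half-life exactly at a window edge is never
    # reclassified by last-bit rounding of the fitted slope
    low, high = config.precision_window_days
    if half_life < low * (1 - 1e-12):
        return FLAG_BELOW
    if half_life > high * (1 + 1e-12):
        return FLAG_ABOVE
    return FLAG_RELIABLE


def aggregate_protein(
    fits: Sequence[PeptideFit], config: FitConfig | None = None
) -> ProteinTurnover | None:
    """Average passing peptide slopes into one protein-level estimate.

    Returns None (protein excluded) when no fit passed. The mean slope is
    the unweighted arithmetic mean of passing slopes; the spread is the
    sample standard deviation (0 for a single peptide) and its standard
    error. Since only negative slopes pass, the mean slope is negative and
    the half-life is always positive.
    """
    config = config or FitConfig()
    passing = [f for f in fits if f.passed]
    if not passing:
        return None
    protein_ids = {f.protein_id for f in passing}
    if len(protein_ids) != 1:
        raise DomainError(f"fits span multiple proteins: {sorted(protein_ids)}")
    slopes = np.array([f.slope_k for f in passing])
    mean_slope = float(slopes.mean())
    assert mean_slope < 0, "only negative slopes pass the fit filter"
    sd = float(slopes.std(ddof=1)) if len(slopes) > 1 else 0.0
    sem = sd / math.sqrt(len(slopes))
    half_life = half_life_from_slope(mean_slope)
    return ProteinTurnover(
        protein_id=protein_ids.pop(),
        n_peptides_used=len(passing),
        mean_slope=mean_slope,
        sd_slope=sd,
        sem_slope=sem,
        half_life_days=half_life,
        precision_flag=_flag(half_life, config),
    )


def run_pipeline(
    observations: Sequence[PeptideObservation],
    qc_config: QCConfig | None = None,
    fit_config: FitConfig | None = None,
) -> PipelineResult:
    """QC -> timecourses -> peptide fits -> protein half-lives, with summary.

    The summary reports the protein counts at the two attrition stages
    (>= min_timepoints detections for at least one peptide; at least one
    passing fit), the distribution of half-lives, and the per-flag counts.
    Deterministic given its inputs.
    """
    qc_config = qc_config or QCConfig()
    fit_config = fit_config or FitConfig()
    retained, qc_report = qc_filter(observations, qc_config)
    timecourses = build_timecourses(retained)

    fits_by_protein: dict[str, list[PeptideFit]] = {}
    proteins_with_enough_timepoints: set[str] = set()
    for tc in timecourses:
        if tc.n_points >= fit_config.min_timepoints:
            proteins_with_enough_timepoints.add(tc.protein_id)
        fit = fit_peptide(tc, fit_config)
        fits_by_protein.setdefault(tc.protein_id, []).append(fit)

    proteins: list[ProteinTurnover] = []
    n_excluded = 0
    for protein_id in sorted(proteins_with_enough_timepoints):
        result = aggregate_protein(fits_by_protein[protein_id], fit_config)
        if result is None:
            n_excluded += 1
        else:
            proteins.append(result)

    half_lives = np.array([p.half_life_days for p in proteins])
    flags = [p.precision_flag for p in proteins]
    summary = {
        "n_observations_input": qc_report.n_input,
        "n_observations_retained": qc_report.n_retained,
        "n_peptides_fit": sum(len(v) for v in fits_by_protein.values()),
        "n_proteins_min_timepoints": len(proteins_with_enough_timepoints),
        "n_proteins_with_halflife": len(proteins),
        "n_proteins_excluded_no_passing_fit": n_excluded,
        "median_half_life_days": float(np.median(half_lives)) if len(half_lives) else None,
        "q1_half_life_days": float(np.percentile(half_lives, 25)) if len(half_lives) else None,
        "q3_half_life_days": float(np.percentile(half_lives, 75)) if len(half_lives) else None,
        "n_below_window": flags.count(FLAG_BELOW),
        "n_reliable": flags.count(FLAG_RELIABLE),
        "n_above_window": flags.count(FLAG_ABOVE),
    }
    return PipelineResult(proteins=proteins, qc_report=qc_report, summary=summary)


def median_turnover_curve(
    timecourses: Sequence[PeptideTimecourse],
) -> pd.DataFrame:
    """Median and SD of protein-level mean %old at each timepoint.

    Each protein contributes, per timepoint, the mean %old over its
    peptides detected there; the curve is the across-protein median with
    one standard deviation, which is how the cohort's turnover behaviour
    is summarised against individual fast/slow proteins.
    """
    if not timecourses:
        raise DomainError("median_turnover_curve requires at least one timecourse")
    per_protein: dict[str, dict[float, list[float]]] = {}
    for tc in timecourses:
        bucket = per_protein.setdefault(tc.protein_id, {})
        for t, p in zip(tc.timepoints, tc.percent_old):
            bucket.setdefault(t, []).append(p)
    per_time: dict[float, list[float]] = {}
    for bucket in per_protein.values():
        for t, values in bucket.items():
            per_time.setdefault(t, []).append(float(np.mean(values)))
    rows = [
        {
            "timepoint": t,
            "median_percent_old": float(np.median(vals)),
            "sd_percent_old": float(np.std(vals)),
            "n_proteins": len(vals),
        }
        for t, vals in sorted(per_time.items())
    ]
    return pd.DataFrame(rows)
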