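"""Peptide-level quality control.

Census-style SILAC quantification attaches two quality metrics to each
peptide observation: a profile score (isotope-envelope fit) and a
regression score (correlation of the heavy and light chromatograms).
Before any kinetic fitting, observations are gated on these scores:

1. any observation with profile score < 0.8 is discarded;
2. observations with *extreme* area ratios (AR < 0.111 or AR > 9) are
   retained only if their regression score is > 0;
3. observations with *intermediate* area ratios (0.111 <= AR <= 9) are
   retained only if their regression score is > 0.8.

Extreme ratios correspond to nearly fully-old or fully-new peptides, where
one chromatogram is close to noise and the heavy/light correlation is
expected to be weak even for a correct quantification — hence the laxer
regression-score gate for that class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import ConfigurationError
from .tables_io import PeptideObservation


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the peptide quality gates (defaults as published)."""

    min_profile_score: float = 0.8
    ar_low: float = 0.111
    ar_high: float = 9.0
    min_regscore_extreme: float = 0.0
    min_regscore_intermediate: float = 0.8

    def __post_init__(self) -> None:
        values = (
            self.min_profile_score, self.ar_low, self.ar_high,
            self.min_regscore_extreme, self.min_regscore_intermediate,
        )
        if not all(math.isfinite(v) for v in values):
            raise ConfigurationError("QC thresholds must all be finite")
        if not self.ar_low < self.ar_high:
            raise ConfigurationError(
                f"ar_low ({self.ar_low}) must be below ar_high ({self.ar_high})"
            )


@dataclass
class QCReport:
    """Tally of QC outcomes; input = retained + dropped (by reason)."""

    n_input: int = 0
    n_dropped_profile: int = 0
    n_dropped_regscore: int = 0
    n_retained: int = 0

    def __post_init__(self) -> None:
        assert self.n_input == (
            self.n_retained + self.n_dropped_profile + self.n_dropped_regscore
        ), "QC tallies do not conserve counts"


def is_extreme(area_ratio: float, config: QCConfig) -> bool:
    """AR class: strict inequalities, so the boundaries 0.111 and 9 count
    as intermediate."""
    return area_ratio < config.ar_low or area_ratio > config.ar_high


def passes_qc(obs: PeptideObservation, config: QCConfig) -> bool:
    """Evaluate the gate rules for a single observation."""
    if obs.profile_score < config.min_profile_score:
        return False
    if is_extreme(obs.area_ratio, config):
        return obs.regression_score > config.min_regscore_extreme
    return obs.regression_score > config.min_regscore_intermediate


def qc_filter(
    observations: Sequence[PeptideObservation], config: QCConfig | None = None
) -> tuple[list[PeptideObservation], QCReport]:
    """Apply the quality gates, returning retained observations and a tally.

    The profile gate is evaluated first, so a row failing both gates is
    counted under the profile reason.
    """
    config = config or QCConfig()
    retained: list[PeptideObservation] = []
    n_profile = 0
    n_regscore = 0
    for obs in observations:
        if obs.profile_score < config.min_profile_score:
            n_profile += 1
        elif not passes_qc(obs, config):
            n_regscore += 1
        else:
            retained.append(obs)
    report = QCReport(
        n_input=len(observations),
        n_dropped_profile=n_profile,
        n_dropped_regscore=n_regscore,
        n_retained=len(retained),
    )
    return retained, report
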