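"""Synthetic dynamic-SILAC pulse-chase peptide tables.

Emulates the statistical structure the analysis assumes: each protein
decays exponentially with its own half-life, several tryptic peptides
report on each protein at a handful of chase timepoints (day 0-3 by
default), the observed area ratio carries multiplicative log-normal noise,
observations go missing at random (detection dropout), and a configurable
fraction of rows carries quality scores that fail QC.

The generative model inverts the analysis equations: a half-life T drawn
from the configured distribution gives the decay slope k = -ln(2)/T, the
old-protein fraction at chase time t is f(t) = exp(k t), and the
noise-free area ratio is AR = (1 - f)/f (new over old). At t = 0 no new
protein exists, so AR is exactly 0; multiplicative noise leaves that zero
untouched, i.e. day-0 rows are noise-free in AR by construction.

All randomness flows from a single seeded generator in a fixed draw order
(per protein: half-life, peptide count, peptide sequences; then per row:
noise multiplier, dropout, badness, scores), so a config is fully
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .tables_io import PeptideObservation

_AMINO_ACIDS = np.array(list("ACDEFGHILMNPQSTVWY"))  # no K/R except C-terminal


@dataclass(frozen=True)
class ScoreModel:
    """Sampling model for profile/regression quality scores.

    Good rows draw both scores high enough to pass every QC gate; bad rows
    (fraction ``bad_fraction``) fail either the profile gate or the
    regression gate, split evenly.
    """

    bad_fraction: float = 0.1
    good_profile_range: tuple[float, float] = (0.85, 1.0)
    good_regression_range: tuple[float, float] = (0.85, 1.0)
    bad_profile_range: tuple[float, float] = (0.0, 0.75)
    bad_regression_range: tuple[float, float] = (-1.0, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.bad_fraction <= 1.0:
            raise ConfigurationError("bad_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Study design of a simulated pulse-chase experiment.

    Defaults mirror the 4-timepoint (day 0-3) chase in non-dividing cells
    with a wide half-life range spanning well beyond the 1-8 day window the
    design resolves precisely.
    """

    n_proteins: int = 200
    peptides_per_protein: int | tuple[int, int] = 3
    timepoints: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    halflife_dist: str = "log-uniform"  # or "log-normal"
    halflife_params: tuple[float, float] = (0.5, 16.0)  # range, or (median, sigma_ln)
    ar_noise_sigma: float = 0.1
    dropout_prob: float = 0.2
    score_model: ScoreModel = field(default_factory=ScoreModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be positive")
        if any(t < 0 for t in self.timepoints) or not self.timepoints:
            raise ConfigurationError("timepoints must be non-negative and non-empty")
        if self.ar_noise_sigma < 0:
            raise ConfigurationError("ar_noise_sigma must be >= 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ConfigurationError("dropout_prob must lie in [0, 1]")
        if self.halflife_dist not in ("log-uniform", "log-normal"):
            raise ConfigurationError(
                f"halflife_dist must be 'log-uniform' or 'log-normal', "
                f"got {self.halflife_dist!r}"
            )
        if isinstance(self.peptides_per_protein, tuple):
            lo, hi = self.peptides_per_protein
            if not 1 <= lo <= hi:
                raise ConfigurationError("peptide count range must satisfy 1 <= lo <= hi")
        elif self.peptides_per_protein < 1:
            raise ConfigurationError("peptides_per_protein must be positive")


@dataclass
class SimTruth:
    """Ground truth of a simulated table.

    ``proteins`` has one row per protein (protein_id, half_life_days,
    slope_k); ``rows`` has one row per emitted observation with the
    uncorrupted area ratio.
    """

    proteins: pd.DataFrame
    rows: pd.DataFrame


def _draw_halflife(config: SimConfig, rng: np.random.Generator) -> float:
    if config.halflife_dist == "log-uniform":
        lo, hi = config.halflife_params
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    median, sigma = config.halflife_params
    return float(np.exp(rng.normal(np.log(median), sigma)))


def _peptide_seq(rng: np.random.Generator, length: int = 9) -> str:
    body = "".join(rng.choice(_AMINO_ACIDS, size=length - 1))
    return body + str(rng.choice(np.array(["K", "R"])))


def true_area_ratio(half_life_days: float, timepoint: float) -> float:
    """Noise-free AR at chase time t: (1 - f)/f with f = 2^(-t/T)."""
    f = math.exp(-math.log(2.0) / half_life_days * timepoint)
    return (1.0 - f) / f


def simulate_table(
    config: SimConfig | None = None,
) -> tuple[list[PeptideObservation], SimTruth]:
    """Generate a peptide observation table plus its ground truth."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    sm = config.score_model

    observations: list[PeptideObservation] = []
    protein_rows = []
    truth_rows = []
    for i in range(config.n_proteins):
        protein_id = f"SIM{i + 1:05d}"
        half_life = _draw_halflife(config, rng)
        slope = -math.log(2.0) / half_life
        protein_rows.append(
            {"protein_id": protein_id, "half_life_days": half_life, "slope_k": slope}
        )
        if isinstance(config.peptides_per_protein, tuple):
            lo, hi = config.peptides_per_protein
            n_peptides = int(rng.integers(lo, hi + 1))
        else:
            n_peptides = config.peptides_per_protein
        peptides = set()
        while len(peptides) < n_peptides:
            peptides.add(_peptide_seq(rng))
        for peptide_seq in sorted(peptides):
            for t in config.timepoints:
                ar_true = true_area_ratio(half_life, t)
                noise = (
                    math.exp(rng.normal(0.0, config.ar_noise_sigma))
                    if config.ar_noise_sigma > 0
                    else 1.0
                )
                dropped = rng.uniform() < config.dropout_prob
                bad = rng.uniform() < sm.bad_fraction
                if bad:
                    # split bad rows evenly between the two failure modes
                    if rng.uniform() < 0.5:
                        profile = float(rng.uniform(*sm.bad_profile_range))
                        regression = float(rng.uniform(*sm.good_regression_range))
                    else:
                        profile = float(rng.uniform(*sm.good_profile_range))
                        regression = float(rng.uniform(*sm.bad_regression_range))
                else:
                    profile = float(rng.uniform(*sm.good_profile_range))
                    regression = float(rng.uniform(*sm.good_regression_range))
                if dropped:
                    continue
                observations.append(
                    PeptideObservation(
                        protein_id=protein_id,
                        peptide_seq=peptide_seq,
                        timepoint=float(t),
                        area_ratio=ar_true * noise,
                        profile_score=profile,
                        regression_score=regression,
                    )
                )
                truth_rows.append(
                    {
                        "protein_id": protein_id,
                        "peptide_seq": peptide_seq,
                        "timepoint": float(t),
                        "true_area_ratio": ar_true,
                        "qc_bad": bad,
                    }
                )
    truth = SimTruth(
        proteins=pd.DataFrame(protein_rows),
        rows=pd.DataFrame(
            truth_rows,
            columns=["protein_id", "peptide_seq", "timepoint", "true_area_ratio", "qc_bad"],
        ),
    )
    return observations, truth


def sim_config_from_dict(raw: dict) -> SimConfig:
    """Build a SimConfig from a YAML-style dictionary."""
    raw = dict(raw)
    if "score_model" in raw and isinstance(raw["score_model"], dict):
        sm = dict(raw["score_model"])
        for key in (
            "good_profile_range", "good_regression_range",
            "bad_profile_range", "bad_regression_range",
        ):
            if key in sm:
                sm[key] = tuple(sm[key])
        raw["score_model"] = ScoreModel(**sm)
    for key in ("timepoints", "halflife_params"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "peptides_per_protein" in raw and isinstance(raw["peptides_per_protein"], list):
        raw["peptides_per_protein"] = tuple(raw["peptides_per_protein"])
    try:
        return SimConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"invalid simulation config: {exc}") from exc
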