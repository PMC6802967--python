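"""Tabular input/output for the turnover pipeline.

Reads peptide-level quantification tables in the style of Census SILAC
output (one row per peptide observation: accession, sequence, chase
timepoint in days, heavy/light area ratio, profile score, regression
score), plus the small side tables the downstream analyses need (protein
group labels, extraluminal domain sizes), and writes the protein-level
result table.

Column naming of quantification exports varies between Census versions and
lab pipelines, so the six semantic fields are bound to file columns through
an explicit :class:`ColumnMap` rather than hard-coded names.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: Semantic fields every peptide table must provide.
SEMANTIC_FIELDS = (
    "protein_id",
    "peptide_seq",
    "timepoint",
    "area_ratio",
    "profile_score",
    "regression_score",
)

#: Fixed header of the protein-level output table.
PROTEIN_TABLE_COLUMNS = (
    "protein_id",
    "n_peptides_used",
    "mean_slope_per_day",
    "sd_slope",
    "sem_slope",
    "half_life_days",
    "precision_flag",
)


@dataclass(frozen=True)
class PeptideObservation:
    """One quantified peptide at one chase timepoint.

    ``area_ratio`` is the Census area ratio AR entering the
    %old = 100/(1+AR) transformation; ``profile_score`` and
    ``regression_score`` are the quantification quality metrics used as
    QC gates downstream.
    """

    protein_id: str
    peptide_seq: str
    timepoint: float
    area_ratio: float
    profile_score: float
    regression_score: float

    def __post_init__(self) -> None:
        if not (self.timepoint >= 0 and math.isfinite(self.timepoint)):
            raise ValidationError(
                f"timepoint must be a finite non-negative number of days, "
                f"got {self.timepoint!r} for {self.protein_id}/{self.peptide_seq}"
            )
        if not (self.area_ratio >= 0 and math.isfinite(self.area_ratio)):
            raise ValidationError(
                f"area_ratio must be finite and >= 0, got {self.area_ratio!r} "
                f"for {self.protein_id}/{self.peptide_seq}"
            )
        if not 0.0 <= self.profile_score <= 1.0:
            raise ValidationError(
                f"profile_score must lie in [0, 1], got {self.profile_score!r} "
                f"for {self.protein_id}/{self.peptide_seq}"
            )


@dataclass(frozen=True)
class ColumnMap:
    """Binding of the six semantic peptide fields to file columns.

    Defaults use the semantic names themselves, which is the dialect the
    bundled simulator writes.
    """

    protein_id: str = "protein_id"
    peptide_seq: str = "peptide_seq"
    timepoint: str = "timepoint"
    area_ratio: str = "area_ratio"
    profile_score: str = "profile_score"
    regression_score: str = "regression_score"
    delimiter: str = "\t"
    na_tokens: tuple[str, ...] = ("NA", "NaN", "")

    def as_dict(self) -> dict[str, str]:
        return {f: getattr(self, f) for f in SEMANTIC_FIELDS}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMap":
        """Load a column map from a YAML file of ``semantic: column`` pairs."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"column map {path} must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(
                f"column map {path} has unknown keys: {sorted(unknown)}"
            )
        if "na_tokens" in raw:
            raw["na_tokens"] = tuple(raw["na_tokens"])
        return cls(**raw)


@dataclass(frozen=True)
class GroupAssignment:
    """Membership of one protein in one comparison group (e.g. INM, NET, ER)."""

    protein_id: str
    group_label: str


@dataclass
class TableReadReport:
    """Accounting of rows seen and dropped while reading a peptide table."""

    n_rows: int = 0
    n_dropped_missing: int = 0
    n_dropped_invalid: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_missing + self.n_dropped_invalid

    @property
    def n_read(self) -> int:
        return self.n_rows - self.n_dropped


def read_peptide_table(
    path: str | Path,
    colmap: ColumnMap | None = None,
    invert_area_ratio: bool = False,
) -> tuple[list[PeptideObservation], TableReadReport]:
    """Read a peptide quantification table.

    Rows with missing-value tokens in a required numeric field are dropped
    and counted; rows with a negative area ratio are rejected and logged.
    ``invert_area_ratio`` replaces AR by 1/AR for tables whose ratio is
    oriented old/new instead of new/old (the orientation the %old formula
    assumes).

    Raises
    ------
    ConfigurationError
        If the header lacks a mapped column.
    ValidationError
        If the same (protein, peptide, timepoint) occurs twice.
    """
    colmap = colmap or ColumnMap()
    path = Path(path)
    frame = pd.read_csv(
        path,
        sep=colmap.delimiter,
        na_values=list(colmap.na_tokens),
        keep_default_na=False,
        dtype={colmap.protein_id: str, colmap.peptide_seq: str},
    )
    missing_cols = [c for c in colmap.as_dict().values() if c not in frame.columns]
    if missing_cols:
        raise ConfigurationError(
            f"{path} is missing mapped column(s): {missing_cols}; "
            f"header has {list(frame.columns)}"
        )

    report = TableReadReport(n_rows=len(frame))
    frame = frame.rename(columns={v: k for k, v in colmap.as_dict().items()})
    frame = frame[list(SEMANTIC_FIELDS)]

    numeric_fields = list(SEMANTIC_FIELDS[2:])
    for col in numeric_fields:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    complete = frame.dropna(subset=list(SEMANTIC_FIELDS))
    report.n_dropped_missing = len(frame) - len(complete)

    observations: list[PeptideObservation] = []
    seen: set[tuple[str, str, float]] = set()
    for row in complete.itertuples(index=False):
        try:
            obs = PeptideObservation(
                protein_id=row.protein_id,
                peptide_seq=row.peptide_seq,
                timepoint=float(row.timepoint),
                area_ratio=float(row.area_ratio),
                profile_score=float(row.profile_score),
                regression_score=float(row.regression_score),
            )
        except ValidationError as exc:
            logger.warning("rejecting row in %s: %s", path, exc)
            report.n_dropped_invalid += 1
            continue
        if invert_area_ratio:
            inv = math.inf if obs.area_ratio == 0 else 1.0 / obs.area_ratio
            if not math.isfinite(inv):
                logger.warning(
                    "rejecting row in %s: area ratio 0 cannot be inverted "
                    "(%s/%s)", path, obs.protein_id, obs.peptide_seq,
                )
                report.n_dropped_invalid += 1
                continue
            obs = PeptideObservation(
                obs.protein_id, obs.peptide_seq, obs.timepoint,
                inv, obs.profile_score, obs.regression_score,
            )
        key = (obs.protein_id, obs.peptide_seq, obs.timepoint)
        if key in seen:
            raise ValidationError(
                f"duplicate observation for protein {key[0]}, peptide {key[1]}, "
                f"timepoint {key[2]} in {path}"
            )
        seen.add(key)
        observations.append(obs)
    return observations, report


def write_protein_table(results: Iterable, path: str | Path) -> None:
    """Write protein-level turnover results as a fixed-header TSV.

    Values round-trip losslessly at 6 significant digits through
    :func:`read_protein_table`.
    """
    rows = [
        {
            "protein_id": r.protein_id,
            "n_peptides_used": r.n_peptides_used,
            "mean_slope_per_day": r.mean_slope,
            "sd_slope": r.sd_slope,
            "sem_slope": r.sem_slope,
            "half_life_days": r.half_life_days,
            "precision_flag": r.precision_flag,
        }
        for r in results
    ]
    frame = pd.DataFrame(rows, columns=list(PROTEIN_TABLE_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_protein_table(path: str | Path) -> pd.DataFrame:
    """Read back a protein result table written by :func:`write_protein_table`."""
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = set(PROTEIN_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigurationError(
            f"{path} is not a protein result table; missing columns {sorted(missing)}"
        )
    return frame


def read_group_table(path: str | Path) -> list[GroupAssignment]:
    """Read a two-column (protein_id, group_label) table.

    A protein listed twice with the same label is de-duplicated; listed
    with conflicting labels it is an error.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep="\t", header=None, names=["protein_id", "group_label"],
            dtype=str, skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return []
    # tolerate an explicit header row
    if (
        len(frame)
        and frame.iloc[0, 0] == "protein_id"
        and frame.iloc[0, 1] == "group_label"
    ):
        frame = frame.iloc[1:]
    labels: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        if row.protein_id is None or row.group_label is None:
            raise ValidationError(f"malformed group row in {path}: {tuple(row)!r}")
        prev = labels.get(row.protein_id)
        if prev is not None and prev != row.group_label:
            raise ValidationError(
                f"protein {row.protein_id} assigned to conflicting groups "
                f"{prev!r} and {row.group_label!r} in {path}"
            )
        labels[row.protein_id] = row.group_label
    return [GroupAssignment(p, g) for p, g in labels.items()]


def read_size_table(path: str | Path) -> dict[str, float]:
    """Read a two-column (protein_id, size_in_residues) table."""
    try:
        frame = pd.read_csv(
            path, sep="\t", header=None, names=["protein_id", "size"], dtype=str
        )
    except pd.errors.EmptyDataError:
        return {}
    if len(frame) and frame.iloc[0, 0] == "protein_id":
        frame = frame.iloc[1:]
    return {
        row.protein_id: float(row.size) for row in frame.itertuples(index=False)
    }


def observations_to_frame(
    observations: Sequence[PeptideObservation], colmap: ColumnMap | None = None
) -> pd.DataFrame:
    """Render observations as a DataFrame under the given column names."""
    colmap = colmap or ColumnMap()
    frame = pd.DataFrame(
        [
            {
                colmap.protein_id: o.protein_id,
                colmap.peptide_seq: o.peptide_seq,
                colmap.timepoint: o.timepoint,
                colmap.area_ratio: o.area_ratio,
                colmap.profile_score: o.profile_score,
                colmap.regression_score: o.regression_score,
            }
            for o in observations
        ],
        columns=list(colmap.as_dict().values()),
    )
    return frame


def write_peptide_table(
    observations: Sequence[PeptideObservation],
    path: str | Path,
    colmap: ColumnMap | None = None,
) -> None:
    """Write observations as a TSV readable by :func:`read_peptide_table`."""
    colmap = colmap or ColumnMap()
    observations_to_frame(observations, colmap).to_csv(
        path, sep=colmap.delimiter, index=False
    )
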