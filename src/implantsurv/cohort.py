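"""Clustered right-censored time-to-event data: records, cohorts, design matrices.

The unit of analysis is one subject interval ``(entry, exit]`` with a binary
event indicator and a cluster (patient) identifier.  Categorical covariates
are described by a :class:`CovariateSpec` that fixes, per category, the
ordered list of levels and the reference level; the design matrix carries one
0/1 dummy column per non-reference level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "cluster_id", "entry_time", "exit_time", "event")


class CohortValidationError(ValueError):
    """Raised when a record or cohort violates a structural invariant."""


@dataclass(frozen=True)
class TimeToEventRecord:
    """One subject's observation interval ``(entry_time, exit_time]`` in days."""

    subject_id: str
    cluster_id: str
    entry_time: float
    exit_time: float
    event: int
    covariates: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.entry_time) or not np.isfinite(self.exit_time):
            raise CohortValidationError(
                f"record {self.subject_id!r}: non-finite times"
            )
        if self.entry_time < 0:
            raise CohortValidationError(
                f"record {self.subject_id!r}: entry_time must be >= 0"
            )
        if self.exit_time <= self.entry_time:
            raise CohortValidationError(
                f"record {self.subject_id!r}: exit_time ({self.exit_time}) must "
                f"exceed entry_time ({self.entry_time})"
            )
        if self.event not in (0, 1):
            raise CohortValidationError(
                f"record {self.subject_id!r}: event must be 0 or 1, got {self.event}"
            )


@dataclass(frozen=True)
class CovariateSpec:
    """Ordered categories, each with ordered levels and a reference level.

    ``categories`` maps category name -> ordered tuple of level labels; the
    first entry of ``references[cat]`` must be a member of that tuple.
    """

    categories: Mapping[str, tuple[str, ...]]
    references: Mapping[str, str]

    def __post_init__(self) -> None:
        for cat, levels in self.categories.items():
            if len(set(levels)) != len(levels):
                raise CohortValidationError(f"category {cat!r}: duplicate levels")
            ref = self.references.get(cat)
            if ref not in levels:
                raise CohortValidationError(
                    f"category {cat!r}: reference {ref!r} not among levels {levels}"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.categories)

    def dummy_columns(self) -> list[tuple[str, str]]:
        """(category, level) pairs for non-reference levels, in spec order."""
        cols = []
        for cat, levels in self.categories.items():
            ref = self.references[cat]
            cols.extend((cat, lev) for lev in levels if lev != ref)
        return cols

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateSpec":
        cats = {}
        refs = {}
        for cat, entry in d.items():
            levels = tuple(entry["levels"])
            cats[cat] = levels
            refs[cat] = entry.get("reference", levels[0])
        return cls(categories=cats, references=refs)

    def to_dict(self) -> dict:
        return {
            cat: {"levels": list(levels), "reference": self.references[cat]}
            for cat, levels in self.categories.items()
        }


def load_covariate_spec(path: str) -> CovariateSpec:
    """Load a covariate specification from a YAML or JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return CovariateSpec.from_dict(data)


class Cohort:
    """Validated collection of :class:`TimeToEventRecord` plus covariate spec.

    Internally stored as a :class:`pandas.DataFrame` for vectorised access;
    the ``records`` iterator exposes the per-record view.
    """

    def __init__(self, records: Sequence[TimeToEventRecord], covariate_spec: CovariateSpec):
        if len(records) == 0:
            raise CohortValidationError("cohort must contain at least one record")
        self.covariate_spec = covariate_spec
        rows = []
        for r in records:
            row = {
                "subject_id": r.subject_id,
                "cluster_id": r.cluster_id,
                "entry_time": float(r.entry_time),
                "exit_time": float(r.exit_time),
                "event": int(r.event),
            }
            for cat in covariate_spec.names:
                if cat not in r.covariates:
                    raise CohortValidationError(
                        f"record {r.subject_id!r}: missing covariate {cat!r}"
                    )
                lev = r.covariates[cat]
                if lev not in covariate_spec.categories[cat]:
                    raise CohortValidationError(
                        f"record {r.subject_id!r}: unknown level {lev!r} "
                        f"for category {cat!r}"
                    )
                row[cat] = lev
            rows.append(row)
        self.df = pd.DataFrame(rows)
        self.drop_report: list[str] = []

    # -- vectorised accessors ------------------------------------------------
    @property
    def entry(self) -> np.ndarray:
        return self.df["entry_time"].to_numpy(float)

    @property
    def exit(self) -> np.ndarray:
        return self.df["exit_time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.df["event"].to_numpy(int)

    @property
    def cluster_codes(self) -> np.ndarray:
        """Integer cluster codes 0..G-1 in order of first appearance."""
        return pd.factorize(self.df["cluster_id"])[0]

    @property
    def n_clusters(self) -> int:
        return int(self.df["cluster_id"].nunique())

    @property
    def n_events(self) -> int:
        return int(self.df["event"].sum())

    @property
    def person_time(self) -> float:
        return float((self.df["exit_time"] - self.df["entry_time"]).sum())

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> Iterator[TimeToEventRecord]:
        for _, row in self.df.iterrows():
            yield TimeToEventRecord(
                subject_id=str(row["subject_id"]),
                cluster_id=str(row["cluster_id"]),
                entry_time=float(row["entry_time"]),
                exit_time=float(row["exit_time"]),
                event=int(row["event"]),
                covariates={c: row[c] for c in self.covariate_spec.names},
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.covariate_spec == other.covariate_spec
            and self.df.equals(other.df)
        )

    def subset(self, mask: np.ndarray) -> "Cohort":
        sub = object.__new__(Cohort)
        sub.covariate_spec = self.covariate_spec
        sub.df = self.df.loc[np.asarray(mask, bool)].reset_index(drop=True)
        sub.drop_report = []
        if len(sub.df) == 0:
            raise CohortValidationError("subset selects no records")
        return sub


@dataclass(frozen=True)
class DesignMatrix:
    """0/1 dummy design for a cohort; reference levels contribute no column."""

    values: np.ndarray           # (n_records, n_columns) float
    columns: tuple[str, ...]     # "category=level" labels
    column_pairs: tuple[tuple[str, str], ...]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def column_index(self, category: str, level: str) -> int:
        return self.column_pairs.index((category, level))


def build_design(cohort: Cohort) -> DesignMatrix:
    """One dummy column per non-reference level; deterministic column order.

    Column order follows the covariate spec: categories in spec order, then
    levels in their declared order (skipping the reference level).
    """
    pairs = cohort.covariate_spec.dummy_columns()
    n = len(cohort)
    X = np.zeros((n, len(pairs)))
    for j, (cat, lev) in enumerate(pairs):
        X[:, j] = (cohort.df[cat] == lev).to_numpy(float)
    labels = tuple(f"{cat}={lev}" for cat, lev in pairs)
    return DesignMatrix(values=X, columns=labels, column_pairs=tuple(pairs))


def read_cohort(path: str, covariate_spec: CovariateSpec) -> Cohort:
    """Read a cohort CSV, dropping (and reporting) records with missing covariates.

    Required columns: ``subject_id, cluster_id, entry_time, exit_time, event``.
    ``entry_time`` may be omitted entirely, in which case it defaults to 0
    (observation measured from implant insertion).  Records with an empty cell
    in any modelled covariate are dropped with a log entry, mirroring the
    exclusion of incompletely observed subjects; no imputation is done.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in raw.columns and c != "entry_time"]
    if missing_cols:
        raise CohortValidationError(f"{path}: missing required columns {missing_cols}")
    if "entry_time" not in raw.columns:
        raw["entry_time"] = "0"

    records = []
    dropped = []
    for idx, row in raw.iterrows():
        missing = [c for c in covariate_spec.names if pd.isna(row.get(c))]
        if missing:
            dropped.append(
                f"row {idx + 2}: subject {row['subject_id']!r} dropped, "
                f"missing covariate(s) {missing}"
            )
            continue
        try:
            entry = float(row["entry_time"])
            exit_ = float(row["exit_time"])
            event = int(float(row["event"]))
        except (TypeError, ValueError) as exc:
            raise CohortValidationError(
                f"{path} row {idx + 2}: malformed numeric field ({exc})"
            ) from exc
        records.append(
            TimeToEventRecord(
                subject_id=str(row["subject_id"]),
                cluster_id=str(row["cluster_id"]),
                entry_time=entry,
                exit_time=exit_,
                event=event,
                covariates={c: str(row[c]) for c in covariate_spec.names},
            )
        )
    cohort = Cohort(records, covariate_spec)
    cohort.drop_report = dropped
    for msg in dropped:
        logger.info("read_cohort: %s", msg)
    return cohort


def write_cohort(cohort: Cohort, path: str) -> None:
    """Write the cohort in the same CSV dialect ``read_cohort`` consumes."""
    cols = list(REQUIRED_COLUMNS) + list(cohort.covariate_spec.names)
    cohort.df.to_csv(path, index=False, columns=cols)


# Covariate set of the implant-complication analysis: 7 categories whose
# non-reference levels give 14 dummy columns.
def implant_covariate_spec() -> CovariateSpec:
    return CovariateSpec(
        categories={
            "periodontal": ("Healthy", "Periodontitis", "No teeth"),
            "extent": ("Single", "Full jaw", "Partial jaw"),
            "age_group": ("<50", "50-59", "60-69", "70-79"),
            "sex": ("Female", "Male"),
            "ever_smoker": ("No", "Yes"),
            "product": ("Type A", "Type B", "Type C", "Type D"),
            "retention": ("Screw-retained", "Cemented", "Both"),
        },
        references={
            "periodontal": "Healthy",
            "extent": "Single",
            "age_group": "<50",
            "sex": "Female",
            "ever_smoker": "No",
            "product": "Type A",
            "retention": "Screw-retained",
        },
    )
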