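"""Core in-memory containers for tractometry data.

A tractometry study samples diffusion metrics (FA, MD, RD, AD, ...) at a
fixed number of equidistant nodes along the core trajectory of each major
white matter tract, for every subject.  The natural container is therefore a
collection of subject x node matrices, one per (metric, tract) pair, plus a
per-subject metadata table and a free-form parameter mapping.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TractometryDataset",
    "ValidationFinding",
    "ValidationReport",
    "validate",
]

#: metrics treated as diffusivities (must be positive where non-missing)
DIFFUSIVITY_METRICS = frozenset({"md", "rd", "ad"})


@dataclass
class TractometryDataset:
    """Subjects x tracts x nodes x metrics value store with metadata.

    Parameters
    ----------
    subject_ids : list of str
        Ordered, unique subject identifiers.  Row ``i`` of every value
        matrix belongs to ``subject_ids[i]``.
    tract_names : list of str
        Ordered, unique tract names (e.g. ``"Left Corticospinal"``).
    metric_names : list of str
        Ordered, unique lower-case metric names (e.g. ``"fa"``, ``"md"``).
    n_nodes : int
        Number of equidistant sample nodes per tract (default 100).
    values : dict
        Mapping ``(metric, tract) -> ndarray`` of shape
        ``(len(subject_ids), n_nodes)``; missing cells are NaN, and a
        missing matrix means no data for that (metric, tract).
    metadata : pandas.DataFrame
        One row per subject, indexed by subject ID; heterogeneous columns.
    params : dict
        Free-form analysis-parameter mapping (JSON-serializable values).
    """

    subject_ids: list[str]
    tract_names: list[str]
    metric_names: list[str]
    n_nodes: int = 100
    values: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metadata is None or (isinstance(self.metadata, pd.DataFrame) and self.metadata.empty and len(self.metadata.columns) == 0):
            self.metadata = pd.DataFrame(index=pd.Index(self.subject_ids, name="subjectID"))
        self.metadata.index.name = "subjectID"
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}

    # -- convenience -----------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subject_index(self, subject_id: str) -> int:
        try:
            return self.subject_ids.index(subject_id)
        except ValueError:
            raise KeyError(f"unknown subject {subject_id!r}") from None

    def get_matrix(self, metric: str, tract: str) -> np.ndarray:
        """Return the subject x node matrix for one (metric, tract)."""
        if metric not in self.metric_names:
            raise KeyError(f"unknown metric {metric!r}")
        if tract not in self.tract_names:
            raise KeyError(f"unknown tract {tract!r}")
        key = (metric, tract)
        if key not in self.values:
            mat = np.full((self.n_subjects, self.n_nodes), np.nan)
        else:
            mat = self.values[key]
        return mat

    def profile(self, subject_id: str, tract: str, metric: str) -> np.ndarray:
        """Return one subject's tract profile (length ``n_nodes``)."""
        return self.get_matrix(metric, tract)[self.subject_index(subject_id)]

    def copy(self) -> "TractometryDataset":
        return TractometryDataset(
            subject_ids=list(self.subject_ids),
            tract_names=list(self.tract_names),
            metric_names=list(self.metric_names),
            n_nodes=self.n_nodes,
            values={k: v.copy() for k, v in self.values.items()},
            metadata=self.metadata.copy(),
            params=dict(self.params),
        )

    def equals(self, other: "TractometryDataset", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Structural + numerical equality (NaNs compare equal)."""
        if (
            self.subject_ids != other.subject_ids
            or self.tract_names != other.tract_names
            or self.metric_names != other.metric_names
            or self.n_nodes != other.n_nodes
            or set(self.values) != set(other.values)
        ):
            return False
        for key, mat in self.values.items():
            omat = other.values[key]
            if mat.shape != omat.shape:
                return False
            if not np.allclose(mat, omat, rtol=rtol, atol=atol, equal_nan=True):
                return False
        a = self.metadata.reindex(self.subject_ids)
        b = other.metadata.reindex(other.subject_ids)
        if list(a.columns) != list(b.columns):
            return False
        for col in a.columns:
            for x, y in zip(a[col].tolist(), b[col].tolist()):
                if _is_missing(x) and _is_missing(y):
                    continue
                if isinstance(x, float) and isinstance(y, float):
                    if not math.isclose(x, y, rel_tol=rtol, abs_tol=atol):
                        return False
                elif x != y:
                    return False
        return self.params == other.params


def _is_missing(x: Any) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    return x is pd.NA or x is pd.NaT


@dataclass(frozen=True)
class ValidationFinding:
    severity: str  # "error" | "warning"
    code: str
    message: str
    locus: str = ""

    def to_dict(self) -> dict[str, str]:
        return dataclasses.asdict(self)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: a flat list of findings."""

    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def valid(self) -> bool:
        return not self.errors

    def add(self, severity: str, code: str, message: str, locus: str = "") -> None:
        self.findings.append(ValidationFinding(severity, code, message, locus))

    def to_json_obj(self) -> list[dict[str, str]]:
        return [f.to_dict() for f in self.findings]


def validate(ds: TractometryDataset) -> ValidationReport:
    """Check every dataset invariant; return findings, never raise.

    Shape and identity problems (wrong matrix shape, duplicate subject IDs,
    metadata rows for unknown subjects) are errors.  Physically implausible
    values -- FA outside [0, 1], non-positive diffusivities -- are warnings,
    since they may be legitimate artifacts of the upstream fit.
    """
    report = ValidationReport()

    if len(set(ds.subject_ids)) != len(ds.subject_ids):
        dupes = sorted({s for s in ds.subject_ids if ds.subject_ids.count(s) > 1})
        report.add("error", "duplicate-subjects", f"duplicate subject IDs: {dupes}")
    if len(set(ds.tract_names)) != len(ds.tract_names):
        report.add("error", "duplicate-tracts", "tract names are not unique")
    if len(set(ds.metric_names)) != len(ds.metric_names):
        report.add("error", "duplicate-metrics", "metric names are not unique")
    if ds.n_nodes < 1:
        report.add("error", "bad-n-nodes", f"n_nodes must be positive, got {ds.n_nodes}")

    for (metric, tract), mat in ds.values.items():
        locus = f"metric={metric}, tract={tract}"
        if metric not in ds.metric_names:
            report.add("error", "unknown-metric", f"values present for unlisted metric {metric!r}", locus)
        if tract not in ds.tract_names:
            report.add("error", "unknown-tract", f"values present for unlisted tract {tract!r}", locus)
        if mat.ndim != 2 or mat.shape != (ds.n_subjects, ds.n_nodes):
            report.add(
                "error",
                "bad-shape",
                f"matrix shape {mat.shape} != ({ds.n_subjects}, {ds.n_nodes})",
                locus,
            )
            continue
        if metric == "fa":
            bad = np.argwhere((~np.isnan(mat)) & ((mat < 0) | (mat > 1)))
            for i, v in bad[:20]:
                report.add(
                    "warning",
                    "fa-out-of-range",
                    f"FA value {mat[i, v]:g} outside [0, 1]",
                    f"subject={ds.subject_ids[i]}, tract={tract}, node={v}",
                )
        elif metric in DIFFUSIVITY_METRICS:
            bad = np.argwhere((~np.isnan(mat)) & (mat <= 0))
            for i, v in bad[:20]:
                report.add(
                    "warning",
                    "nonpositive-diffusivity",
                    f"{metric} value {mat[i, v]:g} is not positive",
                    f"subject={ds.subject_ids[i]}, tract={tract}, node={v}",
                )

    meta_ids = list(ds.metadata.index.astype(str))
    unknown = [s for s in meta_ids if s not in set(ds.subject_ids)]
    if unknown:
        report.add(
            "error",
            "metadata-unknown-subject",
            f"metadata rows for unknown subjects: {unknown}",
            "subjects.csv",
        )
    missing = [s for s in ds.subject_ids if s not in set(meta_ids)]
    if missing:
        report.add(
            "warning",
            "metadata-missing-subject",
            f"subjects without metadata rows: {missing}",
            "subjects.csv",
        )
    return report


def align_metadata(
    ds: TractometryDataset, metadata: pd.DataFrame, warn: bool = True
) -> pd.DataFrame:
    """Align a metadata table to ``ds.subject_ids``.

    Rows for subjects absent from the dataset are dropped with a warning;
    subjects absent from the table get an all-missing row with a warning.
    """
    metadata = metadata.copy()
    metadata.index = metadata.index.astype(str)
    known = set(ds.subject_ids)
    extra = [s for s in metadata.index if s not in known]
    if extra and warn:
        warnings.warn(f"dropping metadata rows for unknown subjects: {extra}", stacklevel=2)
    absent = [s for s in ds.subject_ids if s not in set(metadata.index)]
    if absent and warn:
        warnings.warn(f"subjects missing from metadata get all-missing rows: {absent}", stacklevel=2)
    out = metadata.reindex(ds.subject_ids)
    out.index.name = "subjectID"
    return out


def infer_metadata_types(metadata: pd.DataFrame) -> pd.DataFrame:
    """Coerce each column to float iff every non-missing cell parses as a number."""
    out = metadata.copy()
    for col in out.columns:
        series = out[col]
        if pd.api.types.is_numeric_dtype(series):
            out[col] = series.astype(float)
            continue
        parsed = []
        ok = True
        for x in series.tolist():
            if _is_missing(x) or (isinstance(x, str) and x == ""):
                parsed.append(float("nan"))
                continue
            try:
                parsed.append(float(x))
            except (TypeError, ValueError):
                ok = False
                break
        if ok:
            out[col] = parsed
        else:
            out[col] = [None if _is_missing(x) or x == "" else str(x) for x in series.tolist()]
    return out
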