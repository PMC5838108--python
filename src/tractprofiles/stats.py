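"""Along-tract group statistics and normative comparisons.

The unit of analysis is the tract profile: a diffusion metric sampled at
``n_nodes`` equidistant nodes along one tract for one subject.  This module
implements the statistical operations behind linked tractometry views:

* binning subjects into groups on a metadata column (:func:`bin_subjects`),
* per-node group summaries -- n, mean, SD, SE (:func:`group_profile`,
  :func:`compare_groups`),
* normative per-node z-scores of one subject against a reference group
  (:func:`subject_zscores`), with scalar summaries (:func:`summarize_z`)
  used to quantify focal lesions,
* the fraction of a patient group deviating from control norms within a
  node window (:func:`fraction_deviant`),
* brushing masks over node ranges (:func:`brush_mask`).

Standard deviations use the sample (n-1) denominator throughout: norms are
estimated from a finite sample of reference subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .dataset import TractometryDataset

__all__ = [
    "GroupAssignment",
    "ProfileSummary",
    "ZProfile",
    "NodeRange",
    "bin_subjects",
    "group_profile",
    "compare_groups",
    "subject_zscores",
    "summarize_z",
    "fraction_deviant",
    "brush_mask",
]

UNASSIGNED = "unassigned"

BinMethod = Literal["quantile", "equal_width", "explicit_edges", "categorical"]


@dataclass(frozen=True)
class NodeRange:
    """Inclusive 0-based node range ``[start, end]``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid node range {self.start}-{self.end}")

    def validate(self, n_nodes: int) -> None:
        if self.end > n_nodes - 1:
            raise ValueError(f"node range {self.start}-{self.end} exceeds n_nodes={n_nodes}")

    def slice(self) -> slice:
        return slice(self.start, self.end + 1)

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


@dataclass
class GroupAssignment:
    """Result of binning subjects on a metadata column.

    ``assignment`` maps each subject ID to a 0-based group index, or to the
    string ``"unassigned"`` when the metadata value is missing.  For numeric
    methods the group index is non-decreasing in the metadata value.
    """

    key: str
    method: BinMethod
    n_groups: int
    labels: list[str]
    assignment: dict[str, int | str]
    edges: list[float] | None = None

    def members(self, group: int) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    def group_sizes(self) -> list[int]:
        return [len(self.members(g)) for g in range(self.n_groups)]

    @property
    def unassigned(self) -> list[str]:
        return [s for s, g in self.assignment.items() if g == UNASSIGNED]


@dataclass
class ProfileSummary:
    """Per-node n / mean / SD / SE for one (tract, metric, group).

    ``sd`` and ``se`` are NaN wherever fewer than two non-missing values
    contribute; all fields are NaN at nodes where every member is missing.
    """

    tract: str
    metric: str
    group_label: str
    n: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    se: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.mean)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: tract, metric, group, node, n, mean, sd, se."""
        return pd.DataFrame(
            {
                "tractID": self.tract,
                "metric": self.metric,
                "group": self.group_label,
                "nodeID": np.arange(self.n_nodes),
                "n": self.n,
                "mean": self.mean,
                "sd": self.sd,
                "se": self.se,
            }
        )


@dataclass
class ZProfile:
    """Per-node normative z-scores of one subject against a reference group.

    ``z[v] = (x[v] - mean_ref[v]) / sd_ref[v]``; NaN where the subject value
    or the reference SD is missing, or the reference SD is zero.
    """

    subject_id: str
    tract: str
    metric: str
    reference_label: str
    reference_n: np.ndarray
    z: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.z)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:g}"


def bin_subjects(
    ds: TractometryDataset,
    key: str,
    n_groups: int = 1,
    method: BinMethod = "quantile",
    edges: Sequence[float] | None = None,
) -> GroupAssignment:
    """Divide subjects into groups by binning a metadata column.

    ``quantile`` sorts subjects by value (ties broken by subject ID) and
    splits them into ``n_groups`` contiguous groups of near-equal size
    (sizes differ by at most 1).  ``equal_width`` cuts ``[min, max]`` into
    equal-width intervals.  ``explicit_edges`` uses half-open intervals
    ``[e_i, e_{i+1})`` with the last interval closed.  ``categorical``
    creates one group per distinct level in sorted order (``n_groups`` is
    ignored).  Subjects with missing values are reported as unassigned.
    """
    if key not in ds.metadata.columns:
        raise KeyError(f"unknown metadata column {key!r}")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if (edges is not None) != (method == "explicit_edges"):
        raise ValueError("edges must be given iff method='explicit_edges'")

    col = ds.metadata[key]
    assignment: dict[str, int | str] = {}

    if method == "categorical":
        present = [(s, col.loc[s]) for s in ds.subject_ids]
        levels = sorted({str(v) for _, v in present if not _missing(v)})
        for s, v in present:
            assignment[s] = UNASSIGNED if _missing(v) else levels.index(str(v))
        return GroupAssignment(key, method, len(levels), list(levels), assignment)

    if not pd.api.types.is_numeric_dtype(col):
        raise TypeError(f"metadata column {key!r} is not numeric (method={method!r})")

    pairs = [(s, float(col.loc[s])) for s in ds.subject_ids]
    assigned = [(s, v) for s, v in pairs if not _missing(v)]
    for s, v in pairs:
        if _missing(v):
            assignment[s] = UNASSIGNED

    if method == "quantile":
        if n_groups > len(assigned):
            raise ValueError(
                f"n_groups={n_groups} exceeds the {len(assigned)} subjects with values"
            )
        order = sorted(assigned, key=lambda sv: (sv[1], sv[0]))
        sizes = _near_equal_sizes(len(order), n_groups)
        labels = []
        pos = 0
        for g, size in enumerate(sizes):
            chunk = order[pos : pos + size]
            pos += size
            for s, _ in chunk:
                assignment[s] = g
            labels.append(f"{_fmt(chunk[0][1])}–{_fmt(chunk[-1][1])}")
        return GroupAssignment(key, method, n_groups, labels, assignment)

    if method == "equal_width":
        vals = [v for _, v in assigned]
        lo, hi = min(vals), max(vals)
        edge_arr = np.linspace(lo, hi, n_groups + 1)
    elif method == "explicit_edges":
        edge_arr = np.asarray(list(edges), dtype=float)  # type: ignore[arg-type]
        if len(edge_arr) < 2 or np.any(np.diff(edge_arr) <= 0):
            raise ValueError("edges must be strictly increasing with length >= 2")
        n_groups = len(edge_arr) - 1
    else:
        raise ValueError(f"unknown binning method {method!r}")

    labels = [f"{_fmt(edge_arr[i])}–{_fmt(edge_arr[i + 1])}" for i in range(n_groups)]
    for s, v in assigned:
        if v < edge_arr[0] or v > edge_arr[-1]:
            assignment[s] = UNASSIGNED
            continue
        # half-open [e_i, e_{i+1}), last interval closed on the right
        g = int(np.searchsorted(edge_arr, v, side="right")) - 1
        assignment[s] = min(g, n_groups - 1)
    return GroupAssignment(key, method, n_groups, labels, assignment, list(map(float, edge_arr)))


def _near_equal_sizes(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if g < extra else 0) for g in range(k)]


def _missing(v: object) -> bool:
    return v is None or v is pd.NA or (isinstance(v, float) and v != v)


# ---------------------------------------------------------------------------
# profile summaries
# ---------------------------------------------------------------------------

def group_profile(
    ds: TractometryDataset,
    tract: str,
    metric: str,
    members: Sequence[str],
    group_label: str | None = None,
) -> ProfileSummary:
    """Per-node n / mean / SD / SE over a member list.

    Missing cells are excluded node-wise; SD uses the n-1 denominator and
    SE = SD / sqrt(n).  Nodes where every member is missing get NaN in all
    summary fields (n = 0).
    """
    if len(members) == 0:
        raise ValueError("empty member list")
    idx = [ds.subject_index(s) for s in members]
    mat = ds.get_matrix(metric, tract)[idx]

    present = ~np.isnan(mat)
    n = present.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        mean = np.nanmean(np.where(present, mat, np.nan), axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    mean = np.where(n >= 1, mean, np.nan)
    sd = np.where(n >= 2, sd, np.nan)
    se = sd / np.sqrt(np.where(n > 0, n, 1))
    se = np.where(n >= 2, se, np.nan)
    return ProfileSummary(
        tract=tract,
        metric=metric,
        group_label=group_label if group_label is not None else f"n={len(members)}",
        n=n.astype(int),
        mean=mean,
        sd=sd,
        se=se,
    )


def compare_groups(
    ds: TractometryDataset,
    ga: GroupAssignment,
    tract: str,
    metric: str,
) -> list[ProfileSummary]:
    """One :class:`ProfileSummary` per group, in group-index order.

    Empty groups yield an all-missing summary with n = 0 at every node.
    """
    out = []
    for g in range(ga.n_groups):
        members = ga.members(g)
        if members:
            out.append(group_profile(ds, tract, metric, members, group_label=ga.labels[g]))
        else:
            nan = np.full(ds.n_nodes, np.nan)
            out.append(
                ProfileSummary(
                    tract=tract,
                    metric=metric,
                    group_label=ga.labels[g],
                    n=np.zeros(ds.n_nodes, dtype=int),
                    mean=nan.copy(),
                    sd=nan.copy(),
                    se=nan.copy(),
                )
            )
    return out


def summaries_to_frame(summaries: Iterable[ProfileSummary]) -> pd.DataFrame:
    """Concatenate summaries into one long-format table."""
    return pd.concat([s.to_frame() for s in summaries], ignore_index=True)


# ---------------------------------------------------------------------------
# normative z-scores
# ---------------------------------------------------------------------------

def subject_zscores(
    ds: TractometryDataset,
    subject: str,
    tract: str,
    metric: str,
    reference: Sequence[str],
    exclude_self: bool = True,
    reference_label: str | None = None,
) -> ZProfile:
    """z-score one subject's profile node-wise against reference norms.

    When the subject appears in the reference list it is removed before the
    norms are computed (leave-self-out; toggleable with ``exclude_self``) --
    a patient compared against controls must never contribute to the norm.
    Nodes with zero reference SD yield NaN with a warning.
    """
    if subject not in ds.subject_ids:
        raise KeyError(f"unknown subject {subject!r}")
    ref = list(reference)
    if exclude_self:
        ref = [s for s in ref if s != subject]
    if not ref:
        raise ValueError("reference is empty after self-exclusion")

    summary = group_profile(ds, tract, metric, ref)
    x = ds.profile(subject, tract, metric)
    sd = summary.sd.copy()
    zero_sd = (~np.isnan(sd)) & (sd == 0)
    if zero_sd.any():
        warnings.warn(
            f"zero reference SD at nodes {np.flatnonzero(zero_sd).tolist()} "
            f"({tract}/{metric}); z set to missing there",
            stacklevel=2,
        )
        sd[zero_sd] = np.nan
    z = (x - summary.mean) / sd
    return ZProfile(
        subject_id=subject,
        tract=tract,
        metric=metric,
        reference_label=reference_label if reference_label is not None else f"n={len(ref)}",
        reference_n=summary.n,
        z=z,
    )


def summarize_z(
    zp: ZProfile,
    node_range: NodeRange | None = None,
    how: Literal["peak", "mean"] = "peak",
) -> tuple[float, int | None]:
    """Reduce a z-profile to a scalar over a node range.

    ``peak`` returns the *signed* z at the node of maximum absolute z (ties
    broken toward the lowest node index) together with that node; ``mean``
    returns the mean of non-missing z in the range (node is None).  A focal
    lesion is best captured by the signed peak -- averaging dilutes it.
    """
    if node_range is None:
        node_range = NodeRange(0, zp.n_nodes - 1)
    node_range.validate(zp.n_nodes)
    seg = zp.z[node_range.slice()]
    finite = ~np.isnan(seg)
    if not finite.any():
        raise ValueError(f"all z-values missing in range {node_range}")
    if how == "mean":
        return float(np.mean(seg[finite])), None
    if how == "peak":
        absz = np.where(finite, np.abs(seg), -np.inf)
        local = int(np.argmax(absz))  # argmax takes the first (lowest) index on ties
        return float(seg[local]), node_range.start + local
    raise ValueError(f"unknown z summary {how!r}")


def fraction_deviant(
    ds: TractometryDataset,
    group: Sequence[str],
    reference: Sequence[str],
    tract: str,
    metric: str,
    threshold: float,
    node_range: NodeRange | None = None,
    direction: Literal["absolute", "positive", "negative"] = "absolute",
) -> float:
    """Fraction of ``group`` whose z-profile vs ``reference`` exceeds
    ``threshold`` at one or more nodes within ``node_range``.

    A member is deviant iff strictly ``|z| > threshold`` (direction
    ``absolute``), ``z > threshold`` (``positive``) or ``-z > threshold``
    (``negative``) somewhere in the window.  Group and reference must be
    disjoint -- patients may not contribute to their own norms.
    """
    if not group or not reference:
        raise ValueError("group and reference must be non-empty")
    overlap = set(group) & set(reference)
    if overlap:
        raise ValueError(f"group and reference overlap: {sorted(overlap)}")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if node_range is None:
        node_range = NodeRange(0, ds.n_nodes - 1)
    node_range.validate(ds.n_nodes)

    deviant = 0
    for subject in group:
        zp = subject_zscores(ds, subject, tract, metric, reference)
        seg = zp.z[node_range.slice()]
        if direction == "absolute":
            crossed = np.abs(seg) > threshold
        elif direction == "positive":
            crossed = seg > threshold
        elif direction == "negative":
            crossed = -seg > threshold
        else:
            raise ValueError(f"unknown direction {direction!r}")
        if np.any(crossed & ~np.isnan(seg)):
            deviant += 1
    return deviant / len(group)


# ---------------------------------------------------------------------------
# brushing
# ---------------------------------------------------------------------------

def brush_mask(n_nodes: int, ranges: Iterable[NodeRange]) -> np.ndarray:
    """Boolean per-node mask: True exactly on the union of inclusive ranges."""
    mask = np.zeros(n_nodes, dtype=bool)
    for r in ranges:
        r.validate(n_nodes)
        mask[r.slice()] = True
    return mask
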