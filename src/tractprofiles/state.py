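"""Reversible serialization of the visualization state to a URL query string.

A view over a tractometry dataset -- which metric is plotted, which tracts
and subjects are selected, how subjects are grouped, which node ranges are
brushed -- is captured in a :class:`ViewerState` and rendered as a canonical
query string, so a specific view can be bookmarked, shared and reproduced.

Grammar (this package's own, documented contract):

* keys in lexicographic order, joined with ``&``; pairs are ``key=value``;
* fields at their documented defaults are omitted (the default state
  encodes to the empty string);
* list values are comma-joined in order; node ranges render ``start-end``;
* brushes render ``tract:start-end`` items, comma-joined, sorted by tract;
* the table sort renders ``column:asc`` or ``column:desc``;
* every value element is percent-encoded (UTF-8), so tract names and
  subject IDs may contain any character including ``&``, ``=``, ``,``,
  ``:`` and ``-``.

Keys: ``band``, ``brush``, ``groupKey``, ``metric``, ``nGroups``, ``sort``,
``subjects``, ``tracts``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any
from urllib.parse import quote, unquote

from .stats import NodeRange

__all__ = ["ViewerState", "encode_state", "decode_state", "StateDecodeError"]

#: characters escaped inside value elements (separators of the grammar)
_SAFE = ""  # percent-encode everything non-alphanumeric except -_.~

KNOWN_KEYS = ("band", "brush", "groupKey", "metric", "nGroups", "sort", "subjects", "tracts")


class StateDecodeError(ValueError):
    """Malformed value for a known query key."""


@dataclass(frozen=True)
class ViewerState:
    """Complete, serializable state of a tractometry view."""

    metric: str = "fa"
    selected_tracts: tuple[str, ...] = ()
    group_key: str | None = None
    n_groups: int = 1
    error_band: str = "se"  # "se" | "sd"
    brushes: tuple[tuple[str, NodeRange], ...] = ()
    selected_subjects: tuple[str, ...] = ()
    table_sort: tuple[str, bool] | None = None  # (column, ascending)

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.error_band not in ("se", "sd"):
            raise ValueError(f"error_band must be 'se' or 'sd', got {self.error_band!r}")
        object.__setattr__(self, "selected_tracts", tuple(self.selected_tracts))
        object.__setattr__(self, "selected_subjects", tuple(self.selected_subjects))
        object.__setattr__(
            self, "brushes", tuple(sorted(dict(self.brushes).items()))
        )

    def to_json_obj(self) -> dict[str, Any]:
        return {
            "metric": self.metric,
            "selectedTracts": list(self.selected_tracts),
            "groupKey": self.group_key,
            "nGroups": self.n_groups,
            "errorBand": self.error_band,
            "brushes": {t: [r.start, r.end] for t, r in self.brushes},
            "selectedSubjects": list(self.selected_subjects),
            "tableSort": None
            if self.table_sort is None
            else {"column": self.table_sort[0], "ascending": self.table_sort[1]},
        }


_DEFAULTS = ViewerState()


def _q(s: str) -> str:
    return quote(s, safe=_SAFE)


def encode_state(state: ViewerState, defaults: ViewerState = _DEFAULTS) -> str:
    """Render ``state`` as its canonical query string.

    Fields equal to their value in ``defaults`` are omitted; the default
    state therefore encodes to the empty string.  The output is canonical:
    fixed key order, deterministic separators, percent-encoded elements --
    two equal states always produce identical strings.
    """
    pairs: dict[str, str] = {}
    if state.metric != defaults.metric:
        pairs["metric"] = _q(state.metric)
    if state.selected_tracts != defaults.selected_tracts:
        pairs["tracts"] = ",".join(_q(t) for t in state.selected_tracts)
    if state.group_key != defaults.group_key and state.group_key is not None:
        pairs["groupKey"] = _q(state.group_key)
    if state.n_groups != defaults.n_groups:
        pairs["nGroups"] = str(state.n_groups)
    if state.error_band != defaults.error_band:
        pairs["band"] = state.error_band
    if state.brushes != defaults.brushes:
        pairs["brush"] = ",".join(f"{_q(t)}:{r.start}-{r.end}" for t, r in state.brushes)
    if state.selected_subjects != defaults.selected_subjects:
        pairs["subjects"] = ",".join(_q(s) for s in state.selected_subjects)
    if state.table_sort != defaults.table_sort and state.table_sort is not None:
        col, asc = state.table_sort
        pairs["sort"] = f"{_q(col)}:{'asc' if asc else 'desc'}"
    return "&".join(f"{k}={pairs[k]}" for k in sorted(pairs))


def decode_state(query: str, defaults: ViewerState = _DEFAULTS) -> ViewerState:
    """Parse a query string into a :class:`ViewerState`.

    Missing keys take their value from ``defaults``; unknown keys are
    dropped with a warning; malformed values for known keys raise
    :class:`StateDecodeError` naming the key.
    """
    state = defaults
    if not query:
        return state
    if query.startswith("?"):
        query = query[1:]
    for pair in query.split("&"):
        if not pair:
            continue
        key, sep, value = pair.partition("=")
        if not sep:
            raise StateDecodeError(f"malformed pair {pair!r} (no '=')")
        if key not in KNOWN_KEYS:
            warnings.warn(f"ignoring unknown state key {key!r}", stacklevel=2)
            continue
        state = _apply(state, key, value)
    return state


def _split_list(value: str) -> list[str]:
    return [unquote(x) for x in value.split(",")] if value else []


def _parse_range(text: str, key: str) -> NodeRange:
    start_s, sep, end_s = text.partition("-")
    try:
        start, end = int(start_s), int(end_s)
        return NodeRange(start, end)
    except ValueError as exc:
        raise StateDecodeError(f"malformed node range {text!r} in key {key!r}") from exc


def _apply(state: ViewerState, key: str, value: str) -> ViewerState:
    if key == "metric":
        return replace(state, metric=unquote(value))
    if key == "tracts":
        return replace(state, selected_tracts=tuple(_split_list(value)))
    if key == "groupKey":
        return replace(state, group_key=unquote(value))
    if key == "nGroups":
        try:
            n = int(value)
        except ValueError:
            raise StateDecodeError(f"malformed integer {value!r} for key 'nGroups'") from None
        if n < 1:
            raise StateDecodeError(f"'nGroups' must be >= 1, got {n}")
        return replace(state, n_groups=n)
    if key == "band":
        if value not in ("se", "sd"):
            raise StateDecodeError(f"'band' must be 'se' or 'sd', got {value!r}")
        return replace(state, error_band=value)
    if key == "brush":
        brushes = []
        for item in value.split(",") if value else []:
            tract_enc, sep, range_s = item.rpartition(":")
            if not sep:
                raise StateDecodeError(f"malformed brush item {item!r}")
            brushes.append((unquote(tract_enc), _parse_range(range_s, "brush")))
        return replace(state, brushes=tuple(brushes))
    if key == "subjects":
        return replace(state, selected_subjects=tuple(_split_list(value)))
    if key == "sort":
        col_enc, sep, dir_s = value.rpartition(":")
        if not sep or dir_s not in ("asc", "desc"):
            raise StateDecodeError(f"malformed sort value {value!r}")
        return replace(state, table_sort=(unquote(col_enc), dir_s == "asc"))
    raise AssertionError(key)
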