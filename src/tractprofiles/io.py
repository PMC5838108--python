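"""Readers and writers for tractometry data.

Three on-disk representations are supported:

* **AFQ MAT-files** -- the hierarchical MATLAB struct produced by automated
  fiber quantification pipelines, in both the classic v7 layout and the
  HDF5-backed v7.3 layout (read-only).
* **TRACULA stats folders** -- one whitespace-delimited text table per
  (tract, metric), named ``<tract>.<metric>.txt``, first column the subject
  ID and remaining columns the per-node values (read-only).
* **The tidy bundle** -- the exchange format: ``nodes.csv`` (one row per
  subject/tract/node), ``subjects.csv`` + ``subjects.json`` (metadata) and
  ``params.json``, all plain text, joinable on the shared ``subjectID`` key.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import h5py
import numpy as np
import pandas as pd
import scipy.io

from .dataset import (
    TractometryDataset,
    ValidationReport,
    align_metadata,
    infer_metadata_types,
    validate,
)

__all__ = [
    "TidyBundle",
    "TidyBundleError",
    "MatFormatError",    "read_afq_mat",
    "read_tracula_stats",
    "read_tidy",
    "write_tidy",
    "validate",
    "ValidationReport",
]

NODES_FILE = "nodes.csv"
SUBJECTS_CSV = "subjects.csv"
SUBJECTS_JSON = "subjects.json"
PARAMS_FILE = "params.json"


class TidyBundleError(ValueError):
    """Malformed tidy bundle (bad header, duplicate rows, broken join)."""


class MatFormatError(ValueError):
    """MAT-file missing required fields or internally inconsistent."""


@dataclass(frozen=True)
class TidyBundle:
    """Handle to an on-disk tidy bundle directory."""

    path: Path

    @property
    def nodes_csv(self) -> Path:
        return self.path / NODES_FILE

    @property
    def subjects_csv(self) -> Path:
        return self.path / SUBJECTS_CSV

    @property
    def subjects_json(self) -> Path:
        return self.path / SUBJECTS_JSON

    @property
    def params_json(self) -> Path:
        return self.path / PARAMS_FILE

    def members(self) -> list[Path]:
        return [self.nodes_csv, self.subjects_csv, self.subjects_json, self.params_json]


# ---------------------------------------------------------------------------
# tidy bundle
# ---------------------------------------------------------------------------

def _format_cell(x: float) -> str:
    x = float(x)
    if x != x:  # NaN
        return ""
    return repr(x)  # shortest decimal that round-trips


def write_tidy(ds: TractometryDataset, outdir: str | Path) -> TidyBundle:
    """Write ``ds`` as a tidy bundle under ``outdir``.

    ``nodes.csv`` rows are ordered subject-major, then tract (in
    ``tract_names`` order), then ascending node.  Numbers are serialized as
    the shortest decimal that round-trips; missing values become empty CSV
    cells and JSON ``null``.
    """
    report = validate(ds)
    if not report.valid:
        msgs = "; ".join(f.message for f in report.errors)
        raise ValueError(f"refusing to write invalid dataset: {msgs}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = TidyBundle(outdir)

    n_sub, n_tr, n_nodes = ds.n_subjects, len(ds.tract_names), ds.n_nodes
    header = ["subjectID", "tractID", "nodeID", *ds.metric_names]
    with open(bundle.nodes_csv, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(header) + "\n")
        mats = {
            (m, t): ds.get_matrix(m, t) for m in ds.metric_names for t in ds.tract_names
        }
        for si, sub in enumerate(ds.subject_ids):
            for tract in ds.tract_names:
                cols = [mats[(m, tract)][si] for m in ds.metric_names]
                for v in range(n_nodes):
                    cells = [_csv_quote(sub), _csv_quote(tract), str(v)]
                    cells += [_format_cell(col[v]) for col in cols]
                    fh.write(",".join(cells) + "\n")

    meta = align_metadata(ds, ds.metadata, warn=False)
    with open(bundle.subjects_csv, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(["subjectID", *map(_csv_quote, map(str, meta.columns))]) + "\n")
        for sub in ds.subject_ids:
            row = [_csv_quote(sub)]
            for col in meta.columns:
                row.append(_meta_cell_csv(meta.at[sub, col]))
            fh.write(",".join(row) + "\n")

    records = []
    for sub in ds.subject_ids:
        rec: dict[str, Any] = {"subjectID": sub}
        for col in meta.columns:
            rec[str(col)] = _meta_cell_json(meta.at[sub, col])
        records.append(rec)
    bundle.subjects_json.write_text(
        json.dumps(records, ensure_ascii=False, indent=1) + "\n", encoding="utf-8"
    )
    bundle.params_json.write_text(
        json.dumps(_jsonable(ds.params), ensure_ascii=False, indent=1) + "\n",
        encoding="utf-8",
    )
    return bundle


def _csv_quote(s: str) -> str:
    if any(c in s for c in ',"\n\r'):
        return '"' + s.replace('"', '""') + '"'
    return s


def _meta_cell_csv(x: Any) -> str:
    if x is None or x != x:
        return ""
    if isinstance(x, float):
        return _format_cell(x)
    return _csv_quote(str(x))


def _meta_cell_json(x: Any) -> Any:
    if x is None or x != x:
        return None
    if isinstance(x, (float, int)):
        return float(x)
    return str(x)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_tidy(indir: str | Path) -> TractometryDataset:
    """Reconstruct a :class:`TractometryDataset` from a tidy bundle.

    Subject, tract and metric orders are the first-appearance order in
    ``nodes.csv``.  Structural defects (header mismatch, out-of-range node,
    duplicated rows, subjects missing from the metadata table) raise
    :class:`TidyBundleError` naming the locus.
    """
    bundle = TidyBundle(Path(indir))
    for f in bundle.members():
        if not f.exists():
            raise TidyBundleError(f"missing bundle member: {f.name}")

    nodes = pd.read_csv(
        bundle.nodes_csv,
        dtype={"subjectID": str, "tractID": str},
        keep_default_na=False,
        na_values=[""],
        float_precision="round_trip",
    )
    cols = list(nodes.columns)
    if cols[:3] != ["subjectID", "tractID", "nodeID"]:
        raise TidyBundleError(
            f"nodes.csv header must start with subjectID,tractID,nodeID; got {cols[:3]}"
        )
    metric_names = cols[3:]
    if not metric_names:
        raise TidyBundleError("nodes.csv carries no metric columns")

    subject_ids = list(dict.fromkeys(nodes["subjectID"]))
    tract_names = list(dict.fromkeys(nodes["tractID"]))
    node_ids = nodes["nodeID"].to_numpy()
    if not np.issubdtype(node_ids.dtype, np.integer):
        raise TidyBundleError("nodes.csv nodeID column must be integer")
    n_nodes = int(node_ids.max()) + 1
    if node_ids.min() < 0:
        raise TidyBundleError("nodes.csv nodeID out of range (negative)")

    dup = nodes.duplicated(subset=["subjectID", "tractID", "nodeID"])
    if dup.any():
        row = nodes[dup].iloc[0]
        raise TidyBundleError(
            "duplicate node row: "
            f"subject={row['subjectID']!r}, tract={row['tractID']!r}, node={row['nodeID']}"
        )

    si = {s: i for i, s in enumerate(subject_ids)}
    values: dict[tuple[str, str], np.ndarray] = {}
    for tract, sub_df in nodes.groupby("tractID", sort=False):
        rows = sub_df["subjectID"].map(si).to_numpy()
        cols_idx = sub_df["nodeID"].to_numpy()
        for metric in metric_names:
            mat = np.full((len(subject_ids), n_nodes), np.nan)
            mat[rows, cols_idx] = pd.to_numeric(sub_df[metric], errors="raise").to_numpy(dtype=float)
            values[(metric, str(tract))] = mat

    meta_csv = pd.read_csv(
        bundle.subjects_csv,
        dtype=str,
        keep_default_na=False,
        na_values=[""],
        index_col="subjectID",
    )
    meta_csv = infer_metadata_types(meta_csv)

    records = json.loads(bundle.subjects_json.read_text(encoding="utf-8"))
    meta_json = pd.DataFrame.from_records(records)
    if "subjectID" not in meta_json.columns and records:
        raise TidyBundleError("subjects.json records lack a subjectID key")
    if records:
        meta_json = meta_json.set_index("subjectID")
        meta_json = infer_metadata_types(meta_json)
        if not _meta_equal(meta_csv, meta_json):
            raise TidyBundleError("subjects.csv and subjects.json disagree")

    missing_meta = [s for s in subject_ids if s not in set(meta_csv.index)]
    if missing_meta:
        raise TidyBundleError(
            f"subjects present in nodes.csv but absent from subjects.csv: {missing_meta}"
        )

    params = json.loads(bundle.params_json.read_text(encoding="utf-8"))
    ds = TractometryDataset(
        subject_ids=subject_ids,
        tract_names=tract_names,
        metric_names=metric_names,
        n_nodes=n_nodes,
        values=values,
        metadata=meta_csv.reindex(subject_ids),
        params=params,
    )
    return ds


def _meta_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.columns) != list(b.columns) or list(a.index) != list(b.index):
        return False
    for col in a.columns:
        for x, y in zip(a[col].tolist(), b[col].tolist()):
            x_miss = x is None or x != x
            y_miss = y is None or y != y
            if x_miss and y_miss:
                continue
            if x_miss != y_miss or x != y:
                return False
    return True


# ---------------------------------------------------------------------------
# AFQ MAT-files
# ---------------------------------------------------------------------------

def read_afq_mat(path: str | Path) -> TractometryDataset:
    """Read an AFQ MAT-file (v7 or v7.3/HDF5) into a dataset.

    The file must carry a struct (conventionally named ``afq``; lookup is
    case-insensitive) with per-metric value fields -- one subject x node
    matrix per tract -- a tract-name list, subject identifiers, and an
    optional per-subject metadata struct.  Metric names are lower-cased;
    tract and subject order is preserved from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if h5py.is_hdf5(path):
        raw = _load_mat_hdf5(path)
    else:
        raw = _load_mat_classic(path)
    return _dataset_from_struct(raw, str(path))


def _ci_get(d: Mapping[str, Any], name: str) -> Any:
    for k, v in d.items():
        if k.lower() == name.lower():
            return v
    return None


def _load_mat_classic(path: Path) -> dict[str, Any]:
    try:
        mat = scipy.io.loadmat(path, simplify_cells=True)
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise MatFormatError(f"cannot read MAT-file {path}: {exc}") from exc
    mat = {k: v for k, v in mat.items() if not k.startswith("__")}
    afq = _ci_get(mat, "afq")
    if afq is None:
        # fall back: single root variable that looks like the struct
        candidates = [v for v in mat.values() if isinstance(v, dict)]
        if len(candidates) == 1:
            afq = candidates[0]
    if not isinstance(afq, dict):
        raise MatFormatError(f"{path}: no 'afq' struct found")
    return afq


def _h5_strings(node: h5py.Dataset) -> list[str]:
    out = []
    for x in np.asarray(node[()]).ravel():
        if isinstance(x, bytes):
            out.append(x.decode("utf-8"))
        else:
            out.append(str(x))
    return out


def _load_mat_hdf5(path: Path) -> dict[str, Any]:
    def visit(obj: h5py.Group | h5py.Dataset) -> Any:
        if isinstance(obj, h5py.Group):
            return {k: visit(v) for k, v in obj.items()}
        data = obj[()]
        if obj.dtype.kind in ("S", "O", "U"):
            strs = _h5_strings(obj)
            return strs[0] if obj.shape == () else strs
        return np.asarray(data)

    with h5py.File(path, "r") as fh:
        root = {k: v for k, v in fh.items() if not k.startswith("#")}
        afq_group = None
        for k, v in root.items():
            if k.lower() == "afq" and isinstance(v, h5py.Group):
                afq_group = v
                break
        if afq_group is None:
            groups = [v for v in root.values() if isinstance(v, h5py.Group)]
            if len(groups) == 1:
                afq_group = groups[0]
        if afq_group is None:
            raise MatFormatError(f"{path}: no 'afq' group found")
        return visit(afq_group)


def _as_str_list(x: Any) -> list[str]:
    if x is None:
        return []
    if isinstance(x, str):
        return [x]
    if isinstance(x, np.ndarray):
        x = x.ravel().tolist()
    return [s.decode("utf-8") if isinstance(s, bytes) else str(s) for s in x]


def _dataset_from_struct(afq: Mapping[str, Any], origin: str) -> TractometryDataset:
    vals = _ci_get(afq, "vals")
    if not isinstance(vals, Mapping) or not vals:
        raise MatFormatError(f"{origin}: missing 'vals' field with per-metric matrices")
    tract_names = _as_str_list(_ci_get(afq, "fgnames"))
    if not tract_names:
        raise MatFormatError(f"{origin}: missing 'fgnames' tract-name list")
    subject_ids = _as_str_list(_ci_get(afq, "sub_ids"))
    if not subject_ids:
        raise MatFormatError(f"{origin}: missing 'sub_ids' subject list")

    metric_names = [m.lower() for m in vals.keys()]
    values: dict[tuple[str, str], np.ndarray] = {}
    n_nodes: int | None = None
    n_sub = len(subject_ids)
    for metric_raw, per_tract in vals.items():
        metric = metric_raw.lower()
        mats = _per_tract_matrices(per_tract, tract_names)
        for tract, mat in zip(tract_names, mats):
            mat = np.atleast_2d(np.asarray(mat, dtype=float))
            if mat.shape[0] != n_sub and mat.shape[1] == n_sub:
                mat = mat.T  # MATLAB HDF5 stores column-major
            if mat.shape[0] != n_sub:
                raise MatFormatError(
                    f"{origin}: metric {metric!r} tract {tract!r} has "
                    f"{mat.shape[0]} rows for {n_sub} subjects"
                )
            if n_nodes is None:
                n_nodes = mat.shape[1]
            elif mat.shape[1] != n_nodes:
                raise MatFormatError(
                    f"{origin}: inconsistent node count for metric {metric!r} "
                    f"tract {tract!r}: {mat.shape[1]} != {n_nodes}"
                )
            values[(metric, tract)] = mat
    assert n_nodes is not None

    meta_raw = _ci_get(afq, "metadata")
    if isinstance(meta_raw, Mapping) and meta_raw:
        cols = {}
        for col, arr in meta_raw.items():
            if isinstance(arr, (str, bytes)):
                arr = [arr]
            cols[str(col)] = _as_str_list(arr) if _is_stringy(arr) else np.asarray(arr, dtype=float).ravel()
        metadata = pd.DataFrame(cols, index=pd.Index(subject_ids, name="subjectID"))
        metadata = infer_metadata_types(metadata)
    else:
        if meta_raw is None:
            warnings.warn(f"{origin}: no metadata field; metadata table is empty", stacklevel=2)
        metadata = pd.DataFrame(index=pd.Index(subject_ids, name="subjectID"))

    params_raw = _ci_get(afq, "params")
    if isinstance(params_raw, str):
        try:
            params = json.loads(params_raw)
        except json.JSONDecodeError:
            params = {"raw": params_raw}
    elif isinstance(params_raw, Mapping):
        params = _jsonable(params_raw)
    else:
        params = {}

    return TractometryDataset(
        subject_ids=subject_ids,
        tract_names=tract_names,
        metric_names=metric_names,
        n_nodes=int(n_nodes),
        values=values,
        metadata=metadata,
        params=params,
    )


def _is_stringy(arr: Any) -> bool:
    if isinstance(arr, np.ndarray):
        return arr.dtype.kind in ("U", "S", "O")
    if isinstance(arr, (list, tuple)):
        return any(isinstance(x, (str, bytes)) for x in arr)
    return isinstance(arr, (str, bytes))


def _per_tract_matrices(per_tract: Any, tract_names: list[str]) -> list[np.ndarray]:
    if isinstance(per_tract, Mapping):  # HDF5 layout: one dataset per tract index
        keys = sorted(per_tract.keys(), key=lambda k: (len(k), k))
        return [np.asarray(per_tract[k]) for k in keys]
    if isinstance(per_tract, np.ndarray) and per_tract.dtype == object:
        return [np.asarray(m) for m in per_tract.ravel()]
    if isinstance(per_tract, (list, tuple)):
        return [np.asarray(m) for m in per_tract]
    arr = np.asarray(per_tract)
    if arr.ndim == 3:  # tracts x subjects x nodes
        return [arr[i] for i in range(arr.shape[0])]
    if arr.ndim == 2 and len(tract_names) == 1:
        return [arr]
    raise MatFormatError(f"cannot interpret per-tract value container of shape {arr.shape}")


# ---------------------------------------------------------------------------
# TRACULA stats folders
# ---------------------------------------------------------------------------

def read_tracula_stats(indir: str | Path) -> TractometryDataset:
    """Read a TRACULA-style group-stats folder.

    Expects one whitespace-delimited table per (tract, metric), named
    ``<tract>.<metric>.txt``: first column the subject ID, remaining columns
    the per-node values.  Per-tract node counts may differ in the raw
    files; profiles are harmonized by linear interpolation to the maximum
    node count present (recorded in ``params['tracula_resampled_to']``).
    """
    indir = Path(indir)
    files = sorted(p for p in indir.glob("*.txt") if p.name.count(".") >= 2)
    if not files:
        raise FileNotFoundError(f"no '<tract>.<metric>.txt' tables found in {indir}")

    tables: dict[tuple[str, str], tuple[list[str], np.ndarray]] = {}
    tract_order: list[str] = []
    metric_order: list[str] = []
    for path in files:
        stem = path.name[: -len(".txt")]
        tract, _, metric = stem.rpartition(".")
        metric = metric.lower()
        subs, mat = _parse_tracula_table(path)
        tables[(metric, tract)] = (subs, mat)
        if tract not in tract_order:
            tract_order.append(tract)
        if metric not in metric_order:
            metric_order.append(metric)

    first_key = next(iter(tables))
    subject_ids = tables[first_key][0]
    for (metric, tract), (subs, _) in tables.items():
        if set(subs) != set(subject_ids):
            only_a = sorted(set(subject_ids) - set(subs))
            only_b = sorted(set(subs) - set(subject_ids))
            raise ValueError(
                f"subject sets differ across TRACULA files: {tract}.{metric}.txt "
                f"is missing {only_a} and adds {only_b}"
            )

    n_nodes = max(mat.shape[1] for _, mat in tables.values())
    values: dict[tuple[str, str], np.ndarray] = {}
    resampled = False
    for (metric, tract), (subs, mat) in tables.items():
        order = [subs.index(s) for s in subject_ids]
        mat = mat[order]
        if mat.shape[1] != n_nodes:
            mat = _resample_profiles(mat, n_nodes)
            resampled = True
        values[(metric, tract)] = mat

    params: dict[str, Any] = {"source": "tracula"}
    if resampled:
        params["tracula_resampled_to"] = n_nodes
    return TractometryDataset(
        subject_ids=subject_ids,
        tract_names=tract_order,
        metric_names=metric_order,
        n_nodes=n_nodes,
        values=values,
        metadata=pd.DataFrame(index=pd.Index(subject_ids, name="subjectID")),
        params=params,
    )


def _parse_tracula_table(path: Path) -> tuple[list[str], np.ndarray]:
    subs: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split()
            if len(cells) < 2:
                raise ValueError(f"{path.name}:{lineno}: expected subject ID plus node values")
            vals = []
            for cell in cells[1:]:
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path.name}:{lineno}: non-numeric cell {cell!r}"
                    ) from None
            subs.append(cells[0])
            rows.append(vals)
    if not subs:
        raise ValueError(f"{path.name}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path.name}: rows have differing node counts {sorted(widths)}")
    return subs, np.asarray(rows, dtype=float)


def _resample_profiles(mat: np.ndarray, n_nodes: int) -> np.ndarray:
    """Linearly interpolate each row from its node grid onto ``n_nodes``."""
    old = np.linspace(0.0, 1.0, mat.shape[1])
    new = np.linspace(0.0, 1.0, n_nodes)
    return np.vstack([np.interp(new, old, row) for row in mat])
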