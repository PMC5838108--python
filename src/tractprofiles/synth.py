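"""Seeded generator of synthetic tractometry datasets and on-disk fixtures.

The generator emulates the structure of a real tractometry study: per
subject, a profile of each diffusion metric along each tract, plus a
metadata table.  The per-subject profile for metric *m* on tract *t* is

    x_s(v) = mu(v) + delta * [s in target group] * [v in window]
             + b_s + eps_s(v)

where ``mu`` is a smooth tract-shape (baseline plus Gaussian bumps),
``delta`` an additive group effect over a node window, ``b_s ~ N(0, tau^2)``
a between-subject offset, and ``eps`` stationary AR(1) node noise with
marginal SD ``sigma`` and lag-1 autocorrelation ``rho`` (tract profiles are
spatially smooth, so node noise is strongly autocorrelated).  Everything is
a deterministic function of the seed (NumPy PCG64).

Focal lesions are injected separately (:func:`inject_lesion`) with
amplitude expressed in multiples of the per-node control-group SD, so a
lesion of amplitude A should be recovered as a z-score near A.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.io

from .dataset import TractometryDataset
from .stats import NodeRange

__all__ = [
    "Bump",
    "ProfileShape",
    "GroupEffect",
    "MetadataColumn",
    "SyntheticSpec",
    "LesionSpec",
    "default_spec",
    "generate",
    "inject_lesion",
    "write_mat_fixture",
]

#: the 20 tract names of a standard whole-brain fiber-group segmentation
DEFAULT_TRACTS = [
    "Left Thalamic Radiation",
    "Right Thalamic Radiation",
    "Left Corticospinal",
    "Right Corticospinal",
    "Left Cingulum Cingulate",
    "Right Cingulum Cingulate",
    "Left Cingulum Hippocampus",
    "Right Cingulum Hippocampus",
    "Callosum Forceps Major",
    "Callosum Forceps Minor",
    "Left IFOF",
    "Right IFOF",
    "Left ILF",
    "Right ILF",
    "Left SLF",
    "Right SLF",
    "Left Uncinate",
    "Right Uncinate",
    "Left Arcuate",
    "Right Arcuate",
]

DEFAULT_METRICS = ["fa", "md", "rd", "ad"]

# typical scale of each metric (FA dimensionless; diffusivities in um^2/ms)
_METRIC_BASELINE = {"fa": 0.45, "md": 0.80, "rd": 0.55, "ad": 1.30}
_METRIC_TAU = {"fa": 0.035, "md": 0.04, "rd": 0.04, "ad": 0.05}
_METRIC_SIGMA = {"fa": 0.03, "md": 0.03, "rd": 0.03, "ad": 0.04}


@dataclass(frozen=True)
class Bump:
    """One Gaussian component of a mean tract shape."""

    center: float  # node units
    width: float  # Gaussian sd, node units
    amplitude: float  # metric units, signed

    def profile(self, nodes: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-((nodes - self.center) ** 2) / (2 * self.width**2))


@dataclass(frozen=True)
class ProfileShape:
    baseline: float
    bumps: tuple[Bump, ...] = ()

    def mean(self, n_nodes: int) -> np.ndarray:
        nodes = np.arange(n_nodes, dtype=float)
        mu = np.full(n_nodes, self.baseline)
        for b in self.bumps:
            mu = mu + b.profile(nodes)
        return mu


@dataclass(frozen=True)
class GroupEffect:
    """Additive shift ``delta`` for subjects with ``metadata[column] == value``."""

    column: str
    value: str | float
    metric: str
    tract: str
    window: NodeRange
    delta: float


@dataclass(frozen=True)
class MetadataColumn:
    """Generator for one metadata column.

    ``uniform`` draws in ``[low, high]``; ``normal`` draws ``N(mean, sd)``;
    ``categorical`` draws from ``levels`` with probabilities ``probs``
    (uniform when omitted).
    """

    name: str
    kind: Literal["uniform", "normal", "categorical"]
    low: float = 0.0
    high: float = 1.0
    mean: float = 0.0
    sd: float = 1.0
    levels: tuple[str, ...] = ()
    probs: tuple[float, ...] | None = None

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        if self.kind == "normal":
            return rng.normal(self.mean, self.sd, size=n)
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError(f"column {self.name!r}: categorical needs levels")
            return rng.choice(np.asarray(self.levels, dtype=object), size=n, p=self.probs)
        raise ValueError(f"unknown metadata generator kind {self.kind!r}")


@dataclass
class SyntheticSpec:
    """Full specification of one synthetic study."""

    n_subjects: int
    tract_names: list[str] = field(default_factory=lambda: list(DEFAULT_TRACTS))
    metric_names: list[str] = field(default_factory=lambda: list(DEFAULT_METRICS))
    n_nodes: int = 100
    seed: int = 0
    #: mean shape per metric (key = metric) or per tract (key = (metric, tract))
    profiles: dict[str | tuple[str, str], ProfileShape] = field(default_factory=dict)
    subject_sd: dict[str, float] = field(default_factory=dict)  # tau, per metric
    noise_sd: dict[str, float] = field(default_factory=dict)  # sigma, per metric
    ar1_rho: float = 0.8
    group_effects: list[GroupEffect] = field(default_factory=list)
    metadata_columns: list[MetadataColumn] = field(
        default_factory=lambda: [MetadataColumn("age", "uniform", low=8, high=50)]
    )
    subject_prefix: str = "subject_"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 <= self.ar1_rho < 1):
            raise ValueError("ar1_rho must lie in [0, 1)")
        for m, v in {**self.subject_sd, **self.noise_sd}.items():
            if v < 0:
                raise ValueError(f"negative sd for metric {m!r}")
        for eff in self.group_effects:
            eff.window.validate(self.n_nodes)

    def shape_for(self, metric: str, tract: str) -> ProfileShape:
        if (metric, tract) in self.profiles:
            return self.profiles[(metric, tract)]  # type: ignore[index]
        if metric in self.profiles:
            return self.profiles[metric]  # type: ignore[index]
        return ProfileShape(baseline=_METRIC_BASELINE.get(metric, 1.0))

    def tau_for(self, metric: str) -> float:
        return self.subject_sd.get(metric, _METRIC_TAU.get(metric, 0.04))

    def sigma_for(self, metric: str) -> float:
        return self.noise_sd.get(metric, _METRIC_SIGMA.get(metric, 0.03))


@dataclass(frozen=True)
class LesionSpec:
    """A focal lesion: Gaussian-shaped deviation in control-SD units.

    ``amplitude`` is the peak deviation in multiples of the per-node
    control-group SD; ``width`` is the Gaussian SD in nodes; ``sign``
    +1 raises the metric (diffusivities in damaged tissue), -1 lowers it
    (FA).
    """

    subject: str
    tract: str
    metric: str
    center: int
    width: float = 3.0
    amplitude: float = 5.0
    sign: int = 1

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("lesion width must be > 0")
        if self.amplitude < 0:
            raise ValueError("lesion amplitude must be >= 0")
        if self.sign not in (1, -1):
            raise ValueError("lesion sign must be +1 or -1")


def default_spec(
    n_subjects: int = 40,
    seed: int = 0,
    tract_names: Sequence[str] | None = None,
    metric_names: Sequence[str] | None = None,
    n_nodes: int = 100,
    with_group: bool = True,
) -> SyntheticSpec:
    """A realistic default study: varied smooth tract shapes, age metadata.

    Bump positions/amplitudes are drawn once from a generator seeded from
    ``seed``, so the same seed always yields the same study design.
    """
    tracts = list(tract_names) if tract_names is not None else list(DEFAULT_TRACTS)
    metrics = list(metric_names) if metric_names is not None else list(DEFAULT_METRICS)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD1F]))
    profiles: dict[str | tuple[str, str], ProfileShape] = {}
    for metric in metrics:
        base = _METRIC_BASELINE.get(metric, 1.0)
        for tract in tracts:
            k = int(rng.integers(1, 4))
            bumps = tuple(
                Bump(
                    center=float(rng.uniform(0.15, 0.85) * n_nodes),
                    width=float(rng.uniform(0.05, 0.15) * n_nodes),
                    amplitude=float(rng.uniform(-0.25, 0.25) * base),
                )
                for _ in range(k)
            )
            profiles[(metric, tract)] = ProfileShape(baseline=base, bumps=bumps)
    meta = [MetadataColumn("age", "uniform", low=8, high=50)]
    if with_group:
        meta.append(MetadataColumn("group", "categorical", levels=("control", "patient"), probs=(0.5, 0.5)))
    return SyntheticSpec(
        n_subjects=n_subjects,
        tract_names=tracts,
        metric_names=metrics,
        n_nodes=n_nodes,
        seed=seed,
        profiles=profiles,
        metadata_columns=meta,
    )


def _ar1_noise(rng: np.random.Generator, n_sub: int, n_nodes: int, sigma: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise, marginal SD ``sigma``, lag-1 autocorr ``rho``."""
    z = rng.standard_normal((n_sub, n_nodes))
    eps = np.empty((n_sub, n_nodes))
    eps[:, 0] = sigma * z[:, 0]
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    for v in range(1, n_nodes):
        eps[:, v] = rho * eps[:, v - 1] + innov_sd * z[:, v]
    return eps


def generate(spec: SyntheticSpec) -> TractometryDataset:
    """Materialize a :class:`TractometryDataset` from a spec, seed-determined."""
    rng = np.random.default_rng(spec.seed)
    subject_ids = [f"{spec.subject_prefix}{i:03d}" for i in range(spec.n_subjects)]

    # metadata first: group effects condition on it
    meta_cols = {}
    for col in spec.metadata_columns:
        meta_cols[col.name] = col.draw(rng, spec.n_subjects)
    metadata = pd.DataFrame(meta_cols, index=pd.Index(subject_ids, name="subjectID"))

    values: dict[tuple[str, str], np.ndarray] = {}
    for metric in spec.metric_names:
        tau = spec.tau_for(metric)
        sigma = spec.sigma_for(metric)
        b = rng.normal(0.0, tau, size=spec.n_subjects) if tau > 0 else np.zeros(spec.n_subjects)
        for tract in spec.tract_names:
            mu = spec.shape_for(metric, tract).mean(spec.n_nodes)
            if sigma > 0:
                eps = _ar1_noise(rng, spec.n_subjects, spec.n_nodes, sigma, spec.ar1_rho)
            else:
                eps = np.zeros((spec.n_subjects, spec.n_nodes))
            mat = mu[None, :] + b[:, None] + eps
            for eff in spec.group_effects:
                if eff.metric != metric or eff.tract != tract:
                    continue
                col = metadata[eff.column]
                in_group = np.asarray(
                    [not pd.isna(v) and v == eff.value for v in col.tolist()]
                )
                sl = eff.window.slice()
                mat[np.ix_(in_group, np.arange(spec.n_nodes)[sl])] += eff.delta
            values[(metric, tract)] = mat

    params = {
        "source": "synthetic",
        "seed": spec.seed,
        "n_nodes": spec.n_nodes,
        "ar1_rho": spec.ar1_rho,
    }
    return TractometryDataset(
        subject_ids=subject_ids,
        tract_names=list(spec.tract_names),
        metric_names=list(spec.metric_names),
        n_nodes=spec.n_nodes,
        values=values,
        metadata=metadata,
        params=params,
    )


def inject_lesion(
    ds: TractometryDataset, lesion: LesionSpec, controls: Sequence[str]
) -> TractometryDataset:
    """Return a copy of ``ds`` with a focal lesion added to one subject.

    The deviation added at node v is
    ``sign * A * sd_ctrl(v) * exp(-(v - c)^2 / (2 w^2))`` where ``sd_ctrl``
    is the per-node sample SD over the control subjects, so ``A`` maps
    directly onto the expected z-score magnitude at the lesion center.
    """
    if not controls:
        raise ValueError("controls must be non-empty")
    if lesion.subject not in ds.subject_ids:
        raise KeyError(f"unknown subject {lesion.subject!r}")
    if not (0 <= lesion.center <= ds.n_nodes - 1):
        raise ValueError(f"lesion center {lesion.center} outside 0..{ds.n_nodes - 1}")

    out = ds.copy()
    mat = out.values[(lesion.metric, lesion.tract)]
    ctrl_idx = [ds.subject_index(s) for s in controls]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd_ctrl = np.nanstd(mat[ctrl_idx], axis=0, ddof=1)
    if not np.isfinite(sd_ctrl[lesion.center]) or sd_ctrl[lesion.center] == 0:
        raise ValueError(f"zero/undefined control SD at lesion center node {lesion.center}")
    sd_ctrl = np.where(np.isfinite(sd_ctrl), sd_ctrl, 0.0)

    nodes = np.arange(ds.n_nodes, dtype=float)
    shape = np.exp(-((nodes - lesion.center) ** 2) / (2 * lesion.width**2))
    row = ds.subject_index(lesion.subject)
    mat[row] = mat[row] + lesion.sign * lesion.amplitude * sd_ctrl * shape
    return out


# ---------------------------------------------------------------------------
# MAT fixtures
# ---------------------------------------------------------------------------

_MAT_HEADER_TEXT = b"MATLAB 7.3 MAT-file, Platform: synthetic tractometry fixture"


def write_mat_fixture(
    ds: TractometryDataset,
    path: str | Path,
    version: Literal["7.3", "7"] = "7.3",
    include_metadata: bool = True,
) -> Path:
    """Write ``ds`` as a MAT-file fixture the AFQ reader understands.

    ``version="7.3"`` (default) writes the HDF5 layout -- a 512-byte MATLAB
    userblock followed by an ordinary HDF5 file, openable by any HDF5
    reader -- with groups ``afq/vals/<metric>/<tract index>`` plus
    ``fgnames``, ``sub_ids``, optional ``metadata`` and a JSON ``params``
    string.  ``version="7"`` writes the classic layout via scipy.
    """
    path = Path(path)
    if version == "7":
        return _write_mat_v7(ds, path, include_metadata)
    if version != "7.3":
        raise ValueError(f"unsupported MAT version {version!r}")

    str_t = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w", userblock_size=512) as fh:
        afq = fh.create_group("afq")
        vals = afq.create_group("vals")
        for metric in ds.metric_names:
            g = vals.create_group(metric)
            for ti, tract in enumerate(ds.tract_names):
                g.create_dataset(f"{ti:03d}", data=ds.get_matrix(metric, tract))
        afq.create_dataset("fgnames", data=np.asarray(ds.tract_names, dtype=object), dtype=str_t)
        afq.create_dataset("sub_ids", data=np.asarray(ds.subject_ids, dtype=object), dtype=str_t)
        if include_metadata and len(ds.metadata.columns):
            mg = afq.create_group("metadata")
            meta = ds.metadata.reindex(ds.subject_ids)
            for col in meta.columns:
                series = meta[col]
                if pd.api.types.is_numeric_dtype(series):
                    mg.create_dataset(str(col), data=series.to_numpy(dtype=float))
                else:
                    cells = ["" if pd.isna(x) else str(x) for x in series.tolist()]
                    mg.create_dataset(str(col), data=np.asarray(cells, dtype=object), dtype=str_t)
        if ds.params:
            afq.create_dataset("params", data=json.dumps(ds.params))

    # MATLAB v7.3 userblock: 116-byte description, 8-byte subsystem offset,
    # version 0x0200, endian indicator "IM"
    header = _MAT_HEADER_TEXT.ljust(116, b" ")[:116]
    header += b"\x00" * 8
    header += (0x0200).to_bytes(2, "little") + b"IM"
    with open(path, "r+b") as fh:
        fh.write(header.ljust(512, b"\x00"))
    return path


def _write_mat_v7(ds: TractometryDataset, path: Path, include_metadata: bool) -> Path:
    vals = {}
    for metric in ds.metric_names:
        cell = np.empty(len(ds.tract_names), dtype=object)
        for ti, tract in enumerate(ds.tract_names):
            cell[ti] = ds.get_matrix(metric, tract)
        vals[metric] = cell
    afq: dict[str, object] = {
        "vals": vals,
        "fgnames": np.asarray(ds.tract_names, dtype=object),
        "sub_ids": np.asarray(ds.subject_ids, dtype=object),
    }
    if include_metadata and len(ds.metadata.columns):
        meta = ds.metadata.reindex(ds.subject_ids)
        md = {}
        for col in meta.columns:
            series = meta[col]
            if pd.api.types.is_numeric_dtype(series):
                md[str(col)] = series.to_numpy(dtype=float)
            else:
                md[str(col)] = np.asarray(
                    ["" if pd.isna(x) else str(x) for x in series.tolist()], dtype=object
                )
        afq["metadata"] = md
    if ds.params:
        afq["params"] = json.dumps(ds.params)
    scipy.io.savemat(path, {"afq": afq}, format="5", long_field_names=True)
    return path
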