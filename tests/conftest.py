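from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tractprofiles import TractometryDataset, default_spec, generate


def make_dataset(values_by_metric_tract, metadata=None, params=None):
    """Build a dataset from {(metric, tract): {subject: [node values]}}."""
    subjects: list[str] = []
    tracts: list[str] = []
    metrics: list[str] = []
    n_nodes = None
    for (metric, tract), rows in values_by_metric_tract.items():
        if metric not in metrics:
            metrics.append(metric)
        if tract not in tracts:
            tracts.append(tract)
        for s, vals in rows.items():
            if s not in subjects:
                subjects.append(s)
            n_nodes = len(vals)
    values = {}
    for (metric, tract), rows in values_by_metric_tract.items():
        mat = np.full((len(subjects), n_nodes), np.nan)
        for s, vals in rows.items():
            mat[subjects.index(s)] = vals
        values[(metric, tract)] = mat
    meta = pd.DataFrame(metadata or {}, index=pd.Index(subjects, name="subjectID"))
    return TractometryDataset(
        subject_ids=subjects,
        tract_names=tracts,
        metric_names=metrics,
        n_nodes=n_nodes,
        values=values,
        metadata=meta,
        params=params or {},
    )


def random_small_dataset(rng: np.random.Generator, max_subjects=6, max_nodes=5,
                         missing_rate=0.15):
    """A tiny random dataset for oracle-equivalence checks."""
    n_sub = int(rng.integers(2, max_subjects + 1))
    n_nodes = int(rng.integers(2, max_nodes + 1))
    n_tracts = int(rng.integers(1, 3))
    n_metrics = int(rng.integers(1, 3))
    subjects = [f"s{i}" for i in range(n_sub)]
    tracts = [f"tract{t}" for t in range(n_tracts)]
    metrics = ["fa", "md"][:n_metrics]
    values = {}
    for m in metrics:
        for t in tracts:
            mat = rng.normal(0.5, 0.2, size=(n_sub, n_nodes))
            mask = rng.random((n_sub, n_nodes)) < missing_rate
            mat[mask] = np.nan
            values[(m, t)] = mat
    meta = pd.DataFrame(
        {"age": rng.uniform(8, 50, n_sub), "site": rng.choice(["a", "b"], n_sub)},
        index=pd.Index(subjects, name="subjectID"),
    )
    return TractometryDataset(
        subject_ids=subjects,
        tract_names=tracts,
        metric_names=metrics,
        n_nodes=n_nodes,
        values=values,
        metadata=meta,
    )


@pytest.fixture
def trio_ds():
    """The 3-subject, 4-node dataset behind the worked statistics examples."""
    return make_dataset(
        {
            ("fa", "tract1"): {
                "s1": [0.4, 0.5, 0.6, 0.5],
                "s2": [0.5, 0.6, 0.7, 0.6],
                "s3": [0.6, 0.7, 0.8, 0.7],
            }
        },
        metadata={"age": [10.0, 20.0, 30.0]},
    )


@pytest.fixture
def small_synth_ds():
    spec = default_spec(
        n_subjects=6,
        seed=7,
        tract_names=["Left Arcuate", "Right Corticospinal"],
        metric_names=["fa", "md"],
        n_nodes=30,
    )
    return generate(spec)
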