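"""Cohort split, mutual-information feature screening, and SMOTE balancing.

The protocol mirrors the study design: the cohort is split 2:1
(train:test) stratified by group; screening is computed on the training
cohort only; SMOTE raises the minority (HEAML) class of the *training*
cohort to the majority count — the test cohort is never touched.

Feature tables are pandas DataFrames indexed by subject id with named
feature columns plus a binary ``label`` column (HEAML = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LABEL = "label"
SYNTHETIC = "synthetic"  # flag column added by smote()

_RESERVED = (LABEL, SYNTHETIC)


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _RESERVED]


@dataclass(frozen=True)
class CohortSplit:
    train_ids: tuple
    test_ids: tuple
    seed: int


def stratified_split(table: pd.DataFrame, test_fraction: float = 1 / 3,
                     seed: int = 0) -> CohortSplit:
    """Per-class random 2:1 split: floor(n / 3) of each class to test
    (train >= test always), deterministic given seed."""
    rng = np.random.default_rng(seed)
    train, test = [], []
    for lab in sorted(table[LABEL].unique()):
        ids = np.asarray(table.index[table[LABEL] == lab])
        if test_fraction > 0 and len(ids) < 3:
            raise ValueError(f"class {lab} has fewer than 3 subjects")
        n_test = int(np.floor(len(ids) * test_fraction))
        perm = rng.permutation(len(ids))
        test.extend(ids[perm[:n_test]])
        train.extend(ids[perm[n_test:]])
    return CohortSplit(train_ids=tuple(train), test_ids=tuple(test), seed=seed)


def _equal_frequency_bins(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Bin indices from deciles of x; duplicate edges (ties) merged."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="left")


def mutual_information_rank(train_table: pd.DataFrame,
                            n_bins: int = 10) -> list[tuple[str, float]]:
    """Plug-in mutual information (nats) between each feature — discretized
    into equal-frequency bins with merged ties — and the binary label.
    Descending MI, ties broken by feature name. Monotone-transform invariant
    by construction."""
    y = train_table[LABEL].to_numpy()
    ys = np.unique(y)
    if len(ys) < 2:
        raise ValueError("label is constant on the training cohort")
    yi = np.searchsorted(ys, y)
    n, ny = len(y), len(ys)
    scores = []
    for col in feature_columns(train_table):
        b = _equal_frequency_bins(train_table[col].to_numpy(), n_bins)
        joint = np.bincount(b * ny + yi, minlength=(b.max() + 1) * ny)
        joint = joint.reshape(-1, ny) / n
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        nz = joint > 0
        mi = float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))
        scores.append((col, max(mi, 0.0)))
    return sorted(scores, key=lambda t: (-t[1], t[0]))


def select_top_k(table: pd.DataFrame, ranking: list[tuple[str, float]],
                 k: int) -> pd.DataFrame:
    """Keep the k highest-MI features (plus reserved columns)."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k={k} out of range 1..{len(ranking)}")
    keep = [name for name, _ in ranking[:k]]
    extra = [c for c in _RESERVED if c in table.columns]
    return table[keep + extra].copy()


def smote(train_table: pd.DataFrame, k_neighbors: int = 5,
          seed: int = 0) -> pd.DataFrame:
    """Synthetic minority over-sampling on the training cohort.

    Each synthetic sample is x + u (z - x) with x a random minority row, z
    one of its k nearest minority neighbours (Euclidean distance on
    features standardized by training mean/SD) and u ~ Uniform(0, 1) — an
    exact convex combination in the original feature space. The minority
    count is raised to the majority count; original rows are preserved and
    synthetic rows carry ``synthetic = True``.
    """
    rng = np.random.default_rng(seed)
    cols = feature_columns(train_table)
    y = train_table[LABEL].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote needs exactly two classes")
    minority = classes[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    out = train_table.copy()
    out[SYNTHETIC] = False
    if n_needed == 0:
        return out
    minor = train_table[train_table[LABEL] == minority]
    if len(minor) < 2:
        raise ValueError("minority class must have >= 2 samples for SMOTE")
    X = minor[cols].to_numpy(float)
    mu = train_table[cols].to_numpy(float).mean(axis=0)
    sd = train_table[cols].to_numpy(float).std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    d2 = np.sum((Z[:, None, :] - Z[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    k = min(k_neighbors, len(minor) - 1)
    nn = np.argsort(d2, axis=1)[:, :k]
    rows = []
    for s in range(n_needed):
        i = int(rng.integers(len(minor)))
        j = int(nn[i, rng.integers(k)])
        u = rng.random()
        rows.append(X[i] + u * (X[j] - X[i]))
    synth = pd.DataFrame(rows, columns=cols,
                         index=[f"synthetic-{s:04d}" for s in range(n_needed)])
    synth[LABEL] = minority
    synth[SYNTHETIC] = True
    return pd.concat([out, synth])
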