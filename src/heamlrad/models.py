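"""Radiomics signature models: RF / ridge-logistic / ANN with grid search,
ROC analysis (DeLong confidence intervals) and calibration curves.

"Ridge regression" is implemented as L2-penalized logistic regression so
that all three signatures emit a class probability on the same [0, 1]
scale; the internal model-selection currency is cross-validated AUC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .screening import LABEL, feature_columns

ALGORITHMS = ("RF", "RR", "ANN")

#: default hyperparameter grids, searched exhaustively in declared order
DEFAULT_GRIDS: dict[str, dict[str, tuple]] = {
    "RF": {"n_estimators": (100, 300, 500), "max_depth": (None, 5, 10)},
    "RR": {"alpha": tuple(10.0**e for e in range(-3, 4))},
    "ANN": {"hidden_units": (16, 64), "alpha": (1e-4, 1e-2)},
}


def _build_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 300),
            max_depth=params.get("max_depth"),
            random_state=seed,
        )
    if algorithm == "RR":
        # sklearn parameterizes the (default L2) penalty as C = 1 / alpha
        return LogisticRegression(
            C=1.0 / params.get("alpha", 1.0),
            solver="lbfgs", max_iter=5000,
        )
    if algorithm == "ANN":
        return MLPClassifier(
            hidden_layer_sizes=(params.get("hidden_units", 64),),
            alpha=params.get("alpha", 1e-4),
            early_stopping=True, max_iter=800, random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class SignatureModel:
    algorithm: str
    estimator: object
    scaler: StandardScaler
    columns: list[str]
    grid: dict
    selected_params: dict
    cv_scores: dict = field(default_factory=dict)  # grid point repr -> mean CV AUC
    seed: int = 0

    def manifest(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "grid": {k: list(v) for k, v in self.grid.items()},
            "selected_params": {k: v for k, v in self.selected_params.items()},
            "cv_scores": self.cv_scores,
            "n_features": len(self.columns),
            "seed": self.seed,
        }


def _grid_points(grid: dict[str, tuple]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def cv_auc(algorithm: str, X: np.ndarray, y: np.ndarray, params: dict,
           seed: int, n_folds: int = 5) -> float:
    """Mean held-out AUC of one grid point under stratified K-fold CV."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError("degenerate labels in a CV fold")
        est = _build_estimator(algorithm, params, seed)
        est.fit(X[tr], y[tr])
        s = est.predict_proba(X[te])[:, 1]
        aucs.append(auc_concordance(s, y[te]))
    return float(np.mean(aucs))


def grid_search_fit(
    algorithm: str,
    train_table: pd.DataFrame,
    grid: dict[str, tuple] | None = None,
    seed: int = 0,
    n_folds: int = 5,
) -> SignatureModel:
    """Exhaustive grid search by internal stratified 5-fold CV AUC on the
    training cohort; ties go to the first grid point in declared order; the
    winning point is refit on the full training cohort."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    grid = grid if grid is not None else DEFAULT_GRIDS[algorithm]
    points = _grid_points(grid)
    if not points:
        raise ValueError("empty hyperparameter grid")
    cols = feature_columns(train_table)
    scaler = StandardScaler().fit(train_table[cols].to_numpy(float))
    X = scaler.transform(train_table[cols].to_numpy(float))
    y = train_table[LABEL].to_numpy(int)
    scores = {repr(p): cv_auc(algorithm, X, y, p, seed, n_folds) for p in points}
    best = max(points, key=lambda p: scores[repr(p)])  # first max wins
    est = _build_estimator(algorithm, best, seed)
    est.fit(X, y)
    return SignatureModel(algorithm, est, scaler, cols, grid, best, scores, seed)


def fit_default(algorithm: str, train_table: pd.DataFrame,
                seed: int = 0, **params) -> SignatureModel:
    """Fit one signature at fixed (default) hyperparameters, no grid search."""
    cols = feature_columns(train_table)
    scaler = StandardScaler().fit(train_table[cols].to_numpy(float))
    est = _build_estimator(algorithm, params, seed)
    est.fit(scaler.transform(train_table[cols].to_numpy(float)),
            train_table[LABEL].to_numpy(int))
    return SignatureModel(algorithm, est, scaler, cols,
                          {k: (v,) for k, v in params.items()}, params, {}, seed)


def predict_scores(model: SignatureModel, table: pd.DataFrame) -> pd.Series:
    """Per-subject signature score in [0, 1]; columns matched by name."""
    missing = set(model.columns) - set(table.columns)
    if missing:
        raise ValueError(f"table lacks trained feature columns: {sorted(missing)[:3]}...")
    X = model.scaler.transform(table[model.columns].to_numpy(float))
    return pd.Series(model.estimator.predict_proba(X)[:, 1], index=table.index,
                     name="signature_score")


# ---------------------------------------------------------------------------
# ROC / AUC / calibration
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def auc_concordance(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the pairwise concordance probability, ties counted 1/2
    (rank-statistic form of the Mann-Whitney estimator)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    r = stats.rankdata(s)
    return float((r[y == 1].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the AUC from structural components."""
    psi = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    m, n = len(pos), len(neg)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC curve with concordance AUC and a 95% DeLong confidence interval
    truncated to [0, 1]."""
    from sklearn.metrics import roc_curve

    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    auc = auc_concordance(s, y)
    var = _delong_variance(s[y == 1], s[y == 0])
    half = 1.959963984540054 * np.sqrt(var)
    fpr, tpr, thr = roc_curve(y, s)
    return RocResult(auc, max(0.0, auc - half), min(1.0, auc + half), fpr, tpr, thr)


def calibration_curve(scores: Sequence[float], labels: Sequence[int],
                      n_groups: int = 10) -> pd.DataFrame:
    """Equal-frequency score groups; per group, mean predicted score vs
    observed positive fraction. Every subject lands in exactly one group."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if len(s) < n_groups:
        raise ValueError("need at least one subject per group")
    order = np.argsort(s, kind="stable")
    out = []
    for block in np.array_split(order, n_groups):
        out.append({"mean_score": float(s[block].mean()),
                    "observed_fraction": float(y[block].mean()),
                    "n": int(len(block))})
    return pd.DataFrame(out)
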