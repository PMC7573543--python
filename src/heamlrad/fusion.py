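"""Fusion models: AIC-selected multivariate logistic regression combining the
radiomics signature score with clinical covariates, evaluated by stratified
10-fold cross-validation, decision-curve analysis and diagnostic nomograms;
plus the clinical two-group summary statistics.

Protocol notes. The signature score is forced into every searched covariate
subset (the model "fuses" signature + clinical information); AIC selection is
redone inside each CV training fold (the leakage-free reading); SMOTE is
never applied on this path. The signature score fed to the fusion fit is an
out-of-fold score produced by nested cross-validation, so the logistic stage
never sees optimistic in-bag probabilities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .models import auc_concordance, fit_default, predict_scores
from .screening import LABEL, mutual_information_rank, select_top_k

CLINICAL_COVARIATES = ("sex_female", "age", "max_diameter", "loc_left", "habit_yes")


def encode_clinical(records: pd.DataFrame) -> pd.DataFrame:
    """0/1-code the categorical covariates; continuous covariates pass through.

    Expects the clinical table produced by the cohort generator (columns sex,
    age, max_diameter, location, habit, group).
    """
    out = pd.DataFrame(index=records.index)
    out["sex_female"] = (records["sex"] == "female").astype(float)
    out["age"] = records["age"].astype(float)
    out["max_diameter"] = records["max_diameter"].astype(float)
    out["loc_left"] = (records["location"] == "left").astype(float)
    out["habit_yes"] = (records["habit"] == "yes").astype(float)
    out[LABEL] = (records["group"] == "HEAML").astype(int)
    return out


# ---------------------------------------------------------------------------
# Logistic fit (IRLS) and AIC subset selection
# ---------------------------------------------------------------------------

@dataclass
class FusionModel:
    covariates: list[str]  # in fit order, signature score first
    coef: np.ndarray       # aligned with covariates
    intercept: float
    log_likelihood: float
    aic: float
    regularized: bool = False  # ridge fallback engaged (perfect separation)
    search: dict = field(default_factory=dict)  # subset repr -> AIC

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.covariates].to_numpy(float)
        return self.intercept + X @ self.coef

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(self.linear_predictor(table), -35, 35)))


def _irls(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
          tol: float = 1e-8, max_iter: int = 200):
    """Iteratively reweighted least squares for logistic regression.

    Returns (beta, logL, converged). X includes the intercept column.
    ``ridge`` penalizes all coefficients except the intercept.
    """
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.eye(p) * ridge
    pen[0, 0] = 0.0
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300))
                   - 0.5 * ridge * beta[1:] @ beta[1:])
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        beta = np.linalg.solve(XtW @ X + pen, XtW @ z)
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300)))
    return beta, ll, converged


def fit_logistic(table: pd.DataFrame, covariates: list[str]) -> FusionModel:
    """Maximum-likelihood logistic fit by IRLS (|delta logL| < 1e-8).

    Perfect separation (non-convergence or exploding coefficients) triggers a
    ridge-1e-6 refit, flagged on the returned model. AIC = 2k - 2 logL with k
    counting the intercept.
    """
    y = table[LABEL].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are one-class; logistic fit undefined")
    X = np.column_stack([np.ones(len(table))]
                        + [table[c].to_numpy(float) for c in covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates")
    beta, ll, converged = _irls(X, y)
    mu = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -35, 35)))
    separated = bool(np.all(np.abs(y - mu) < 1e-6))  # fit saturates at 0/1
    regularized = False
    if not converged or separated or not np.isfinite(ll):
        beta, ll, _ = _irls(X, y, ridge=1e-6)
        regularized = True
    k = X.shape[1]
    return FusionModel(
        covariates=list(covariates), coef=beta[1:], intercept=float(beta[0]),
        log_likelihood=ll, aic=2.0 * k - 2.0 * ll, regularized=regularized,
    )


def aic_select(
    table: pd.DataFrame,
    score_col: str | None = "signature_score",
    clinical: tuple[str, ...] = CLINICAL_COVARIATES,
) -> FusionModel:
    """Exhaustive search over all clinical-covariate subsets, the signature
    score always included; lowest AIC wins, ties resolved toward fewer
    covariates then lexicographic order.

    ``score_col=None`` searches clinical-only models (used for the clinical
    comparator); the intercept-only model is then a legal subset."""
    required = [] if score_col is None else [score_col]
    if score_col is not None and score_col not in table.columns:
        raise ValueError(f"missing signature score column {score_col!r}")
    subsets = []
    for r in range(len(clinical) + 1):
        subsets.extend(itertools.combinations(sorted(clinical), r))
    best: FusionModel | None = None
    search = {}
    for sub in subsets:  # ordered by (size, lexicographic)
        model = fit_logistic(table, [*required, *sub])
        search[",".join(sub) or "(none)"] = model.aic
        if best is None or model.aic < best.aic - 1e-9:
            best = model
    assert best is not None
    best.search = search
    return best


# ---------------------------------------------------------------------------
# Cross-validated fusion evaluation
# ---------------------------------------------------------------------------

def _standardize(train: pd.DataFrame, other: pd.DataFrame,
                 cols: tuple[str, ...]) -> tuple[pd.DataFrame, pd.DataFrame]:
    tr, ot = train.copy(), other.copy()
    for c in cols:
        mu, sd = train[c].mean(), train[c].std(ddof=0)
        sd = sd if sd > 0 else 1.0
        tr[c] = (train[c] - mu) / sd
        ot[c] = (other[c] - mu) / sd
    return tr, ot


def out_of_fold_scores(features: pd.DataFrame, seed: int = 0,
                       n_folds: int = 5, screen_k: int | None = None,
                       algorithm: str = "RF") -> pd.Series:
    """Nested out-of-fold signature scores on one cohort: within each inner
    fold, MI screening (optional) and the signature model are fit on the
    remaining folds only."""
    y = features[LABEL].to_numpy(int)
    n_folds = min(n_folds, int(np.bincount(y).min()))  # keep folds stratifiable
    if n_folds < 2:
        raise ValueError("need >= 2 subjects per class for out-of-fold scores")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = pd.Series(np.nan, index=features.index, name="signature_score")
    for tr, te in skf.split(np.zeros(len(y)), y):
        train_tab = features.iloc[tr]
        test_tab = features.iloc[te]
        if screen_k is not None:
            rank = mutual_information_rank(train_tab)
            train_tab = select_top_k(train_tab, rank, min(screen_k, len(rank)))
        model = fit_default(algorithm, train_tab, seed=seed)
        scores.iloc[te] = predict_scores(model, test_tab).to_numpy()
    return scores


@dataclass
class FusionCvResult:
    fold_aucs: list[float]
    mean_auc: float         # mean of fold AUCs
    pooled_auc: float       # AUC of pooled out-of-fold predictions
    selected_subsets: list[tuple[str, ...]]
    pooled_scores: pd.Series
    labels: pd.Series
    # comparator models evaluated on the same folds
    signature_fold_aucs: list[float] = field(default_factory=list)
    clinical_fold_aucs: list[float] = field(default_factory=list)

    @property
    def mean_signature_auc(self) -> float:
        return float(np.mean(self.signature_fold_aucs))

    @property
    def mean_clinical_auc(self) -> float:
        return float(np.mean(self.clinical_fold_aucs))


def cross_validate_fusion(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    n_folds: int = 10,
    seed: int = 0,
    screen_k: int | None = None,
    signature_algorithm: str = "RF",
    inner_folds: int = 5,
) -> FusionCvResult:
    """Stratified 10-fold evaluation of the fusion model.

    Per outer fold: out-of-fold signature scores are built inside the
    training folds (nested CV), the signature model is refit on all training
    folds to score the held-out fold, AIC subset selection and the logistic
    fit use training rows only, and the held-out fold is scored once. No
    SMOTE anywhere on this path. Reports per-fold AUCs, their mean, and the
    pooled-prediction AUC.
    """
    assert features.index.equals(clinical.index)
    y = features[LABEL].to_numpy(int)
    counts = np.bincount(y)
    if counts.min() < n_folds:
        raise ValueError("each class must have at least n_folds subjects")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_aucs, sig_aucs, clin_aucs, chosen = [], [], [], []
    pooled = pd.Series(np.nan, index=features.index, name="fusion_probability")
    clin_cols = [c for c in CLINICAL_COVARIATES if c in clinical.columns]
    cont = tuple(c for c in ("age", "max_diameter") if c in clin_cols)
    for tr, te in skf.split(np.zeros(len(y)), y):
        f_tr, f_te = features.iloc[tr], features.iloc[te]
        # nested signature: out-of-fold scores for training rows,
        # full-training-fold model for test rows
        if screen_k is not None:
            rank = mutual_information_rank(f_tr)
            f_tr_s = select_top_k(f_tr, rank, min(screen_k, len(rank)))
        else:
            f_tr_s = f_tr
        sig = fit_default(signature_algorithm, f_tr_s, seed=seed)
        score_tr = out_of_fold_scores(f_tr, seed=seed, n_folds=inner_folds,
                                      screen_k=screen_k, algorithm=signature_algorithm)
        score_te = predict_scores(sig, f_te)
        c_tr, c_te = _standardize(clinical.iloc[tr], clinical.iloc[te], cont)
        tab_tr = c_tr[clin_cols].assign(signature_score=score_tr.to_numpy(),
                                        **{LABEL: y[tr]})
        tab_te = c_te[clin_cols].assign(signature_score=score_te.to_numpy(),
                                        **{LABEL: y[te]})
        model = aic_select(tab_tr, clinical=tuple(clin_cols))
        chosen.append(tuple(model.covariates[1:]))
        prob = model.predict_proba(tab_te)
        pooled.iloc[te] = prob
        fold_aucs.append(auc_concordance(prob, y[te]))
        # comparators on the same fold: raw signature score, clinical-only MLR
        sig_aucs.append(auc_concordance(score_te.to_numpy(), y[te]))
        clin_model = aic_select(tab_tr, score_col=None, clinical=tuple(clin_cols))
        clin_prob = clin_model.predict_proba(tab_te)
        if np.ptp(clin_prob) == 0:  # intercept-only comparator: all ties
            clin_aucs.append(0.5)
        else:
            clin_aucs.append(auc_concordance(clin_prob, y[te]))
    return FusionCvResult(
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        pooled_auc=auc_concordance(pooled.to_numpy(), y),
        selected_subsets=chosen,
        pooled_scores=pooled,
        labels=pd.Series(y, index=features.index, name=LABEL),
        signature_fold_aucs=sig_aucs,
        clinical_fold_aucs=clin_aucs,
    )


# ---------------------------------------------------------------------------
# Decision curve analysis
# ---------------------------------------------------------------------------

@dataclass
class DcaCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray       # model
    net_benefit_all: np.ndarray   # treat-all
    net_benefit_none: np.ndarray  # treat-none (identically 0)


def decision_curve(scores, labels, thresholds=None) -> DcaCurve:
    """Net benefit NB(t) = TP/n - FP/n * t/(1-t), classifying by score >= t,
    with treat-all and treat-none references."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    t = (np.arange(1, 100) / 100.0) if thresholds is None else np.asarray(thresholds, float)
    n = len(y)
    prev = y.mean()
    nb, nb_all = [], []
    for ti in t:
        pred = s >= ti
        tp = float(np.sum(pred & (y == 1)))
        fp = float(np.sum(pred & (y == 0)))
        w = ti / (1.0 - ti)
        nb.append(tp / n - fp / n * w)
        nb_all.append(prev - (1.0 - prev) * w)
    return DcaCurve(t, np.asarray(nb), np.asarray(nb_all), np.zeros_like(t))


# ---------------------------------------------------------------------------
# Nomogram
# ---------------------------------------------------------------------------

@dataclass
class NomogramScale:
    covariate: str
    beta: float
    low: float   # declared value range
    high: float
    points_at_low: float
    points_at_high: float

    def points(self, x) -> np.ndarray:
        """Affine map value -> points (0 at the range endpoint minimizing
        beta * x)."""
        span = self.high - self.low
        if span == 0 or self.points_at_high == self.points_at_low:
            return np.zeros_like(np.asarray(x, float))
        frac = (np.asarray(x, float) - self.low) / span
        return self.points_at_low + frac * (self.points_at_high - self.points_at_low)


@dataclass
class Nomogram:
    scales: list[NomogramScale]
    intercept: float
    base_offset: float   # sum over covariates of min(beta x) over the range
    per_point: float     # linear-predictor units per nomogram point

    def total_points(self, table: pd.DataFrame) -> np.ndarray:
        return sum(sc.points(table[sc.covariate].to_numpy(float)) for sc in self.scales)

    def probability(self, total_points) -> np.ndarray:
        lp = self.intercept + self.base_offset + np.asarray(total_points, float) * self.per_point
        return 1.0 / (1.0 + np.exp(-lp))


def build_nomogram(model: FusionModel, value_ranges: dict[str, tuple[float, float]]) -> Nomogram:
    """Standard points convention: each covariate's contribution beta * x is
    rescaled so the widest contribution range spans 0-100 points; total
    points map back to predicted probability through the logistic inverse of
    the reassembled linear predictor (an exact round trip)."""
    ranges = {}
    for c, b in zip(model.covariates, model.coef):
        lo, hi = value_ranges[c]
        ranges[c] = abs(b) * (hi - lo)
    max_range = max(ranges.values())
    if max_range == 0:
        raise ValueError("all covariates have zero contribution range")
    per_point = max_range / 100.0
    scales, base = [], 0.0
    for c, b in zip(model.covariates, model.coef):
        lo, hi = value_ranges[c]
        contrib_lo, contrib_hi = b * lo, b * hi
        ref = min(contrib_lo, contrib_hi)
        base += ref
        scales.append(NomogramScale(
            covariate=c, beta=float(b), low=lo, high=hi,
            points_at_low=(contrib_lo - ref) / per_point,
            points_at_high=(contrib_hi - ref) / per_point,
        ))
    return Nomogram(scales=scales, intercept=model.intercept,
                    base_offset=base, per_point=per_point)


# ---------------------------------------------------------------------------
# Clinical two-group statistics
# ---------------------------------------------------------------------------

def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction on a 2x2 table
    [[a, b], [c, d]]; returns (statistic, p)."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den == 0:
        return 0.0, 1.0
    stat = num / den
    return float(stat), float(stats.chi2.sf(stat, df=1))


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def clinical_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Two-group (HEAML vs non-HEAML) covariate summary: counts (%) with
    two-sided Pearson chi-squared (no continuity correction) for categorical
    covariates, mean +/- SD with the two-sided normal-approximation
    Mann-Whitney U (tie-corrected) for continuous ones. p floored at <0.001.
    """
    g1 = records[records["group"] == "HEAML"]
    g0 = records[records["group"] != "HEAML"]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for cov, level in (("sex", "female"), ("location", "left"), ("habit", "yes")):
        a, c = int((g1[cov] == level).sum()), int((g0[cov] == level).sum())
        b, d = len(g1) - a, len(g0) - c
        stat, p = chi2_2x2(a, b, c, d)
        rows.append({
            "covariate": cov,
            "heaml": f"{a} ({100 * a / len(g1):.0f}%)",
            "non_heaml": f"{c} ({100 * c / len(g0):.0f}%)",
            "statistic": stat, "p_value": p, "p_display": _fmt_p(p),
        })
    for cov in ("age", "max_diameter"):
        x, z = g1[cov].to_numpy(float), g0[cov].to_numpy(float)
        res = stats.mannwhitneyu(x, z, alternative="two-sided", method="asymptotic")
        rows.append({
            "covariate": cov,
            "heaml": f"{x.mean():.1f} ± {x.std(ddof=1):.1f}",
            "non_heaml": f"{z.mean():.1f} ± {z.std(ddof=1):.1f}",
            "statistic": float(res.statistic), "p_value": float(res.pvalue),
            "p_display": _fmt_p(float(res.pvalue)),
        })
    return pd.DataFrame(rows).set_index("covariate")
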