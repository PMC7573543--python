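"""Seeded cohort-level experiment drivers.

These functions run whole replicates of the study protocol on phantom
cohorts — simulate, extract the 423-feature panel, split/screen/balance,
fit the signature, cross-validate the fusion model — entirely in memory.
They back the analysis scripts and the acceptance harness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cohort as coh
from . import fusion as fus
from . import models as mod
from . import screening as scr
from .wavelet import full_feature_vector


def extract_cohort_features(
    spec: coh.CohortSpec,
    profiles: dict[str, coh.ClassProfile],
    n_bins: int = 64,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one phantom cohort and extract the full feature panel.

    Returns (features with binary ``label`` column, raw clinical table).
    """
    records = coh.generate_clinical_cohort(spec, profiles)
    rows = {}
    for i, rec in enumerate(records):
        sub_seed = int(coh._subject_rng(spec.seed, i).integers(0, 2**31 - 1))
        img, mask = coh.generate_phantom(profiles[rec.class_label],
                                         rec.max_diameter, spec, sub_seed)
        rows[rec.subject_id] = full_feature_vector(img, mask, n_bins=n_bins)
    feats = pd.DataFrame.from_dict(rows, orient="index")
    feats.index.name = "subject_id"
    clinical = coh.records_to_frame(records)
    feats[scr.LABEL] = (clinical.loc[feats.index, "group"] == "HEAML").astype(int)
    return feats, clinical


def signature_replicate(
    features: pd.DataFrame,
    seed: int,
    screen_k: int = 80,
    algorithm: str = "RF",
    smote_k: int = 5,
) -> dict:
    """One pass of the signature protocol: stratified 2:1 split, MI
    screening and SMOTE on the training cohort only, model fit, train/test
    AUC."""
    split = scr.stratified_split(features, seed=seed)
    train = features.loc[list(split.train_ids)]
    test = features.loc[list(split.test_ids)]
    ranking = scr.mutual_information_rank(train)
    k = min(screen_k, len(ranking))
    train_k = scr.select_top_k(train, ranking, k)
    test_k = scr.select_top_k(test, ranking, k)
    balanced = scr.smote(train_k, k_neighbors=smote_k, seed=seed)
    model = mod.fit_default(algorithm, balanced.drop(columns=[scr.SYNTHETIC]),
                            seed=seed)
    train_auc = mod.auc_concordance(mod.predict_scores(model, train_k),
                                    train_k[scr.LABEL])
    test_auc = mod.auc_concordance(mod.predict_scores(model, test_k),
                                   test_k[scr.LABEL])
    return {"train_auc": train_auc, "test_auc": test_auc, "screen_k": k,
            "n_train": len(train), "n_test": len(test),
            "n_balanced": len(balanced), "model": model, "split": split}


def fusion_replicate(
    features: pd.DataFrame,
    clinical_raw: pd.DataFrame,
    seed: int,
    screen_k: int = 80,
    n_folds: int = 10,
    inner_folds: int = 3,
) -> fus.FusionCvResult:
    """Stratified 10-fold fusion-model evaluation (no SMOTE on this path)."""
    clin = fus.encode_clinical(clinical_raw).loc[features.index]
    return fus.cross_validate_fusion(
        features, clin, n_folds=n_folds, seed=seed, screen_k=screen_k,
        inner_folds=inner_folds)


def permute_labels(features: pd.DataFrame, clinical_raw: pd.DataFrame,
                   seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Null cohort: class labels randomly reassigned across subjects (the
    feature-label and clinical-label pairings are both broken)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(features))
    f = features.copy()
    f[scr.LABEL] = f[scr.LABEL].to_numpy()[perm]
    c = clinical_raw.copy()
    c["group"] = np.where(f[scr.LABEL] == 1, "HEAML", "non-HEAML")
    return f, c
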