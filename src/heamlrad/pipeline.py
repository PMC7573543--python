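"""End-to-end pipeline stages over flat-file artifacts.

Each stage reads the previous stage's outputs from the working directory,
writes its own tables/JSON plus a manifest (config hash, seed), and can be
rerun in isolation. Stage order: simulate -> extract -> train -> report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as _cohort
from . import fusion as _fusion
from . import models as _models
from . import screening as _screening
from .preprocess import load_case, resample, select_slice
from .texture import feature_dictionary
from .wavelet import full_feature_vector

log = logging.getLogger("heamlrad")

DEFAULT_SCREEN_K = {"CT": 80, "MRI": 95}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    modality: str = "CT"
    n_per_class: dict = field(
        default_factory=lambda: {"HEAML": 33, "HCC": 78, "FNH": 59})
    image_size: int = 64
    pixel_spacing: float = 2.5      # mm, generator grid
    target_spacing: float | None = None  # mm; None = keep the native grid
    n_bins: int = 64
    screen_k: int | None = None     # None = per-modality default (80 CT / 95 MRI)
    smote_k_neighbors: int = 5
    signature_algorithms: tuple = ("RF", "RR", "ANN")
    grid_search: bool = True
    fusion_folds: int = 10
    seed: int = 0
    image_format: str = "nii"
    out_dir: str = "results/pipeline"

    def validate(self) -> None:
        if self.pixel_spacing <= 0:
            raise ConfigError("pixel_spacing must be > 0")
        if self.target_spacing is not None and self.target_spacing <= 0:
            raise ConfigError("target_spacing must be > 0")
        if self.image_size < 16:
            raise ConfigError("image_size must be >= 16")
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")
        if self.modality.upper() not in ("CT", "MRI"):
            raise ConfigError(f"modality must be CT or MRI, got {self.modality!r}")

    @property
    def effective_screen_k(self) -> int:
        return self.screen_k if self.screen_k is not None \
            else DEFAULT_SCREEN_K[self.modality.upper()]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.signature_algorithms, list):
            cfg.signature_algorithms = tuple(cfg.signature_algorithms)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(out: Path, stage: str, cfg: PipelineConfig, extra: dict) -> None:
    manifest = {"stage": stage, "config_hash": cfg.config_hash(),
                "seed": cfg.seed, "config": dataclasses.asdict(cfg), **extra}
    (out / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def cmd_simulate(cfg: PipelineConfig) -> Path:
    cfg.validate()
    out = Path(cfg.out_dir)
    spec = _cohort.CohortSpec(cfg.modality.upper(), cfg.n_per_class,
                              cfg.image_size, cfg.pixel_spacing, cfg.seed)
    profiles = _cohort.default_profiles(cfg.modality)
    log.info("simulate: stage=simulate seed=%d hash=%s", cfg.seed, cfg.config_hash())
    _cohort.generate_study(spec, profiles, out / "dataset", cfg.image_format)
    _write_manifest(out, "simulate", cfg, {"n_subjects": sum(cfg.n_per_class.values())})
    return out / "dataset"


def extract_features_dataset(dataset_dir: Path, cfg: PipelineConfig) -> pd.DataFrame:
    manifest = json.loads((dataset_dir / "manifest.json").read_text())
    rows = {}
    for sid, files in manifest["files"].items():
        img, mask = load_case(dataset_dir / "images" / files["image"],
                              dataset_dir / "images" / files["mask"])
        img, mask = select_slice(img, mask)
        if cfg.target_spacing is not None:
            img, mask = resample(img, mask, cfg.target_spacing)
        rows[sid] = full_feature_vector(img, mask, n_bins=cfg.n_bins)
    feats = pd.DataFrame.from_dict(rows, orient="index")
    feats.index.name = "subject_id"
    clin = pd.read_csv(dataset_dir / "clinical.csv", index_col="subject_id")
    feats[_screening.LABEL] = (clin.loc[feats.index, "group"] == "HEAML").astype(int)
    return feats


def cmd_extract(cfg: PipelineConfig) -> Path:
    cfg.validate()
    out = Path(cfg.out_dir)
    dataset = out / "dataset"
    if not (dataset / "manifest.json").exists():
        raise FileNotFoundError(f"run simulate first: missing {dataset}/manifest.json")
    log.info("extract: stage=extract seed=%d hash=%s", cfg.seed, cfg.config_hash())
    feats = extract_features_dataset(dataset, cfg)
    feats.to_csv(out / "features.csv")
    (out / "feature_dictionary.json").write_text(
        json.dumps(feature_dictionary(), indent=2, sort_keys=True))
    _write_manifest(out, "extract", cfg, {
        "n_subjects": len(feats),
        "n_features": len(_screening.feature_columns(feats)),
    })
    return out / "features.csv"


def cmd_train(cfg: PipelineConfig) -> dict:
    cfg.validate()
    out = Path(cfg.out_dir)
    fpath = out / "features.csv"
    if not fpath.exists():
        raise FileNotFoundError(f"run extract first: missing {fpath}")
    feats = pd.read_csv(fpath, index_col="subject_id")
    split = _screening.stratified_split(feats, seed=cfg.seed)
    train, test = feats.loc[list(split.train_ids)], feats.loc[list(split.test_ids)]
    ranking = _screening.mutual_information_rank(train)
    k = min(cfg.effective_screen_k, len(ranking))
    train_k = _screening.select_top_k(train, ranking, k)
    test_k = _screening.select_top_k(test, ranking, k)
    balanced = _screening.smote(train_k, cfg.smote_k_neighbors, seed=cfg.seed)
    balanced_fit = balanced.drop(columns=[_screening.SYNTHETIC])

    results = {}
    for algo in cfg.signature_algorithms:
        model = (_models.grid_search_fit(algo, balanced_fit, seed=cfg.seed)
                 if cfg.grid_search
                 else _models.fit_default(algo, balanced_fit, seed=cfg.seed))
        roc_tr = _models.roc_auc(_models.predict_scores(model, train_k),
                                 train_k[_screening.LABEL])
        roc_te = _models.roc_auc(_models.predict_scores(model, test_k),
                                 test_k[_screening.LABEL])
        results[algo] = {
            "train_auc": roc_tr.auc, "train_ci": [roc_tr.ci_low, roc_tr.ci_high],
            "test_auc": roc_te.auc, "test_ci": [roc_te.ci_low, roc_te.ci_high],
            "selected_params": {k_: str(v) for k_, v in model.selected_params.items()},
        }
        log.info("train: algo=%s train_auc=%.3f test_auc=%.3f",
                 algo, roc_tr.auc, roc_te.auc)

    (out / "screening.csv").write_text(
        "feature,mi_nats,rank\n" + "\n".join(
            f"{name},{mi:.6f},{i + 1}" for i, (name, mi) in enumerate(ranking)))
    (out / "signature_results.json").write_text(
        json.dumps(results, indent=2, sort_keys=True))
    split_manifest = {"train": list(map(str, split.train_ids)),
                      "test": list(map(str, split.test_ids)), "seed": split.seed,
                      "screen_k": k, "n_balanced": len(balanced)}
    (out / "split.json").write_text(json.dumps(split_manifest, indent=2))
    _write_manifest(out, "train", cfg, {"signatures": results})
    return results


def cmd_report(cfg: PipelineConfig) -> dict:
    cfg.validate()
    out = Path(cfg.out_dir)
    if not (out / "features.csv").exists():
        raise FileNotFoundError("run extract first")
    feats = pd.read_csv(out / "features.csv", index_col="subject_id")
    clin_raw = pd.read_csv(out / "dataset" / "clinical.csv", index_col="subject_id")
    clin = _fusion.encode_clinical(clin_raw).loc[feats.index]

    cv = _fusion.cross_validate_fusion(
        feats, clin, n_folds=cfg.fusion_folds, seed=cfg.seed,
        screen_k=cfg.effective_screen_k)
    dca = _fusion.decision_curve(cv.pooled_scores.to_numpy(),
                                 cv.labels.to_numpy())
    # final fusion model on the full cohort for the nomogram
    score_full = _fusion.out_of_fold_scores(feats, seed=cfg.seed,
                                            screen_k=cfg.effective_screen_k)
    clin_cols = list(_fusion.CLINICAL_COVARIATES)
    tab = clin[clin_cols].assign(signature_score=score_full.to_numpy(),
                                 **{_screening.LABEL: feats[_screening.LABEL]})
    final = _fusion.aic_select(tab)
    ranges = {c: (float(tab[c].min()), float(tab[c].max()))
              for c in final.covariates}
    nomo = _fusion.build_nomogram(final, ranges)
    stats_tab = _fusion.clinical_stats(clin_raw)

    pd.DataFrame({"threshold": dca.thresholds, "nb_model": dca.net_benefit,
                  "nb_all": dca.net_benefit_all,
                  "nb_none": dca.net_benefit_none}).to_csv(out / "dca.csv", index=False)
    stats_tab.to_csv(out / "clinical_stats.csv")
    nomo_json = {
        "per_point": nomo.per_point,
        "intercept": nomo.intercept,
        "base_offset": nomo.base_offset,
        "scales": [dataclasses.asdict(s) for s in nomo.scales],
    }
    report = {
        "fusion_mean_cv_auc": cv.mean_auc,
        "fusion_pooled_cv_auc": cv.pooled_auc,
        "signature_mean_cv_auc": cv.mean_signature_auc,
        "clinical_mean_cv_auc": cv.mean_clinical_auc,
        "fold_aucs": cv.fold_aucs,
        "selected_subsets": [list(s) for s in cv.selected_subsets],
        "final_model": {
            "covariates": final.covariates,
            "coefficients": list(map(float, final.coef)),
            "intercept": final.intercept,
            "aic": final.aic,
            "regularized": final.regularized,
        },
        "nomogram": nomo_json,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("report: fusion mean CV AUC=%.3f pooled=%.3f",
             cv.mean_auc, cv.pooled_auc)
    _write_manifest(out, "report", cfg, {"fusion_mean_cv_auc": cv.mean_auc})
    return report


def cmd_all(cfg: PipelineConfig) -> dict:
    cmd_simulate(cfg)
    cmd_extract(cfg)
    sig = cmd_train(cfg)
    rep = cmd_report(cfg)
    return {"signatures": sig, "report": rep}
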