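import numpy as np
import pandas as pd
import pytest

import heamlrad as h
from heamlrad import fusion as fus
from heamlrad import screening as scr
from heamlrad.pipeline import PipelineConfig, cmd_simulate, extract_features_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small but separable CT-styled cohort with extracted features and
    encoded clinical covariates — shared by the model/fusion tests."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = PipelineConfig(
        n_per_class={"HEAML": 15, "HCC": 20, "FNH": 15},
        image_size=48, seed=11, out_dir=str(out), grid_search=False,
    )
    dataset = cmd_simulate(cfg)
    feats = extract_features_dataset(dataset, cfg)
    clin_raw = pd.read_csv(dataset / "clinical.csv", index_col="subject_id")
    clin = fus.encode_clinical(clin_raw).loc[feats.index]
    return {"features": feats, "clinical": clin, "clinical_raw": clin_raw,
            "config": cfg, "dataset": dataset}


@pytest.fixture(scope="session")
def toy_feature_table():
    """Deterministic 60-subject table: two informative features, one noise."""
    rng = np.random.default_rng(7)
    n1, n0 = 20, 40
    y = np.array([1] * n1 + [0] * n0)
    f1 = np.where(y == 1, 2.0, 0.0) + rng.normal(0, 0.6, 60)
    f2 = np.where(y == 1, -1.5, 0.0) + rng.normal(0, 0.6, 60)
    noise = rng.normal(size=60)
    return pd.DataFrame(
        {"sig_a": f1, "sig_b": f2, "noise": noise, scr.LABEL: y},
        index=[f"s{i:02d}" for i in range(60)],
    )
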