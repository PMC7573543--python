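#!/usr/bin/env python
"""Extract the 423-feature texture/wavelet panel for both phantom cohorts.

Reads the datasets written by 01_simulate_cohorts.py (their manifests carry
the generating config); writes results/pipeline_{ct,mri}/features.csv plus
the feature dictionary JSON.
"""

import json
from pathlib import Path

import pandas as pd

from heamlrad.pipeline import PipelineConfig, cmd_extract


def main():
    for modality in ("CT", "MRI"):
        out_dir = Path(f"results/pipeline_{modality.lower()}")
        manifest = json.loads((out_dir / "manifest_simulate.json").read_text())
        config = manifest["config"]
        config["signature_algorithms"] = tuple(config["signature_algorithms"])
        cfg = PipelineConfig(**config)
        path = cmd_extract(cfg)
        feats = pd.read_csv(path, index_col="subject_id")
        n_feat = feats.shape[1] - 1  # minus the label column
        print(f"[{modality}] features: {feats.shape[0]} subjects x {n_feat} "
              f"features -> {path}")
        assert n_feat == 423


if __name__ == "__main__":
    main()
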