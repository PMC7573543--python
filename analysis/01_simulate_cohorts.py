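#!/usr/bin/env python
"""Generate the CT-styled (33/78/59) and MRI-styled (30/77/30) phantom
cohorts and summarize their clinical covariates HEAML vs non-HEAML.

Writes results/pipeline_{ct,mri}/dataset/ and results/clinical_stats_*.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from heamlrad import clinical_stats
from heamlrad.pipeline import PipelineConfig, cmd_simulate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    for modality in ("CT", "MRI"):
        cfg = PipelineConfig(modality=modality, seed=SEED,
                             out_dir=f"results/pipeline_{modality.lower()}")
        if modality == "MRI":
            cfg.n_per_class = {"HEAML": 30, "HCC": 77, "FNH": 30}
        dataset = cmd_simulate(cfg)
        clin = pd.read_csv(dataset / "clinical.csv", index_col="subject_id")
        table = clinical_stats(clin)
        out = Path(f"results/clinical_stats_{modality.lower()}.csv")
        table.to_csv(out)
        print(f"[{modality}] {len(clin)} subjects "
              f"({(clin.group == 'HEAML').sum()} HEAML) -> {dataset}")
        print(table[["heaml", "non_heaml", "p_display"]].to_string(), "\n")


if __name__ == "__main__":
    main()
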