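#!/usr/bin/env python
"""Power-law normalize the merged libraries and build consensus clusters.

Replicates are merged on raw tags per condition, each merged sample is
normalized onto the reference power law (alpha 1.05, one million tags),
CTSSs supported by >= 0.5 tpm somewhere are chained into tag clusters
(gap <= 20 bp, trimmed to the 10-90% expression quantiles, > 5 tpm kept)
and aggregated across conditions into consensus clusters (within 100 bp),
annotated against the gene models.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from promoterome.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = PipelineConfig.from_yaml(args.results / "data" /
                                   "pipeline_config.yaml")
    run_pipeline(cfg, stages=["normalize", "cluster"])

    for cond in sorted(cfg.samples):
        model = json.loads((cfg.outdir / f"powerlaw_{cond}.json").read_text())
        print(f"{cond}: fitted reverse-cumulative slope "
              f"{model['fitted_slope']:.3f} (reference -{model['alpha_ref']})")
    ccs = pd.read_csv(cfg.outdir / "cc_table.tsv", sep="\t")
    support = [c for c in ccs.columns if c.startswith("tc_support_")]
    print(f"{len(ccs)} consensus clusters; "
          f"{int(ccs[support].all(axis=1).sum())} shared between conditions")
    print("feature classes:", ccs["feature"].value_counts().to_dict())
    print(f"promoter-proximal set (<=1 kb upstream or 5'UTR): "
          f"{int(ccs['promoter_set'].sum())}")


if __name__ == "__main__":
    main()
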