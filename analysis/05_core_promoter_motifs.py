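#!/usr/bin/env python
"""Core-promoter motif usage in the differential-expression groups.

Promoter windows (-120..+50 around each dominant TSS) are scanned with the
PFMs; a hit is a >= 90% match. Occurrence per DE group is compared with the
unchanged background by Fisher's exact test, plus the TATA match-percent
distribution in -40..-20, WW-dinucleotide profiles and poly-W pentamers.
"""

import argparse
from pathlib import Path

import pandas as pd

from promoterome.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = PipelineConfig.from_yaml(args.results / "data" /
                                   "pipeline_config.yaml")
    run_pipeline(cfg, stages=["motifs"])

    enr = pd.read_csv(cfg.outdir / "motif_enrichment.tsv", sep="\t")
    print("motif enrichment vs unchanged background:")
    for _, r in enr.sort_values(["group", "motif"]).iterrows():
        star = "*" if r["significant"] else " "
        print(f"  {r['group']:>8} {r['motif']:>6}: log2 OR "
              f"{r['log2_odds_ratio']:+.2f}  p={r['p_value']:.2e} {star}")
    bins = pd.read_csv(cfg.outdir / "tata_match_bins.tsv", sep="\t")
    print("TATA match distribution in -40..-20:",
          dict(zip(bins["match_bin"], bins["n_promoters"])))
    pent = pd.read_csv(cfg.outdir / "polyw_pentamers.tsv", sep="\t")
    top = pent[pent["p_value"] < 0.01].sort_values("p_value").head(6)
    print("significantly used poly-W pentamers (p < 0.01):")
    for _, r in top.iterrows():
        print(f"  {r['pentamer']} in {r['group']}: "
              f"{r['n_group_hit']}/{r['n_group']} promoters, "
              f"{r['n_tata_overlap']} overlapping a canonical TATA")


if __name__ == "__main__":
    main()
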