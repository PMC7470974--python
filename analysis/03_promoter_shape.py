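#!/usr/bin/env python
"""Classify promoter shape per condition and count shape transitions.

Shape classes (sharp / peaked broad / broad) follow the interquantile-width
and dominant-TSS-fraction rules; transitions are counted on consensus
clusters with >= 10 tpm in both conditions. With truth available, planted
shape recovery is reported.
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
    run_pipeline(cfg, stages=["shape"])

    conds = sorted(cfg.samples)
    ccs = pd.read_csv(cfg.outdir / "cc_table.tsv", sep="\t")
    truth = pd.read_csv(args.results / "data" / "truth_genes.tsv", sep="\t")
    calls = {c: pd.read_csv(cfg.outdir / f"shape_calls_{c}.tsv", sep="\t")
             for c in conds}
    for cond in conds:
        expressed = calls[cond][calls[cond]["tpm"] >= 10]
        print(f"{cond} shape classes (tpm >= 10):",
              expressed["shape_class"].value_counts(normalize=True)
              .round(3).to_dict())
    pairs = pd.read_csv(cfg.outdir / "shape_transitions.tsv", sep="\t")
    n_trans = int(pairs["transitioning"].sum())
    print(f"shape transitions: {n_trans}/{len(pairs)} "
          f"({100 * n_trans / len(pairs):.1f}%) of well-expressed CCs")

    m = (ccs[["cc_id", "gene_id"]].merge(calls[conds[0]], on="cc_id")
         .merge(calls[conds[1]], on="cc_id", suffixes=("_a", "_b"))
         .merge(truth, on="gene_id"))
    well = m[(m["tpm_a"] >= 10) & (m["tpm_b"] >= 10)]
    for cond, suffix in zip(conds, ("_a", "_b")):
        acc = (well[f"shape_class{suffix}"] == well[f"shape_{cond}"]).mean()
        print(f"planted shape recovery {cond}: {100 * acc:.1f}% "
              f"(n={len(well)})")


if __name__ == "__main__":
    main()
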