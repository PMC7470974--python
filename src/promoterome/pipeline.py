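"""End-to-end orchestration of the promoterome analysis stages.

Stages run in dependency order — normalize, cluster, shape, diffexp, motifs,
genesets, altprom, temporal — each reading its inputs from the output
directory of the previous stages, so any stage can be re-run from cached
intermediates. Every stage appends a JSON log line with the exact parameters
used and checksums of its inputs; all outputs are plain TSV with fixed float
formatting, so a rerun from the same config and seed is byte-identical.

Catalogue-dependent stages (genesets, altprom, temporal) are skipped with a
warning when their catalogue files are not configured.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import alt_promoters, clustering, diffexp, gene_set_statistics, \
    motif_enrichment, normalization, shape, temporal_dynamics
from .io_formats import clusters_to_bed, extract_promoter_window, \
    read_annotation, read_ctss, read_pwm_jaspar

STAGES = ["normalize", "cluster", "shape", "diffexp", "motifs", "genesets",
          "altprom", "temporal"]

FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    """User-actionable pipeline failure (missing input or intermediate)."""


@dataclass
class PipelineConfig:
    """Validated run configuration; every analysis parameter has a default
    so a minimal config (samples + genome + annotation + pwms) runs."""

    outdir: Path
    seed: int = 0
    samples: dict[str, list[Path]] = field(default_factory=dict)
    genome: Path | None = None
    annotation: Path | None = None
    pwms: Path | None = None
    catalogues: dict[str, Path] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    DEFAULT_PARAMS = {
        "alpha_ref": normalization.DEFAULT_ALPHA,
        "total_ref": normalization.DEFAULT_TOTAL,
        "fit_range": list(normalization.DEFAULT_FIT_RANGE),
        "min_ctss_tpm": clustering.DEFAULT_MIN_CTSS_TPM,
        "max_gap": clustering.DEFAULT_MAX_GAP,
        "min_cluster_tpm": clustering.DEFAULT_MIN_CLUSTER_TPM,
        "max_cc_gap": clustering.DEFAULT_MAX_CC_GAP,
        "promoter_window": 1000,
        "sharp_width": shape.DEFAULT_SHARP_WIDTH,
        "dom_frac": shape.DEFAULT_DOM_FRAC,
        "strict_sharp": False,
        "shape_min_tpm": shape.DEFAULT_MIN_TPM,
        "window_up": 120,
        "window_down": 50,
        "hit_percent": motif_enrichment.DEFAULT_HIT_PERCENT,
        "p_threshold": motif_enrichment.DEFAULT_P_THRESHOLD,
        "de_alpha": diffexp.DEFAULT_ALPHA,
        "n_perm": gene_set_statistics.DEFAULT_N_PERM,
        "alt_min_tpm": alt_promoters.DEFAULT_MIN_TPM,
        "alt_rel_fold": alt_promoters.DEFAULT_REL_FOLD,
        "temporal_min_tpm": temporal_dynamics.DEFAULT_MIN_TPM,
        "temporal_fold": temporal_dynamics.DEFAULT_FOLD,
    }

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        merged = dict(self.DEFAULT_PARAMS)
        merged.update(self.params or {})
        self.params = merged
        if len(self.samples) not in (0, 2):
            raise PipelineError(
                f"expected two conditions, got {sorted(self.samples)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = {cond: [Path(p) for p in paths]
                   for cond, paths in (raw.get("samples") or {}).items()}
        cfg = cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            samples=samples,
            genome=Path(raw["genome"]) if raw.get("genome") else None,
            annotation=Path(raw["annotation"]) if raw.get("annotation") else None,
            pwms=Path(raw["pwms"]) if raw.get("pwms") else None,
            catalogues={k: Path(v)
                        for k, v in (raw.get("catalogues") or {}).items()},
            params=raw.get("params") or {},
        )
        cfg.validate_paths()
        return cfg

    def validate_paths(self) -> None:
        missing = []
        for cond, paths in self.samples.items():
            missing += [p for p in paths if not Path(p).exists()]
        for p in (self.genome, self.annotation, self.pwms):
            if p is not None and not Path(p).exists():
                missing.append(p)
        missing += [p for p in self.catalogues.values() if not Path(p).exists()]
        if missing:
            raise PipelineError(f"missing input files: {missing}")

    # -- bookkeeping -------------------------------------------------------

    def path(self, name: str) -> Path:
        return self.outdir / name

    def require(self, name: str, producer: str) -> Path:
        p = self.path(name)
        if not p.exists():
            raise PipelineError(
                f"missing intermediate {p}; re-run stage {producer!r} first")
        return p

    def log(self, stage: str, params: dict, inputs: list[Path]) -> None:
        entry = {
            "stage": stage,
            "params": params,
            "inputs": {str(p): _checksum(p) for p in inputs if p is not None},
        }
        with open(self.path("pipeline_log.jsonl"), "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True, default=str) + "\n")


def _checksum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_normalize(cfg: PipelineConfig) -> None:
    """Merge replicates per condition on raw tags, fit each merged sample's
    power law and write normalized CTSS tables plus model sidecars."""
    if not cfg.samples:
        raise PipelineError("no samples configured")
    p = cfg.params
    for cond, paths in cfg.samples.items():
        tables = [read_ctss(path) for path in paths]
        merged = normalization.merge_replicates(tables)
        norm, model = normalization.normalize_sample(
            merged, fit_range=tuple(p["fit_range"]),
            alpha_ref=p["alpha_ref"], total_ref=p["total_ref"])
        norm.to_csv(cfg.path(f"ctss_norm_{cond}.tsv"), sep="\t", index=False,
                    float_format="%.8g")
        model.to_json(cfg.path(f"powerlaw_{cond}.json"))
        cfg.log("normalize", {k: p[k] for k in
                              ("alpha_ref", "total_ref", "fit_range")}, paths)


def stage_cluster(cfg: PipelineConfig) -> None:
    """Filter supported CTSSs, call per-condition tag clusters, aggregate
    into consensus clusters, annotate, and extract per-replicate raw counts
    per CC for differential expression."""
    p = cfg.params
    conds = sorted(cfg.samples)
    norm_tables = {c: pd.read_csv(cfg.require(f"ctss_norm_{c}.tsv", "normalize"),
                                  sep="\t", dtype={"chrom": str})
                   for c in conds}
    filtered = clustering.filter_supported_ctss(norm_tables,
                                                min_tpm=p["min_ctss_tpm"])
    tc_sets = {}
    for cond, table in filtered.items():
        tcs = clustering.call_tag_clusters(
            table, sample_id=cond, max_gap=p["max_gap"],
            min_cluster_tpm=p["min_cluster_tpm"])
        tc_sets[cond] = tcs
        _write(clustering.tag_clusters_frame(tcs), cfg.path(f"tc_{cond}.tsv"))
    ccs = clustering.build_consensus_clusters(tc_sets, filtered,
                                              max_cc_gap=p["max_cc_gap"])
    annotation = read_annotation(cfg.annotation) if cfg.annotation else None
    ccs = clustering.annotate_cc(ccs, annotation,
                                 promoter_window=p["promoter_window"])
    _write(ccs, cfg.path("cc_table.tsv"))
    clusters_to_bed(ccs, cfg.path("cc_table.bed"))
    # per-replicate raw counts per CC, for the NB test
    rep_tables = {}
    for cond, paths in cfg.samples.items():
        for i, path in enumerate(paths):
            t = read_ctss(path)
            t["tpm"] = 0.0
            rep_tables[f"{cond}_rep{i + 1}"] = t
    counts = cc_count_matrix(ccs, rep_tables)
    _write(counts, cfg.path("cc_counts.tsv"), index=True)
    cfg.log("cluster", {k: p[k] for k in
                        ("min_ctss_tpm", "max_gap", "min_cluster_tpm",
                         "max_cc_gap", "promoter_window")},
            [cfg.annotation] if cfg.annotation else [])


def cc_count_matrix(ccs: pd.DataFrame,
                    replicate_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Sum each replicate's raw counts over every CC span (cc_id x sample)."""
    cols = {}
    for sample, table in replicate_tables.items():
        idx = clustering._assign_to_spans(table, ccs)
        sub = table.loc[idx >= 0, ["count"]].copy()
        sub["cc_idx"] = idx[idx >= 0]
        sums = sub.groupby("cc_idx")["count"].sum()
        cols[sample] = sums.reindex(range(len(ccs))).fillna(0).astype(int)
    out = pd.DataFrame(cols)
    out.index = ccs["cc_id"]
    return out


def stage_shape(cfg: PipelineConfig) -> None:
    """Per-condition shape calls and the between-condition transition matrix
    on CCs well expressed in both conditions."""
    p = cfg.params
    ccs = pd.read_csv(cfg.require("cc_table.tsv", "cluster"), sep="\t",
                      dtype={"chrom": str})
    conds = sorted(cfg.samples)
    calls = {}
    for cond in conds:
        calls[cond] = shape.shape_calls(
            ccs, cond, sharp_width=p["sharp_width"], dom_frac=p["dom_frac"],
            strict_sharp=p["strict_sharp"])
        _write(calls[cond], cfg.path(f"shape_calls_{cond}.tsv"))
    matrix, pairs = shape.shape_transition_matrix(
        calls[conds[0]], calls[conds[1]], min_tpm=p["shape_min_tpm"])
    _write(matrix, cfg.path("shape_transitions_matrix.tsv"), index=True)
    _write(pairs, cfg.path("shape_transitions.tsv"))
    _write(shape.transition_long_format(matrix), cfg.path("shape_sankey.tsv"))
    cfg.log("shape", {k: p[k] for k in
                      ("sharp_width", "dom_frac", "strict_sharp",
                       "shape_min_tpm")}, [cfg.path("cc_table.tsv")])


def stage_diffexp(cfg: PipelineConfig) -> None:
    """NB Wald differential expression on representative promoter CCs."""
    p = cfg.params
    ccs = pd.read_csv(cfg.require("cc_table.tsv", "cluster"), sep="\t",
                      dtype={"chrom": str})
    counts = pd.read_csv(cfg.require("cc_counts.tsv", "cluster"), sep="\t",
                         index_col=0)
    # shared CCs only (tag-cluster support in every condition), then one CC
    # per gene: the highest-expressed representative, promoter set only
    support_cols = [c for c in ccs.columns if c.startswith("tc_support_")]
    shared = ccs[ccs["promoter_set"] & ccs[support_cols].all(axis=1)]
    rep = clustering.reduce_to_representative(shared)
    counts = counts.loc[rep["cc_id"]]
    conditions = {col: col.rsplit("_rep", 1)[0] for col in counts.columns}
    res = diffexp.run_diffexp(counts, conditions, alpha=p["de_alpha"])
    res = res.join(rep.set_index("cc_id")["gene_id"])
    _write(res, cfg.path("diffexp.tsv"), index=True)
    cfg.log("diffexp", {"de_alpha": p["de_alpha"]},
            [cfg.path("cc_counts.tsv")])


def _de_groups(cfg: PipelineConfig) -> tuple[pd.Series, str]:
    res = pd.read_csv(cfg.require("diffexp.tsv", "diffexp"), sep="\t",
                      index_col=0)
    return res["call"], "unchanged"


def stage_motifs(cfg: PipelineConfig) -> None:
    """Scan promoter windows of the tested CCs and compute enrichment of each
    motif in each differential-expression group, the TATA match distribution,
    WW-dinucleotide profiles and poly-W pentamer usage."""
    import pyfaidx

    p = cfg.params
    if cfg.genome is None or cfg.pwms is None:
        warnings.warn("motifs stage skipped: genome or PWM file not configured")
        return
    ccs = pd.read_csv(cfg.require("cc_table.tsv", "cluster"), sep="\t",
                      dtype={"chrom": str})
    groups, background = _de_groups(cfg)
    pwms = read_pwm_jaspar(cfg.pwms)
    genome = pyfaidx.Fasta(str(cfg.genome))
    sub = ccs[ccs["cc_id"].isin(groups.index)].dropna(subset=["dominant_pos"])
    windows = {
        row.cc_id: extract_promoter_window(
            genome, row.chrom, int(row.dominant_pos), row.strand,
            up=p["window_up"], down=p["window_down"])
        for row in sub.itertuples()}
    hits = motif_enrichment.motif_hit_table(pwms, windows,
                                            hit_percent=p["hit_percent"])
    _write(hits, cfg.path("motif_hits.tsv"))
    enr = motif_enrichment.motif_group_enrichment(
        groups, hits, background, p_threshold=p["p_threshold"])
    _write(enr, cfg.path("motif_enrichment.tsv"))
    _write(motif_enrichment.enrichment_heatmap_matrix(enr),
           cfg.path("motif_enrichment_heatmap.tsv"), index=True)
    tata = next((m for m in pwms if "TATA" in m.name.upper()), None)
    if tata is not None:
        per_prom, dist = motif_enrichment.tata_match_distribution(tata, windows)
        _write(per_prom, cfg.path("tata_match.tsv"))
        _write(dist, cfg.path("tata_match_bins.tsv"))
        pent = motif_enrichment.polyw_pentamer_enrichment(
            groups, windows, background, tata_pwm=tata,
            hit_percent=p["hit_percent"])
        _write(pent, cfg.path("polyw_pentamers.tsv"))
    profiles = []
    for grp in sorted(groups.unique()):
        ids = groups.index[groups == grp]
        prof = motif_enrichment.ww_dinucleotide_profile(
            {i: windows[i] for i in ids if i in windows})
        prof.insert(0, "group", grp)
        profiles.append(prof)
    _write(pd.concat(profiles, ignore_index=True), cfg.path("ww_profile.tsv"))
    cfg.log("motifs", {k: p[k] for k in
                       ("window_up", "window_down", "hit_percent",
                        "p_threshold")}, [cfg.pwms, cfg.genome])


def stage_genesets(cfg: PipelineConfig) -> None:
    """Cell-cycle catalogue permutation enrichment per DE group and
    tissue-specificity scores, when catalogues are configured."""
    import numpy as np

    p = cfg.params
    groups, background = _de_groups(cfg)
    res = pd.read_csv(cfg.path("diffexp.tsv"), sep="\t", index_col=0)
    gene_of = res["gene_id"]
    did_anything = False
    if "cell_cycle_genes" in cfg.catalogues:
        catalogue = gene_set_statistics.read_gene_set(
            cfg.catalogues["cell_cycle_genes"])
        universe = set(gene_of.dropna())
        rows = []
        rng = np.random.default_rng(cfg.seed)
        for grp in sorted(groups.unique()):
            query = set(gene_of[groups == grp].dropna())
            if not query:
                continue
            r = gene_set_statistics.permutation_enrichment(
                query, catalogue, universe, n_perm=p["n_perm"], seed=rng)
            rows.append({"group": grp, **r})
        _write(pd.DataFrame(rows), cfg.path("cellcycle_enrichment.tsv"))
        did_anything = True
    if "tissue_expression" in cfg.catalogues:
        expr = pd.read_csv(cfg.catalogues["tissue_expression"], sep="\t",
                           index_col=0)
        spec = gene_set_statistics.specificity_table(expr)
        _write(spec, cfg.path("tissue_specificity.tsv"), index=True)
        did_anything = True
    if not did_anything:
        warnings.warn("genesets stage skipped: no catalogues configured")
        return
    cfg.log("genesets", {"n_perm": p["n_perm"]},
            list(cfg.catalogues.values()))


def stage_altprom(cfg: PipelineConfig) -> None:
    """Alternative-promoter utilization classes from a twinned-pair TPM table."""
    p = cfg.params
    if "alt_pairs" not in cfg.catalogues:
        warnings.warn("altprom stage skipped: alt_pairs catalogue not configured")
        return
    pairs = pd.read_csv(cfg.catalogues["alt_pairs"], sep="\t")
    calls = alt_promoters.classify_pairs(pairs, min_tpm=p["alt_min_tpm"],
                                         rel_fold=p["alt_rel_fold"])
    _write(calls, cfg.path("alt_promoter_calls.tsv"))
    cfg.log("altprom", {k: p[k] for k in ("alt_min_tpm", "alt_rel_fold")},
            [cfg.catalogues["alt_pairs"]])


def stage_temporal(cfg: PipelineConfig) -> None:
    """Monotone temporal trend calls from a three-stage CC tpm table."""
    p = cfg.params
    if "temporal_tpm" not in cfg.catalogues:
        warnings.warn("temporal stage skipped: temporal_tpm catalogue not configured")
        return
    tpm = pd.read_csv(cfg.catalogues["temporal_tpm"], sep="\t", index_col=0)
    stage_cols = [c for c in tpm.columns if c.startswith("stage")][:3]
    calls = temporal_dynamics.classify_table(
        tpm, stage_cols, min_tpm=p["temporal_min_tpm"], fold=p["temporal_fold"])
    _write(calls, cfg.path("temporal_calls.tsv"), index=True)
    cfg.log("temporal", {k: p[k] for k in ("temporal_min_tpm", "temporal_fold")},
            [cfg.catalogues["temporal_tpm"]])


_STAGE_FUNCS = {
    "normalize": stage_normalize,
    "cluster": stage_cluster,
    "shape": stage_shape,
    "diffexp": stage_diffexp,
    "motifs": stage_motifs,
    "genesets": stage_genesets,
    "altprom": stage_altprom,
    "temporal": stage_temporal,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Execute the requested stages (all, in dependency order, by default).

    Returns the output directory. A fresh full run clears the stage log so
    reruns are reproducible byte-for-byte.
    """
    stages = STAGES if stages is None else stages
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise PipelineError(f"unknown stages {unknown}; choose from {STAGES}")
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    if set(stages) == set(STAGES):
        log = cfg.path("pipeline_log.jsonl")
        if log.exists():
            log.unlink()
    for name in STAGES:
        if name in stages:
            _STAGE_FUNCS[name](cfg)
    return cfg.outdir
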