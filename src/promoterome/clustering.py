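"""Tag clusters, consensus clusters, and annotation against gene models.

The clustering model follows standard CAGE practice: per sample, CTSSs on
the same strand are chained into tag clusters (TCs) while neighbouring
positions are at most ``max_gap`` apart; each TC is trimmed to the positions
of the 10th and 90th percentiles of its expression (robust boundaries) and
weakly expressed TCs are discarded. TCs from all samples are then aggregated
transitively into consensus clusters (CCs) when their spans lie within
``max_cc_gap`` of each other; CCs are the unit of all downstream promoter
analyses. All span coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_formats import parse_exon_blocks

DEFAULT_MIN_CTSS_TPM = 0.5
DEFAULT_MAX_GAP = 20
DEFAULT_MIN_CLUSTER_TPM = 5.0
DEFAULT_MAX_CC_GAP = 100
QUANTILES = (0.1, 0.9)

FEATURE_PRECEDENCE = [
    "Promoter(<=1kb)", "5'UTR", "Exon", "Intron", "3'UTR",
    "Promoter(1-3kb)", "Downstream(<3kb)", "Distal intergenic",
]
PROMOTER_SET_FEATURES = {"Promoter(<=1kb)", "5'UTR"}


# ---------------------------------------------------------------------------
# Tag clusters
# ---------------------------------------------------------------------------

@dataclass
class TagCluster:
    """One per-sample transcriptional cluster; members sorted by position."""

    sample_id: str
    chrom: str
    strand: str
    positions: np.ndarray
    tpms: np.ndarray
    trimmed: bool = False

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.tpms = np.asarray(self.tpms, dtype=float)
        if self.positions.size == 0:
            raise ValueError("tag cluster with no members")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("member CTSSs must be sorted by ascending position")

    @property
    def start(self) -> int:
        return int(self.positions[0])

    @property
    def end(self) -> int:
        return int(self.positions[-1])

    @property
    def total_tpm(self) -> float:
        return float(self.tpms.sum())

    @property
    def dominant_pos(self) -> int:
        return int(dominant_position(self.positions, self.tpms, self.strand))

    @property
    def dominant_tpm(self) -> float:
        return float(self.tpms.max())

    @property
    def q_low(self) -> int:
        lo, _ = interquantile_bounds(self.positions, self.tpms)
        return int(lo)

    @property
    def q_high(self) -> int:
        _, hi = interquantile_bounds(self.positions, self.tpms)
        return int(hi)

    @property
    def iq_width(self) -> int:
        lo, hi = interquantile_bounds(self.positions, self.tpms)
        return int(hi - lo + 1)


def dominant_position(positions: np.ndarray, tpms: np.ndarray,
                      strand: str) -> int:
    """Position of maximal expression; ties resolved to the most 5' position
    on the transcribed strand (a deterministic, reproducible rule)."""
    best = tpms == tpms.max()
    candidates = positions[best]
    return int(candidates.min() if strand == "+" else candidates.max())


def interquantile_bounds(positions: np.ndarray, tpms: np.ndarray,
                         low: float = QUANTILES[0],
                         high: float = QUANTILES[1]) -> tuple[int, int]:
    """Positions of the ``low`` and ``high`` expression percentiles.

    q_low (q_high) is the smallest position whose cumulative expression,
    scanning 5'->3' in genomic order, reaches ``low`` (``high``) of the
    cluster total.
    """
    cum = np.cumsum(tpms)
    total = cum[-1]
    i_low = int(np.searchsorted(cum, low * total, side="left"))
    i_high = int(np.searchsorted(cum, high * total, side="left"))
    return int(positions[i_low]), int(positions[i_high])


def trim_cluster(cluster: TagCluster) -> TagCluster:
    """Drop members outside the 10th-90th expression percentile positions.

    Trimming is a one-shot boundary-robustness step: a cluster already
    trimmed is returned unchanged, so the operation is idempotent by
    construction and never widens the interquantile span.
    """
    if cluster.trimmed:
        return cluster
    lo, hi = interquantile_bounds(cluster.positions, cluster.tpms)
    keep = (cluster.positions >= lo) & (cluster.positions <= hi)
    return replace(cluster, positions=cluster.positions[keep],
                   tpms=cluster.tpms[keep], trimmed=True)


def filter_supported_ctss(tables: dict[str, pd.DataFrame],
                          min_tpm: float = DEFAULT_MIN_CTSS_TPM,
                          ) -> dict[str, pd.DataFrame]:
    """Keep a CTSS key (in every sample) iff its tpm reaches ``min_tpm`` in
    at least one sample."""
    if min_tpm <= 0:
        return {s: t.copy() for s, t in tables.items()}
    key_cols = ["chrom", "pos", "strand"]
    supported = pd.concat(
        [t.loc[t["tpm"] >= min_tpm, key_cols] for t in tables.values()],
        ignore_index=True).drop_duplicates()
    out = {}
    for sample, t in tables.items():
        merged = t.merge(supported, on=key_cols, how="inner")
        out[sample] = merged.sort_values(key_cols, ignore_index=True)
    return out


def call_tag_clusters(table: pd.DataFrame, sample_id: str = "sample",
                      max_gap: int = DEFAULT_MAX_GAP,
                      min_cluster_tpm: float = DEFAULT_MIN_CLUSTER_TPM,
                      trim: bool = True) -> list[TagCluster]:
    """Chain same-strand CTSSs into clusters, trim, and drop weak clusters.

    Neighbouring CTSSs are joined while their position difference is at most
    ``max_gap`` (inclusive). After trimming (skipped when ``trim=False``),
    clusters whose total tpm does not exceed ``min_cluster_tpm`` (strict)
    are discarded.
    """
    clusters: list[TagCluster] = []
    for (chrom, strand), grp in table.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        tpm = grp["tpm"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for p, t in zip(np.split(pos, breaks), np.split(tpm, breaks)):
            tc = TagCluster(sample_id, chrom, strand, p, t)
            if trim:
                tc = trim_cluster(tc)
            if tc.total_tpm > min_cluster_tpm:
                clusters.append(tc)
    return clusters


def tag_clusters_frame(clusters: list[TagCluster]) -> pd.DataFrame:
    """Flatten TagCluster objects into the TC summary table."""
    rows = [{
        "sample_id": tc.sample_id, "chrom": tc.chrom, "strand": tc.strand,
        "start": tc.start, "end": tc.end, "n_ctss": len(tc.positions),
        "total_tpm": tc.total_tpm, "dominant_pos": tc.dominant_pos,
        "dominant_tpm": tc.dominant_tpm, "q_low": tc.q_low,
        "q_high": tc.q_high, "iq_width": tc.iq_width,
    } for tc in clusters]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Consensus clusters
# ---------------------------------------------------------------------------

def merge_intervals(starts: np.ndarray, ends: np.ndarray,
                    max_gap: int) -> list[tuple[int, int]]:
    """Transitive merge of 1-based inclusive intervals whose end-to-start
    gap is at most ``max_gap``."""
    order = np.argsort(starts, kind="stable")
    merged: list[list[int]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    return [(s, e) for s, e in merged]


def build_consensus_clusters(tc_sets: dict[str, list[TagCluster]],
                             ctss_tables: dict[str, pd.DataFrame],
                             max_cc_gap: int = DEFAULT_MAX_CC_GAP,
                             ) -> pd.DataFrame:
    """Aggregate per-sample tag clusters into consensus clusters.

    Returns a wide CC table: one row per CC with span columns plus, per
    sample ``s``: ``tpm_s`` and ``count_s`` (sums over the sample's CTSSs
    inside the span; 0 when absent), ``dom_s``, ``iqw_s`` and ``domfrac_s``
    (NaN when the sample has no expression in the span). Pooled columns
    (``dominant_pos``, ``iq_width``, ``dominant_frac``, ``total_tpm``) are
    computed on the sample-summed CTSS profile.
    """
    samples = list(ctss_tables)
    # 1. consensus spans from TC spans, per (chrom, strand)
    span_rows = []
    for tcs in tc_sets.values():
        for tc in tcs:
            span_rows.append((tc.chrom, tc.strand, tc.start, tc.end))
    if not span_rows:
        return pd.DataFrame()
    spans = pd.DataFrame(span_rows, columns=["chrom", "strand", "start", "end"])
    cc_rows = []
    for (chrom, strand), grp in spans.groupby(["chrom", "strand"], sort=True):
        for s, e in merge_intervals(grp["start"].to_numpy(),
                                    grp["end"].to_numpy(), max_cc_gap):
            cc_rows.append((chrom, strand, s, e))
    ccs = pd.DataFrame(cc_rows, columns=["chrom", "strand", "start", "end"])
    ccs = ccs.sort_values(["chrom", "start", "strand"], ignore_index=True)
    ccs.insert(0, "cc_id", [f"cc_{i:06d}" for i in range(len(ccs))])

    # 2. assign every sample CTSS to its CC (if any) and aggregate
    assigned = []
    for sample in samples:
        t = ctss_tables[sample]
        idx = _assign_to_spans(t, ccs)
        sub = t.loc[idx >= 0, ["chrom", "pos", "strand", "count", "tpm"]].copy()
        sub["cc_idx"] = idx[idx >= 0]
        sub["sample"] = sample
        assigned.append(sub)
    members = pd.concat(assigned, ignore_index=True)

    for sample in samples:
        sub = members[members["sample"] == sample]
        stats = _profile_stats(sub, ccs)
        ccs[f"tpm_{sample}"] = stats["tpm"].reindex(ccs.index).fillna(0.0)
        ccs[f"count_{sample}"] = (stats["count"].reindex(ccs.index)
                                  .fillna(0).astype(np.int64))
        ccs[f"dom_{sample}"] = stats["dom"].reindex(ccs.index)
        ccs[f"iqw_{sample}"] = stats["iqw"].reindex(ccs.index)
        ccs[f"domfrac_{sample}"] = stats["domfrac"].reindex(ccs.index)

    pooled = (members.groupby(["cc_idx", "chrom", "pos", "strand"],
                              as_index=False)
              .agg(tpm=("tpm", "sum"), count=("count", "sum")))
    pstats = _profile_stats(pooled.assign(sample="pooled"), ccs)
    ccs["total_tpm"] = pstats["tpm"].reindex(ccs.index).fillna(0.0)
    ccs["dominant_pos"] = pstats["dom"].reindex(ccs.index)
    ccs["iq_width"] = pstats["iqw"].reindex(ccs.index)
    ccs["dominant_frac"] = pstats["domfrac"].reindex(ccs.index)

    # which samples contributed a called TC to each CC ("shared" CCs are
    # those supported by a tag cluster in every sample)
    for sample, tcs in tc_sets.items():
        support = np.zeros(len(ccs), dtype=bool)
        if tcs:
            tc_frame = pd.DataFrame({
                "chrom": [tc.chrom for tc in tcs],
                "pos": [tc.start for tc in tcs],
                "strand": [tc.strand for tc in tcs]})
            idx = _assign_to_spans(tc_frame, ccs)
            support[idx[idx >= 0]] = True
        ccs[f"tc_support_{sample}"] = support
    support_cols = [f"tc_support_{s}" for s in tc_sets]
    ccs["n_tc_samples"] = ccs[support_cols].sum(axis=1)
    return ccs


def _assign_to_spans(table: pd.DataFrame, ccs: pd.DataFrame) -> np.ndarray:
    """Index of the CC whose span contains each CTSS, or -1. Spans on one
    (chrom, strand) never overlap, so binary search suffices."""
    result = np.full(len(table), -1, dtype=np.int64)
    tkeys = table.groupby(["chrom", "strand"]).indices
    ckeys = ccs.groupby(["chrom", "strand"]).indices
    for key, t_idx in tkeys.items():
        if key not in ckeys:
            continue
        c_idx = ckeys[key]
        starts = ccs["start"].to_numpy()[c_idx]
        ends = ccs["end"].to_numpy()[c_idx]
        order = np.argsort(starts)
        starts, ends, c_idx = starts[order], ends[order], c_idx[order]
        pos = table["pos"].to_numpy()[t_idx]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos <= ends[np.clip(j, 0, None)])
        result[t_idx[ok]] = c_idx[j[ok]]
    return result


def _profile_stats(members: pd.DataFrame, ccs: pd.DataFrame) -> dict[str, pd.Series]:
    """Per-CC totals, dominant position, interquantile width and dominant
    fraction from one sample's (or the pooled) CTSS profile."""
    if members.empty:
        empty = pd.Series(dtype=float)
        return {k: empty for k in ("tpm", "count", "dom", "iqw", "domfrac")}
    m = members.sort_values(["cc_idx", "pos"], kind="stable")
    g = m.groupby("cc_idx")
    tpm_sum = g["tpm"].sum()
    count_sum = g["count"].sum()
    # dominant: max tpm, ties to the most 5' position on the strand
    strands = ccs["strand"]
    m2 = m.assign(rank_pos=np.where(
        strands.reindex(m["cc_idx"]).to_numpy() == "+",
        m["pos"].to_numpy(), -m["pos"].to_numpy()))
    m2 = m2.sort_values(["cc_idx", "tpm", "rank_pos"],
                        ascending=[True, False, True], kind="stable")
    dom_rows = m2.drop_duplicates("cc_idx").set_index("cc_idx")
    dom = dom_rows["pos"].astype(float)
    domfrac = dom_rows["tpm"] / tpm_sum
    # interquantile bounds on the genomic-order cumulative profile
    cum = g["tpm"].cumsum()
    total = g["tpm"].transform("sum")
    lo_mask = cum >= QUANTILES[0] * total
    hi_mask = cum >= QUANTILES[1] * total
    q_low = m.loc[lo_mask].groupby("cc_idx")["pos"].first()
    q_high = m.loc[hi_mask].groupby("cc_idx")["pos"].first()
    iqw = (q_high - q_low + 1).astype(float)
    return {"tpm": tpm_sum, "count": count_sum, "dom": dom,
            "iqw": iqw, "domfrac": domfrac}


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate_cc(ccs: pd.DataFrame, annotation: pd.DataFrame,
                promoter_window: int = 1000) -> pd.DataFrame:
    """Assign each CC to the nearest annotated TSS on its strand and label
    its genomic feature class.

    Distance is from the CC's pooled dominant position to the gene TSS,
    signed in the transcription direction (negative = upstream). Feature
    precedence: Promoter(<=1kb) > 5'UTR > Exon > Intron > 3'UTR >
    Promoter(1-3kb) > Downstream(<3kb) > Distal intergenic. ``promoter_set``
    flags CCs in Promoter(<=1kb) or 5'UTR — the promoter-proximal set kept
    for downstream analyses.
    """
    out = ccs.copy()
    gene_ids, distances, features = [], [], []
    if annotation is None or len(annotation) == 0:
        import warnings
        warnings.warn("empty annotation: all CCs classified as distal")
        out["gene_id"] = None
        out["tss_distance"] = np.nan
        out["feature"] = "Distal intergenic"
        out["promoter_set"] = False
        return out
    ann_by_key = dict(tuple(annotation.groupby(["chrom", "strand"])))
    for _, cc in out.iterrows():
        genes = ann_by_key.get((cc["chrom"], cc["strand"]))
        dom = cc["dominant_pos"]
        if genes is None or np.isnan(dom):
            gene_ids.append(None)
            distances.append(np.nan)
            features.append("Distal intergenic")
            continue
        dom = int(dom)
        sign = 1 if cc["strand"] == "+" else -1
        d = sign * (dom - genes["tss"].to_numpy())
        k = int(np.abs(d).argmin())
        gene = genes.iloc[k]
        dist = int(d[k])
        gene_ids.append(gene["gene_id"])
        distances.append(dist)
        features.append(_feature_class(dom, dist, gene, promoter_window))
    out["gene_id"] = gene_ids
    out["tss_distance"] = distances
    out["feature"] = features
    out["promoter_set"] = out["feature"].isin(PROMOTER_SET_FEATURES)
    return out


def _in_interval(pos: int, start, end) -> bool:
    """1-based point inside a 0-based half-open interval."""
    return start <= pos - 1 < end


def _feature_class(dom: int, dist: int, gene: pd.Series,
                   promoter_window: int) -> str:
    if -promoter_window <= dist <= 0:
        return "Promoter(<=1kb)"
    if _in_interval(dom, gene["utr5_start"], gene["utr5_end"]):
        return "5'UTR"
    if any(_in_interval(dom, a, b)
           for a, b in parse_exon_blocks(gene["exon_blocks"])):
        return "Exon"
    in_gene = _in_interval(dom, gene["gene_start"], gene["gene_end"])
    in_utr3 = _in_interval(dom, gene["utr3_start"], gene["utr3_end"])
    if in_gene and not in_utr3:
        return "Intron"
    if in_utr3:
        return "3'UTR"
    if -3000 <= dist < -promoter_window:
        return "Promoter(1-3kb)"
    sign = 1 if gene["strand"] == "+" else -1
    past_end = (dom - gene["gene_end"]) if sign == 1 else (gene["gene_start"] + 1 - dom)
    if 0 <= past_end < 3000:
        return "Downstream(<3kb)"
    return "Distal intergenic"


def reduce_to_representative(ccs: pd.DataFrame,
                             tpm_cols: list[str] | None = None) -> pd.DataFrame:
    """When several CCs map to one gene, keep the highest-expressed CC
    (summed tpm across samples) as the gene's representative."""
    if tpm_cols is None:
        tpm_cols = [c for c in ccs.columns if c.startswith("tpm_")]
    ranked = ccs.assign(_rank=ccs[tpm_cols].sum(axis=1))
    ranked = ranked.sort_values("_rank", ascending=False, kind="stable")
    keep_mask = ~ranked.duplicated("gene_id") | ranked["gene_id"].isna()
    out = ranked[keep_mask].drop(columns="_rank")
    return out.sort_index()
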