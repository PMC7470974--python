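"""Core-promoter motif scanning and group-wise enrichment statistics.

Promoter windows (120 bp upstream to 50 bp downstream of the dominant TSS,
strand-oriented) are scanned on the sense strand with position weight
matrices. Scores are log2-odds against a uniform background, expressed as a
*match percent*: 100 * (score - min) / (max - min) where min/max are the
PWM's attainable extremes, so 100% is the consensus and the conventional
"90% match" hit threshold is scale-free. Motif occurrence is scored as
presence/absence per promoter and compared between gene groups and a
background group with two-sided Fisher's exact tests; effect size is the
log2 odds ratio (Haldane 0.5 correction when a cell is empty).
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BASES, PWMModel, PromoterWindow

DEFAULT_HIT_PERCENT = 90.0
DEFAULT_P_THRESHOLD = 0.01
TATA_REGION = (-40, -20)
W_PENTAMERS = ["".join(p) for p in product("AT", repeat=5)]

_ENCODE = np.full(128, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def pwm_match_percent(pwm: PWMModel, window: PromoterWindow
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Match percent at every offset where the full motif fits the window.

    Returns (motif-start offsets, match percents). Only the sense strand of
    the transcript is scanned. Ambiguous bases score the per-position
    minimum (conservative).
    """
    span = pwm.max_score - pwm.min_score
    if span <= 0:
        raise ValueError(f"degenerate PWM {pwm.name}: max score equals min score")
    L = len(pwm)
    codes = _encode(window.seq)
    n = len(codes) - L + 1
    if n <= 0:
        return (np.empty(0, dtype=int), np.empty(0))
    lo = np.column_stack([pwm.log_odds, pwm.log_odds.min(axis=1)])
    idx = codes[np.arange(n)[:, None] + np.arange(L)[None, :]]
    scores = lo[np.arange(L)[None, :], idx].sum(axis=1)
    offsets = window.offset_start + np.arange(n)
    return offsets, 100.0 * (scores - pwm.min_score) / span


def best_match(pwm: PWMModel, window: PromoterWindow,
               region: tuple[int, int] | None = None
               ) -> tuple[float, int | None]:
    """Best match percent (and its offset) optionally restricted to motif
    start offsets inside the inclusive ``region``."""
    offsets, percents = pwm_match_percent(pwm, window)
    if region is not None:
        keep = (offsets >= region[0]) & (offsets <= region[1])
        offsets, percents = offsets[keep], percents[keep]
    if len(percents) == 0:
        return float("nan"), None
    k = int(percents.argmax())
    return float(percents[k]), int(offsets[k])


def motif_hit_table(pwms: list[PWMModel],
                    windows: dict[str, PromoterWindow],
                    hit_percent: float = DEFAULT_HIT_PERCENT,
                    region: tuple[int, int] | None = None) -> pd.DataFrame:
    """Scan every promoter window with every PWM.

    One row per (cc_id, motif): best match percent, its offset, all hit
    offsets at the threshold (comma-joined), and the presence/absence flag
    used for enrichment.
    """
    rows = []
    for cc_id, window in windows.items():
        for pwm in pwms:
            offsets, percents = pwm_match_percent(pwm, window)
            if region is not None:
                keep = (offsets >= region[0]) & (offsets <= region[1])
                offsets, percents = offsets[keep], percents[keep]
            if len(percents):
                k = int(percents.argmax())
                best, best_off = float(percents[k]), int(offsets[k])
                hits = offsets[percents >= hit_percent]
            else:
                best, best_off, hits = float("nan"), None, []
            rows.append({
                "cc_id": cc_id, "motif": pwm.name,
                "best_percent": best, "best_offset": best_off,
                "hit_offsets": ",".join(str(int(o)) for o in hits),
                "is_hit": bool(len(hits)),
            })
    return pd.DataFrame(rows)


def log2_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """log2[(a/b)/(c/d)] with Haldane 0.5 added to all cells if any is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(np.log2((a * d) / (b * c)))


def fisher_enrichment(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact p and log2 OR for table [[a, b], [c, d]]."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p), log2_odds_ratio(a, b, c, d)


def motif_group_enrichment(groups: pd.Series, hits: pd.DataFrame,
                           background_group: str,
                           p_threshold: float = DEFAULT_P_THRESHOLD
                           ) -> pd.DataFrame:
    """Fisher enrichment of each motif in each gene group vs the background.

    ``groups`` maps cc_id -> group label; each CC belongs to exactly one
    group. Hit means any offset at the match threshold (presence/absence).
    Adds a BH-adjusted column for convenience; the ``significant`` flag uses
    the raw p < ``p_threshold`` rule.
    """
    from .diffexp import bh_adjust

    import warnings
    h = hits.merge(groups.rename("group"), left_on="cc_id", right_index=True)
    rows = []
    bg = h[h["group"] == background_group]
    if bg.empty:
        raise ValueError(f"background group {background_group!r} is empty")
    for group in sorted(set(h["group"]) - {background_group}):
        sub = h[h["group"] == group]
        if sub.empty:
            warnings.warn(f"group {group!r} is empty; skipped")
            continue
        for motif, msub in sub.groupby("motif"):
            mbg = bg[bg["motif"] == motif]
            a = int(msub["is_hit"].sum())
            b = int(len(msub) - a)
            c = int(mbg["is_hit"].sum())
            d = int(len(mbg) - c)
            p, l2or = fisher_enrichment(a, b, c, d)
            rows.append({"motif": motif, "group": group,
                         "a": a, "b": b, "c": c, "d": d,
                         "log2_odds_ratio": l2or, "p_value": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
        out["significant"] = out["p_value"] < p_threshold
    return out


def enrichment_heatmap_matrix(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Motif x group matrix of log2 OR with significance stars appended to
    the group labels' values table (heatmap-ready TSV)."""
    if enrichment.empty:
        return pd.DataFrame()
    mat = enrichment.pivot(index="motif", columns="group",
                           values="log2_odds_ratio")
    stars = enrichment.assign(star=np.select(
        [enrichment["p_value"] < 0.001, enrichment["p_value"] < 0.01,
         enrichment["p_value"] < 0.05], ["***", "**", "*"], ""))
    star_mat = stars.pivot(index="motif", columns="group", values="star")
    return mat.round(4).astype(str) + star_mat.fillna("")


def tata_match_distribution(tata_pwm: PWMModel,
                            windows: dict[str, PromoterWindow],
                            region: tuple[int, int] = TATA_REGION,
                            bins: tuple[float, float] = (75.0, 90.0),
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Best TATA match percent per promoter within the upstream region
    (motif start offset in ``region``), plus the binned distribution
    (<75, 75-90, >90 by default)."""
    rows = []
    for cc_id, window in windows.items():
        best, off = best_match(tata_pwm, window, region=region)
        rows.append({"cc_id": cc_id, "best_percent": best, "best_offset": off})
    per_promoter = pd.DataFrame(rows)
    lo, hi = bins
    labels = [f"<{lo:g}", f"{lo:g}-{hi:g}", f">{hi:g}"]
    binned = pd.cut(per_promoter["best_percent"], [-np.inf, lo, hi, np.inf],
                    labels=labels)
    dist = (binned.value_counts().reindex(labels).rename("n_promoters")
            .rename_axis("match_bin").reset_index())
    return per_promoter, dist


def ww_dinucleotide_profile(windows: dict[str, PromoterWindow] | list[PromoterWindow]
                            ) -> pd.DataFrame:
    """Fraction of promoters whose bases at (offset, offset+1) are both A/T,
    per offset across the window."""
    if isinstance(windows, dict):
        windows = list(windows.values())
    ww_counts: dict[int, int] = {}
    totals: dict[int, int] = {}
    for w in windows:
        is_w = np.isin(_encode(w.seq), [0, 3])  # A or T
        ww = is_w[:-1] & is_w[1:]
        for j, flag in enumerate(ww):
            off = w.offset_start + j
            totals[off] = totals.get(off, 0) + 1
            ww_counts[off] = ww_counts.get(off, 0) + int(flag)
    offsets = sorted(totals)
    return pd.DataFrame({
        "offset": offsets,
        "ww_frequency": [ww_counts[o] / totals[o] for o in offsets],
        "n_windows": [totals[o] for o in offsets],
    })


def _pentamer_occurrences(window: PromoterWindow,
                          region: tuple[int, int]) -> dict[str, list[int]]:
    """Poly-W pentamers found with start offset inside ``region``."""
    found: dict[str, list[int]] = {}
    for off in range(region[0], region[1] + 1):
        i = off - window.offset_start
        if i < 0 or i + 5 > len(window.seq):
            continue
        pent = window.seq[i:i + 5]
        if set(pent) <= {"A", "T"}:
            found.setdefault(pent, []).append(off)
    return found


def polyw_pentamer_enrichment(groups: pd.Series,
                              windows: dict[str, PromoterWindow],
                              background_group: str,
                              tata_pwm: PWMModel | None = None,
                              region: tuple[int, int] = TATA_REGION,
                              hit_percent: float = DEFAULT_HIT_PERCENT,
                              ) -> pd.DataFrame:
    """Per poly-W pentamer (the 32 words over {A,T}^5): promoter occurrence
    counts per group, Fisher p vs the background group, and the fraction of
    occurrences overlapping a canonical (>= ``hit_percent``) TATA PWM hit —
    separating pentamers embedded in a real TATA-box from W-box-like words.
    """
    occ_rows = []
    for cc_id, window in windows.items():
        group = groups.get(cc_id)
        if group is None:
            continue
        tata_hits: list[tuple[int, int]] = []
        if tata_pwm is not None:
            offs, percents = pwm_match_percent(tata_pwm, window)
            tata_hits = [(int(o), int(o) + len(tata_pwm) - 1)
                         for o in offs[percents >= hit_percent]]
        for pent, starts in _pentamer_occurrences(window, region).items():
            overlap = any(s <= te and s + 4 >= ts
                          for s in starts for ts, te in tata_hits)
            occ_rows.append({"cc_id": cc_id, "group": group,
                             "pentamer": pent, "tata_overlap": overlap})
    occ = pd.DataFrame(occ_rows,
                       columns=["cc_id", "group", "pentamer", "tata_overlap"])
    group_sizes = groups.value_counts()
    n_bg = int(group_sizes.get(background_group, 0))
    if n_bg == 0:
        raise ValueError(f"background group {background_group!r} is empty")
    rows = []
    for group in sorted(set(groups) - {background_group}):
        n_grp = int(group_sizes[group])
        for pent in W_PENTAMERS:
            sub = occ[occ["pentamer"] == pent]
            a = sub[sub["group"] == group]["cc_id"].nunique()
            c = sub[sub["group"] == background_group]["cc_id"].nunique()
            b, d = n_grp - a, n_bg - c
            p, l2or = fisher_enrichment(a, b, c, d)
            n_overlap = int(sub[(sub["group"] == group)
                                & sub["tata_overlap"]]["cc_id"].nunique())
            rows.append({"pentamer": pent, "group": group,
                         "n_group_hit": a, "n_group": n_grp,
                         "n_background_hit": c, "n_background": n_bg,
                         "log2_odds_ratio": l2or, "p_value": p,
                         "n_tata_overlap": n_overlap})
    return pd.DataFrame(rows)
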