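"""Differential utilization of canonical vs alternative promoters.

Each gene carries a twinned pair of promoter regions (canonical and
alternative) with a TPM value per region per condition. Pairs expressed in
both conditions (TPM > 5 in either region, in each condition) are candidates
when the alternative promoter's expression *relative* to the canonical
(rel = alt/cano) changes at least two-fold between conditions. Candidates
are then segregated by which promoter moved: e.g. *canonical down* means the
canonical promoter lost more than half its expression in condition B while
the alternative stayed within 25% of its condition-A level.

Delta values are signed relative changes vs condition A (G1 in the original
design): d = (x_B - x_A) / x_A; "unchanged" means |d| < 0.25 (strict) and
"down"/"up" mean d <= -0.5 / d >= +0.5 (inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_MIN_TPM = 5.0
DEFAULT_REL_FOLD = 2.0
UNCHANGED_BOUND = 0.25
MOVED_BOUND = 0.5
PSEUDO_TPM = 0.5

GROUPS = ["canonical_down", "alternative_down", "canonical_up",
          "alternative_up", "discarded", "not_candidate"]

PAIR_COLUMNS = ["gene_id", "cano_a", "alt_a", "cano_b", "alt_b"]


def select_expressed_pairs(pairs: pd.DataFrame,
                           min_tpm: float = DEFAULT_MIN_TPM) -> pd.DataFrame:
    """Keep pairs with TPM > ``min_tpm`` in either region, in each condition."""
    keep = ((np.maximum(pairs["cano_a"], pairs["alt_a"]) > min_tpm)
            & (np.maximum(pairs["cano_b"], pairs["alt_b"]) > min_tpm))
    return pairs[keep].reset_index(drop=True)


def _delta(x_a: float, x_b: float) -> float:
    """Signed relative change of condition B vs condition A."""
    if x_a > 0:
        return (x_b - x_a) / x_a
    return 0.0 if x_b == 0 else np.inf


def _relative(alt: float, cano: float) -> tuple[float, bool]:
    """alt/cano with a 0.5 pseudo-TPM applied to both when cano is 0."""
    if cano == 0:
        return (alt + PSEUDO_TPM) / (cano + PSEUDO_TPM), True
    return alt / cano, False


def classify_alt_usage(cano_a: float, alt_a: float,
                       cano_b: float, alt_b: float,
                       rel_fold: float = DEFAULT_REL_FOLD,
                       unchanged_bound: float = UNCHANGED_BOUND,
                       moved_bound: float = MOVED_BOUND) -> dict:
    """Classify one expressed pair.

    Candidate iff the relative expression rel = alt/cano changes by at least
    ``rel_fold`` between conditions (either direction). Candidates fall into
    one of four groups by the signed relative changes of each promoter, or
    ``discarded`` when the pattern matches none.
    """
    rel_a, pseudo_a = _relative(alt_a, cano_a)
    rel_b, pseudo_b = _relative(alt_b, cano_b)
    if rel_a == 0 and rel_b == 0:
        fold = 1.0
    elif min(rel_a, rel_b) == 0:
        fold = np.inf
    else:
        fold = max(rel_a / rel_b, rel_b / rel_a)
    d_cano = _delta(cano_a, cano_b)
    d_alt = _delta(alt_a, alt_b)
    if fold < rel_fold:
        group = "not_candidate"
    elif d_cano <= -moved_bound and abs(d_alt) < unchanged_bound:
        group = "canonical_down"
    elif abs(d_cano) < unchanged_bound and d_alt <= -moved_bound:
        group = "alternative_down"
    elif d_cano >= moved_bound and abs(d_alt) < unchanged_bound:
        group = "canonical_up"
    elif abs(d_cano) < unchanged_bound and d_alt >= moved_bound:
        group = "alternative_up"
    else:
        group = "discarded"
    return {"rel_a": rel_a, "rel_b": rel_b, "rel_fold_change": fold,
            "delta_cano": d_cano, "delta_alt": d_alt,
            "used_pseudo_tpm": pseudo_a or pseudo_b, "group": group}


def classify_pairs(pairs: pd.DataFrame,
                   min_tpm: float = DEFAULT_MIN_TPM,
                   rel_fold: float = DEFAULT_REL_FOLD) -> pd.DataFrame:
    """Select expressed pairs and classify each; returns the call table with
    all intermediate quantities."""
    selected = select_expressed_pairs(pairs, min_tpm=min_tpm)
    rows = []
    for _, r in selected.iterrows():
        call = classify_alt_usage(r["cano_a"], r["alt_a"],
                                  r["cano_b"], r["alt_b"], rel_fold=rel_fold)
        rows.append({"gene_id": r["gene_id"], **r[PAIR_COLUMNS[1:]].to_dict(),
                     **call})
    return pd.DataFrame(rows)
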