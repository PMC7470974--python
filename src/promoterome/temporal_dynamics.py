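"""Monotone expression trends across three ordered developmental stages.

A consensus cluster expressed above ``min_tpm`` in at least one stage is
*gained* when expression rises more than ``fold``-fold at each sequential
step, *lost* when it falls more than ``fold``-fold at each step, and *none*
otherwise. A 0.5 pseudo-TPM is added to all three values before the ratio
tests whenever any stage is zero.
"""

from __future__ import annotations

import pandas as pd

DEFAULT_MIN_TPM = 5.0
DEFAULT_FOLD = 1.5
PSEUDO_TPM = 0.5

TRENDS = ["gained", "lost", "none"]


def classify_temporal(t1: float, t2: float, t3: float,
                      min_tpm: float = DEFAULT_MIN_TPM,
                      fold: float = DEFAULT_FOLD) -> str:
    """Trend of one tpm triple across the three ordered stages."""
    if min(t1, t2, t3) < 0:
        raise ValueError("tpm values must be non-negative")
    if max(t1, t2, t3) <= min_tpm:
        return "none"
    if min(t1, t2, t3) == 0:
        t1, t2, t3 = t1 + PSEUDO_TPM, t2 + PSEUDO_TPM, t3 + PSEUDO_TPM
    if t2 / t1 > fold and t3 / t2 > fold:
        return "gained"
    if t1 / t2 > fold and t2 / t3 > fold:
        return "lost"
    return "none"


def classify_table(tpm: pd.DataFrame, stage_cols: list[str] | None = None,
                   min_tpm: float = DEFAULT_MIN_TPM,
                   fold: float = DEFAULT_FOLD) -> pd.DataFrame:
    """Per-CC trend calls from a three-stage tpm table (index = cc_id)."""
    if stage_cols is None:
        stage_cols = list(tpm.columns[:3])
    if len(stage_cols) != 3:
        raise ValueError("exactly three ordered stage columns are required")
    out = tpm[stage_cols].copy()
    out["trend"] = [classify_temporal(a, b, c, min_tpm=min_tpm, fold=fold)
                    for a, b, c in out[stage_cols].to_numpy()]
    return out
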