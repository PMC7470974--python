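"""Promoter shape classes and between-condition shape transitions.

Shape is read off the TSS distribution within a consensus cluster: *sharp*
promoters concentrate initiation in a narrow window (interquantile width
below 10 bp), *peaked broad* promoters are wide but dominated by one TSS
carrying more than 60% of the expression, and *broad* promoters are the
rest. The default classifies sharp on width alone; ``strict_sharp=True``
additionally requires the >60% dominant fraction for the sharp class
(promoters failing it fall to broad when wide).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SHAPE_CLASSES = ["sharp", "peaked_broad", "broad"]
DEFAULT_SHARP_WIDTH = 10
DEFAULT_DOM_FRAC = 0.6
DEFAULT_MIN_TPM = 10.0


def classify_shape(iq_width: float, dominant_fraction: float,
                   sharp_width: float = DEFAULT_SHARP_WIDTH,
                   dom_frac: float = DEFAULT_DOM_FRAC,
                   strict_sharp: bool = False) -> str:
    """Classify one promoter.

    sharp: iq_width < sharp_width (with ``strict_sharp`` also
    dominant_fraction > dom_frac); peaked_broad: wide with
    dominant_fraction > dom_frac; broad: the rest. Boundaries: width exactly
    ``sharp_width`` is not sharp; fraction exactly ``dom_frac`` is not peaked.
    """
    if not (np.isfinite(iq_width) and np.isfinite(dominant_fraction)):
        raise ValueError("iq_width and dominant_fraction must be finite")
    if iq_width < sharp_width and (not strict_sharp
                                   or dominant_fraction > dom_frac):
        return "sharp"
    if dominant_fraction > dom_frac:
        return "peaked_broad"
    return "broad"


def shape_calls(ccs: pd.DataFrame, sample: str,
                sharp_width: float = DEFAULT_SHARP_WIDTH,
                dom_frac: float = DEFAULT_DOM_FRAC,
                strict_sharp: bool = False) -> pd.DataFrame:
    """Per-CC shape calls for one sample of a wide CC table
    (columns ``tpm_<sample>``, ``iqw_<sample>``, ``domfrac_<sample>``)."""
    out = pd.DataFrame({
        "cc_id": ccs["cc_id"],
        "sample_id": sample,
        "tpm": ccs[f"tpm_{sample}"],
        "iq_width": ccs[f"iqw_{sample}"],
        "dominant_fraction": ccs[f"domfrac_{sample}"],
    })
    expressed = out["tpm"] > 0
    out["shape_class"] = [
        classify_shape(w, f, sharp_width, dom_frac, strict_sharp)
        if ok else None
        for w, f, ok in zip(out["iq_width"], out["dominant_fraction"], expressed)]
    return out


def shape_transition_matrix(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                            min_tpm: float = DEFAULT_MIN_TPM,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """3x3 shape transition counts between two conditions.

    Restricted to CCs with tpm >= ``min_tpm`` in both conditions. Returns
    (matrix, per-CC long table); transitioning CCs are the off-diagonal rows.
    """
    a = calls_a.set_index("cc_id")
    b = calls_b.set_index("cc_id")
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    keep = (a["tpm"] >= min_tpm) & (b["tpm"] >= min_tpm)
    pairs = pd.DataFrame({
        "cc_id": shared[keep],
        "shape_a": a.loc[keep, "shape_class"].to_numpy(),
        "shape_b": b.loc[keep, "shape_class"].to_numpy(),
    })
    pairs["transitioning"] = pairs["shape_a"] != pairs["shape_b"]
    matrix = pd.DataFrame(0, index=SHAPE_CLASSES, columns=SHAPE_CLASSES)
    counts = pairs.groupby(["shape_a", "shape_b"]).size()
    for (sa, sb), n in counts.items():
        matrix.loc[sa, sb] = int(n)
    return matrix, pairs


def transition_long_format(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sankey-ready long table (source shape, target shape, count)."""
    rows = [(sa, sb, int(matrix.loc[sa, sb]))
            for sa in matrix.index for sb in matrix.columns]
    return pd.DataFrame(rows, columns=["source", "target", "count"])
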