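"""Power-law normalization of CAGE tag counts to tags-per-million (tpm).

CAGE CTSS count distributions follow an approximate power law: the reverse
cumulative frequency revcum(x) = #{CTSS with count >= x} is close to linear
in log10-log10 space. Libraries of different depth and slope are made
comparable by (1) fitting each sample's reverse cumulative with ordinary
least squares over a mid-range of counts and (2) monotonically mapping raw
counts onto a reference power law with exponent ``alpha_ref`` whose implied
total tag count equals ``total_ref`` (one million, hence "tags per million").

With the sample fit revcum(x) = 10^b * x^s and the reference law
revcum_ref(y) = beta * y^(-alpha_ref), a raw count x maps to the tpm value y
at the same reverse-cumulative rank:

    tpm(x) = (10^b * x^s / beta) ** (-1 / alpha_ref)

The reference intercept beta is fixed by the library-size constraint: under
the continuous law the total tag count is integral_1^inf y d(-revcum) =
beta * alpha / (alpha - 1), so beta = total_ref * (alpha_ref - 1) / alpha_ref.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from functools import reduce

import numpy as np
import pandas as pd

DEFAULT_ALPHA = 1.05
DEFAULT_TOTAL = 1e6
DEFAULT_FIT_RANGE = (5, 1000)
MIN_DISTINCT = 10


@dataclass
class PowerLawModel:
    """Fitted sample power law plus the reference law it is mapped onto."""

    alpha_ref: float = DEFAULT_ALPHA
    total_ref: float = DEFAULT_TOTAL
    fit_range: tuple[int, int] = DEFAULT_FIT_RANGE
    fitted_slope: float | None = None
    fitted_intercept: float | None = None

    def __post_init__(self):
        lo, hi = self.fit_range
        if lo < 1 or lo >= hi:
            raise ValueError(f"invalid fit_range {self.fit_range}")
        if self.alpha_ref <= 0 or self.total_ref <= 0:
            raise ValueError("alpha_ref and total_ref must be positive")

    @property
    def beta(self) -> float:
        """Reference-law intercept implied by the total-tag constraint."""
        return self.total_ref * (self.alpha_ref - 1) / self.alpha_ref

    @property
    def fitted(self) -> bool:
        return self.fitted_slope is not None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PowerLawModel":
        with open(path) as fh:
            d = json.load(fh)
        d["fit_range"] = tuple(d["fit_range"])
        return cls(**d)


def reverse_cumulative(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct count values x (ascending) and revcum(x) = #{counts >= x}."""
    counts = np.asarray(counts)
    values, freq = np.unique(counts, return_counts=True)
    revcum = freq[::-1].cumsum()[::-1]
    return values, revcum


def fit_power_law(counts, fit_range: tuple[int, int] = DEFAULT_FIT_RANGE,
                  alpha_ref: float = DEFAULT_ALPHA,
                  total_ref: float = DEFAULT_TOTAL) -> PowerLawModel:
    """OLS fit of log10 revcum vs log10 count over distinct counts in range.

    One regression point per distinct observed count value. Raises if fewer
    than ten distinct values fall inside ``fit_range``.
    """
    model = PowerLawModel(alpha_ref=alpha_ref, total_ref=total_ref,
                          fit_range=tuple(fit_range))
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("no positive counts to fit")
    values, revcum = reverse_cumulative(counts)
    lo, hi = model.fit_range
    sel = (values >= lo) & (values <= hi)
    if sel.sum() < MIN_DISTINCT:
        raise ValueError(
            f"only {int(sel.sum())} distinct count values in fit_range "
            f"{model.fit_range}; widen the range (need >= {MIN_DISTINCT})")
    x = np.log10(values[sel].astype(float))
    y = np.log10(revcum[sel].astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    model.fitted_slope = float(slope)
    model.fitted_intercept = float(intercept)
    return model


def tpm_of_count(x, model: PowerLawModel):
    """Map raw counts through the fitted sample law onto the reference law."""
    if not model.fitted:
        raise ValueError("power-law model is not fitted")
    x = np.asarray(x, dtype=float)
    log_revcum = model.fitted_intercept + model.fitted_slope * np.log10(x)
    return (10.0 ** log_revcum / model.beta) ** (-1.0 / model.alpha_ref)


def normalize_to_tpm(table: pd.DataFrame, model: PowerLawModel) -> pd.DataFrame:
    """Return a copy of a CTSS table with a ``tpm`` column appended.

    The mapping is strictly increasing in the raw count, so ranks are
    preserved exactly and equal counts share one tpm value.
    """
    out = table.copy()
    out["tpm"] = np.where(out["count"].to_numpy() > 0,
                          tpm_of_count(np.maximum(out["count"].to_numpy(), 1),
                                       model),
                          0.0)
    return out


def normalize_sample(table: pd.DataFrame,
                     fit_range: tuple[int, int] = DEFAULT_FIT_RANGE,
                     alpha_ref: float = DEFAULT_ALPHA,
                     total_ref: float = DEFAULT_TOTAL,
                     ) -> tuple[pd.DataFrame, PowerLawModel]:
    """Fit this sample's power law and normalize it in one step."""
    model = fit_power_law(table["count"].to_numpy(), fit_range=fit_range,
                          alpha_ref=alpha_ref, total_ref=total_ref)
    return normalize_to_tpm(table, model), model


def merge_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum raw counts per (chrom, pos, strand) across biological replicates.

    Replicates are merged on raw tags before one joint normalization, which
    keeps tpm well-defined for the merged sample.
    """
    if not tables:
        raise ValueError("no replicate tables given")
    merged = reduce(
        lambda a, b: pd.concat([a, b], ignore_index=True),
        [t[["chrom", "pos", "strand", "count"]] for t in tables])
    out = (merged.groupby(["chrom", "pos", "strand"], as_index=False)["count"]
           .sum())
    return out.sort_values(["chrom", "pos", "strand"], ignore_index=True)
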