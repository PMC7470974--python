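"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
CTSS positions are 1-based single-base points on a named strand, the native
convention of CAGE tag counting. Interval fields in annotation tables are
half-open ``[start, end)`` in 0-based coordinates (BED-like). Exported BED
records are converted accordingly.

A CTSS table is a :class:`pandas.DataFrame` with columns ``chrom`` (str),
``pos`` (int, >= 1), ``strand`` (``+``/``-``), ``count`` (int, >= 0) and,
after normalization, ``tpm`` (float). ``(chrom, pos, strand)`` is unique
within one sample.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CTSS_COLUMNS = ["chrom", "pos", "strand", "count"]
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# CTSS tables
# ---------------------------------------------------------------------------

def read_ctss(path, has_header: bool | None = None) -> pd.DataFrame:
    """Read a CTSS TSV (chrom, pos, strand, count) into a validated table.

    ``has_header=None`` sniffs the first line; duplicate (chrom, pos, strand)
    keys and negative counts are errors. Rows are returned sorted by
    (chrom, pos, strand).
    """
    with open(path) as fh:
        text = fh.read()
    if text.strip() == "":
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                             zip(CTSS_COLUMNS, [str, np.int64, str, np.int64])})
    first = text.splitlines()[0]
    if has_header is None:
        has_header = first.split("\t")[:2] == ["chrom", "pos"]
    raw = pd.read_csv(
        io.StringIO(text), sep="\t", header=0 if has_header else None,
        names=CTSS_COLUMNS, dtype=str, comment="#", skip_blank_lines=True,
    )
    offset = 2 if has_header else 1
    if raw.shape[1] != 4 or raw[["chrom", "pos", "strand", "count"]].isna().any().any():
        bad = int(raw.isna().any(axis=1).idxmax()) if raw.isna().any().any() else 0
        raise ParseError(f"{path}: malformed CTSS line {bad + offset}")
    for col in ("pos", "count"):
        converted = pd.to_numeric(raw[col], errors="coerce")
        if converted.isna().any():
            bad = int(converted.isna().idxmax())
            raise ParseError(f"{path}: non-integer {col!r} at line {bad + offset}")
        raw[col] = converted.astype(np.int64)
    table = raw
    _validate_ctss(table, origin=str(path))
    return table.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def _validate_ctss(table: pd.DataFrame, origin: str = "CTSS table") -> None:
    if (table["pos"] < 1).any():
        raise ParseError(f"{origin}: CTSS positions must be >= 1")
    if (table["count"] < 0).any():
        raise ParseError(f"{origin}: negative tag count")
    bad_strand = ~table["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ParseError(f"{origin}: strand must be '+' or '-'")
    if table.duplicated(["chrom", "pos", "strand"]).any():
        dup = table[table.duplicated(["chrom", "pos", "strand"])].iloc[0]
        raise ParseError(
            f"{origin}: duplicate CTSS key ({dup.chrom},{dup.pos},{dup.strand})")


def write_ctss(table: pd.DataFrame, path) -> None:
    """Write a CTSS table (with any extra columns, e.g. tpm) as headered TSV."""
    out = table.sort_values(["chrom", "pos", "strand"], ignore_index=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Position frequency/weight matrices
# ---------------------------------------------------------------------------

@dataclass
class PWMModel:
    """Position frequency matrix with log-odds scoring.

    ``matrix`` is (length, 4) of per-position base frequencies in ACGT order,
    column-normalized after pseudocount regularization. Scores are log2-odds
    against a uniform 0.25 background; ``match_percent`` semantics (min-max
    scaled score) live in :mod:`promoterome.motif_enrichment`.
    """

    name: str
    matrix: np.ndarray
    pseudocount: float = 0.8
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.name}: matrix must be (L, 4)")
        if len(self.matrix) < 2:
            raise ValueError(f"PWM {self.name}: length must be >= 2")
        if not np.allclose(self.matrix.sum(axis=1), 1.0):
            raise ValueError(f"PWM {self.name}: rows must sum to 1")

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray,
                    pseudocount: float = 0.8) -> "PWMModel":
        """Build from a (L, 4) count matrix, spreading ``pseudocount`` over
        the four bases by the uniform background before normalizing."""
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError(f"PWM {name}: counts must be (L, 4)")
        if (counts.sum(axis=1) == 0).any():
            raise ParseError(f"PWM {name}: column with all-zero counts")
        if (counts < 0).any():
            raise ParseError(f"PWM {name}: negative count")
        reg = counts + pseudocount * 0.25
        return cls(name, reg / reg.sum(axis=1, keepdims=True), pseudocount)

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


def read_pwm_jaspar(path, pseudocount: float = 0.8) -> list[PWMModel]:
    """Read one or more JASPAR-text PFMs (">ID NAME" header, 4 labelled base
    rows of counts) into frequency models."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    records: list[tuple[str, dict[str, list[float]]]] = []
    current: dict[str, list[float]] | None = None
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith(">"):
            header = line[1:].strip()
            name = header.split()[-1] if header else f"motif{len(records) + 1}"
            current = {}
            records.append((name, current))
            continue
        if current is None:
            raise ParseError(f"{path}:{lineno}: counts before '>' header")
        parts = line.replace("[", " ").replace("]", " ").split()
        if not parts or parts[0].upper() not in _BASE_INDEX:
            raise ParseError(f"{path}:{lineno}: expected base-labelled row")
        base = parts[0].upper()
        try:
            values = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric count") from exc
        if base in current:
            raise ParseError(f"{path}:{lineno}: duplicate {base} row")
        current[base] = values
    models = []
    for name, rows in records:
        if sorted(rows) != list("ACGT"):
            raise ParseError(
                f"{path}: motif {name}: need exactly A/C/G/T rows, got {sorted(rows)}")
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise ParseError(f"{path}: motif {name}: base rows of unequal length")
        counts = np.column_stack([rows[b] for b in BASES])
        models.append(PWMModel.from_counts(name, counts, pseudocount))
    return models


def write_pwm_jaspar(models: list[PWMModel], path, scale: float = 100.0) -> None:
    """Write frequency models back out as JASPAR-text count matrices."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.name} {m.name}\n")
            counts = m.matrix * scale
            for i, base in enumerate(BASES):
                row = " ".join(f"{v:.2f}" for v in counts[:, i])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Genome windows
# ---------------------------------------------------------------------------

@dataclass
class PromoterWindow:
    """Strand-oriented promoter sequence anchored on the dominant TSS.

    ``seq[i]`` is the base at offset ``offset_start + i`` where offset 0 is
    the dominant TSS and negative offsets are upstream (5') on the
    transcribed strand. ``clipped_*`` record truncation at chromosome ends.
    """

    seq: str
    offset_start: int
    chrom: str
    dominant_pos: int
    strand: str
    clipped_upstream: bool = False
    clipped_downstream: bool = False

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.offset_start, self.offset_start + len(self.seq))

    def base_at(self, offset: int) -> str:
        return self.seq[offset - self.offset_start]


def extract_promoter_window(genome, chrom: str, dominant_pos: int, strand: str,
                            up: int = 120, down: int = 50) -> PromoterWindow:
    """Extract the strand-oriented sequence from ``up`` bp 5' to ``down`` bp
    3' of a dominant TSS, clipping at chromosome ends.

    ``genome`` is a :class:`pyfaidx.Fasta` (or any mapping of chrom ->
    sequence-like supporting ``len`` and slicing with 0-based indices).
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome")
    record = genome[chrom]
    chrom_len = len(record)
    if not 1 <= dominant_pos <= chrom_len:
        raise ValueError(f"position {dominant_pos} outside {chrom} (len {chrom_len})")
    if strand == "+":
        avail_up = min(up, dominant_pos - 1)
        avail_down = min(down, chrom_len - dominant_pos)
        lo = dominant_pos - avail_up  # 1-based inclusive
        hi = dominant_pos + avail_down
        seq = str(record[lo - 1:hi]).upper()
    elif strand == "-":
        avail_up = min(up, chrom_len - dominant_pos)
        avail_down = min(down, dominant_pos - 1)
        lo = dominant_pos - avail_down
        hi = dominant_pos + avail_up
        seq = reverse_complement(str(record[lo - 1:hi]).upper())
    else:
        raise ValueError(f"invalid strand {strand!r}")
    return PromoterWindow(
        seq=seq, offset_start=-avail_up, chrom=chrom,
        dominant_pos=dominant_pos, strand=strand,
        clipped_upstream=avail_up < up, clipped_downstream=avail_down < down)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "gene_id", "chrom", "strand", "tss", "gene_start", "gene_end",
    "utr5_start", "utr5_end", "utr3_start", "utr3_end", "exon_blocks",
]


def read_annotation(path) -> pd.DataFrame:
    """Read a gene-annotation TSV.

    Columns: gene_id, chrom, strand, tss (1-based), then half-open 0-based
    intervals gene_start/gene_end, utr5_*, utr3_*, and ``exon_blocks`` as a
    comma-separated list of ``start-end`` spans.
    """
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ParseError(f"{path}: annotation missing columns {missing}")
    for _, row in ann.iterrows():
        for a, b in (("gene_start", "gene_end"), ("utr5_start", "utr5_end"),
                     ("utr3_start", "utr3_end")):
            if row[b] < row[a]:
                raise ParseError(f"{path}: negative-length interval for {row.gene_id}")
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def parse_exon_blocks(blocks: str) -> list[tuple[int, int]]:
    if not isinstance(blocks, str) or not blocks.strip():
        return []
    out = []
    for span in blocks.split(","):
        a, b = span.split("-")
        out.append((int(a), int(b)))
    return out


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------

def clusters_to_bed(df: pd.DataFrame, path, name_col: str = "cc_id",
                    score_col: str | None = None) -> None:
    """Export cluster spans (1-based inclusive start/end columns) as BED6."""
    score = df[score_col] if score_col else 0
    bed = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(int) - 1,
        "end": df["end"].astype(int),
        "name": df[name_col],
        "score": score,
        "strand": df["strand"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)
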