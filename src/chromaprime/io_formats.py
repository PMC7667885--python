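"""Readers and writers for the BED/TSV dialects the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention).  Summits
and cut sites are single-base features stored as 1-bp BED intervals
(``end == pos + 1``).  Chromosome names are matched as exact strings; no
"chr" aliasing is performed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from chromaprime.errors import DuplicateKey, MalformedRecord, UnwritablePath

__all__ = [
    "GenomicInterval",
    "SummitRecord",
    "CutSite",
    "TssRecord",
    "ExpressionTable",
    "read_intervals",
    "write_intervals",
    "read_expression",
    "read_tss",
    "write_tss",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval (BED record)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise MalformedRecord("empty chromosome name")
        if self.start < 0:
            raise MalformedRecord(f"negative start {self.start}")
        if self.end <= self.start:
            raise MalformedRecord(f"end {self.end} <= start {self.start}")
        if self.score is not None and self.score < 0:
            raise MalformedRecord(f"negative score {self.score}")
        if self.strand not in _STRANDS:
            raise MalformedRecord(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SummitRecord:
    """A single-base peak summit with its peak score."""

    chrom: str
    pos: int
    score: float = 0.0
    sample_id: str = ""

    def __post_init__(self):
        if not self.chrom:
            raise MalformedRecord("empty chromosome name")
        if self.pos < 0:
            raise MalformedRecord(f"negative summit position {self.pos}")


@dataclass(frozen=True)
class CutSite:
    """A single DNase cleavage / transposition event position (strandless)."""

    chrom: str
    pos: int

    def __post_init__(self):
        if not self.chrom:
            raise MalformedRecord("empty chromosome name")
        if self.pos < 0:
            raise MalformedRecord(f"negative cut position {self.pos}")


@dataclass(frozen=True)
class TssRecord:
    """A gene transcription start site (0-based point, stranded)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self):
        if not self.gene_id:
            raise MalformedRecord("empty gene_id")
        if self.tss < 0:
            raise MalformedRecord(f"negative TSS position {self.tss}")
        if self.strand not in _STRANDS:
            raise MalformedRecord(f"invalid strand {self.strand!r}")


class ExpressionTable:
    """Gene × sample TPM table with an optional sample→condition mapping.

    Parameters
    ----------
    tpm :
        DataFrame indexed by ``gene_id`` with one numeric column per sample.
        All values must be non-negative.
    sample_conditions :
        Optional mapping ``sample label -> condition label``.
    """

    def __init__(self, tpm: pd.DataFrame, sample_conditions: dict[str, str] | None = None):
        if tpm.index.has_duplicates:
            dups = tpm.index[tpm.index.duplicated()].unique().tolist()
            raise DuplicateKey(f"duplicate gene_id rows: {dups}")
        if tpm.columns.has_duplicates:
            raise DuplicateKey("duplicate sample columns")
        if (tpm.to_numpy() < 0).any():
            raise MalformedRecord("negative TPM value")
        self.tpm = tpm.astype(float)
        self.sample_conditions = dict(sample_conditions or {})

    @property
    def genes(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.tpm.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s, c in self.sample_conditions.items() if c == condition]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionTable)
            and self.tpm.equals(other.tpm)
            and self.sample_conditions == other.sample_conditions
        )


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _is_data_line(line: str) -> bool:
    s = line.strip()
    return bool(s) and not s.startswith(("#", "track", "browser"))


def _parse_int(field: str, what: str, lineno: int) -> int:
    try:
        return int(field)
    except ValueError:
        raise MalformedRecord(f"non-integer {what} {field!r}", lineno) from None


def read_intervals(path: str | Path, kind: str = "peak"):
    """Read a BED-like file as a list of typed records.

    ``kind`` selects the record type: ``peak`` -> :class:`GenomicInterval`,
    ``summit`` -> :class:`SummitRecord` (requires 1-bp intervals,
    ``pos = start``), ``cutsite`` -> :class:`CutSite`, ``tss`` ->
    :class:`TssRecord` (name column holds the gene_id).  Comment, ``track``
    and ``browser`` lines are skipped.  Records are returned in file order.
    """
    if kind not in {"peak", "summit", "cutsite", "tss"}:
        raise ValueError(f"unknown kind {kind!r}")
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not _is_data_line(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise MalformedRecord(
                    f"expected >= 3 tab-separated columns, got {len(fields)}", lineno
                )
            chrom = fields[0]
            start = _parse_int(fields[1], "start", lineno)
            end = _parse_int(fields[2], "end", lineno)
            if start < 0 or end <= start:
                raise MalformedRecord(f"invalid interval [{start}, {end})", lineno)
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise MalformedRecord(f"non-numeric score {fields[4]!r}", lineno) from None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                if kind == "peak":
                    records.append(GenomicInterval(chrom, start, end, name, score, strand))
                elif kind == "summit":
                    if end != start + 1:
                        raise MalformedRecord(
                            f"summit interval [{start}, {end}) is not 1 bp", lineno
                        )
                    records.append(
                        SummitRecord(chrom, start, score if score is not None else 0.0,
                                     name or "")
                    )
                elif kind == "cutsite":
                    # Strand, if present, is deliberately ignored: tags are
                    # counted as strandless single positions.
                    records.append(CutSite(chrom, start))
                else:  # tss
                    if name is None:
                        raise MalformedRecord("TSS record missing gene_id (name column)", lineno)
                    records.append(TssRecord(name, chrom, start, strand))
            except MalformedRecord as exc:
                if exc.line_number is None:
                    raise MalformedRecord(str(exc), lineno) from None
                raise
    return records


def write_intervals(records: Sequence, path: str | Path) -> Path:
    """Write records as BED; inverse of :func:`read_intervals` (round trip).

    Optional fields (name/score/strand) are emitted only as far as they are
    set, so a bare interval becomes a 3-column line.  Summits, cut sites and
    TSS records are written as 1-bp intervals.
    """
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        with _open_text(path, "wt") as fh:
            for rec in records:
                fh.write("\t".join(_bed_fields(rec)) + "\n")
    except OSError as exc:
        raise UnwritablePath(f"cannot write {path}: {exc}") from exc
    return path


def _format_score(score: float) -> str:
    return f"{score:g}"


def _bed_fields(rec) -> list[str]:
    if isinstance(rec, GenomicInterval):
        fields = [rec.chrom, str(rec.start), str(rec.end)]
        if rec.strand != ".":
            fields += [rec.name or ".",
                       _format_score(rec.score) if rec.score is not None else ".",
                       rec.strand]
        elif rec.score is not None:
            fields += [rec.name or ".", _format_score(rec.score)]
        elif rec.name is not None:
            fields.append(rec.name)
        return fields
    if isinstance(rec, SummitRecord):
        return [rec.chrom, str(rec.pos), str(rec.pos + 1),
                rec.sample_id or ".", _format_score(rec.score)]
    if isinstance(rec, CutSite):
        return [rec.chrom, str(rec.pos), str(rec.pos + 1)]
    if isinstance(rec, TssRecord):
        return [rec.chrom, str(rec.tss), str(rec.tss + 1), rec.gene_id, ".", rec.strand]
    raise TypeError(f"cannot serialize {type(rec).__name__}")


def read_expression(
    path: str | Path, sample_conditions: dict[str, str] | None = None
) -> ExpressionTable:
    """Read a TPM TSV (``gene_id`` column + one numeric column per sample)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise MalformedRecord("expression table missing 'gene_id' column")
    df = df.set_index("gene_id")
    if df.shape[1] == 0:
        raise MalformedRecord("expression table has no sample columns")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            gene = df.index[(bad | df[col].isna())][0]
            raise MalformedRecord(f"non-numeric TPM for gene {gene!r} in sample {col!r}")
        if (vals < 0).any():
            gene = df.index[vals < 0][0]
            raise MalformedRecord(f"negative TPM for gene {gene!r} in sample {col!r}")
        df[col] = vals
    return ExpressionTable(df, sample_conditions)


def read_tss(path: str | Path) -> list[TssRecord]:
    """Read a TSS table: TSV with header (gene_id, chrom, tss, strand) or BED."""
    path = Path(path)
    with _open_text(path) as fh:
        first = fh.readline()
    if first.startswith("gene_id"):
        df = pd.read_csv(path, sep="\t")
        return [
            TssRecord(str(r.gene_id), str(r.chrom), int(r.tss), str(getattr(r, "strand", "+")))
            for r in df.itertuples(index=False)
        ]
    return read_intervals(path, kind="tss")


def write_tss(records: Iterable[TssRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [(r.gene_id, r.chrom, r.tss, r.strand) for r in records],
        columns=["gene_id", "chrom", "tss", "strand"],
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def validate_shared_chromosomes(*chrom_sets: Iterable[str]) -> list[str]:
    """Return chromosome names present in only some of the inputs.

    Exact string matching is used; a non-empty return value signals a likely
    naming mismatch (e.g. "1" vs "chr1") that would silently drop data.
    """
    sets = [set(s) for s in chrom_sets]
    if not sets:
        return []
    union = set.union(*sets)
    common = set.intersection(*sets)
    return sorted(union - common)
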