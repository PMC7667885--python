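"""Set-level annotation of DHS calls.

Overlap of called windows with external peak sets (subset detection and
Venn partitions), IUPAC consensus motif scanning around summits, and
summit-to-summit proximity (the "inducible site within 25 kb" analysis).
Consensus scanning (default GAS/STAT5 ``TTCYNRGAA`` and AP-1 ``TGASTCA``)
is a deterministic stand-in for matrix-based motif discovery, so motif
fractions are approximate by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from chromaprime.errors import LengthMismatch, MissingSequence
from chromaprime.io_formats import GenomicInterval, SummitRecord
from chromaprime.windows_counting import Window, WindowSet

__all__ = ["MotifModel", "DEFAULT_MOTIFS", "overlap_flags", "venn_partition",
           "scan_consensus", "nearest_distance"]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifModel:
    """An IUPAC consensus motif scanned around window summits."""

    name: str
    consensus: str
    max_mismatches: int = 0
    flank: int = 100

    def __post_init__(self):
        cons = self.consensus.upper()
        if len(cons) < 4:
            raise ValueError("consensus length must be >= 4")
        bad = set(cons) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC letters in consensus: {sorted(bad)}")
        object.__setattr__(self, "consensus", cons)

    @property
    def reverse_complement(self) -> str:
        return self.consensus.translate(_COMPLEMENT)[::-1]

    def regex(self) -> re.Pattern:
        """Exact-match (0-mismatch) regex for both strands."""
        def expand(cons):
            return "".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in cons)
        return re.compile(f"(?={expand(self.consensus)})|(?={expand(self.reverse_complement)})")


DEFAULT_MOTIFS = (
    MotifModel("STAT5_GAS", "TTCYNRGAA"),
    MotifModel("AP1", "TGASTCA"),
)


def _as_intervals(items) -> list[tuple[str, int, int]]:
    out = []
    for x in items:
        if isinstance(x, Window):
            out.append((x.chrom, x.start, x.end))
        elif isinstance(x, GenomicInterval):
            out.append((x.chrom, x.start, x.end))
        elif isinstance(x, SummitRecord):
            out.append((x.chrom, x.pos, x.pos + 1))
        else:
            chrom, start, end = x[0], int(x[1]), int(x[2])
            out.append((chrom, start, end))
    return out


def overlap_flags(query, target) -> np.ndarray:
    """Boolean per query interval: true iff >= 1 bp overlap with any target.

    Accepts WindowSets, interval/summit records, or (chrom, start, end)
    triples; half-open semantics throughout.
    """
    q = _as_intervals(query)
    t = _as_intervals(target)
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in t:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    flags = np.zeros(len(q), dtype=bool)
    for i, (chrom, start, end) in enumerate(q):
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(start, end):
            flags[i] = True
    return flags


def venn_partition(flag_vectors: Mapping[str, Sequence[bool]]) -> dict:
    """Exhaustive 2^k partition of a query by k membership flag vectors.

    Returns ``{"cells": {frozen label subset as sorted tuple: count},
    "n_query": n, "n_any": count in >= 1 target, "fraction_any": share}``.
    Cell counts sum to the query size.
    """
    labels = list(flag_vectors)
    arrays = [np.asarray(flag_vectors[l], dtype=bool) for l in labels]
    if len({a.shape[0] for a in arrays} or {0}) > 1:
        raise LengthMismatch("flag vectors differ in length")
    n = arrays[0].shape[0] if arrays else 0
    cells: dict[tuple[str, ...], int] = {}
    if arrays:
        stacked = np.stack(arrays, axis=1)  # n x k
        for row in stacked:
            key = tuple(l for l, f in zip(labels, row) if f)
            cells[key] = cells.get(key, 0) + 1
        n_any = int(stacked.any(axis=1).sum())
    else:
        n_any = 0
    return {
        "cells": cells,
        "n_query": n,
        "n_any": n_any,
        "fraction_any": (n_any / n) if n else 0.0,
    }


def scan_consensus(
    windows: WindowSet | Sequence,
    genome: Mapping[str, str],
    motif: MotifModel,
) -> tuple[np.ndarray, list[str]]:
    """Flag windows whose summit +/- flank region contains the consensus.

    ``genome`` maps chromosome name to sequence (a pyfaidx.Fasta works).
    Matching is on either strand; with ``max_mismatches > 0`` a sliding
    Hamming comparison against the IUPAC degeneracy sets is used.  Windows
    whose chromosome has no sequence are reported (second return value)
    and flagged False.
    """
    items = list(windows)
    flags = np.zeros(len(items), dtype=bool)
    missing: list[str] = []
    pattern = motif.regex()
    for i, w in enumerate(items):
        if isinstance(w, Window):
            chrom, summit, wid = w.chrom, w.summit_pos, w.window_id
        elif isinstance(w, SummitRecord):
            chrom, summit, wid = w.chrom, w.pos, f"{w.chrom}:{w.pos}"
        else:
            chrom, summit = w[0], int(w[1])
            wid = f"{chrom}:{summit}"
        if chrom not in genome:
            missing.append(wid)
            continue
        seq = genome[chrom]
        start = max(0, summit - motif.flank)
        end = min(len(seq), summit + motif.flank + 1)
        region = str(seq[start:end]).upper()
        if motif.max_mismatches == 0:
            flags[i] = bool(pattern.search(region))
        else:
            flags[i] = _mismatch_scan(region, motif)
    return flags, missing


def _mismatch_scan(region: str, motif: MotifModel) -> bool:
    for cons in (motif.consensus, motif.reverse_complement):
        k = len(cons)
        allowed = [IUPAC[c] for c in cons]
        for i in range(len(region) - k + 1):
            mism = 0
            for base, ok in zip(region[i:i + k], allowed):
                if base not in ok:
                    mism += 1
                    if mism > motif.max_mismatches:
                        break
            else:
                return True
    return False


def nearest_distance(
    query: Sequence, target: Sequence, max_dist: int = 25_000
) -> pd.DataFrame:
    """Summit-to-summit distance from each query to its closest target.

    Queries and targets are summit-like (SummitRecord, Window — its summit
    is used — or (chrom, pos) pairs).  Queries with no same-chromosome
    target get distance ``inf``.  Returns a DataFrame with columns
    ``chrom, pos, distance, within`` (``within``: distance <= max_dist).
    """
    def points(items):
        out = []
        for x in items:
            if isinstance(x, SummitRecord):
                out.append((x.chrom, x.pos))
            elif isinstance(x, Window):
                out.append((x.chrom, x.summit_pos))
            else:
                out.append((x[0], int(x[1])))
        return out

    q = points(query)
    t = points(target)
    grouped: dict[str, list[int]] = {}
    for chrom, pos in t:
        grouped.setdefault(chrom, []).append(pos)
    by_chrom = {c: np.sort(np.asarray(p)) for c, p in grouped.items()}
    rows = []
    for chrom, pos in q:
        tp = by_chrom.get(chrom)
        if tp is None or tp.size == 0:
            dist = np.inf
        else:
            j = np.searchsorted(tp, pos)
            cands = []
            if j < tp.size:
                cands.append(abs(int(tp[j]) - pos))
            if j > 0:
                cands.append(abs(int(tp[j - 1]) - pos))
            dist = float(min(cands))
        rows.append((chrom, pos, dist, dist <= max_dist))
    return pd.DataFrame(rows, columns=["chrom", "pos", "distance", "within"])
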