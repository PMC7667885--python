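"""Union window construction and per-window tag counting.

The study's union summit set (pooled alignments re-called with MACS2) is
emulated by single-linkage clustering of per-sample summits; a precomputed
union summit BED may be supplied instead for bit-faithful reruns.  Windows
are the summit +/- ``flank`` bp (401 bp at the default flank of 200,
inclusive of the summit base), half-open, and tags are counted as single
cut positions with no shift or extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from chromaprime.io_formats import CutSite, SummitRecord

__all__ = ["Window", "WindowSet", "CountMatrix", "pool_summits", "make_windows",
           "count_cuts", "naive_summit_call"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    """A summit-centered counting window, 0-based half-open."""

    window_id: str
    chrom: str
    summit_pos: int
    start: int
    end: int
    provenance: tuple[str, ...] = ()


class WindowSet:
    """Ordered collection of summit-centered windows, sorted by (chrom, start)."""

    def __init__(self, windows: Sequence[Window]):
        self.windows = sorted(windows, key=lambda w: (w.chrom, w.start, w.end))
        ids = [w.window_id for w in self.windows]
        if len(set(ids)) != len(ids):
            raise ValueError("window_ids are not unique")
        self._by_id = {w.window_id: w for w in self.windows}

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, window_id: str) -> Window:
        return self._by_id[window_id]

    @property
    def ids(self) -> list[str]:
        return [w.window_id for w in self.windows]

    def chromosomes(self) -> set[str]:
        return {w.chrom for w in self.windows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(w.window_id, w.chrom, w.summit_pos, w.start, w.end) for w in self.windows],
            columns=["window_id", "chrom", "summit", "start", "end"],
        )

    def coordinate_key(self) -> pd.DataFrame:
        """(chrom, start) per window_id — the canonical tie-break key."""
        return self.to_frame().set_index("window_id")[["chrom", "start"]]


@dataclass
class CountMatrix:
    """windows x samples tag counts, raw or normalized.

    ``df`` is indexed by window_id with one column per sample, in window
    (chrom, start) order.  ``factors`` is attached once normalization has
    been applied.
    """

    df: pd.DataFrame
    raw: bool = True
    factors: "object | None" = None
    window_key: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.df.index.has_duplicates or self.df.columns.has_duplicates:
            raise ValueError("row/column labels must be unique")
        if (self.df.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    @property
    def window_ids(self) -> list[str]:
        return list(self.df.index)

    def to_tsv(self, path) -> None:
        self.df.rename_axis("window_id").to_csv(path, sep="\t")


def pool_summits(
    summit_sets: Iterable[Sequence[SummitRecord]], cluster_dist: int = 200
) -> list[SummitRecord]:
    """Merge per-sample summits into a union set.

    Single-linkage clustering per chromosome: consecutive (sorted) summits
    at distance <= ``cluster_dist`` join one cluster.  Each cluster is
    represented by its highest-scoring summit; ties broken by lower
    coordinate, then lexicographic sample_id.  Idempotent.
    """
    if cluster_dist < 0:
        raise ValueError("cluster_dist must be >= 0")
    all_summits = [s for subset in summit_sets for s in subset]
    all_summits.sort(key=lambda s: (s.chrom, s.pos, s.sample_id))
    out: list[SummitRecord] = []
    cluster: list[SummitRecord] = []

    def flush():
        if cluster:
            best = max(cluster, key=lambda s: (s.score, -s.pos, _neg_lex(s.sample_id)))
            out.append(best)

    for s in all_summits:
        if cluster and (s.chrom != cluster[-1].chrom or s.pos - cluster[-1].pos > cluster_dist):
            flush()
            cluster = []
        cluster.append(s)
    flush()
    return out


class _neg_lex(str):
    """Reverses lexicographic order so max() picks the smallest sample_id."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def make_windows(
    summits: Sequence[SummitRecord],
    flank: int = 200,
    chrom_lengths: Mapping[str, int] | None = None,
) -> WindowSet:
    """Summit +/- ``flank`` windows, clipped at 0 and the chromosome end.

    Window ids are assigned in (chrom, start) sorted order.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    recs = sorted(summits, key=lambda s: (s.chrom, s.pos))
    windows = []
    for i, s in enumerate(recs):
        start = max(0, s.pos - flank)
        end = s.pos + flank + 1
        if chrom_lengths is not None and s.chrom in chrom_lengths:
            end = min(end, chrom_lengths[s.chrom])
        windows.append(Window(f"w{i:06d}", s.chrom, s.pos, start, end,
                              provenance=(s.sample_id,) if s.sample_id else ()))
    return WindowSet(windows)


def count_cuts(
    windows: WindowSet, tracks: Mapping[str, Sequence[CutSite]]
) -> CountMatrix:
    """Raw tag counts per window per sample.

    Entry (w, s) is the number of cut positions p of sample s with
    ``start <= p < end``; a cut under two overlapping windows counts in
    both.  Tags on chromosomes absent from the window set are ignored and
    reported via a warning.
    """
    win_chroms = windows.chromosomes()
    wdf = windows.to_frame()
    counts = pd.DataFrame(
        0, index=pd.Index(wdf["window_id"], name="window_id"),
        columns=list(tracks), dtype=np.int64,
    )
    by_chrom = {ch: grp for ch, grp in wdf.groupby("chrom", sort=False)}
    for sample, cuts in tracks.items():
        pos_by_chrom: dict[str, list[int]] = {}
        skipped = 0
        for c in cuts:
            if c.chrom in win_chroms:
                pos_by_chrom.setdefault(c.chrom, []).append(c.pos)
            else:
                skipped += 1
        if skipped:
            logger.warning(
                "sample %s: %d cut(s) on chromosomes absent from the window set "
                "were ignored", sample, skipped,
            )
        for ch, grp in by_chrom.items():
            pos = np.sort(np.asarray(pos_by_chrom.get(ch, []), dtype=np.int64))
            if pos.size == 0:
                continue
            lo = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
            hi = np.searchsorted(pos, grp["end"].to_numpy(), side="left")
            counts.loc[grp["window_id"], sample] = hi - lo
    return CountMatrix(counts, raw=True, window_key=windows.coordinate_key())


def naive_summit_call(
    track: Sequence[CutSite], bin: int = 50, min_count: float = 20.0
) -> list[SummitRecord]:
    """Convenience summit caller for synthetic tracks (not a peak caller).

    Bins cut positions at ``bin`` bp, smooths with a 3-bin moving average,
    and emits local maxima whose smoothed count reaches ``min_count``;
    the summit is the center of the maximal bin.  Maxima closer than
    ``2 * bin`` are merged keeping the higher.
    """
    if bin <= 0:
        raise ValueError("bin must be > 0")
    by_chrom: dict[str, list[int]] = {}
    for c in track:
        by_chrom.setdefault(c.chrom, []).append(c.pos)
    out: list[SummitRecord] = []
    for chrom in sorted(by_chrom):
        pos = np.asarray(by_chrom[chrom])
        n_bins = int(pos.max() // bin) + 1
        hist = np.bincount(pos // bin, minlength=n_bins).astype(float)
        smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
        candidates = []
        for i in range(len(smooth)):
            left = smooth[i - 1] if i > 0 else -np.inf
            right = smooth[i + 1] if i + 1 < len(smooth) else -np.inf
            if smooth[i] >= min_count and smooth[i] >= left and smooth[i] > right:
                candidates.append((i * bin + bin // 2, smooth[i]))
        merged: list[tuple[int, float]] = []
        for p, score in candidates:
            if merged and p - merged[-1][0] < 2 * bin:
                if score > merged[-1][1]:
                    merged[-1] = (p, score)
            else:
                merged.append((p, score))
        out.extend(SummitRecord(chrom, p, s) for p, s in merged)
    return out
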