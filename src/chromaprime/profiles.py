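"""Binned tag-density matrices and average profiles around summits.

Each window contributes one row covering summit +/- span/2 (default 2 kb
span at 10-bp bins, i.e. 200 bins), in the caller's ordering — typically
the fold-change ranking — matching the layout of ranked tag-density
heatmaps.  Rows for windows near a chromosome edge keep out-of-range bins
at zero so the matrix stays rectangular.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from chromaprime.errors import EmptyMatrix
from chromaprime.io_formats import CutSite
from chromaprime.windows_counting import Window

__all__ = ["ProfileMatrix", "density_matrix", "average_profile"]


@dataclass
class ProfileMatrix:
    """windows x bins normalized tag density for one sample."""

    values: pd.DataFrame  # index window_id (caller's order), columns bin start offsets
    bin_width: int
    span: int
    sample: str = ""
    clipped_windows: tuple[str, ...] = ()

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def row_sums(self) -> pd.Series:
        return self.values.sum(axis=1)

    def to_tsv(self, path) -> None:
        self.values.rename_axis("window_id").to_csv(path, sep="\t")


def density_matrix(
    windows: Sequence[Window],
    track: Sequence[CutSite],
    factor: float = 1.0,
    bin_width: int = 10,
    span: int = 2_000,
    sample: str = "",
) -> ProfileMatrix:
    """Binned cut counts around each window summit, scaled by ``factor``.

    Bin j of a window covers ``[summit - span/2 + j*bin_width, ... +
    bin_width)``, half-open.  Rows follow the order of ``windows`` (pass a
    ranked list for heatmap-style output).  A cut under several windows'
    spans contributes to each.
    """
    if span % 2 or span % bin_width:
        raise ValueError("span must be even and divisible by bin_width")
    n_bins = span // bin_width
    half = span // 2
    by_chrom: dict[str, list[int]] = {}
    for c in track:
        by_chrom.setdefault(c.chrom, []).append(c.pos)
    pos_sorted = {ch: np.sort(np.asarray(p, dtype=np.int64)) for ch, p in by_chrom.items()}
    ids = [w.window_id for w in windows]
    mat = np.zeros((len(windows), n_bins))
    clipped = []
    for i, w in enumerate(windows):
        lo = w.summit_pos - half
        if lo < 0:
            clipped.append(w.window_id)
        pos = pos_sorted.get(w.chrom)
        if pos is None:
            continue
        a = np.searchsorted(pos, lo, side="left")
        b = np.searchsorted(pos, lo + span, side="left")
        if a == b:
            continue
        bins = (pos[a:b] - lo) // bin_width
        mat[i] = np.bincount(bins, minlength=n_bins) * factor
    offsets = [-half + j * bin_width for j in range(n_bins)]
    values = pd.DataFrame(mat, index=pd.Index(ids, name="window_id"), columns=offsets)
    return ProfileMatrix(values, bin_width, span, sample, tuple(clipped))


def average_profile(matrix: ProfileMatrix) -> pd.Series:
    """Per-bin arithmetic mean across windows (the average tag density plot)."""
    if matrix.values.shape[0] == 0:
        raise EmptyMatrix("profile matrix has no rows")
    return matrix.values.mean(axis=0)
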