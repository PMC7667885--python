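"""Replicate-consistent fold-change classification of DHS windows.

The core rule: a window belongs to a condition-dependent call set iff, in
EVERY replicate pair of the contrast, its pseudocounted fold change
reaches the threshold (default 2) AND the higher of the two normalized
counts clears a background cutoff.  The same machinery with
maintained/withdrawn pairs calls primed DHSs (pDHSs) and with
stimulated/unstimulated pairs calls inducible DHSs (iDHSs); intersecting
the two recovers the cytokine-dependent inducible subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from chromaprime.errors import ConfigError, InsufficientWindows, WindowSetMismatch
from chromaprime.windows_counting import CountMatrix

__all__ = ["ContrastSpec", "ClassParams", "DHSCallSet", "per_window_fold",
           "call_dependent", "intersect_calls", "select_invariant", "rank_windows"]


@dataclass(frozen=True)
class ContrastSpec:
    """A labeled contrast of positionally paired replicates.

    Each pair (sample_A, sample_B) compares condition A against condition B
    within one replicate, e.g. (IL2_r1, IL2nil_r1).
    """

    label: str
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.pairs:
            raise ConfigError(f"contrast {self.label!r} has no replicate pairs")

    def samples(self) -> list[str]:
        return [s for pair in self.pairs for s in pair]


@dataclass(frozen=True)
class ClassParams:
    """Calling thresholds.

    fold_threshold : minimal fold change, required in every replicate (>= is in).
    pseudocount    : added to both normalized counts before the ratio.
    min_count      : background cutoff on the higher condition's normalized count.
    """

    fold_threshold: float = 2.0
    pseudocount: float = 1.0
    min_count: float = 20.0

    def __post_init__(self):
        if self.fold_threshold < 1:
            raise ConfigError("fold_threshold must be >= 1")
        if self.pseudocount < 0 or self.min_count < 0:
            raise ConfigError("pseudocount and min_count must be >= 0")


@dataclass
class DHSCallSet:
    """A called window set with the per-replicate fold changes behind it."""

    label: str
    members: list[str]
    folds: pd.DataFrame  # all windows x one column per replicate pair
    params: ClassParams
    provenance: tuple[str, ...] = ()

    @property
    def member_set(self) -> set[str]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def to_detail_frame(self) -> pd.DataFrame:
        out = self.folds.copy()
        out["member"] = out.index.isin(self.member_set)
        return out


def per_window_fold(
    matrix: CountMatrix, pair: tuple[str, str], pseudocount: float = 1.0
) -> pd.Series:
    """Fold change (a + p) / (b + p) per window for one replicate pair.

    With ``pseudocount == 0`` a zero denominator yields +inf, which is
    permitted: such windows trivially exceed any finite threshold.
    """
    a, b = pair
    num = matrix.df[a].to_numpy(dtype=float) + pseudocount
    den = matrix.df[b].to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(den == 0, np.where(num == 0, 1.0, np.inf), num / den)
    return pd.Series(fc, index=matrix.df.index, name=f"{a}/{b}")


def call_dependent(
    matrix: CountMatrix, contrast: ContrastSpec, params: ClassParams = ClassParams()
) -> DHSCallSet:
    """Call windows dependent on condition A of the contrast.

    Membership requires, for every replicate pair: fold change >=
    ``fold_threshold`` AND max(a, b) >= ``min_count``.  Fold changes for
    all windows are retained for ranking and plotting.
    """
    if matrix.raw:
        raise ValueError("call_dependent expects a normalized matrix")
    missing = [s for s in contrast.samples() if s not in matrix.samples]
    if missing:
        raise ConfigError(f"contrast {contrast.label!r} names unknown samples {missing}")
    folds = {}
    ok = np.ones(len(matrix.df), dtype=bool)
    for pair in contrast.pairs:
        fc = per_window_fold(matrix, pair, params.pseudocount)
        folds[fc.name] = fc
        a = matrix.df[pair[0]].to_numpy(dtype=float)
        b = matrix.df[pair[1]].to_numpy(dtype=float)
        ok &= (fc.to_numpy() >= params.fold_threshold) & (
            np.maximum(a, b) >= params.min_count
        )
    folds_df = pd.DataFrame(folds, index=matrix.df.index)
    members = list(matrix.df.index[ok])
    return DHSCallSet(contrast.label, members, folds_df, params)


def intersect_calls(set_a: DHSCallSet, set_b: DHSCallSet) -> DHSCallSet:
    """Windows called in both sets; fold columns of both parents retained."""
    if not set_a.folds.index.equals(set_b.folds.index):
        raise WindowSetMismatch(
            f"call sets {set_a.label!r} and {set_b.label!r} are on different windows"
        )
    members = [w for w in set_a.members if w in set_b.member_set]
    folds = set_a.folds.join(set_b.folds, how="left", rsuffix="_b")
    return DHSCallSet(
        f"{set_a.label}&{set_b.label}", members, folds, set_a.params,
        provenance=(set_a.label, set_b.label),
    )


def _coordinate_order(matrix: CountMatrix) -> pd.Index:
    """Window ids sorted by (chrom, start); falls back to matrix row order."""
    if matrix.window_key is None:
        return matrix.df.index
    key = matrix.window_key.loc[matrix.df.index]
    return key.sort_values(["chrom", "start"], kind="mergesort").index


def select_invariant(
    matrix: CountMatrix,
    contrasts: Sequence[ContrastSpec],
    n: int,
    params: ClassParams = ClassParams(),
) -> DHSCallSet:
    """Select the n most fold-change-stable well-covered control windows.

    Eligible windows have normalized count >= ``min_count`` in every
    sample; each is scored by its worst (largest) |log2 FC| over all
    contrasts and replicate pairs, and the n lowest-scoring windows are
    returned, ties broken by (chrom, start).
    """
    if matrix.raw:
        raise ValueError("select_invariant expects a normalized matrix")
    coord_order = _coordinate_order(matrix)
    df = matrix.df.loc[coord_order]
    eligible = (df.to_numpy() >= params.min_count).all(axis=1)
    folds = {}
    score = np.zeros(len(df))
    reindexed = CountMatrix(df, raw=False, factors=matrix.factors,
                            window_key=matrix.window_key)
    for contrast in contrasts:
        for pair in contrast.pairs:
            fc = per_window_fold(reindexed, pair, params.pseudocount)
            folds[f"{contrast.label}:{fc.name}"] = fc
            score = np.maximum(score, np.abs(np.log2(fc.to_numpy())))
    n_eligible = int(eligible.sum())
    if n > n_eligible:
        raise InsufficientWindows(f"requested {n} invariant windows, {n_eligible} eligible")
    elig_idx = np.flatnonzero(eligible)
    # stable sort on score preserves the coordinate order among ties
    chosen = elig_idx[np.argsort(score[elig_idx], kind="stable")[:n]]
    members = list(df.index[np.sort(chosen)])
    return DHSCallSet("invariant", members, pd.DataFrame(folds, index=df.index), params)


def rank_windows(matrix: CountMatrix, pair: tuple[str, str],
                 pseudocount: float = 1.0) -> list[str]:
    """Window ids ordered by increasing fold change for one replicate pair.

    This is the ordering used for fold-change-ranked tag-density heatmaps.
    Ties are broken by (chrom, start).
    """
    if matrix.raw:
        raise ValueError("rank_windows expects a normalized matrix")
    coord_order = _coordinate_order(matrix)
    reindexed = CountMatrix(matrix.df.loc[coord_order], raw=False,
                            factors=matrix.factors, window_key=matrix.window_key)
    fc = per_window_fold(reindexed, pair, pseudocount)
    order = np.argsort(fc.to_numpy(), kind="stable")
    return list(fc.index[order])
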