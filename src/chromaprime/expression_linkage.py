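"""Expression filtering/normalization and the nearest-gene join.

TPM tables are filtered to genes detected above 1 TPM in at least one
sample, upper-quartile normalized (each sample scaled so its 75th
percentile of retained TPMs equals the geometric mean of the per-sample
75th percentiles; type-7 linear-interpolation percentile), and
log2(TPM + 1) transformed.  Windows are joined to their nearest TSS, and
the fold-change-ranked window ordering is tested for a monotone
expression trend by Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from chromaprime.errors import DegenerateSample
from chromaprime.io_formats import ExpressionTable, TssRecord
from chromaprime.windows_counting import WindowSet

__all__ = ["GeneLink", "normalize_tpm", "gene_fold_changes", "nearest_gene",
           "rank_expression_trend"]

THREEFOLD = float(np.log2(3.0))


@dataclass(frozen=True)
class GeneLink:
    """The nearest gene to one window.

    ``distance`` is signed along the gene: negative when the summit lies
    upstream of the TSS (by gene strand).  ``gene_id`` is None for windows
    with no TSS on their chromosome.
    """

    window_id: str
    gene_id: str | None
    distance: float

    @property
    def linked(self) -> bool:
        return self.gene_id is not None


def normalize_tpm(table: ExpressionTable) -> tuple[pd.DataFrame, dict[str, float]]:
    """Filter, upper-quartile normalize and log2(x+1)-transform a TPM table.

    Genes with TPM <= 1 in every sample are dropped.  Returns the
    log2-scale matrix and the per-sample scaling factors applied.
    """
    tpm = table.tpm
    keep = (tpm > 1.0).any(axis=1)
    kept = tpm.loc[keep]
    if kept.empty:
        return kept.copy(), {s: 1.0 for s in tpm.columns}
    uq = kept.quantile(0.75, interpolation="linear")
    zero = uq[uq == 0]
    if len(zero):
        raise DegenerateSample(
            f"75th percentile of retained TPMs is 0 for samples {list(zero.index)}"
        )
    ref = float(np.exp(np.mean(np.log(uq.to_numpy()))))
    factors = (ref / uq).to_dict()
    scaled = kept.mul(pd.Series(factors), axis=1)
    return np.log2(scaled + 1.0), factors


def gene_fold_changes(
    logmatrix: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
) -> pd.DataFrame:
    """Per-gene log2 fold change: mean log value in A minus mean in B.

    The ``threefold`` column flags |log2FC| > log2(3), the magnitude
    filter used for differentially expressed genes (significance testing
    is out of scope; externally computed adjusted p-values can be joined
    on gene_id).
    """
    if not samples_a or not samples_b:
        raise ValueError("each condition needs >= 1 sample")
    log2fc = logmatrix[list(samples_a)].mean(axis=1) - logmatrix[list(samples_b)].mean(axis=1)
    return pd.DataFrame({
        "log2fc": log2fc,
        "threefold": log2fc.abs() > THREEFOLD,
    })


def nearest_gene(windows: WindowSet, tss: Sequence[TssRecord]) -> list[GeneLink]:
    """Nearest TSS (by |summit - tss|, same chromosome) per window.

    Ties broken by lower TSS coordinate, then lexicographic gene_id;
    windows with no same-chromosome TSS yield unlinked records.
    """
    by_chrom: dict[str, list[TssRecord]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t)
    sorted_chrom: dict[str, tuple[np.ndarray, list[TssRecord]]] = {}
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda t: (t.tss, t.gene_id))
        sorted_chrom[chrom] = (np.asarray([t.tss for t in recs]), recs)
    links: list[GeneLink] = []
    for w in windows:
        entry = sorted_chrom.get(w.chrom)
        if entry is None:
            links.append(GeneLink(w.window_id, None, np.inf))
            continue
        positions, recs = entry
        j = int(np.searchsorted(positions, w.summit_pos))
        cands = []
        if j < len(positions):
            cands.append(abs(int(positions[j]) - w.summit_pos))
        if j > 0:
            cands.append(abs(int(positions[j - 1]) - w.summit_pos))
        best_dist = min(cands)
        # all TSSs at exactly best_dist (either side), then the tie-break
        lo = int(np.searchsorted(positions, w.summit_pos - best_dist, side="left"))
        hi = int(np.searchsorted(positions, w.summit_pos + best_dist, side="right"))
        tied = [r for r in recs[lo:hi] if abs(r.tss - w.summit_pos) == best_dist]
        best = min(tied, key=lambda t: (t.tss, t.gene_id))
        signed = (w.summit_pos - best.tss) if best.strand != "-" else (best.tss - w.summit_pos)
        links.append(GeneLink(w.window_id, best.gene_id, float(signed)))
    return links


def rank_expression_trend(
    ranked_windows: Sequence[str],
    links: Sequence[GeneLink],
    gene_log2fc: Mapping[str, float] | pd.Series,
) -> tuple[pd.DataFrame, float]:
    """Expression fold change of the nearest gene along the window ranking.

    ``ranked_windows`` is the fold-change-ordered window list; the series
    pairs each rank with the linked gene's log2 FC (missing links or genes
    dropped).  Returns the series and the Spearman rho of rank vs FC
    (0.0 when the FC is constant or fewer than 2 points remain).
    """
    link_by_window = {l.window_id: l for l in links}
    if isinstance(gene_log2fc, pd.Series):
        gene_log2fc = gene_log2fc.to_dict()
    rows = []
    for rank, wid in enumerate(ranked_windows):
        link = link_by_window.get(wid)
        if link is None or not link.linked or link.gene_id not in gene_log2fc:
            continue
        rows.append((rank, wid, link.gene_id, float(gene_log2fc[link.gene_id])))
    series = pd.DataFrame(rows, columns=["rank", "window_id", "gene_id", "log2fc"])
    if len(series) < 2 or series["log2fc"].nunique() == 1:
        return series, 0.0
    rho = stats.spearmanr(series["rank"], series["log2fc"]).statistic
    return series, float(rho)
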