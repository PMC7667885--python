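"""Cross-sample scaling of count matrices.

DNase/ATAC samples are scaled with a correction factor based on the median
of each sample's top-N window counts (N defaults to 25,000, clamped to the
number of windows); ChIP-style samples are scaled by mapped-read depth.
The common reference is the geometric mean of the per-sample statistics,
which makes the factors symmetric in the samples and idempotent under
re-normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from chromaprime.errors import DegenerateSample, MissingFactor
from chromaprime.windows_counting import CountMatrix

__all__ = ["NormFactors", "topn_median_factors", "apply_factors", "depth_factors"]


@dataclass
class NormFactors:
    """Per-sample scaling factors and the statistic they equalize."""

    factors: dict[str, float]
    method: str  # "topn_median" or "depth"
    basis: dict[str, float] = field(default_factory=dict)  # sample -> m_s or depth
    n_top: int | None = None
    reference: float = 1.0  # geometric mean of the per-sample statistics

    def __post_init__(self):
        bad = [s for s, f in self.factors.items() if not f > 0]
        if bad:
            raise DegenerateSample(f"non-positive factor for samples {bad}")

    def __getitem__(self, sample: str) -> float:
        return self.factors[sample]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": list(self.factors),
            "method": self.method,
            "statistic": [self.basis.get(s, np.nan) for s in self.factors],
            "factor": list(self.factors.values()),
        })


def topn_median_factors(
    matrix: CountMatrix,
    n_top: int = 25_000,
    basis_windows: Sequence[str] | None = None,
) -> NormFactors:
    """Correction factors from the median of each sample's top-N counts.

    For sample s, ``m_s`` is the median of its ``n_top`` largest counts
    (restricted to ``basis_windows`` when given; all windows are used when
    fewer than ``n_top`` are available).  The factor is ``G / m_s`` with G
    the geometric mean of the ``m_s``, so multiplying by the factor
    equalizes the top-N medians across samples.
    """
    if not matrix.raw:
        raise ValueError("topn_median_factors expects a raw count matrix")
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    df = matrix.df
    if basis_windows is not None:
        missing = set(basis_windows) - set(df.index)
        if missing:
            raise KeyError(f"basis windows absent from matrix: {sorted(missing)[:5]}")
        df = df.loc[list(basis_windows)]
    n_eff = min(n_top, len(df))
    if n_eff == 0:
        raise ValueError("empty basis")
    medians: dict[str, float] = {}
    for s in df.columns:
        top = np.sort(df[s].to_numpy())[-n_eff:]
        m = float(np.median(top))
        if m == 0:
            raise DegenerateSample(f"sample {s!r}: median of top {n_eff} counts is 0")
        medians[s] = m
    ref = float(np.exp(np.mean(np.log(list(medians.values())))))
    factors = {s: ref / m for s, m in medians.items()}
    return NormFactors(factors, "topn_median", basis=medians, n_top=n_eff, reference=ref)


def apply_factors(matrix: CountMatrix, factors: NormFactors) -> CountMatrix:
    """Scale every sample column by its factor; flags the matrix normalized."""
    missing = [s for s in matrix.samples if s not in factors.factors]
    if missing:
        raise MissingFactor(f"no factor for samples {missing}")
    scaled = matrix.df.astype(float).mul(
        pd.Series({s: factors[s] for s in matrix.samples}), axis=1
    )
    return CountMatrix(scaled, raw=False, factors=factors, window_key=matrix.window_key)


def depth_factors(mapped_read_counts: Mapping[str, int]) -> NormFactors:
    """Mapped-read-depth scaling: factor_s = (geometric mean depth) / depth_s."""
    bad = [s for s, d in mapped_read_counts.items() if d <= 0]
    if bad:
        raise DegenerateSample(f"zero/negative depth for samples {bad}")
    depths = {s: float(d) for s, d in mapped_read_counts.items()}
    ref = float(np.exp(np.mean(np.log(list(depths.values())))))
    return NormFactors({s: ref / d for s, d in depths.items()}, "depth",
                       basis=depths, reference=ref)
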