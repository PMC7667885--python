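# chromaprime

Differential DNase-I hypersensitivity analysis for cytokine-primed T cells —
a tested, reusable implementation of the peak-summit window counting,
top-N-median normalization and replicate-consistent fold-change
classification used to separate **primed** DNase-I hypersensitive sites
(pDHSs: open-chromatin regions maintained by γc-cytokine/STAT5 signaling)
from **inducible** DHSs (iDHSs: regions that open upon TCR-pathway
stimulation), together with the downstream overlap, consensus-motif,
proximity and nearest-gene analyses.

It is written for epigenomics analysts who have per-sample cut-site tracks
(DNase-Seq or ATAC-Seq tag positions, BED) and MACS-style peak-summit calls,
and who want the classification and its follow-up analyses to be scriptable,
deterministic and unit-testable. A synthetic cut-site generator with planted
effect classes makes every stage verifiable without any sequencing data.

## The method

1. **Union windows.** Summits from all samples are merged into a union set
   (single-linkage clustering at ≤ 200 bp; a precomputed union summit BED is
   also accepted), and each summit is expanded to a window of summit ± 200 bp
   (401 bp, half-open coordinates).
2. **Counting.** Cut sites are counted per window per sample: entry
   *c<sub>ws</sub>* = #{cuts *p* of sample *s* : start ≤ *p* < end}.
3. **Normalization.** Each DNase/ATAC sample *s* gets a correction factor
   *f<sub>s</sub>* = *G* / *m<sub>s</sub>*, where *m<sub>s</sub>* is the
   median of the sample's top 25,000 window counts and *G* is the geometric
   mean of the *m<sub>s</sub>*; ChIP-style samples can instead be scaled by
   mapped-read depth.
4. **Classification.** For a contrast with replicate pairs (*a*, *b*), the
   per-window fold change is FC = (*a* + 1)/(*b* + 1) on normalized counts.
   A window is condition-dependent iff **in every replicate** FC ≥ 2 and
   max(*a*, *b*) ≥ 20 (background cutoff). Primed sites use
   maintained-vs-withdrawn cytokine pairs, inducible sites use
   stimulated-vs-unstimulated pairs, and intersecting the two yields the
   cytokine-dependent inducible subset.
5. **Annotation.** Overlap flags and 2^k Venn partitions against external
   peak sets; IUPAC consensus scanning (STAT5/GAS `TTCYNRGAA`, AP-1
   `TGASTCA`) in summit ± 100 bp; summit-to-summit nearest distances with a
   25-kb proximity flag.
6. **Expression linkage.** TPM tables are filtered (TPM > 1 in ≥ 1 sample),
   upper-quartile normalized, log2(TPM+1)-transformed; each window is joined
   to its nearest TSS, and the fold-change-ranked window ordering is tested
   for a monotone expression trend (Spearman ρ).
7. **Profiles.** Tag-density matrices (± 1 kb around summits, 10-bp bins)
   and per-bin average profiles, in fold-change rank order.

## Worked example

```python
import chromaprime as cp

cfg = cp.SimulationConfig(
    n_chroms=2, chrom_length=2_000_000,
    n_dependent_primed=30, n_inducible=30, n_invariant=120,
    n_genes=40, seed=12345,
)
ds = cp.simulate_experiment(cfg)                     # 8 samples, 4 conditions
union = cp.pool_summits(ds.summits.values())
windows = cp.make_windows(union, flank=200)
raw = cp.count_cuts(windows, ds.cut_tracks)
norm = cp.apply_factors(raw, cp.topn_median_factors(raw))

primed = cp.call_dependent(
    norm, cp.ContrastSpec("primed", (("A_r1", "A_nil_r1"), ("A_r2", "A_nil_r2"))))
inducible = cp.call_dependent(
    norm, cp.ContrastSpec("inducible", (("A_stim_r1", "A_r1"), ("A_stim_r2", "A_r2"))))
dist = cp.nearest_distance([windows[w] for w in primed.members],
                           [windows[w] for w in inducible.members], max_dist=25_000)
```

This prints (via the obvious `print` statements):

```
180 union windows, 28 primed calls
factor A_r1 = 1.003
26 inducible calls; 28.57% of primed calls have one within 25 kb
```

i.e. of 180 union windows the rule recovers 28 of the 30 planted
cytokine-dependent windows (two fall below the twofold threshold in one
replicate by sampling noise), the normalization factor is ≈ 1 because all
samples were simulated at equal depth, and about a quarter of the primed
calls have an inducible call within 25 kb — a density set by the synthetic
window placement, not a biological constant.

The same run is available as a CLI:

```sh
chromaprime run --config config.yaml --seed 12345 --out out/
```

with `simulate`, `count`, `normalize`, `classify` and `validate`
subcommands for stage-wise reruns on the documented BED/TSV artifacts.

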