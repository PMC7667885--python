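# Methods

## Model and procedure

The package classifies open-chromatin windows by pure fold-change rules on
normalized tag counts; there is no statistical test and no p-value anywhere
in the core method. The operating assumptions are:

- A **window** is a peak summit ± `flank` (default 200 bp, so 401 bp
  including the summit base), half-open in 0-based BED coordinates. Cut
  sites are strandless single positions; no read shift or extension is
  applied, and a cut under two overlapping windows counts in both.
- The **union summit set** is formed by single-linkage clustering of all
  per-sample summits at ≤ `cluster_dist` (default 200 bp), keeping the
  highest-scoring summit per cluster (ties: lower coordinate, then
  lexicographic sample id). The original analyses this emulates pooled
  alignments and re-called peaks instead; since peak-calling internals are
  out of scope, a precomputed union summit BED is accepted for reruns that
  must match an external caller exactly.
- **Normalization** equalizes the median of each sample's top-`n_top`
  window counts (default 25,000, clamped to the number of windows). The
  common reference is the geometric mean of the per-sample medians, which
  makes the factors symmetric in the samples and the procedure idempotent;
  no sample is designated as reference. Consequence: multiplying one
  sample's counts by *c* changes its factor by 1/*c* relative to the common
  rescaling (exact), not absolutely.
- **Classification** is replicate-consistent: membership requires
  FC = (a+1)/(b+1) ≥ `fold_threshold` (default 2, closed bound) **and**
  max(a, b) ≥ `min_count` (default 20 normalized counts) in *every*
  replicate pair. Replicates are paired positionally (rep 1 vs rep 1). The
  pseudocount of 1 bounds fold changes at zero counts and is negligible at
  the `min_count` scale; `min_count` itself stands in for an unstated
  "exclude background" cutoff and is therefore surfaced as an explicit,
  logged parameter.
- **Invariant controls** are the *n* windows with the smallest worst-case
  |log2 FC| across all contrasts among windows covered ≥ `min_count` in
  every sample; ties break by (chrom, start).

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `flank` | 200 | bp | window half-width around summits |
| `cluster_dist` | 200 | bp | summit pooling linkage distance |
| `n_top` | 25,000 | windows | basis of the median correction factor |
| `fold_threshold` | 2.0 | — | per-replicate fold-change bound (≥) |
| `pseudocount` | 1.0 | counts | added to both sides of every ratio |
| `min_count` | 20.0 | normalized counts | background cutoff |
| proximity `max_dist` | 25,000 | bp | summit-to-summit "nearby" flag |
| motif `flank` | 100 | bp | consensus scan half-width |
| TPM filter | > 1 | TPM | detected-gene threshold |
| gene fold flag | 3 | fold | |log2FC| > log2 3 "changed" flag |

## Synthetic data: what it emulates, and what it does not

`simulate_experiment` emulates a two-factor T-blast design — cytokine
maintained/withdrawn (`A` / `A_nil`) × restimulated or not (`A_stim` /
`A_stim_nil`) — with 2 replicates per condition by default. Planted
classes: *dependent_primed* windows drop fourfold on cytokine withdrawal in
both stimulation states; *inducible* windows gain fourfold on stimulation
in both cytokine states; *invariant* windows are constant. Window counts
are negative-binomial with Var = m + α·m² (α = 0.1 by default; α = 0
degenerates to Poisson) — the standard overdispersed model for sequencing
counts — cut positions scatter as a Gaussian (sd 60 bp) around each summit,
and a uniform background covers every chromosome. Each sample draws from
its own hash-derived substream of the root seed, so adding a sample never
perturbs the others, and all outputs are byte-identical under a fixed seed.

Desk-scale choices, stated as such:

- Genome: 2 chromosomes × 25 Mb; windows placed ≥ 20 kb apart. The spacing
  matches realistic inter-DHS/gene distances; at kilobase spacing the
  nearest-TSS join would mostly hit a *neighboring* window's gene and the
  expression trend would be structurally scrambled, which is a property of
  dense placement, not of the method.
- Background rate: 0.002 tags/bp (~0.8 background tags per 401-bp window,
  ~10⁵ background tags per sample). This keeps the per-window background
  far below `min_count`, as in real data where the cutoff separates peaks
  from background noise.
- Expression coupling: each planted window gets a dedicated gene with a TSS
  within 10 kb; its TPM is the window's true per-condition mean × gain
  (default 1) × lognormal noise (σ = 0.25), plus unlinked filler genes.
  This produces the monotone DHS-rank-vs-expression trend as a testable
  analog; it does not model transcript structure, distal regulation, or
  measurement correlation between replicates.

Not simulated: raw reads/FASTQ, GC or fragment-length bias, chromatin
domain correlation, replicate batch effects. Passing recovery tests on this
generator therefore demonstrates correctness of the *rules* under the
declared noise model, not performance on any particular real dataset.

### Intrinsic sensitivity of the two-replicate rule

At the default operating point (base mean 50, fourfold effect, α = 0.1),
requiring ≥ 2-fold in *each* of two replicates has an intrinsic per-replicate
pass probability of ≈ 0.89 for a truly fourfold window, hence joint
sensitivity ≈ 0.80 — the AND across replicates buys a very low false
discovery proportion (≈ 0.01 per-window false-positive rate on invariant
windows, FDP well under 0.10) at the price of sensitivity. Sensitivity
approaches 1 only as dispersion falls or the true effect grows; this
trade-off is a property of the rule, and the acceptance suite reports it as
measured.

## Numerical choices

- Upper-quartile normalization uses the linear-interpolation (type-7)
  percentile; the reference is again the geometric mean of per-sample upper
  quartiles, making the transform idempotent to 1e-9.
- Fold-change ranking and invariant selection break ties by (chrom, start);
  sorts are stable throughout.
- With pseudocount 0, a zero denominator yields +inf (permitted); 0/0 is
  defined as 1.
- Profile matrices are summit-centered; windows clipped at a chromosome
  edge keep out-of-range bins at zero and are flagged, so the matrix stays
  rectangular.
- Consensus motif scanning treats the IUPAC string as exact degeneracy sets
  on both strands; with `max_mismatches > 0` a sliding Hamming comparison
  is used. Consensus scanning approximates matrix-based motif discovery and
  is labeled approximate in reports.

## Known limitations

- No statistical testing of differential accessibility (by design: the
  method is a fold-change rule); no batch correction.
- Peak calling on real data is out of scope; the built-in caller
  (`naive_summit_call`) is a smoothing histogram mode-finder adequate only
  for synthetic tracks.
- Differential-expression significance is not computed; externally derived
  adjusted p-values can be joined on `gene_id` to express "3-fold AND
  significant" filters.
- The expression trend along the ranking is emitted as the raw series; any
  smoothing (rolling median) is the caller's choice and logged when used.
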