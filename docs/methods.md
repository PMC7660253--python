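# Methods

## Scope and model

`karyoshift` analyses whole-chromosome copy-number instability in yeast
strain populations, with hybrid sub-genomes as the motivating case. All
statistics operate on whole chromosomes: segmental aneuploidies must be
collapsed to whole-chromosome calls upstream, and the depth model treats a
chromosome as either carried or absent in a given cell.

## Chromosome population frequency φ

A sequenced culture is modelled as a mixture: a fraction φ_c of cells
carries chromosome c (at its baseline copy number), the rest lack it.
Read depth is assumed proportional to the DNA present, with no GC or
mappability correction (out of scope), so

    φ̂_c = mean observed depth on c / expected depth per haploid copy.

The expected depth per copy comes from the raw sequencing arithmetic
`total_bases / model_genome_size`, using raw read counts (not post-filter
counts) — this matches how such baselines are quoted for a run. The model
genome size is the sum of the haploid sub-genome sizes and is a required
user input: for an allotriploid one lists three haploid sizes.

Choices:

- **Length-weighted means.** Per-chromosome mean depth weights each
  window by its length, making the summary invariant to re-partitioning
  of the same per-base depth field (tested).
- **Missing positions are zero.** When converting samtools-depth input,
  absent positions count as depth 0 (`-a` semantics); silently skipping
  them would bias means upward exactly on the lost chromosomes of
  interest.
- **States.** `lost` below φ = 0.002, `present` above φ = 0.5,
  `low_frequency` between; these qualitative labels are exposed as
  configuration since the underlying calls are threshold conventions, not
  estimates. Chromosomes with no windows report `no_data` rather than a
  number.
- **Unclipped φ̂ with a clipped companion.** Sampling noise can push φ̂
  slightly above the copy-number ceiling; the raw value is reported for
  diagnostics, the clipped value (default ceiling 1.0) for
  interpretation.
- **CI.** Nonparametric bootstrap over windows (default 1000 resamples,
  seeded, 2.5/97.5 percentiles). No distributional assumption is needed,
  and the interval inherits whatever overdispersion the windows show. The
  estimator's API accepts the window-level profile for this purpose; the
  point estimate needs only the summary.

φ̂ is linear in observed depth and unbiased on simulated data
(|mean bias| < 0.01 at λ = 100 over 500 windows across 100 seeds, tested).

## Aneuploidy frequency f

Over a panel's strain × chromosome copy-number matrix with per-strain
baseline ploidy:

1. the aneuploid subset = strains with ≥1 chromosome differing from their
   baseline;
2. within that subset, f_c = (#strains abnormal at c) / (#strains normal
   at c), gains and losses counted identically.

f is an odds, not a proportion; it exceeds 1 when a chromosome is
abnormal in most aneuploid strains. Two published descriptions of this
statistic differ subtly (ratio to normal-copy strains vs. frequency among
aneuploid strains), so both alternative denominators (`aneuploid`, `all`)
are available behind a flag; the default combines the restriction to the
aneuploid subset with the abnormal/normal ratio. Missing cells are
excluded from both numerator and denominator; a chromosome abnormal in
every aneuploid strain has an undefined f (NaN), never a silent infinity.
When a ploidy column is absent the baseline is inferred as the per-strain
mode of chromosome copies, ties toward the smaller value.

The size association is a plain Pearson correlation of f against
chromosome length with the two-sided t-test on n − 2 df; it requires ≥3
chromosomes with defined f and non-constant inputs.

## Bootstrap enrichment engine

Feature values are computed **once per gene with respect to its true
chromosome** (an intra-chromosomal interaction stays intra when the gene
is later drawn into a random set); the resampling then only permutes
which genes form a set. This keeps the null well defined: the question is
"is the mean over this chromosome's genes unusual for a set of n_c
genes", not "what would interactions look like on a fictional
chromosome".

Per (chromosome, feature): draw `reps` (default 10,000) sets of size n_c
without replacement from the full gene universe, record each set's mean,
and report the CDF of the observed mean. The default CDF is the normal
approximation Φ((x̄ − μ₀)/σ₀) with μ₀, σ₀ (ddof = 1) from the resamples —
this mirrors standard practice and is accurate for the feature shapes
involved (means over tens-to-hundreds of counts or flags); an empirical
CDF with midpoint tie correction is available for strongly skewed
features, and the two agree within 0.02 on smooth nulls at reps = 20,000
(tested). Degenerate nulls (σ₀ = 0, e.g. a constant feature) map to 0.5
at the null mean and to 0/1 by sign otherwise.

Sums and means are interchangeable: each set has exactly n_c genes, so
the sum is the mean scaled by a constant, and both the z-score and the
empirical rank are scale-invariant — the two CDF matrices are identical
draw-for-draw under a shared seed (tested).

Sampling is vectorized (random keys + argpartition per rep, chunked to
bound memory); argpartition of distinct uniforms is an exact uniform
without-replacement draw. One shared seed governs a whole matrix, with a
deterministic `SeedSequence` substream per (chromosome, feature) in fixed
order, so any single cell can be recomputed in isolation.

The 17 default features are interaction counts (physical: all/intra/
inter; genetic: the same three partitions × all/positive/negative
scores), complex membership (0/1) and four binary stress up-regulation
flags (glycerol, lactate, ethanol, oxidative). No multiple-testing
correction is applied — the matrix is descriptive; a BH companion can be
added downstream.

Heatmap ordering uses average-linkage hierarchical clustering on
1 − Pearson correlation, rows and columns independently; only the leaf
ordering is produced (values are not re-normalised). Zero-variance
vectors get the maximal distance 2 with a warning. The scipy leaf order
is verified against a hand-written naive agglomeration oracle on random
matrices.

## Least-epistasis network

S(i, j) sums signed genetic-interaction scores over all retained pairs
spanning chromosomes i ≠ j; positive and negative scores offset. Scores
enter unfiltered by significance or magnitude (a filter is available but
off by default, since plain summation is the documented procedure).
Duplicate unordered gene pairs are collapsed to their mean score at load
time, which also guarantees exact symmetry of S. Each chromosome then
points at argmin_j |S(i, j)|, ties broken toward the lexicographically
smallest target so the network is deterministic. The construction is
scale-invariant (positive rescaling of all scores changes nothing) but
not shift-invariant — adding a constant moves which sum is nearest zero —
both tested. Hubs are the top in-degree nodes (ties by id); mutual edges
are reported explicitly since reciprocal "most neutral" pairs are a
finding of interest.

## Synthetic data

The generators produce the statistical structure the pipeline assumes,
not sequence-level realism:

- **Genome**: 16 chromosomes with the S288C lengths by default; gene
  counts Poisson with density 50 genes/100 kb (≈6000 genes over 12 Mb,
  the reference density); uniform gene placement, fixed 1 kb gene length.
  Gene overlap is permitted (no statistic depends on it).
- **Copy numbers**: each strain × chromosome cell deviates from baseline
  with a per-chromosome probability; default probabilities are inversely
  proportional to length, scaled to 0.30 at the smallest chromosome so
  the planted range matches the 0.05–0.33 spread seen in real panels.
  Gains are twice as likely as losses (gains are observed to be the more
  frequent event; the exact odds are configurable), losses floor at 0.
- **Interactions**: pairs uniform over genes at a configurable expected
  rate per gene; genetic scores Normal(μ_block, σ) with planted
  per-chromosome-pair means (default 0 everywhere, σ = 0.1).
- **Expression**: Bernoulli flags at a base rate 0.1 with planted
  per-condition enriched chromosomes (rate × factor, clipped to 1).
- **Depth**: window base counts Poisson(λ × copies × φ × window length);
  overdispersion a > 0 switches to a gamma-Poisson mixture with
  Var = μ + aμ². Default λ = 100 per haploid copy, 1 kb windows. φ acts
  on whole chromosomes only.

Every generator is a pure function of (config, seed), with independent
derived substreams per table. What the simulations do **not** contain —
mappability/GC structure, segmental events, correlated aneuploidies,
realistic interaction-network topology — bounds what passing tests show:
they validate the estimators and the engine under their stated model, not
robustness to real-data artefacts.

## Problem sizes in the bundled checks

The bundled tests and the acceptance script run at reduced but still
informative sizes chosen as the package's own defaults for quick
verification: bootstrap calibration at 16 chromosomes × 17 iid features
with reps = 2000 on a ~1200-gene genome; φ recovery over 80 simulated
chromosomes of 1000 windows; planted-rate recovery over 2000 strains;
network-oracle agreement over 100 random instances of ≤6 chromosomes.
Production runs use the full defaults (reps = 10,000, full gene density).

## Known limitations

- No GC/mappability correction and no segmental CNV segmentation; φ is a
  whole-chromosome average.
- The f statistic requires pre-collapsed whole-chromosome calls and a
  meaningful baseline ploidy; highly mosaic panels violate its premise.
- The normal-CDF option can misestimate tail CDFs for very small n_c
  combined with very sparse features; use the empirical method there.
- The least-epistasis rule ranks only |S|; it ignores the number of pairs
  behind each sum, so sparsely covered chromosome pairs can win argmin by
  chance. The optional magnitude filter mitigates this.
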