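# karyoshift

Aneuploidy pattern analysis for unstable hybrid yeast genomes.

Interspecific *Saccharomyces* hybrids (e.g. *S. cerevisiae* ×
*S. kudriavzevii* allotriploids used in winemaking) can lose or gain whole
chromosomes within a handful of generations, so a sequenced culture is
really a mixed population of karyotypes. `karyoshift` provides the four
statistics used to dissect such instability:

1. **Chromosome population frequency (φ)** — from windowed read depth.
   With `B` total sequenced bases over a model genome of `G` bp (one entry
   per haploid sub-genome copy), the expected per-copy coverage is
   `E = B / G`, and for each chromosome `φ̂ = mean depth / E`: the fraction
   of cells in the population still carrying that chromosome. Chromosomes
   are labelled `present`, `low_frequency` or `lost` by configurable
   thresholds, with a bootstrap CI over windows.
2. **Aneuploidy frequency (f)** — over a strain panel's copy-number calls,
   restricted to strains aneuploid for ≥1 chromosome:
   `f_c = n_abnormal(c) / n_normal(c)`, counting gains and losses alike.
   `f` is an abnormal:normal odds (it can exceed 1). A Pearson correlation
   of `f` against chromosome length quantifies the small-chromosome bias.
3. **Bootstrap gene-feature enrichment** — for each chromosome `c` with
   `n_c` genes and each gene-level feature (physical/genetic interaction
   counts split by sign and intra/inter partner, complex membership,
   stress up-regulation flags), a null is built from 10,000 random gene
   sets of size `n_c` drawn without replacement from the genome; the
   reported value is the CDF of the observed per-gene mean under that
   null, `Φ((x̄ − μ₀)/σ₀)` — near 0 depleted, near 1 enriched. Rows and
   columns are ordered by average-linkage clustering on 1 − Pearson
   correlation.
4. **Least-epistasis network** — signed genetic-interaction scores are
   summed over every inter-chromosomal gene pair into `S(i, j)` (positive
   epistasis compensating negative), and each chromosome points an arrow
   at the partner with `|S|` nearest to zero. In-degree hubs are the
   recurrently "most neutral" partners.

A seeded synthetic-data module generates every input type with planted,
recoverable structure, so the full pipeline is testable offline.

## Worked example

```
$ karyoshift simulate --seed 1 --out demo
fixtures written to demo/fixtures
$ karyoshift coverage --depth demo/fixtures/depth.tsv \
    --genome demo/fixtures/genome.tsv \
    --read-pairs 250000 --read-length 100 --sizes 1000000 --out -
```

yields (first rows)

```
chrom	mean_depth	median_depth	n_windows	phi_hat	phi_hat_clipped	ci_low	ci_high	state
chrI	100.00431764675221	100.01	231	2.0000863529350443	1.0	1.9992073092519214	2.0009179164949487	present
chrII	99.9945153864316	99.9855	814	1.999890307728632	1.0	1.9994517218993622	2.0003247032651896	present
```

Here the simulated strain is diploid for every chromosome while the
expected coverage was computed per haploid copy, so `φ̂ ≈ 2` per copy and
the clipped estimate saturates at 1: every cell carries the chromosome.
For the published hybrid sequencing run (116,062,916 pairs of 100 bp reads
over a ~36 Mb triploid model genome) the same arithmetic gives an expected
645× per haploid copy, and an observed 5.6× mean depth corresponds to
`φ̂ ≈ 0.0087` — the chromosome survives only in a small minority of cells.

The other stages run analogously (`karyoshift aneuploidy`, `enrich`,
`episnet`), or end-to-end from a YAML config with `karyoshift run`.

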