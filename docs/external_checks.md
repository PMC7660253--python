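# Reproducing the published numbers from public sources

The test suite runs entirely on synthetic data. The published strain-panel
and sequencing-run numbers can be reproduced from their public sources with
the recipes below; they require downloads and are therefore not part of the
automated suite.

## Chromosome copy-number panel (1011 S. cerevisiae genomes)

Source: the chromosome copy-number calls distributed at
`http://1002genomes.u-strasbg.fr/files/`.

1. Download the per-strain chromosome copy-number table and reshape it to
   the copy-number dialect: first column `strain`, one column per
   chromosome (`chrI` … `chrXVI`), plus a `ploidy` column with each
   strain's overall ploidy. Segmental calls must be collapsed to
   whole-chromosome copy numbers first (the statistic is defined on whole
   chromosomes).
2. Run:

   ```
   karyoshift aneuploidy --copies panel.tsv --genome s288c_map.tsv \
       --denominator normal --out f_per_chromosome.tsv
   ```

   where `s288c_map.tsv` carries the S288C chromosome lengths (the bundled
   simulator defaults list them; a map without gene rows suffices).

Expected output at the published panel: 217 strains aneuploid for at least
one chromosome; per-chromosome frequencies near f = 0.33 (chrI),
0.27 (chrIX), 0.15 (chrIII), 0.14 (chrVIII), 0.13 (chrXI), 0.06 (chrVI)
and 0.05 (chrIV); and a size–frequency Pearson correlation near r = −0.79
(P ≈ 2.8e−4) printed on stderr.

## Sub-genome coverage of the hybrid sequencing run

Sources: SRA run `SRR9925222` (Illumina, BioProject PRJNA611499) and the
S. kudriavzevii IFO1802 reference assembly.

1. Map the reads with `bowtie2` (default settings) to IFO1802, filter to
   uniquely mapped reads with `samtools view -q`, and produce per-base
   depths with `samtools depth -a`.
2. Convert to windows and estimate per-chromosome population frequencies:

   ```
   karyoshift coverage --depth depth.tsv --dialect depth --window-size 1000 \
       --genome ifo1802_map.tsv --read-pairs 116062916 --read-length 100 \
       --sizes 12000000,12000000,12000000
   ```

Expected output: mean coverages near 5.6x, 10.4x and 2.5x for chromosomes
III, VI and XI respectively, an expected per-haploid-copy coverage of
645x, and correspondingly small phi estimates (state `low_frequency`).

## File-shape example

`docs/examples/synthetic_panel_example.tsv` is a small synthetic stand-in
showing the exact panel dialect the recipes above produce; it contains no
real strain data.
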