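# ssrkit

A toolkit for developing microsatellite (SSR) markers from a partial
genome assembly, modeled on the marker-development pipelines used for
non-model plant species such as ruzigrass (*Brachiaria ruziziensis*), a
diploid tropical forage grass.  Given assembled contigs and their read
depths, `ssrkit` mines perfect di-, tri- and tetra-nucleotide tandem
repeats, applies coverage-tiered locus selection, prepares primer-design
candidates, assembles fluorescently labeled markers into multiplex PCR
panels, snaps raw electrophoretic fragment sizes onto repeat-unit
lattices (allelic binning), and computes the marker descriptive
statistics breeders report: expected and observed heterozygosity,
polymorphism information content, allele-frequency classes, expected-size
concordance, cross-species transferability, and the attrition arithmetic
of marker development.

It is intended for researchers building first marker sets for species
with little genomic information: the input is plain FASTA plus a
two-column coverage table, the outputs are plain TSV/CSV/GFF3/Boulder-IO
text files, and every step is available both as a Python API and as a
`ssrkit` subcommand.

## The statistics at the core

For a marker with allele frequencies *p₁ … p_k* estimated by direct
counting (two allele copies per genotyped diploid, missing calls
excluded):

- expected heterozygosity (Nei's gene diversity): `He = 1 − Σ pᵢ²`
- observed heterozygosity: `Ho = (# heterozygous individuals) / (# genotyped)`
- polymorphism information content (Botstein):
  `PIC = 1 − Σ pᵢ² − Σ_{i<j} 2 pᵢ² pⱼ²`

Repeat motifs are classified canonically: a motif class is the
lexicographically smallest string (A<C<G<T) over all rotations of the
motif and of its reverse complement, so GA, CT and TC are all class AG.
Allelic binning fits, per marker, the offset of the lattice
`offset + k·period` that minimizes the squared distances of observed
fragment sizes to their nearest lattice points (solved exactly; the
objective is piecewise quadratic in the offset).

## Worked example

Simulate a small contig set with planted repeats, detect and select
loci, and genotype a panel of 11 individuals:

```sh
$ ssrkit --seed 7 simulate genome --n-contigs 20 \
      --fasta contigs.fa --coverage coverage.tsv --truth truth.tsv
20 contigs, 45 planted loci (seed 7)

$ ssrkit find contigs.fa coverage.tsv --out catalog.tsv --summary summary.csv
45 loci in 20 contigs -> catalog.tsv

$ ssrkit select catalog.tsv contigs.fa coverage.tsv --tier 1 --out tier1.tsv
tier 1: 35/45 loci on 17/20 contigs -> tier1.tsv
```

The detector found exactly the 45 planted loci; tier-1 selection keeps
the 35 loci on the 17 contigs longer than 200 bp with depth ≥ 10×.
`summary.csv` partitions the catalog by canonical motif class
(`AG,2,6,0.133333` means six AG-class dinucleotide loci, 13.3% of the
catalog).  Genotyping statistics:

```sh
$ ssrkit --seed 7 simulate genotypes --n-markers 6 --n-individuals 11 \
      --out geno.csv --raw raw.csv
$ ssrkit stats geno.csv --out stats.csv --freq-db freqs.csv
6/6 polymorphic; mean He 0.590, mean Ho 0.623, mean PIC 0.533 -> stats.csv
```

Each row of `stats.csv` carries the marker's allele count, observed size
range, He, Ho and PIC — e.g. `Sim0001,3,275.0,279.0,0.595,0.600,0.528,1,0`
is a polymorphic tri-allelic marker with He 0.595.  Attrition arithmetic
answers planning questions such as "how many primer pairs must be tested
to end with 198 polymorphic markers if half are lost at that step":

```sh
$ ssrkit attrition --target 198 --rate 0.5 --step-name polymorphic
polymorphic  396
target       198
```

The package also bundles a published validation set — the 30 most
informative ruzigrass markers arranged in 11 multiplex panels with their
primers, dyes, size ranges and statistics — as
`ssrkit.datasets.load_ruzigrass_top30()`; their mean PIC is 0.803
(range 0.74–0.87).

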