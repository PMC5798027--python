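# cnscan

Per-base cross-species conservation scoring and conserved noncoding
sequence (CNS) discovery, built around reference-anchored multiple
alignments (MAF).

The conservation score of a reference base under a clade is the number of
clade species whose aligned base is identical to the reference, divided by
the clade size, giving a value in [0, 1]. CNSs are called from the score
track as non-coding runs at score >= 0.7, merged across gaps of <= 3 bp and
filtered to >= 6 bp (all parameters configurable). On top of that the
toolkit provides:

- **alnio** — readers/writers for MAF 1.0, GFF3, VCF 4.x, BED6, bedGraph,
  FASTA and 2-column IUPAC motif tables; all internal coordinates are
  0-based half-open.
- **conscore** — per-base matched/aligned counting per clade
  (`score_genome`), with exact-rational threshold comparisons and per-region
  coverage curves.
- **cnscall** — CNS calling, region partitioning (CDS/UTR5/UTR3/intron/
  intergenic), summaries, constrained-bp fractions, downstream-gene
  association, bigfoot genes and feature overlap.
- **genescore** — gene-level mean scores, highly-conserved and
  clade-exclusive gene sets, TSS/TES meta-profiles, exon-rank profiles.
- **popsel** — conservation classes for SNP sites, folded MAF spectra, SNP
  depletion folds, invariant sites, effect tabulation, intra/inter variation
  correlation and outlier gene lists.
- **motifscan** — IUPAC motif scanning (both strands, overlapping hits) and
  binomial z / chi-squared enrichment of CNS categories vs a disjoint
  genomic background.
- **simgen** — deterministic synthetic-data generator (reference, alignment
  blocks, gene models, SNPs, planted motifs) with truth records used by the
  recovery tests.

## CLI

```sh
cnscan simulate --config sim.yaml --out sim/
cnscan score  --maf sim/aln.maf --clades sim/clades.tsv --clade all \
              --ref-name refsp --fasta sim/ref.fa --out out/
cnscan call   --maf sim/aln.maf --clades sim/clades.tsv --clade all \
              --ref-name refsp --fasta sim/ref.fa --gff sim/genes.gff3 \
              --threshold 0.7 --merge-gap 3 --min-len 6 --out out/
cnscan annotate --cns out/cns_all.bed --gff sim/genes.gff3 \
              --fasta sim/ref.fa --ref-name refsp --out out/
cnscan gene-scores ... --cutoff 0.9 --out out/
cnscan popsel ... --vcf sim/snps.vcf --out out/
cnscan motifs --cns out/cns_all.bed --fasta sim/ref.fa \
              --motifs sim/motifs.tsv --out out/
cnscan run-all --config run.yaml --out out/   # whole pipeline + manifest
```

Exit codes: 0 ok, 1 bad input, 2 internal error.

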