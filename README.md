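# abtmap

Nucleotide-level breakpoint mapping for **apparently balanced translocations
(ABTs)** from whole-genome mate-pair sequencing signal.

An ABT exchanges segments between two non-homologous chromosomes with no
visible gain or loss of material. Mapping its breakpoints to the base pair
matters clinically: a breakpoint can disrupt a gene, sit inside repeats, or
displace conserved regulatory elements, and in familial cases the same
translocation is carried by affected and unaffected relatives — so the
question is whether the junctions are truly identical between carriers and
whether any *patient-specific* structural variant exists besides the shared
translocation.

`abtmap` implements the full analysis path as a library:

- **simulate** — a mate-pair read simulator with engineered rearrangements
  and complete ground truth: multi-chromosome genomes, reciprocal
  translocations with configurable junction micro-features (microhomology
  0–10 bp, per-chromosome deletions/duplications, untemplated insertions),
  2–4 kb inserts sequenced as 100 bp pairs, PCR duplicates, multimapping
  reads in repeat regions, and decoy SVs for filter testing.
- **detect** — classification of aligned pairs (concordant / interchromosomal
  / orientation anomaly / insert anomaly) and single-linkage clustering of
  discordant pairs into junction intervals with read-pair support.
- **filter** — support threshold (≥ 5 independent pairs), ≥ 80 % overlap
  exclusion against a known-SV catalogue, and family comparison to isolate
  patient-specific variants.
- **junction** — split alignment of a junction-spanning sequence against the
  two partner flanks. With junction sequence *J*, let *L* be the maximal
  prefix of *J* matching partner A and *R* the maximal suffix matching
  partner B: *L + R − |J| > 0* is **microhomology** (breakpoint ambiguous
  over *L+R−|J|+1* placements), *< 0* leaves an **untemplated insertion**,
  *= 0* is a blunt join. Reconciling the two reciprocal derivatives yields
  per-chromosome deletions (bases on neither derivative) and duplications
  (bases on both), and a per-member concordance verdict.
- **annotate** — disrupted genes with strand-aware intron/exon indices,
  repeat overlap, conserved non-coding elements within ±1 Mb, and a repair-
  mechanism call: long (≥ 50 bp, ≥ 90 % identity) shared flank homology →
  NAHR; ≥ 2 bp junction microhomology → MHMR/MMEJ; blunt joins, 1 bp
  homology or untemplated insertions → NHEJ.
- **pipeline** — simulate → detect → filter → refine → annotate → report,
  fully deterministic under a seed, with every intermediate written as plain
  text (FASTA, pair TSV, BEDPE, filter report, VCF 4.2 breakends).

## Worked example

`examples/05_full_pipeline.py` runs a two-member family carrying the same
t(chr1;chr2) with a 1 bp / 2 bp microhomology pair, 3 bp deletions on both
chromosomes, and three decoy deletions (one in the known-SV catalogue, one
shared by both members, one private to the proband):

```
member   chrom  mps_junction        read_pairs  breakpoint_interval  indel         microhomology  disrupted_genes   mechanism
proband  chr1   chr1:399056–401258  11          chr1:400000–400004   3bp-TGC del.  T              —                 NHEJ
proband  chr2   chr2:299386–300853  9           chr2:300000–300004   3bp-TAT del.  GC             GENE1 (intron 1)  MHMR
mother   chr1   chr1:399968–401540  12          chr1:400000–400004   3bp-TGC del.  T              —                 NHEJ
mother   chr2   chr2:299934–301148  10          chr2:300000–300004   3bp-TAT del.  GC             GENE1 (intron 1)  MHMR

family concordance: identical
patient-specific SVs: ['proband_deletion_5']
```

Reading the report: the clustered mate-pair estimate (`mps_junction`, a few
hundred bp to a couple of kb wide) differs per member because read sampling
differs, but the refined breakpoint interval is identical — the junction
spans chr1:400000–400004, a 5 bp interval covering the 3 bp deleted bases
plus the two retained flank bases. One junction carries 1 bp microhomology
(below the 2 bp MHMR minimum → NHEJ), the other a 2 bp run → MHMR. The
chr2 breakpoint falls in intron 1 (transcription order, minus strand) of the
synthetic gene model. Of the three decoys, only the proband's private
deletion survives filtering.

`examples/03_refine_junction.py` prints the junction itself:

```
chrA:150000  TCACGCCGCTAGTACACTAGCCAT--------------------------
TCACGCCGCTAGTACACTAGC[CAT]CCATCCTCCTCATGGCGTTGAGTA
--------------------------CCATCCTCCTCATGGCGTTGAGTA  chrB:90001
```

The bracketed `CAT` is shared by both reference flanks, so the breakpoint is
ambiguous over 4 placements; the canonical call anchors it to the prefix
chromosome.

A thin CLI mirrors the library (`abtmap simulate|detect|filter|run|check-fixture`).

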