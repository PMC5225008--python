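# Methods

## The signal being modelled

A long-insert mate-pair library circularises 2–4 kb genomic fragments and
sequences 100 bp from each end, so each aligned pair brackets a span far
longer than the reads themselves. A reciprocal translocation t(A;B) produces
two derivative chromosomes, each with one junction; fragments spanning a
junction yield pairs whose mates align to the two partner chromosomes. The
package maps those junctions in two stages that the output keeps visible as
two coordinate columns: a clustered mate-pair estimate (tens of bp to ~kb
wide) and a nucleotide-level refinement of a junction-spanning sequence.

All internal coordinates are 1-based and fully closed, matching the notation
breakpoint reports print (`chr:start–end`, width = end − start + 1); BED-family
files are converted exactly once at the I/O boundary.

## Simulator

`generate_reference` draws i.i.d. uniform bases per chromosome (defaults:
chr1/chr2/chr3 of 3/2/1 Mb). Designated repeat regions are tiled with one
random motif (default 300 bp) so reads inside them genuinely multimap; a read
whose midpoint falls in a repeat of *c* motif copies is flagged non-unique
with probability 1 − 1/*c*.

A rearrangement spec fixes, per chromosome X, the last base retained by the
prefix-bearing derivative (a_X) and the first base retained by the other
derivative (b_X + 1): b_X > a_X is a deletion (bases on neither derivative),
b_X < a_X a duplication (bases on both), b_X = a_X balanced. Per junction it
fixes either a microhomology length or an untemplated insertion (mutually
exclusive).

Microhomology is engineered by rewriting reference bases so the two partner
flanks genuinely share the run — the downstream placement ambiguity is real,
not cosmetic. The requested features translate into a small system of
equality and inequality constraints over individual bases (the run itself,
plus guard bases that stop extension exactly at the requested length);
constraints are solved by union-find plus greedy 4-letter colouring,
preferring the existing random base. Some requests are structurally
impossible — a fully balanced translocation provably has equal microhomology
at its two junctions, and an indel shorter than an adjacent microhomology run
can couple the two junctions into a contradiction — and these raise
`InfeasibleSpec` rather than silently degrading; the random spec sampler
draws until feasible. After construction every feature is re-measured from
the final sequences and asserted equal to the request.

Read simulation draws insert sizes from a truncated normal (mean 3000 bp,
sd 400, hard bounds [2000, 4000] — the bounds are honoured exactly) and
fragment starts uniformly. Pairs are emitted as post-alignment records with
truthful coordinates; alignment itself is out of scope, so a read crossing a
junction is clipped to its longest single-segment match, as a local aligner's
primary alignment would be. The mate orientation convention is configurable
(`rf`, the processed mate-pair layout, is the default; `fr` covers plain
paired-end) and the detector reads the convention from configuration rather
than assuming one aligner's dialect. PCR duplicates are re-emissions of
already-drawn fragments under fresh, higher pair ids, so duplicate removal
(keep the lowest id per coordinate signature) deterministically retains the
original. Sequencing errors are not applied to pair coordinates; the
configured error rate instead perturbs extracted junction evidence to
exercise the mismatch-tolerant refinement mode.

What the simulator does **not** model: coverage and GC bias, chimeric library
artefacts, indel-containing alignments, mapping-quality gradients, the
~200–400 bp post-circularisation fragments (physical-coverage arithmetic uses
the 2–4 kb insert throughout), and real repeat taxonomy. Passing tests
therefore demonstrate correctness of the algorithms under clean mapping
statistics, not robustness to every artefact of a real library.

## Detection and clustering

After duplicate/uniqueness filtering, a pair is interchromosomal, an
orientation anomaly, an insert anomaly (outside the configured bounds), or
concordant. Discordant pairs are grouped by chromosome pair and strand
combination — for interchromosomal pairs the mate carrying the convention's
"fragment-left" strand sits on the junction's prefix chromosome, which is
what separates the two reciprocal derivatives — then single-linkage
clustered with a distance cap on **both** partners (default = the upper
insert bound: a pair cannot span farther than its insert).

Each pair constrains the breakpoint: on the prefix side it lies at or beyond
the mate's inner end, but within the insert capacity left after the other
mate's aligned length; symmetrically on the suffix side. The cluster interval
is the intersection of these per-pair ranges — adding pairs can only narrow
it, and the true breakpoint is guaranteed inside as long as inserts respect
the hard bounds — with a fallback to the span of inner read ends if an
outlier empties the intersection. Support is the count of distinct
contributing pairs; the ≥ 5 support threshold is applied after duplicate
removal, since duplicates are not independent observations.

## Junction refinement and the placement convention

The junction-spanning sequence (in simulation, a window of the derivative
chromosome centred on the junction — the in-silico stand-in for a
Sanger-sequenced PCR amplicon) is anchored in each partner flank by an exact,
unique 20-mer and extended: maximal prefix match length L against partner A,
maximal suffix match R against partner B. L + R − |J| > 0 bases of overlap
are microhomology (ambiguity over overlap + 1 placements); a gap is an
untemplated insertion; equality is a blunt join. The tolerant mode (roughly
one mismatch per 50 aligned bases, extension must end in 8 exact matches so
it cannot creep past the junction on 25 %-matching random sequence) exists
for error-bearing evidence; exact matching is the default.

Where microhomology makes the placement ambiguous, the canonical placement
**anchors the shared bases to the prefix chromosome** of each junction
(rightmost on the prefix coordinate); the full ambiguity interval is always
reported alongside. This convention was chosen over leftmost normalisation
deliberately: under prefix anchoring the per-chromosome deletion and
duplication strings produced by reconciling the two reciprocal junctions are
independent of the microhomology lengths, and the reported breakpoint
interval (last base retained by one derivative to first base retained by the
other, inclusive) obeys simple arithmetic — width = deletion + 2, balanced
→ 2, duplication → its own length. Under leftmost placement the reconciled
deletion length would depend on the difference of the two junctions'
microhomologies, which is not how breakpoint reports are written in
practice. Duplication vs microhomology is decided by evidence class:
sequence shared between the two *partner references* at one junction is
microhomology; sequence retained by *both derivatives* at the same reference
locus is a duplication — only cross-derivative reconciliation can tell them
apart. All indel strings are read from the reference + strand.

Family concordance is exact equality of breakpoints, microhomology,
insertion and indel strings across members; any difference is enumerated and
the verdict is discordant.

## Annotation and mechanism classification

Gene disruption is assessed at the breakpoint-interval midpoint (intervals
are a few bp wide, so midpoint error is negligible; intervals straddling an
exon boundary are flagged ambiguous), with intron/exon indices counted in
transcription order — for a minus-strand gene the genomically last exon is
exon 1. Repeat overlap is strict; the CNE window (default 1 Mb) is closed at
both ends.

Mechanism calls make an ordinarily qualitative argument explicit. Flanks of
f = 500 bp around the two breakpoints are scanned for the longest equal-length
substring pair at Hamming identity ≥ 90 % (per alignment diagonal, the
longest window with match fraction above threshold via prefix sums); a hit of
≥ 50 bp is NAHR evidence. Otherwise microhomology ≥ 2 bp → MHMR; blunt
joins, 1 bp homology, untemplated insertions or small imbalances → NHEJ.
These thresholds (Lmin = 50, Imin = 0.9, Mmin = 2, f = 500) are module
parameters with documented defaults, chosen as a reproducible proxy for a
narrative distinction; no empirical calibration is claimed for them.

## Pipeline, determinism and problem sizes

The pipeline runs each family member's library independently from the same
rearranged genome (members share the translocation; decoy SVs are per
member), derives per-member read seeds from the run seed, and writes every
intermediate as plain text. Reruns are byte-identical; `--resume` leaves
existing outputs untouched. The shared translocation is deliberately *not* a
patient-specific survivor — family comparison removes it, mirroring the
logic that a variant shared with unaffected carriers cannot explain a
discordant phenotype — while junction analysis processes it for all members.

Default problem sizes were chosen so the full validation remains laptop-
scale: recovery runs use a 6 Mb three-chromosome genome at 10× physical
coverage (≈ 20 000 pairs per member, expected junction-spanning support
≈ pair_count × (insert − 2·read_length) / genome_length ≈ 9–10), repeated
over 25 seeds; signature recovery uses 200 random specs with features in
0–10 bp; filter checks use 1000 randomised cases against brute-force
dispositions. At these sizes every recovery metric measures 100 %.

## Known limitations

- Only cis-joined (+/+) reciprocal junctions are simulated; the refiner
  accepts reverse-oriented flanks but that path is not exercised end to end.
- Three-or-more-way rearrangements, inversion breakpoint refinement and
  coverage-based CNV calling are out of scope; orientation-anomaly and
  insert-anomaly clusters are emitted but only translocation and deletion
  clusters flow through refinement and filtering.
- The mismatch-tolerant refinement requires clean 20-mer anchors; evidence
  with errors inside an anchor raises an explicit unanchored-junction error
  rather than guessing.
- Heterozygosity is not modelled: reads are drawn from the derivative-bearing
  haplotype only. Concordant coverage from the normal homolog would not
  change discordant-pair clustering, but allele-fraction effects are absent.
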