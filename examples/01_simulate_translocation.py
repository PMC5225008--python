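"""Engineer a reciprocal translocation with junction micro-features.

Builds a small two-chromosome genome, applies a t(A;B) translocation carrying
3 bp of microhomology at one junction, a 2 bp untemplated insertion at the
other, and a 3 bp deletion on chromosome A, then prints the ground truth the
simulator guarantees.
"""

import abtmap as m

config = m.SimulationConfig(seed=11, chromosome_lengths={"chrA": 300_000, "chrB": 200_000})
genome = m.generate_reference(config)

spec = m.RearrangementSpec(
    kind="reciprocal_translocation",
    chrom_a="chrA", pos_a=150_000, chrom_b="chrB", pos_b=90_000,
    junction_ab=m.JunctionFeatures(microhomology=3),
    junction_ba=m.JunctionFeatures(insertion="GC"),
    deletion_a=3,
)
result = m.apply_rearrangement(genome, spec)

for j in result.truth.junctions:
    print(
        f"{j.derivative}: {j.prefix_chrom}:{j.prefix_end} | {j.suffix_chrom}:{j.suffix_start}"
        f"  microhomology={j.microhomology!r}  insertion={j.insertion!r}"
    )
for indel in result.truth.indels:
    print(f"{indel.chrom}: {indel.kind}" + (f" {indel.sequence!r} at {indel.interval}" if indel.sequence else ""))

total_der = sum(c.length for c in result.sample.chromosomes.values())
print(f"derivative genome: {total_der:,} bp vs reference {genome.total_length():,} bp")
print("(the 3 bp deletion and 2 bp insertion account for the 1 bp net difference)")
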