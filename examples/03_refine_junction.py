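"""Refine a junction to the nucleotide and characterise its signature.

Extracts a junction-spanning sequence from the derivative chromosome (the
in-silico analogue of a Sanger-sequenced PCR amplicon), split-aligns it
against the two partner reference flanks, reconciles the reciprocal
derivatives into per-chromosome indels, and classifies the repair mechanism.
"""

import abtmap as m

config = m.SimulationConfig(seed=11, chromosome_lengths={"chrA": 300_000, "chrB": 200_000})
genome = m.generate_reference(config)
spec = m.RearrangementSpec(
    kind="reciprocal_translocation", chrom_a="chrA", pos_a=150_000, chrom_b="chrB", pos_b=90_000,
    junction_ab=m.JunctionFeatures(microhomology=3), junction_ba=m.JunctionFeatures(insertion="GC"),
    deletion_a=3,
)
result = m.apply_rearrangement(genome, spec)

refined = {}
for tj in result.truth.junctions:
    J = m.extract_junction_sequence(result.sample, tj, window=400)
    region_a = m.GenomicInterval(tj.prefix_chrom, tj.prefix_end - 2500, tj.prefix_end + 2500)
    region_b = m.GenomicInterval(tj.suffix_chrom, tj.suffix_start - 2500, tj.suffix_start + 2500)
    refined[tj.derivative] = m.refine_breakpoint(
        J, result.reference, tj.prefix_chrom, region_a, tj.suffix_chrom, region_b,
        derivative=tj.derivative,
    )

rec = m.reconcile_derivatives(refined["der(chrA)"], refined["der(chrB)"], result.reference)
for chrom, r in m.breakpoint_interval_report(rec).items():
    info = rec.reconciliation[chrom]
    indel = f"{len(info.sequence)}bp-{info.sequence} {info.kind}" if info.sequence else "balanced"
    print(f"{chrom}: breakpoint interval {r} (width {r.width})  {indel}")

for der, j in refined.items():
    call = m.classify_mechanism(j, result.reference)
    print(f"{der}: microhomology={j.microhomology!r} insertion={j.insertion!r} -> {call.label}")

print()
print(m.render_junction(refined["der(chrA)"], result.reference, flank=24))
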