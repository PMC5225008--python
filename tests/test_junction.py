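import numpy as np
import pytest

import abtmap as m
from abtmap.junction import UnanchoredJunctionError

from oracles import split_decompositions

SLACK = 2500


def refine_from_truth(res, tj, window=400, **kw):
    J = m.extract_junction_sequence(res.sample, tj, window=window, **{
        k: v for k, v in kw.items() if k in ("error_rate", "seed")
    })
    ra = m.GenomicInterval(tj.prefix_chrom, max(1, tj.prefix_end - SLACK), tj.prefix_end + SLACK)
    rb = m.GenomicInterval(tj.suffix_chrom, max(1, tj.suffix_start - SLACK), tj.suffix_start + SLACK)
    return m.refine_breakpoint(
        J, res.reference, tj.prefix_chrom, ra, tj.suffix_chrom, rb,
        derivative=tj.derivative, tolerant=kw.get("tolerant", False),
    )


def literal_mh_genome(rng):
    """Two chromosomes whose breakpoint flanks share exactly 'TAA'."""
    bases = "ACGT"
    fill = lambda n: "".join(bases[i] for i in rng.integers(0, 4, n))
    a0, a1 = fill(3000), fill(3000)
    b0, b1 = fill(3000), fill(3000)
    chr_a = a0 + "GTAA" + "G" + a1
    chr_b = b0 + "CTAA" + "T" + b1
    pos = 3004  # both flanks end ...TAA
    return m.Genome({"chrA": chr_a, "chrB": chr_b}), pos, pos


def test_blunt_junction_extraction_matches_both_references(small_genome):
    spec = m.RearrangementSpec(
        kind="reciprocal_translocation", chrom_a="chrA", pos_a=60_000, chrom_b="chrB", pos_b=30_000
    )
    res = m.apply_rearrangement(small_genome, spec)
    tj = next(j for j in res.truth.junctions if j.derivative == "der(chrA)")
    J = m.extract_junction_sequence(res.sample, tj, window=200)
    assert len(J) == 200
    assert J[:100] == res.reference.fetch("chrA", tj.prefix_end - 99, tj.prefix_end)
    assert J[100:] == res.reference.fetch("chrB", tj.suffix_start, tj.suffix_start + 99)
    # and it is literally a substring of the derivative
    der = res.sample.chromosomes["der(chrA)"].sequence(res.reference)
    assert J in der


def test_insertion_appears_verbatim_in_junction_sequence(translocation_result):
    _, res = translocation_result
    tj = next(j for j in res.truth.junctions if j.insertion)
    J = m.extract_junction_sequence(res.sample, tj, window=300)
    assert tj.insertion in J
    refined = refine_from_truth(res, tj)
    assert refined.insertion == tj.insertion == "GC"
    assert refined.microhomology == ""
    assert refined.prefix.ambiguity.width == 1


def test_engineered_taa_microhomology_refines_to_taa(rng):
    genome, pos_a, pos_b = literal_mh_genome(rng)
    spec = m.RearrangementSpec(
        kind="reciprocal_translocation", chrom_a="chrA", pos_a=pos_a, chrom_b="chrB", pos_b=pos_b,
        junction_ab=m.JunctionFeatures(microhomology=3),
        junction_ba=m.JunctionFeatures(microhomology=3),
    )
    res = m.apply_rearrangement(genome, spec)
    tj = next(j for j in res.truth.junctions if j.derivative == "der(chrA)")
    assert tj.microhomology == "TAA"
    refined = refine_from_truth(res, tj)
    assert refined.microhomology == "TAA"
    assert refined.prefix.ambiguity.width == 4  # microhomology + 1
    assert refined.prefix.position == pos_a
    assert refined.suffix.position == pos_b + 1


def test_blunt_junction_is_blunt(small_genome):
    spec = m.RearrangementSpec(
        kind="reciprocal_translocation", chrom_a="chrA", pos_a=60_000, chrom_b="chrB", pos_b=30_000
    )
    res = m.apply_rearrangement(small_genome, spec)
    refined = refine_from_truth(res, res.truth.junctions[0])
    assert refined.microhomology == "" and refined.insertion == ""
    assert refined.prefix.ambiguity.width == 1


def test_unanchored_junction_raises(small_genome):
    with pytest.raises(UnanchoredJunctionError):
        m.refine_breakpoint(
            "ACGT" * 30, small_genome, "chrA", m.GenomicInterval("chrA", 1, 500),
            "chrB", m.GenomicInterval("chrB", 1, 500),
        )


def test_refinement_recovers_random_engineered_features(small_genome, rng):
    """refine + reconcile must reproduce every simulator feature string exactly."""
    for _ in range(40):
        spec = m.random_translocation_spec(rng, small_genome, "chrA", "chrB")
        res = m.apply_rearrangement(small_genome, spec)
        by_der = {j.derivative: j for j in res.truth.junctions}
        r_ab = refine_from_truth(res, by_der["der(chrA)"])
        r_ba = refine_from_truth(res, by_der["der(chrB)"])
        for refined, tj in ((r_ab, by_der["der(chrA)"]), (r_ba, by_der["der(chrB)"])):
            assert refined.microhomology == tj.microhomology
            assert refined.insertion == tj.insertion
            assert refined.prefix.position == tj.prefix_end
            assert refined.suffix.position == tj.suffix_start
        rec = m.reconcile_derivatives(r_ab, r_ba, res.reference)
        truth_indels = {i.chrom: i for i in res.truth.indels}
        for chrom, r in rec.reconciliation.items():
            assert (r.kind, r.sequence) == (truth_indels[chrom].kind, truth_indels[chrom].sequence)


def test_split_alignment_matches_enumeration_oracle(small_genome, rng):
    """For windows <= 300 bp the fast split must equal exhaustive decomposition."""
    for _ in range(25):
        spec = m.random_translocation_spec(rng, small_genome, "chrA", "chrB")
        res = m.apply_rearrangement(small_genome, spec)
        for tj in res.truth.junctions:
            window = int(rng.integers(120, 301))
            J = m.extract_junction_sequence(res.sample, tj, window=window)
            ra = m.GenomicInterval(tj.prefix_chrom, tj.prefix_end - SLACK, tj.prefix_end + SLACK)
            rb = m.GenomicInterval(tj.suffix_chrom, tj.suffix_start - SLACK, tj.suffix_start + SLACK)
            refined = m.refine_breakpoint(
                J, res.reference, tj.prefix_chrom, ra, tj.suffix_chrom, rb, derivative=tj.derivative
            )
            ref_a = res.reference.fetch(tj.prefix_chrom, ra.start, ra.end)
            ref_b = res.reference.fetch(tj.suffix_chrom, rb.start, rb.end)
            anchor_a = ref_a.find(J[:20])
            anchor_b_end = ref_b.find(J[-20:]) + 19
            oracle = split_decompositions(J, ref_a, anchor_a, ref_b, anchor_b_end)
            if oracle["placements"]:
                positions = [ra.start + anchor_a + i - 1 for i in oracle["placements"]]
                assert refined.prefix.ambiguity.start == min(positions)
                assert refined.prefix.ambiguity.end == max(positions)
                i_min, i_max = min(oracle["placements"]), max(oracle["placements"])
                assert refined.microhomology == J[i_min:i_max]
                assert refined.insertion == ""
            else:
                assert refined.microhomology == ""
                assert len(refined.insertion) == oracle["insertion"]["length"]
                assert refined.insertion in oracle["insertion"]["strings"]


def toy_reconciled(p_shift=0):
    """Hand-built reciprocal junctions over a literal toy genome."""
    genome = m.Genome({"chrX": "ACGTACGTAA" * 20, "chrY": "TTGCAGGCAT" * 20})
    p, q = 100, 80
    mk = lambda c, pos: m.BreakpointCall(c, pos, m.GenomicInterval(c, pos, pos))
    j_ab = m.RefinedJunction("der(chrX)", mk("chrX", p + p_shift), mk("chrY", q + 4), "", "")
    j_ba = m.RefinedJunction("der(chrY)", mk("chrY", q), mk("chrX", p + 4), "", "")
    return genome, m.reconcile_derivatives(j_ab, j_ba, genome)


def test_reconcile_deletion_duplication_and_balanced_arithmetic():
    genome, rec = toy_reconciled()
    # chrX: retained <= 100, resumed at 104 -> 3 bp deletion, interval width 5
    rx = rec.reconciliation["chrX"]
    assert rx.kind == "deletion"
    assert rx.sequence == genome.fetch("chrX", 101, 103)
    assert rx.interval == m.GenomicInterval("chrX", 100, 104) and rx.interval.width == 5
    # chrY: retained <= 80, resumed at 84 -> same pattern
    assert rec.reconciliation["chrY"].kind == "deletion"

    mk = lambda c, pos: m.BreakpointCall(c, pos, m.GenomicInterval(c, pos, pos))
    # duplication: derY resumes chrX at 99 while derX keeps through 100
    j_ab = m.RefinedJunction("der(chrX)", mk("chrX", 100), mk("chrY", 81), "", "")
    j_ba = m.RefinedJunction("der(chrY)", mk("chrY", 80), mk("chrX", 99), "", "")
    rec2 = m.reconcile_derivatives(j_ab, j_ba, genome)
    rx2 = rec2.reconciliation["chrX"]
    assert rx2.kind == "duplication" and rx2.sequence == genome.fetch("chrX", 99, 100)
    assert rx2.interval.width == 2
    ry2 = rec2.reconciliation["chrY"]
    assert ry2.kind == "balanced" and ry2.sequence == "" and ry2.interval.width == 2


def test_breakpoint_interval_widths_follow_indel_arithmetic(small_genome, rng):
    for _ in range(10):
        spec = m.random_translocation_spec(rng, small_genome, "chrA", "chrB")
        res = m.apply_rearrangement(small_genome, spec)
        by_der = {j.derivative: j for j in res.truth.junctions}
        rec = m.reconcile_derivatives(
            refine_from_truth(res, by_der["der(chrA)"]),
            refine_from_truth(res, by_der["der(chrB)"]),
            res.reference,
        )
        report = m.breakpoint_interval_report(rec)
        for chrom, d, u in (("chrA", spec.deletion_a, spec.duplication_a),
                            ("chrB", spec.deletion_b, spec.duplication_b)):
            if d:
                assert report[chrom].width == d + 2
            elif u:
                assert report[chrom].width == u if u > 1 else 1
            else:
                assert report[chrom].width == 2


def test_family_concordance_verdicts():
    _, rec1 = toy_reconciled()
    _, rec2 = toy_reconciled()
    report = m.compare_family({"proband": rec1, "mother": rec2})
    assert report.verdict == "identical" and report.diffs == []
    _, shifted = toy_reconciled(p_shift=1)
    report2 = m.compare_family({"proband": rec1, "mother": shifted})
    assert report2.verdict == "discordant"
    assert any("prefix" in d for d in report2.diffs)
    with pytest.raises(ValueError):
        m.compare_family({"proband": rec1})
    with pytest.raises(ValueError):
        m.compare_family({"proband": rec1, "mother": None})


def test_differing_microhomology_is_discordant():
    genome, rec1 = toy_reconciled()
    mk = lambda c, pos, w: m.BreakpointCall(c, pos, m.GenomicInterval(c, pos - w, pos))
    j_ab = m.RefinedJunction("der(chrX)", mk("chrX", 100, 1), mk("chrY", 84, 1), "A", "")
    rec3 = m.ReconciledTranslocation(j_ab, rec1.junction_ba, rec1.reconciliation)
    report = m.compare_family({"proband": rec1, "mother": rec3})
    assert report.verdict == "discordant"
    assert any("microhomology" in d for d in report.diffs)


def test_tolerant_mode_recovers_breakpoints_from_error_bearing_evidence(small_genome):
    spec = m.RearrangementSpec(
        kind="reciprocal_translocation", chrom_a="chrA", pos_a=60_000, chrom_b="chrB", pos_b=30_000
    )
    res = m.apply_rearrangement(small_genome, spec)
    tj = res.truth.junctions[0]
    clean = m.extract_junction_sequence(res.sample, tj, window=400)
    noisy = m.extract_junction_sequence(res.sample, tj, window=400, error_rate=0.004, seed=1)
    assert clean != noisy  # the evidence really carries errors
    refined = refine_from_truth(res, tj, error_rate=0.004, seed=1, tolerant=True)
    assert refined.prefix.position == tj.prefix_end
    assert refined.suffix.position == tj.suffix_start


def test_render_junction_marks_microhomology(translocation_result):
    _, res = translocation_result
    tj = next(j for j in res.truth.junctions if j.microhomology)
    refined = refine_from_truth(res, tj)
    text = m.render_junction(refined, res.reference)
    assert f"[{tj.microhomology}]" in text
    assert tj.prefix_chrom in text and tj.suffix_chrom in text
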