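import numpy as np
import pytest

import abtmap as m
from abtmap.annotate import MHMR, NAHR, NHEJ

from oracles import brute_longest_shared_run


def minus_strand_gene(chrom="chr7", start=1000, n_exons=4, exon_w=100, intron_w=900):
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append(m.GenomicInterval(chrom, pos, pos + exon_w - 1, "-"))
        pos += exon_w + intron_w
    return m.FeatureRecord(
        m.GenomicInterval(chrom, exons[0].start, exons[-1].end, "-"), "gene", "GENE_M",
        {"exons": exons},
    )


def test_minus_strand_intron_indexing():
    gene = minus_strand_gene()
    # between the last two genomic exons = between transcription exons 1 and 2
    last, second_last = gene.attributes["exons"][-1], gene.attributes["exons"][-2]
    mid = (second_last.end + last.start) // 2
    (d,) = m.genes_at_breakpoint(m.GenomicInterval("chr7", mid - 2, mid + 2), [gene])
    assert (d.gene, d.region, d.index) == ("GENE_M", "intron", 1)
    # inside the second genomic exon of a 4-exon minus gene = exon 3
    e2 = gene.attributes["exons"][1]
    (d2,) = m.genes_at_breakpoint(m.GenomicInterval("chr7", e2.start + 10, e2.start + 12), [gene])
    assert (d2.region, d2.index) == ("exon", 3)


def test_plus_strand_exon_indexing_and_intergenic():
    exons = [m.GenomicInterval("chr1", s, s + 99, "+") for s in (1000, 3000, 5000)]
    gene = m.FeatureRecord(m.GenomicInterval("chr1", 1000, 5099, "+"), "gene", "GENE_P",
                           {"exons": exons})
    (d,) = m.genes_at_breakpoint(m.GenomicInterval("chr1", 5010, 5012), [gene])
    assert (d.region, d.index, d.ambiguous) == ("exon", 3, False)
    assert m.genes_at_breakpoint(m.GenomicInterval("chr1", 900_000, 900_010), [gene]) == []


def test_exon_boundary_straddling_is_flagged_ambiguous():
    exons = [m.GenomicInterval("chr1", 1000, 1099, "+"), m.GenomicInterval("chr1", 2000, 2099, "+")]
    gene = m.FeatureRecord(m.GenomicInterval("chr1", 1000, 2099, "+"), "gene", "G", {"exons": exons})
    (d,) = m.genes_at_breakpoint(m.GenomicInterval("chr1", 1095, 1104), [gene])
    assert d.ambiguous


def test_repeats_strict_overlap():
    rpt = m.FeatureRecord(m.GenomicInterval("chr2", 1000, 1500), "repeat", "LINE-L1-L1M5")
    inside = m.repeats_at_breakpoint(m.GenomicInterval("chr2", 1200, 1210), [rpt])
    assert [r.name for r in inside] == ["LINE-L1-L1M5"]
    assert m.repeats_at_breakpoint(m.GenomicInterval("chr2", 1501, 1510), [rpt]) == []
    assert m.repeats_at_breakpoint(m.GenomicInterval("chr2", 100, 110), []) == []


def test_cne_window_boundaries():
    bp = m.Breakpoint("chr4", 5_000_000)
    near = m.FeatureRecord(m.GenomicInterval("chr4", 5_500_000, 5_500_200), "CNE", "cne_near")
    far = m.FeatureRecord(m.GenomicInterval("chr4", 6_500_000, 6_500_200), "CNE", "cne_far")
    edge = m.FeatureRecord(m.GenomicInterval("chr4", 6_000_000, 6_000_050), "CNE", "cne_edge")
    ann = m.cne_proximity(bp, [near, far, edge], window=1_000_000)
    names = {rec.name for rec, _ in ann.cnes}
    assert names == {"cne_near", "cne_edge"}  # closed window includes the 1.0 Mb boundary
    assert ann.position_effect
    dist = dict((rec.name, d) for rec, d in ann.cnes)
    assert dist["cne_near"] == 500_000
    empty = m.cne_proximity(bp, [far], window=1_000_000)
    assert not empty.position_effect and empty.cnes == []
    with pytest.raises(ValueError):
        m.cne_proximity(bp, [near], window=0)


def test_annotation_is_order_invariant(rng):
    records = [
        m.FeatureRecord(m.GenomicInterval("chr1", int(s), int(s) + 200), "repeat", f"r{i}")
        for i, s in enumerate(rng.integers(1, 10_000, 15))
    ]
    probe = m.GenomicInterval("chr1", 4000, 4400)
    base = m.repeats_at_breakpoint(probe, records)
    shuffled = list(records)
    rng.shuffle(shuffled)
    assert m.repeats_at_breakpoint(probe, shuffled) == base


@pytest.mark.parametrize("identity", [1.0, 0.9])
def test_shared_run_scan_matches_brute_force(identity, rng):
    bases = "ACGT"
    for _ in range(15):
        a = "".join(bases[i] for i in rng.integers(0, 4, int(rng.integers(20, 60))))
        b = "".join(bases[i] for i in rng.integers(0, 4, int(rng.integers(20, 60))))
        if rng.random() < 0.5:  # plant a shared block
            k = int(rng.integers(5, 15))
            block = a[:k]
            j = int(rng.integers(0, len(b) - k))
            b = b[:j] + block + b[j + k:]
        fast_len, _ = m.longest_shared_run(a, b, identity)
        assert fast_len == brute_longest_shared_run(a, b, identity)


def mk_junction(chrom_a, pos_a, chrom_b, pos_b, mh="", ins=""):
    amb_a = m.GenomicInterval(chrom_a, pos_a - len(mh), pos_a)
    amb_b = m.GenomicInterval(chrom_b, pos_b - len(mh), pos_b)
    return m.RefinedJunction(
        "der(test)",
        m.BreakpointCall(chrom_a, pos_a, amb_a),
        m.BreakpointCall(chrom_b, pos_b, amb_b),
        mh, ins,
    )


@pytest.fixture(scope="module")
def mechanism_genomes():
    rng = np.random.default_rng(99)
    bases = "ACGT"
    fill = lambda n: "".join(bases[i] for i in rng.integers(0, 4, n))
    shared = fill(300)
    nahr = m.Genome({
        "chrA": fill(700) + shared + fill(700),
        "chrB": fill(700) + shared + fill(700),
    })
    plain = m.Genome({"chrA": fill(1700), "chrB": fill(1700)})
    return nahr, plain


def test_mechanism_classification_under_defaults(mechanism_genomes):
    nahr_genome, plain = mechanism_genomes
    # 300 bp identical flanks on both partners -> NAHR
    call = m.classify_mechanism(mk_junction("chrA", 850, "chrB", 850), nahr_genome)
    assert call.label == NAHR
    assert call.homology_length >= 300
    # 3 bp microhomology, no long homology -> MHMR
    call2 = m.classify_mechanism(mk_junction("chrA", 850, "chrB", 850, mh="TAA"), plain)
    assert call2.label == MHMR
    # blunt junction with a 2 bp untemplated insertion -> NHEJ
    call3 = m.classify_mechanism(mk_junction("chrA", 850, "chrB", 850, ins="GC"), plain)
    assert call3.label == NHEJ
    # 1 bp homology is below the MHMR minimum -> NHEJ
    call4 = m.classify_mechanism(mk_junction("chrA", 850, "chrB", 850, mh="T"), plain)
    assert call4.label == NHEJ


def test_raising_microhomology_minimum_moves_calls_to_nhej(mechanism_genomes):
    _, plain = mechanism_genomes
    j = mk_junction("chrA", 850, "chrB", 850, mh="TAA")
    assert m.classify_mechanism(j, plain, min_microhomology=2).label == MHMR
    assert m.classify_mechanism(j, plain, min_microhomology=4).label == NHEJ
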