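import numpy as np
import pytest

import abtmap as m
from abtmap.detect import CONVENTIONS, INTERCHROMOSOMAL, CONCORDANT, INSERT_ANOMALY, ORIENTATION_ANOMALY

from oracles import connected_component_clusters


def mk_pair(pid, c1, s1, st1, c2, s2, st2, unique1=True, unique2=True, rl=100):
    return m.AlignedPair(
        pid,
        m.MateAlignment(c1, s1, s1 + rl - 1, st1, unique1),
        m.MateAlignment(c2, s2, s2 + rl - 1, st2, unique2),
    )


def test_dedupe_keeps_one_of_identical_pairs_and_drops_multimappers():
    a = mk_pair("p2", "chr1", 100, "-", "chr2", 500, "+")
    b = mk_pair("p1", "chr1", 100, "-", "chr2", 500, "+")
    c = mk_pair("p3", "chr1", 900, "-", "chr2", 900, "+", unique2=False)
    out = m.dedupe_and_unique_filter([a, b, c])
    assert [p.pair_id for p in out] == ["p1"]


def test_dedupe_is_identity_on_distinct_unique_pairs():
    pairs = [mk_pair(f"p{i}", "chr1", 100 + 10 * i, "-", "chr1", 3000 + 10 * i, "+") for i in range(8)]
    assert m.dedupe_and_unique_filter(pairs) == sorted(pairs, key=lambda p: p.pair_id)


@pytest.mark.parametrize(
    "pair,expected",
    [
        (mk_pair("p", "chr1", 100, "-", "chr7", 999, "+"), INTERCHROMOSOMAL),
        (mk_pair("p", "chr1", 100, "-", "chr1", 3001, "+"), CONCORDANT),  # insert 3100 w/ rl 100
        (mk_pair("p", "chr1", 100, "-", "chr1", 11901, "+"), INSERT_ANOMALY),  # insert 12000
        (mk_pair("p", "chr1", 100, "+", "chr1", 3001, "+"), ORIENTATION_ANOMALY),
    ],
)
def test_classify_pair_default_convention(pair, expected):
    assert m.classify_pair(pair, "rf", 2000, 4000) == expected


def test_classify_pair_follows_configured_convention():
    pair = mk_pair("p", "chr1", 100, "+", "chr1", 3001, "-")
    assert m.classify_pair(pair, "fr", 2000, 4000) == CONCORDANT
    assert m.classify_pair(pair, "rf", 2000, 4000) == ORIENTATION_ANOMALY


def test_cluster_empty_input(small_genome):
    assert m.cluster_discordant([], small_genome) == []


def test_cluster_recovers_simulated_junctions(translocation_result, small_config):
    _, res = translocation_result
    pairs, truth = m.simulate_mate_pairs(res.sample, small_config, res.truth, seed=77)
    usable = m.dedupe_and_unique_filter(pairs)
    preds = m.cluster_discordant(usable, res.reference)
    trans = [p for p in preds if p.sv_type == "translocation"]
    assert len(trans) == 2  # one per derivative
    for tj in res.truth.junctions:
        hit = [
            p for p in trans
            if p.interval_a.chrom == tj.prefix_chrom and p.interval_b.chrom == tj.suffix_chrom
        ]
        assert len(hit) == 1
        p = hit[0]
        assert p.interval_a.contains(tj.prefix_chrom, tj.prefix_end)
        assert p.interval_b.contains(tj.suffix_chrom, tj.suffix_start)
        # support = spanning fragments that stayed informative: a fragment whose
        # junction falls inside a read gets that read clipped to its majority
        # side and can land both mates on one chromosome
        spanning = set(truth.spanning_fragments[tj.derivative])
        informative = [
            q for q in usable
            if q.pair_id in spanning
            and {q.mate1.chrom, q.mate2.chrom} == {tj.prefix_chrom, tj.suffix_chrom}
        ]
        assert p.support == len(informative) >= 4


def test_two_distant_junction_clusters_stay_separate(small_genome):
    d = 4000
    pairs = []
    for i in range(6):
        pairs.append(mk_pair(f"a{i}", "chrA", 10_000 + 20 * i, "-", "chrB", 50_000 + 20 * i, "+"))
        pairs.append(mk_pair(f"b{i}", "chrA", 10_000 + 3 * d + 20 * i, "-", "chrB", 50_000 + 3 * d + 20 * i, "+"))
    preds = m.cluster_discordant(pairs, small_genome)
    assert len(preds) == 2
    assert sorted(p.support for p in preds) == [6, 6]


def test_partition_property_and_oracle_equivalence(small_genome, rng):
    """Single-linkage clusters must match brute-force connected components."""
    for trial in range(5):
        pairs = []
        for i in range(int(rng.integers(20, 120))):
            c2 = "chrB" if rng.random() < 0.7 else "chrC"
            s1 = int(rng.integers(1, 120_000))
            s2 = int(rng.integers(1, 80_000))
            pairs.append(mk_pair(f"t{trial}_p{i:03d}", "chrA", s1, "-", c2, s2, "+"))
        preds = m.cluster_discordant(pairs, small_genome)
        # partition: every discordant pair in exactly one cluster
        all_ids = sorted(pid for p in preds for pid in p.pair_ids)
        assert all_ids == sorted(p.pair_id for p in pairs)

        def compatible(x, y):
            return (
                x.mate2.chrom == y.mate2.chrom
                and abs(x.mate1.start - y.mate1.start) <= 4000
                and abs(x.mate2.start - y.mate2.start) <= 4000
            )

        comps = connected_component_clusters(pairs, compatible)
        oracle = sorted(
            tuple(sorted(pairs[i].pair_id for i in comp)) for comp in comps
        )
        ours = sorted(tuple(p.pair_ids) for p in preds)
        assert ours == oracle


def test_adding_spanning_pairs_never_widens_the_interval(translocation_result, small_config):
    _, res = translocation_result
    pairs, truth = m.simulate_mate_pairs(res.sample, small_config, res.truth, seed=13)
    tj = res.truth.junctions[0]
    span_ids = set(truth.spanning_fragments[tj.derivative])
    spanning = [p for p in pairs if p.pair_id in span_ids and p.mate1.chrom != p.mate2.chrom]
    assert len(spanning) >= 4
    widths = []
    for k in range(2, len(spanning) + 1):
        preds = m.cluster_discordant(spanning[:k], res.reference)
        (p,) = [q for q in preds if q.interval_a.chrom == tj.prefix_chrom]
        widths.append((p.interval_a.width, p.interval_b.width))
        assert p.interval_a.contains(tj.prefix_chrom, tj.prefix_end)
    assert all(w2 <= w1 for (w1, _), (w2, _) in zip(widths, widths[1:]))
    assert all(w2 <= w1 for (_, w1), (_, w2) in zip(widths, widths[1:]))


def test_deletion_signal_clusters_as_insert_anomaly(small_genome):
    # pairs spanning a 15 kb deletion: apparent insert ~ 18 kb
    pairs = [
        mk_pair(f"d{i}", "chrA", 30_000 + 40 * i, "-", "chrA", 48_000 + 40 * i, "+")
        for i in range(7)
    ]
    preds = m.cluster_discordant(pairs, small_genome)
    assert len(preds) == 1
    assert preds[0].sv_type == "deletion"
    assert preds[0].support == 7
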