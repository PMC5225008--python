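import numpy as np
import pytest

import abtmap as m
import abtmap.io as aio
from abtmap.simulate import InfeasibleSpec


def test_reference_is_deterministic_and_honours_lengths(small_config):
    g1 = m.generate_reference(small_config)
    g2 = m.generate_reference(small_config)
    assert all(g1.sequence(c) == g2.sequence(c) for c in g1.chromosomes)
    assert {c: g1.length(c) for c in g1.chromosomes} == small_config.chromosome_lengths


def test_repeat_region_is_tiled_with_motif():
    cfg = m.SimulationConfig(
        seed=3,
        chromosome_lengths={"chrA": 100_000},
        repeat_regions=[m.RepeatRegion("chrA", 20_001, 25_000)],
        repeat_motif_length=300,
    )
    g = m.generate_reference(cfg)
    span = g.fetch("chrA", 20_001, 25_000)
    motif = span[:300]
    assert span.count(motif) >= 5000 // 300  # >= 16 full copies


def test_blunt_translocation_conserves_sequence(small_genome):
    spec = m.RearrangementSpec(
        kind="reciprocal_translocation", chrom_a="chrA", pos_a=70_000, chrom_b="chrB", pos_b=40_000
    )
    res = m.apply_rearrangement(small_genome, spec)
    der = {n: c.length for n, c in res.sample.chromosomes.items()}
    assert der["der(chrA)"] + der["der(chrB)"] == small_genome.length("chrA") + small_genome.length("chrB")


@pytest.mark.parametrize(
    "kwargs,delta",
    [
        ({"deletion_a": 3}, -3),
        ({"deletion_b": 7}, -7),
        ({"duplication_a": 4}, +4),
        ({"junction_ab": m.JunctionFeatures(insertion="ACGTA")}, +5),
        ({"deletion_a": 2, "duplication_b": 6}, +4),
    ],
)
def test_derivative_length_accounting(small_genome, kwargs, delta):
    spec = m.RearrangementSpec(
        kind="reciprocal_translocation", chrom_a="chrA", pos_a=70_000, chrom_b="chrB", pos_b=40_000,
        **kwargs,
    )
    res = m.apply_rearrangement(small_genome, spec)
    total = sum(c.length for n, c in res.sample.chromosomes.items() if n.startswith("der"))
    base = small_genome.length("chrA") + small_genome.length("chrB")
    assert total - base == delta


def test_engineered_microhomology_is_real_shared_sequence(small_genome):
    k = 5
    spec = m.RearrangementSpec(
        kind="reciprocal_translocation", chrom_a="chrA", pos_a=70_000, chrom_b="chrB", pos_b=40_000,
        junction_ab=m.JunctionFeatures(microhomology=k), deletion_b=3,
    )
    res = m.apply_rearrangement(small_genome, spec)
    tj = next(j for j in res.truth.junctions if j.derivative == "der(chrA)")
    assert len(tj.microhomology) == k
    # the k-mer ends the retained A flank and precedes the resumed B flank
    a_flank = res.reference.fetch("chrA", tj.prefix_end - k + 1, tj.prefix_end)
    b_flank = res.reference.fetch("chrB", tj.suffix_start - k, tj.suffix_start - 1)
    assert a_flank == b_flank == tj.microhomology
    # string-search oracle: the junction window holds exactly one copy of the
    # k-mer context spanning the join
    der = res.sample.chromosomes["der(chrA)"].sequence(res.reference)
    window = der[tj.sample_pos - 30 : tj.sample_pos + 30]
    probe = der[tj.sample_pos - k : tj.sample_pos + k]
    assert window.count(probe) == 1


def test_infeasible_specs_are_rejected(small_genome):
    with pytest.raises(InfeasibleSpec):
        m.RearrangementSpec(
            kind="reciprocal_translocation", chrom_a="chrA", pos_a=70_000,
            chrom_b="chrB", pos_b=40_000, deletion_a=2, duplication_a=2,
        )
    with pytest.raises(InfeasibleSpec):
        m.JunctionFeatures(microhomology=2, insertion="AC")
    # fully balanced translocation: the two junctions provably share their
    # microhomology, so unequal requests cannot be engineered
    spec = m.RearrangementSpec(
        kind="reciprocal_translocation", chrom_a="chrA", pos_a=70_000, chrom_b="chrB", pos_b=40_000,
        junction_ab=m.JunctionFeatures(microhomology=4),
        junction_ba=m.JunctionFeatures(microhomology=1),
    )
    with pytest.raises(InfeasibleSpec):
        m.apply_rearrangement(small_genome, spec)
    with pytest.raises(InfeasibleSpec):
        m.apply_rearrangement(
            small_genome,
            m.RearrangementSpec(
                kind="reciprocal_translocation", chrom_a="chrA", pos_a=500,
                chrom_b="chrB", pos_b=40_000,
            ),
        )


def test_random_specs_all_realise_requested_features(small_genome, rng):
    for _ in range(30):
        spec = m.random_translocation_spec(rng, small_genome, "chrA", "chrB")
        res = m.apply_rearrangement(small_genome, spec)
        by_der = {j.derivative: j for j in res.truth.junctions}
        assert len(by_der["der(chrA)"].microhomology) == spec.junction_ab.microhomology
        assert by_der["der(chrA)"].insertion == spec.junction_ab.insertion
        assert len(by_der["der(chrB)"].microhomology) == spec.junction_ba.microhomology
        indels = {i.chrom: i for i in res.truth.indels}
        for chrom, d, u in (("chrA", spec.deletion_a, spec.duplication_a),
                            ("chrB", spec.deletion_b, spec.duplication_b)):
            if d:
                assert indels[chrom].kind == "deletion" and len(indels[chrom].sequence) == d
            elif u:
                assert indels[chrom].kind == "duplication" and len(indels[chrom].sequence) == u
            else:
                assert indels[chrom].kind == "balanced"


def test_no_rearrangement_and_no_duplicates_gives_clean_concordant_pairs(small_genome, small_config):
    sample = m.SampleGenome(
        small_genome,
        [type(c)(n, c.segments) for n, c in
         m.apply_rearrangements(small_genome, []).sample.chromosomes.items()],
    )
    cfg = m.SimulationConfig(
        seed=5, chromosome_lengths=small_config.chromosome_lengths, duplicate_fraction=0.0,
        physical_coverage=5.0,
    )
    pairs, _ = m.simulate_mate_pairs(sample, cfg)
    assert pairs
    assert all(p.mate1.chrom == p.mate2.chrom for p in pairs)
    assert all(cfg.insert_min <= p.insert_size <= cfg.insert_max for p in pairs)


def test_duplicates_are_exact_copies_found_by_the_detector(translocation_result, small_config):
    _, res = translocation_result
    cfg = m.SimulationConfig(
        seed=9, chromosome_lengths=small_config.chromosome_lengths, duplicate_fraction=0.1,
        physical_coverage=5.0,
    )
    pairs, _ = m.simulate_mate_pairs(res.sample, cfg, seed=123)
    unique_keys = {p.coordinate_key for p in pairs}
    n_dup = len(pairs) - len(unique_keys)
    assert n_dup >= int(0.09 * len(unique_keys))
    survivors = m.dedupe_and_unique_filter(pairs)
    assert len({p.coordinate_key for p in survivors}) == len(survivors)


def test_junction_spanning_fragment_count_matches_binomial_expectation(small_genome):
    spec = m.RearrangementSpec(
        kind="reciprocal_translocation", chrom_a="chrA", pos_a=70_000, chrom_b="chrB", pos_b=40_000,
    )
    res = m.apply_rearrangement(small_genome, spec)
    cfg = m.SimulationConfig(
        seed=0, chromosome_lengths={c: small_genome.length(c) for c in small_genome.chromosomes},
        duplicate_fraction=0.0, physical_coverage=10.0,
    )
    total_len = res.sample.total_length()
    n_pairs = cfg.effective_pair_count(total_len)
    observed = 0
    n_seeds = 20
    for s in range(n_seeds):
        truth = m.TruthRecord(junctions=list(res.truth.junctions))
        _, truth = m.simulate_mate_pairs(res.sample, cfg, truth, seed=1000 + s)
        observed += sum(len(v) for v in truth.spanning_fragments.values())
    # a fragment of length L spans a junction from L-1 start positions
    lam_per_pair = 2 * (cfg.insert_mean - 1) / total_len
    expected = n_seeds * n_pairs * lam_per_pair
    sd = np.sqrt(expected)
    assert abs(observed - expected) < 3 * sd


def test_known_catalogue_marks_common_decoys_only(small_genome, tmp_path):
    specs = [
        m.RearrangementSpec(kind="deletion", chrom="chrC", start=10_000, end=30_000, name="d_common"),
        m.RearrangementSpec(kind="deletion", chrom="chrC", start=60_000, end=80_000, name="d_private"),
    ]
    res = m.apply_rearrangements(small_genome, specs)
    catalogue, truth = m.make_known_catalogue(res.truth, ["d_common"], seed=4)
    from abtmap import overlap_fraction

    common = next(d for d in truth.decoys if d.name == "d_common")
    private = next(d for d in truth.decoys if d.name == "d_private")
    assert common.common and not private.common
    assert any(overlap_fraction(common.interval, rec.interval) >= 0.8 for rec in catalogue)
    assert not any(overlap_fraction(private.interval, rec.interval) >= 0.8 for rec in catalogue)
    path = tmp_path / "cat.bed"
    aio.write_bed(catalogue, path)
    back = aio.read_bed(path, kind="known_sv")
    assert [(r.interval, r.name) for r in back] == [(r.interval, r.name) for r in catalogue]
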