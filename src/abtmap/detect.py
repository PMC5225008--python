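"""Discordant mate-pair classification and clustering into SV predictions.

A mate-pair library turns a long fragment (here 2–4 kb) into two short reads
that flank the fragment. A pair is *discordant* when its mates align to
different chromosomes, in an unexpected strand configuration, or at a distance
outside the expected insert range — the long-range signature of a structural
variant. Clustering discordant pairs that agree on both partners localises
each breakpoint to a junction interval before nucleotide-level refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core import Genome, GenomicInterval

# Mate-pair orientation conventions, expressed as the read strands expected for
# the (fragment-left, fragment-right) mates of a concordant +-strand fragment.
# "rf" is the processed Nextera mate-pair layout; "fr" is plain paired-end.
CONVENTIONS: Dict[str, Tuple[str, str]] = {"rf": ("-", "+"), "fr": ("+", "-")}

CONCORDANT = "concordant"
INTERCHROMOSOMAL = "interchromosomal"
ORIENTATION_ANOMALY = "orientation_anomaly"
INSERT_ANOMALY = "insert_anomaly"


@dataclass(frozen=True)
class MateAlignment:
    """One aligned read of a pair: closed 1-based span plus strand and uniqueness."""

    chrom: str
    start: int
    end: int
    strand: str
    unique: bool = True

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad mate span {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"mate strand must be +/-, got {self.strand!r}")

    @property
    def aligned_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AlignedPair:
    """A mate-pair after alignment: two mates plus a stable pair identifier."""

    pair_id: str
    mate1: MateAlignment
    mate2: MateAlignment

    @property
    def insert_size(self) -> Optional[int]:
        """Outer distance between mates; defined only for same-chromosome pairs."""
        if self.mate1.chrom != self.mate2.chrom:
            return None
        return max(self.mate1.end, self.mate2.end) - min(
            self.mate1.start, self.mate2.start
        ) + 1

    @property
    def coordinate_key(self) -> tuple:
        m1, m2 = sorted(
            (self.mate1, self.mate2), key=lambda m: (m.chrom, m.start, m.strand)
        )
        return (m1.chrom, m1.start, m1.strand, m2.chrom, m2.start, m2.strand)


@dataclass
class SVPrediction:
    """A cluster of discordant pairs supporting one structural variant."""

    sv_type: str  # translocation | deletion | insertion | inversion
    interval_a: GenomicInterval
    interval_b: GenomicInterval
    pair_ids: Tuple[str, ...]
    orientation: Tuple[str, str] = ("+", "+")
    name: str = ""

    def __post_init__(self) -> None:
        if self.sv_type == "translocation" and self.interval_a.chrom == self.interval_b.chrom:
            raise ValueError("translocation partners must be on different chromosomes")
        if len(set(self.pair_ids)) != len(self.pair_ids):
            raise ValueError("contributing pair ids must be distinct")

    @property
    def support(self) -> int:
        return len(self.pair_ids)

    @property
    def span(self) -> GenomicInterval:
        """Whole affected interval for an intrachromosomal prediction."""
        if self.interval_a.chrom != self.interval_b.chrom:
            raise ValueError("span is defined only for intrachromosomal predictions")
        return GenomicInterval(
            self.interval_a.chrom,
            min(self.interval_a.start, self.interval_b.start),
            max(self.interval_a.end, self.interval_b.end),
        )


def dedupe_and_unique_filter(pairs: Sequence[AlignedPair]) -> List[AlignedPair]:
    """Drop pairs with any non-uniquely-mapping mate, then collapse PCR duplicates.

    Duplicates share the full coordinate signature (chrom, position, strand of
    both mates); the survivor is the pair with the lexicographically lowest id.
    """
    best: Dict[tuple, AlignedPair] = {}
    for p in pairs:
        if not (p.mate1.unique and p.mate2.unique):
            continue
        key = p.coordinate_key
        kept = best.get(key)
        if kept is None or p.pair_id < kept.pair_id:
            best[key] = p
    return sorted(best.values(), key=lambda p: p.pair_id)


def classify_pair(
    pair: AlignedPair,
    convention: str = "rf",
    insert_min: int = 2000,
    insert_max: int = 4000,
) -> str:
    """Assign a pair to concordant / interchromosomal / orientation / insert anomaly."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if pair.mate1.chrom != pair.mate2.chrom:
        return INTERCHROMOSOMAL
    left, right = sorted((pair.mate1, pair.mate2), key=lambda m: m.start)
    exp_left, exp_right = CONVENTIONS[convention]
    if (left.strand, right.strand) != (exp_left, exp_right):
        return ORIENTATION_ANOMALY
    ins = pair.insert_size
    if ins is None or not (insert_min <= ins <= insert_max):
        return INSERT_ANOMALY
    return CONCORDANT


def _prefix_suffix_mates(
    pair: AlignedPair, convention: str, genome_order: Dict[str, int]
) -> Optional[Tuple[MateAlignment, MateAlignment]]:
    """Split an interchromosomal pair into (fragment-left, fragment-right) mates.

    The mate carrying the convention's left-read strand sits on the *prefix*
    chromosome of the derivative (breakpoint to its right); the other mate sits
    on the *suffix* chromosome (breakpoint to its left). Pairs whose strands do
    not form a left/right combination (inverted joins) return None.
    """
    exp_left, exp_right = CONVENTIONS[convention]
    m1, m2 = pair.mate1, pair.mate2
    if m1.strand == exp_left and m2.strand == exp_right:
        return m1, m2
    if m2.strand == exp_left and m1.strand == exp_right:
        return m2, m1
    return None


@dataclass
class _ClusterMember:
    pair: AlignedPair
    prefix: MateAlignment
    suffix: MateAlignment


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _breakpoint_constraints(
    member: _ClusterMember, insert_max: int
) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Admissible breakpoint ranges implied by one pair.

    On the prefix chromosome, the last retained base lies at or beyond the
    mate's inner (right) end, but no farther than the fragment could reach
    given the bases already spent on the other mate. Symmetrically on the
    suffix chromosome for the first retained base.
    """
    pre, suf = member.prefix, member.suffix
    pre_lo = pre.end
    pre_hi = pre.start + insert_max - 1 - suf.aligned_length
    suf_hi = suf.start
    suf_lo = suf.end - insert_max + pre.aligned_length + 1
    return (pre_lo, pre_hi), (suf_lo, suf_hi)


def _intersect_or_span(
    ranges: List[Tuple[int, int]], inner_points: List[int]
) -> Tuple[int, int]:
    lo = max(r[0] for r in ranges)
    hi = min(r[1] for r in ranges)
    if lo <= hi:
        return lo, hi
    # Contradictory constraints (e.g. outlier insert): fall back to the span of
    # inner read ends so the interval still brackets the evidence.
    return min(inner_points), max(inner_points)


def cluster_discordant(
    pairs: Sequence[AlignedPair],
    genome: Genome,
    convention: str = "rf",
    insert_min: int = 2000,
    insert_max: int = 4000,
    distance: Optional[int] = None,
) -> List[SVPrediction]:
    """Single-linkage clustering of discordant pairs into SV predictions.

    Two pairs link when they agree on chromosome pair and orientation and their
    mate start positions lie within ``distance`` on *both* partners (default:
    the upper insert bound — a pair cannot span farther than its insert).
    Each cluster's junction intervals are the intersection of the per-pair
    admissible breakpoint ranges, falling back to the span of inner read ends
    when the intersection is empty.
    """
    d = insert_max if distance is None else distance
    order = {c: i for i, c in enumerate(genome.chromosomes)}

    groups: Dict[tuple, List[_ClusterMember]] = {}
    for p in pairs:
        label = classify_pair(p, convention, insert_min, insert_max)
        if label == CONCORDANT:
            continue
        if label == INTERCHROMOSOMAL:
            ps = _prefix_suffix_mates(p, convention, order)
            if ps is None:
                # inverted interchromosomal join; keep as its own orientation class
                m1, m2 = sorted(
                    (p.mate1, p.mate2), key=lambda m: (order.get(m.chrom, 1 << 30), m.start)
                )
                key = ("translocation_inverted", m1.chrom, m2.chrom, m1.strand, m2.strand)
                groups.setdefault(key, []).append(_ClusterMember(p, m1, m2))
                continue
            pre, suf = ps
            key = ("translocation", pre.chrom, suf.chrom, pre.strand, suf.strand)
            groups.setdefault(key, []).append(_ClusterMember(p, pre, suf))
        elif label == INSERT_ANOMALY:
            ins = p.insert_size
            sv = "deletion" if ins is not None and ins > insert_max else "insertion"
            left, right = sorted((p.mate1, p.mate2), key=lambda m: m.start)
            key = (sv, left.chrom, left.chrom, left.strand, right.strand)
            groups.setdefault(key, []).append(_ClusterMember(p, left, right))
        else:  # orientation anomaly -> inversion-type evidence
            left, right = sorted((p.mate1, p.mate2), key=lambda m: m.start)
            key = ("inversion", left.chrom, left.chrom, left.strand, right.strand)
            groups.setdefault(key, []).append(_ClusterMember(p, left, right))

    predictions: List[SVPrediction] = []
    for key in sorted(groups, key=lambda k: (order.get(k[1], 1 << 30), order.get(k[2], 1 << 30), k)):
        sv_type = "translocation" if key[0].startswith("translocation") else key[0]
        members = groups[key]
        members.sort(key=lambda m: (m.prefix.start, m.suffix.start, m.pair.pair_id))
        uf = _UnionFind(len(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if (
                    abs(a.prefix.start - b.prefix.start) <= d
                    and abs(a.suffix.start - b.suffix.start) <= d
                ):
                    uf.union(i, j)
        clusters: Dict[int, List[_ClusterMember]] = {}
        for i in range(len(members)):
            clusters.setdefault(uf.find(i), []).append(members[i])
        for root in sorted(clusters, key=lambda r: members[r].prefix.start):
            cl = clusters[root]
            if key[0] == "translocation":
                constraints = [_breakpoint_constraints(m, insert_max) for m in cl]
                a_lo, a_hi = _intersect_or_span(
                    [c[0] for c in constraints], [m.prefix.end for m in cl]
                )
                b_lo, b_hi = _intersect_or_span(
                    [c[1] for c in constraints], [m.suffix.start for m in cl]
                )
                ivl_a = GenomicInterval(key[1], max(1, a_lo), max(1, a_lo, a_hi))
                ivl_b = GenomicInterval(key[2], max(1, b_lo), max(1, b_lo, b_hi))
            elif key[0] == "deletion":
                # left mate bounds the left breakpoint, right mate the right one
                constraints = [_breakpoint_constraints(m, insert_max) for m in cl]
                a_lo, a_hi = _intersect_or_span(
                    [c[0] for c in constraints], [m.prefix.end for m in cl]
                )
                b_lo, b_hi = _intersect_or_span(
                    [c[1] for c in constraints], [m.suffix.start for m in cl]
                )
                ivl_a = GenomicInterval(key[1], max(1, a_lo), max(1, a_lo, a_hi))
                ivl_b = GenomicInterval(key[2], max(1, b_lo), max(1, b_lo, b_hi))
            else:
                ivl_a = GenomicInterval(
                    key[1], min(m.prefix.start for m in cl), max(m.prefix.end for m in cl)
                )
                ivl_b = GenomicInterval(
                    key[2], min(m.suffix.start for m in cl), max(m.suffix.end for m in cl)
                )
            predictions.append(
                SVPrediction(
                    sv_type=sv_type,
                    interval_a=ivl_a,
                    interval_b=ivl_b,
                    pair_ids=tuple(sorted(m.pair.pair_id for m in cl)),
                    orientation=(key[3], key[4]),
                )
            )
    for i, pred in enumerate(predictions, 1):
        if not pred.name:
            pred.name = f"{pred.sv_type}_{i}"
    return predictions
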