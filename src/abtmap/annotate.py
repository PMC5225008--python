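"""Breakpoint annotation and repair-mechanism classification.

Annotation is pure lookup against gene models, repeat tracks and conserved
non-coding element (CNE) tracks. Mechanism classification turns the usual
qualitative argument into explicit thresholds: long high-identity homology
shared by both partner flanks points to non-allelic homologous recombination
(NAHR); a few bases of junction microhomology to microhomology-mediated
repair (MHMR/MMEJ); blunt joins, 1 bp homology, untemplated insertions or
small imbalances to non-homologous end-joining (NHEJ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .core import Breakpoint, FeatureRecord, Genome, GenomicInterval
from .junction import ReconciledTranslocation, RefinedJunction

NAHR = "NAHR"
MHMR = "MHMR"
NHEJ = "NHEJ"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GeneDisruption:
    gene: str
    region: str  # "exon" | "intron"
    index: int  # 1-based, in transcription order
    ambiguous: bool = False  # breakpoint interval straddles an exon boundary


@dataclass
class BreakpointAnnotation:
    disruptions: List[GeneDisruption] = field(default_factory=list)
    repeats: List[FeatureRecord] = field(default_factory=list)
    cnes: List[Tuple[FeatureRecord, int]] = field(default_factory=list)  # (record, signed distance)
    position_effect: bool = False


@dataclass(frozen=True)
class MechanismCall:
    label: str
    homology_length: int = 0
    homology_identity: float = 0.0
    microhomology_length: int = 0
    insertion_length: int = 0
    indels_present: bool = False


class FeatureIndex:
    """Interval-tree lookup over feature records, one tree per chromosome."""

    def __init__(self, records: Sequence[FeatureRecord]):
        self.records = list(records)
        self._trees: Dict[str, IntervalTree] = {}
        for rec in self.records:
            tree = self._trees.setdefault(rec.interval.chrom, IntervalTree())
            # half-open internally for intervaltree
            tree[rec.interval.start : rec.interval.end + 1] = rec

    def overlapping(self, ivl: GenomicInterval) -> List[FeatureRecord]:
        tree = self._trees.get(ivl.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(ivl.start, ivl.end + 1)]
        return sorted(hits, key=lambda r: (r.interval.start, r.interval.end, r.name))


def genes_at_breakpoint(
    bp_interval: GenomicInterval, genes: Sequence[FeatureRecord]
) -> List[GeneDisruption]:
    """Genes disrupted at a breakpoint interval's midpoint.

    The exon/intron index is counted in transcription order: for a minus-strand
    gene the last exon in genomic coordinates is exon 1. All overlapping gene
    models are reported. The ``ambiguous`` flag marks intervals that straddle
    an exon boundary, where the midpoint call could go either way.
    """
    mid = bp_interval.midpoint
    out: List[GeneDisruption] = []
    for gene in genes:
        if gene.kind != "gene" or not gene.interval.contains(bp_interval.chrom, mid):
            continue
        exons: List[GenomicInterval] = gene.attributes["exons"]
        n = len(exons)
        minus = gene.interval.strand == "-"
        region, plus_index = _locate_in_gene(exons, mid)
        if region == "exon":
            index = (n - plus_index + 1) if minus else plus_index
        else:
            index = (n - plus_index) if minus else plus_index
        ambiguous = any(
            bp_interval.start <= edge < bp_interval.end
            for e in exons
            for edge in (e.start - 1, e.end)  # boundaries between exon and flanking intron
            if gene.interval.start < edge < gene.interval.end
        )
        out.append(GeneDisruption(gene.name, region, index, ambiguous))
    return sorted(out, key=lambda d: d.gene)


def _locate_in_gene(exons: Sequence[GenomicInterval], pos: int) -> Tuple[str, int]:
    """(region, 1-based plus-strand index) of a position within a gene span."""
    for i, e in enumerate(exons, 1):
        if e.start <= pos <= e.end:
            return "exon", i
        if pos < e.start:
            # between exon i-1 and exon i (or upstream of exon 1 inside the span)
            return "intron", max(i - 1, 1)
    return "intron", len(exons) - 1 if len(exons) > 1 else 1


def repeats_at_breakpoint(
    bp_interval: GenomicInterval, repeats: Sequence[FeatureRecord] | FeatureIndex
) -> List[FeatureRecord]:
    """Repeat records strictly overlapping the breakpoint interval."""
    index = repeats if isinstance(repeats, FeatureIndex) else FeatureIndex(repeats)
    return [r for r in index.overlapping(bp_interval) if r.kind == "repeat"]


def cne_proximity(
    bp: Breakpoint,
    cnes: Sequence[FeatureRecord] | FeatureIndex,
    window: int = 1_000_000,
) -> BreakpointAnnotation:
    """CNEs within ±window (closed at both ends) of a breakpoint.

    Distance is signed: negative upstream of the breakpoint, positive
    downstream, 0 when the CNE contains it. Any hit sets the position-effect
    flag — a conserved element moved relative to its regulatory target can
    perturb developmental genes in the same topological domain.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    index = cnes if isinstance(cnes, FeatureIndex) else FeatureIndex(cnes)
    probe = GenomicInterval(bp.chrom, max(1, bp.position - window), bp.position + window)
    hits: List[Tuple[FeatureRecord, int]] = []
    for rec in index.overlapping(probe):
        if rec.kind != "CNE":
            continue
        if rec.interval.contains(bp.chrom, bp.position):
            dist = 0
        elif rec.interval.end < bp.position:
            dist = rec.interval.end - bp.position
        else:
            dist = rec.interval.start - bp.position
        if abs(dist) <= window:
            hits.append((rec, dist))
    ann = BreakpointAnnotation(cnes=hits, position_effect=bool(hits))
    return ann


# ---------------------------------------------------------------------------
# Flank homology scan (NAHR evidence)


def longest_shared_run(
    seq_a: str, seq_b: str, min_identity: float = 0.9
) -> Tuple[int, float]:
    """Longest equal-length substring pair with Hamming identity >= min_identity.

    Scans every alignment offset (diagonal) of the two sequences; on each
    diagonal the longest window whose match fraction meets the threshold is
    found from prefix sums of (match − min_identity). Returns (length,
    identity of the best run).
    """
    if not seq_a or not seq_b:
        return 0, 0.0
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    best_len, best_ident = 0, 0.0
    for d in range(-(len(b) - 1), len(a)):
        lo_a = max(0, d)
        hi_a = min(len(a), len(b) + d)
        if hi_a - lo_a <= best_len:
            continue
        x = (a[lo_a:hi_a] == b[lo_a - d : hi_a - d]).astype(np.float64)
        score = np.concatenate(([0.0], np.cumsum(x - min_identity)))
        # longest j - i with score[j] >= score[i]
        length, ident = _longest_nonneg_span(score, x)
        if length > best_len:
            best_len, best_ident = length, ident
    return best_len, best_ident


def _longest_nonneg_span(prefix: np.ndarray, x: np.ndarray) -> Tuple[int, float]:
    n = len(prefix)
    # indices of strictly decreasing prefix minima
    stack = [0]
    for i in range(1, n):
        if prefix[i] < prefix[stack[-1]]:
            stack.append(i)
    best = 0
    best_pair = None
    for j in range(n - 1, 0, -1):
        while stack and prefix[j] >= prefix[stack[-1]]:
            i = stack.pop()
            if j - i > best:
                best = j - i
                best_pair = (i, j)
    if best == 0 or best_pair is None:
        return 0, 0.0
    i, j = best_pair
    ident = float(x[i:j].mean()) if j > i else 0.0
    return best, ident


def classify_mechanism(
    reconciled_or_junction: ReconciledTranslocation | RefinedJunction,
    reference: Genome,
    flank: int = 500,
    min_homology_length: int = 50,
    min_identity: float = 0.9,
    min_microhomology: int = 2,
) -> MechanismCall:
    """Classify the likely double-strand-break repair mechanism of a junction.

    Order of evidence: shared flank homology (>= min_homology_length bp at
    >= min_identity) → NAHR; junction microhomology >= min_microhomology →
    MHMR; otherwise (blunt, 1 bp homology, untemplated insertion, or indels)
    → NHEJ.
    """
    if isinstance(reconciled_or_junction, ReconciledTranslocation):
        junction = reconciled_or_junction.junction_ab
        indels_present = any(
            r.kind != "balanced" for r in reconciled_or_junction.reconciliation.values()
        )
    else:
        junction = reconciled_or_junction
        indels_present = False

    a_chrom, a_pos = junction.prefix.chrom, junction.prefix.position
    b_chrom, b_pos = junction.suffix.chrom, junction.suffix.position
    flank_a = reference.fetch(
        a_chrom, max(1, a_pos - flank + 1), min(reference.length(a_chrom), a_pos + flank)
    )
    flank_b = reference.fetch(
        b_chrom, max(1, b_pos - flank), min(reference.length(b_chrom), b_pos + flank - 1)
    )
    hom_len, hom_ident = longest_shared_run(flank_a, flank_b, min_identity)
    mh_len = len(junction.microhomology)
    ins_len = len(junction.insertion)

    if hom_len >= min_homology_length:
        label = NAHR
    elif mh_len >= min_microhomology:
        label = MHMR
    else:
        label = NHEJ
    return MechanismCall(
        label=label,
        homology_length=hom_len,
        homology_identity=round(hom_ident, 4),
        microhomology_length=mh_len,
        insertion_length=ins_len,
        indels_present=indels_present,
    )
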