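"""Synthetic mate-pair data with engineered rearrangements and full ground truth.

The generator emulates the signal a long-insert (2–4 kb) mate-pair library
produces after alignment: concordant pairs inside chromosomes, discordant
pairs spanning engineered junctions, PCR duplicates, and multimapping reads
in repeat regions. Rearrangements carry configurable junction micro-features
(microhomology, per-chromosome deletions/duplications, untemplated
insertions) so the downstream refinement has something real to recover.

Microhomology is engineered by rewriting reference bases: the two partner
flanks genuinely share the homologous run in the emitted reference, so the
breakpoint-placement ambiguity downstream is mathematically real. Guard
bases adjacent to each engineered run stop accidental extension, and every
feature is re-measured from the final sequences; a request the sequences
cannot satisfy (e.g. different microhomologies at the two junctions of a
perfectly balanced translocation, which are provably equal) raises
:class:`InfeasibleSpec`.

Alignment itself is out of scope: emitted pair coordinates are truthful
post-alignment records, with reads crossing a junction clipped to their
longest single-segment match, as a local aligner would place them.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import FeatureRecord, Genome, GenomicInterval
from .detect import CONVENTIONS, AlignedPair, MateAlignment

BASES = "ACGT"


class InfeasibleSpec(ValueError):
    """The requested rearrangement features cannot coexist in any sequence."""


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class RepeatRegion:
    chrom: str
    start: int
    end: int


@dataclass
class SimulationConfig:
    """Study conditions for the mate-pair simulator.

    Defaults mirror a long-insert library: 2–4 kb fragments (truncated normal,
    mean 3 kb, sd 400 bp) sequenced as 100 bp read pairs, over a small
    multi-chromosome genome.
    """

    seed: int = 0
    chromosome_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 3_000_000, "chr2": 2_000_000, "chr3": 1_000_000}
    )
    insert_mean: int = 3000
    insert_sd: int = 400
    insert_min: int = 2000
    insert_max: int = 4000
    read_length: int = 100
    pair_count: Optional[int] = None
    physical_coverage: float = 10.0
    duplicate_fraction: float = 0.05
    error_rate: float = 0.0  # per-base, applied to extracted junction evidence
    convention: str = "rf"
    repeat_regions: List[RepeatRegion] = field(default_factory=list)
    repeat_motif_length: int = 300

    def __post_init__(self) -> None:
        if not (0 < self.insert_min <= self.insert_mean <= self.insert_max):
            raise ValueError("need 0 < insert_min <= insert_mean <= insert_max")
        if self.read_length >= self.insert_min:
            raise ValueError("read length must be below the lower insert bound")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1]")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown mate-pair convention {self.convention!r}")

    def effective_pair_count(self, genome_length: int) -> int:
        if self.pair_count is not None:
            return self.pair_count
        return int(round(self.physical_coverage * genome_length / self.insert_mean))


@dataclass(frozen=True)
class JunctionFeatures:
    """Micro-features of one derivative junction (mutually exclusive fields)."""

    microhomology: int = 0
    insertion: str = ""

    def __post_init__(self) -> None:
        if self.microhomology < 0:
            raise ValueError("microhomology length must be >= 0")
        if self.microhomology and self.insertion:
            raise InfeasibleSpec(
                "a junction cannot carry both microhomology and an untemplated insertion"
            )
        if set(self.insertion.upper()) - set(BASES):
            raise ValueError("insertion must be over ACGT")


@dataclass(frozen=True)
class RearrangementSpec:
    """An engineered rearrangement with junction micro-features.

    For a reciprocal translocation between ``chrom_a:pos_a`` and
    ``chrom_b:pos_b``, der(A) = A[1..pos_a] ⊕ insertion ⊕ B[pos_b'..] and
    der(B) = B[1..pos_b] ⊕ insertion ⊕ A[pos_a'..], where the resume points
    pos' absorb the per-chromosome deletion (bases lost from both
    derivatives) or duplication (bases kept on both).
    """

    kind: str  # reciprocal_translocation | deletion | tandem_duplication | insertion
    chrom_a: str = ""
    pos_a: int = 0
    chrom_b: str = ""
    pos_b: int = 0
    junction_ab: JunctionFeatures = field(default_factory=JunctionFeatures)
    junction_ba: JunctionFeatures = field(default_factory=JunctionFeatures)
    deletion_a: int = 0
    duplication_a: int = 0
    deletion_b: int = 0
    duplication_b: int = 0
    # intrachromosomal kinds
    chrom: str = ""
    start: int = 0
    end: int = 0
    insert_length: int = 0
    name: str = ""

    KINDS = ("reciprocal_translocation", "deletion", "tandem_duplication", "insertion")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown rearrangement kind {self.kind!r}")
        if self.kind == "reciprocal_translocation":
            if self.deletion_a and self.duplication_a:
                raise InfeasibleSpec("deletion and duplication on chrom A are exclusive")
            if self.deletion_b and self.duplication_b:
                raise InfeasibleSpec("deletion and duplication on chrom B are exclusive")
            if min(self.deletion_a, self.duplication_a, self.deletion_b, self.duplication_b) < 0:
                raise ValueError("indel lengths must be >= 0")
            if self.chrom_a == self.chrom_b:
                raise ValueError("translocation partners must differ")


@dataclass(frozen=True)
class TruthJunction:
    """Ground truth for one derivative junction, in reference coordinates."""

    derivative: str
    prefix_chrom: str
    prefix_end: int  # last reference base retained before the junction
    suffix_chrom: str
    suffix_start: int  # first reference base retained after the junction
    microhomology: str
    insertion: str
    sample_chrom: str
    sample_pos: int  # derivative coordinate of the last prefix base


@dataclass(frozen=True)
class ChromIndel:
    chrom: str
    kind: str  # deletion | duplication | balanced
    sequence: str
    interval: Optional[GenomicInterval]


@dataclass(frozen=True)
class DecoySV:
    name: str
    sv_type: str
    interval: GenomicInterval
    common: bool  # True: should appear in the known-SV catalogue


@dataclass
class TruthRecord:
    specs: List[RearrangementSpec] = field(default_factory=list)
    junctions: List[TruthJunction] = field(default_factory=list)
    indels: List[ChromIndel] = field(default_factory=list)
    decoys: List[DecoySV] = field(default_factory=list)
    spanning_fragments: Dict[str, List[str]] = field(default_factory=dict)

    def junction_key(self, j: TruthJunction) -> str:
        return j.derivative


# ---------------------------------------------------------------------------
# Sample genome: chromosomes as segment lists over the reference


@dataclass(frozen=True)
class Segment:
    """A contiguous piece of a sample chromosome: reference slice or novel bases."""

    ref_chrom: Optional[str]  # None for untemplated sequence
    start: int = 0  # reference coords, closed
    end: int = 0
    strand: str = "+"
    novel: str = ""

    @property
    def length(self) -> int:
        return len(self.novel) if self.ref_chrom is None else self.end - self.start + 1


class SampleChromosome:
    def __init__(self, name: str, segments: Sequence[Segment]):
        self.name = name
        self.segments = [s for s in segments if s.length > 0]
        self._offsets = [0]
        for s in self.segments:
            self._offsets.append(self._offsets[-1] + s.length)

    @property
    def length(self) -> int:
        return self._offsets[-1]

    def sequence(self, reference: Genome) -> str:
        parts = []
        for s in self.segments:
            if s.ref_chrom is None:
                parts.append(s.novel)
            else:
                seq = reference.fetch(s.ref_chrom, s.start, s.end)
                parts.append(seq if s.strand == "+" else _revcomp(seq))
        return "".join(parts)

    def segment_sample_span(self, i: int) -> Tuple[int, int]:
        """1-based closed sample coordinates covered by segment i."""
        return self._offsets[i] + 1, self._offsets[i + 1]

    def sample_position(self, ref_chrom: str, ref_pos: int) -> Optional[int]:
        for i, s in enumerate(self.segments):
            if s.ref_chrom == ref_chrom and s.start <= ref_pos <= s.end:
                lo, _ = self.segment_sample_span(i)
                if s.strand == "+":
                    return lo + (ref_pos - s.start)
                return lo + (s.end - ref_pos)
        return None

    def map_read(self, rs: int, re_: int) -> Optional[Tuple[str, int, int, str]]:
        """Place a sample-coordinate read onto the reference.

        Returns the longest single-segment match (a local aligner's primary
        alignment for a junction-crossing read), or None if no reference
        segment overlaps.
        """
        i = bisect.bisect_right(self._offsets, rs - 1) - 1
        best = None
        best_len = 0
        while i < len(self.segments):
            lo, hi = self.segment_sample_span(i)
            if lo > re_:
                break
            s = self.segments[i]
            ov_lo, ov_hi = max(rs, lo), min(re_, hi)
            ov = ov_hi - ov_lo + 1
            if s.ref_chrom is not None and ov > best_len:
                if s.strand == "+":
                    a = s.start + (ov_lo - lo)
                    b = s.start + (ov_hi - lo)
                else:
                    b = s.end - (ov_lo - lo)
                    a = s.end - (ov_hi - lo)
                best = (s.ref_chrom, a, b, s.strand)
                best_len = ov
            i += 1
        return best


def _revcomp(seq: str) -> str:
    from .core import revcomp

    return revcomp(seq)


class SampleGenome:
    """The rearranged genome reads are drawn from, with its reference and maps."""

    def __init__(self, reference: Genome, chromosomes: Sequence[SampleChromosome]):
        self.reference = reference
        self.chromosomes = {c.name: c for c in chromosomes}

    def names(self) -> List[str]:
        return list(self.chromosomes)

    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes.values())

    def as_genome(self) -> Genome:
        return Genome({n: c.sequence(self.reference) for n, c in self.chromosomes.items()})

    def splice_deletion(self, ref_chrom: str, start: int, end: int) -> None:
        """Remove reference span [start, end] from whichever sample chromosome holds it."""
        for name, chrom in self.chromosomes.items():
            for i, s in enumerate(chrom.segments):
                if s.ref_chrom == ref_chrom and s.start <= start and end <= s.end:
                    if s.strand != "+":
                        raise ValueError("deletion inside a reversed segment is unsupported")
                    left = replace(s, end=start - 1)
                    right = replace(s, start=end + 1)
                    new = chrom.segments[:i] + [left, right] + chrom.segments[i + 1 :]
                    self.chromosomes[name] = SampleChromosome(name, new)
                    return
        raise ValueError(f"no sample segment fully contains {ref_chrom}:{start}-{end}")

    def splice_tandem_duplication(self, ref_chrom: str, start: int, end: int) -> None:
        for name, chrom in self.chromosomes.items():
            for i, s in enumerate(chrom.segments):
                if s.ref_chrom == ref_chrom and s.start <= start and end <= s.end:
                    if s.strand != "+":
                        raise ValueError("duplication inside a reversed segment is unsupported")
                    left = replace(s, end=end)
                    right = replace(s, start=start)
                    new = chrom.segments[:i] + [left, right] + chrom.segments[i + 1 :]
                    self.chromosomes[name] = SampleChromosome(name, new)
                    return
        raise ValueError(f"no sample segment fully contains {ref_chrom}:{start}-{end}")

    def splice_insertion(self, ref_chrom: str, pos: int, novel: str) -> None:
        for name, chrom in self.chromosomes.items():
            for i, s in enumerate(chrom.segments):
                if s.ref_chrom == ref_chrom and s.start <= pos < s.end:
                    left = replace(s, end=pos)
                    right = replace(s, start=pos + 1)
                    ins = Segment(None, novel=novel)
                    new = chrom.segments[:i] + [left, ins, right] + chrom.segments[i + 1 :]
                    self.chromosomes[name] = SampleChromosome(name, new)
                    return
        raise ValueError(f"no sample segment contains {ref_chrom}:{pos}")


# ---------------------------------------------------------------------------
# Reference generation


def generate_reference(config: SimulationConfig) -> Genome:
    """A deterministic random genome with optional repeat regions.

    Repeat regions are tiled with a single random motif so reads inside them
    genuinely have multiple near-identical placements.
    """
    rng = np.random.default_rng(config.seed)
    seqs: Dict[str, str] = {}
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    for name, length in config.chromosome_lengths.items():
        idx = rng.integers(0, 4, size=length)
        seqs[name] = base_arr[idx].tobytes().decode()
    if config.repeat_regions:
        motif_idx = rng.integers(0, 4, size=config.repeat_motif_length)
        motif = base_arr[motif_idx].tobytes().decode()
        for rr in config.repeat_regions:
            span = rr.end - rr.start + 1
            tiled = (motif * (span // len(motif) + 1))[:span]
            s = seqs[rr.chrom]
            seqs[rr.chrom] = s[: rr.start - 1] + tiled + s[rr.end :]
    return Genome(seqs)


# ---------------------------------------------------------------------------
# Constraint solver for engineered junction features


class _BaseConstraints:
    """Equality/inequality constraints over individual reference bases."""

    def __init__(self) -> None:
        self.parent: Dict[tuple, tuple] = {}
        self.unequal: List[Tuple[tuple, tuple]] = []
        self.forbidden: Dict[tuple, set] = {}

    def _find(self, x: tuple) -> tuple:
        while self.parent.setdefault(x, x) != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def equal(self, a: tuple, b: tuple) -> None:
        ra, rb = self._find(a), self._find(b)
        if ra != rb:
            self.parent[rb] = ra

    def not_equal(self, a: tuple, b: tuple) -> None:
        self._find(a)  # register both endpoints so they receive an assignment
        self._find(b)
        self.unequal.append((a, b))

    def forbid(self, a: tuple, letter: str) -> None:
        self._find(a)
        self.forbidden.setdefault(a, set()).add(letter)

    def solve(self, current: Dict[tuple, str]) -> Dict[tuple, str]:
        """Assign a base to every constrained position.

        Keeps the current reference base where possible; raises InfeasibleSpec
        when two positions forced equal are also forced unequal.
        """
        classes: Dict[tuple, List[tuple]] = {}
        for x in list(self.parent):
            classes.setdefault(self._find(x), []).append(x)
        for x in list(self.forbidden):
            classes.setdefault(self._find(x), []).append(x)
        neighbours: Dict[tuple, List[tuple]] = {}
        for a, b in self.unequal:
            ra, rb = self._find(a), self._find(b)
            if ra == rb:
                raise InfeasibleSpec(
                    "requested junction features force the same base to be both "
                    "equal and different (e.g. unequal microhomology at the two "
                    "junctions of a fully balanced translocation)"
                )
            neighbours.setdefault(ra, []).append(rb)
            neighbours.setdefault(rb, []).append(ra)
        assignment: Dict[tuple, str] = {}
        for root in sorted(classes):
            banned = set()
            for member in classes[root]:
                banned |= self.forbidden.get(member, set())
            for other in neighbours.get(root, []):
                if other in assignment:
                    banned.add(assignment[other])
            preferred = current.get(root, "A")
            choice = preferred if preferred not in banned else next(
                b for b in BASES if b not in banned
            )
            assignment[root] = choice
        out: Dict[tuple, str] = {}
        for root, members in classes.items():
            for m in members:
                out[m] = assignment[root]
        return out


def _engineer_junction(
    cons: _BaseConstraints,
    prefix: Tuple[str, int],  # (chrom, last retained base aX)
    suffix: Tuple[str, int],  # (chrom, first retained base bY+1)
    feats: JunctionFeatures,
) -> None:
    """Add the base constraints that realise one junction's features."""
    (pc, a), (sc, s) = prefix, suffix
    b = s - 1  # bY: base just before the suffix resume point
    ins = feats.insertion.upper()
    if ins:
        # stop split-alignment extension at the insertion's first and last base
        cons.forbid((pc, a + 1), ins[0])
        if b >= 1:
            cons.forbid((sc, b), ins[-1])
        return
    m = feats.microhomology
    for k in range(m):
        cons.equal((pc, a - k), (sc, b - k))
    if a - m >= 1 and b - m >= 1:
        cons.not_equal((pc, a - m), (sc, b - m))
    cons.not_equal((pc, a + 1), (sc, b + 1))


def _measure_junction(
    reference: Genome,
    prefix_chrom: str,
    prefix_end: int,
    suffix_chrom: str,
    suffix_start: int,
    insertion: str,
) -> Tuple[str, int, int]:
    """Measure the junction's actual microhomology from the final reference.

    Returns (microhomology string under prefix-anchored placement, backward
    extension, forward extension). An untemplated insertion precludes
    microhomology by definition.
    """
    if insertion:
        return "", 0, 0
    A, B = reference.sequence(prefix_chrom), reference.sequence(suffix_chrom)
    a, b = prefix_end, suffix_start - 1
    bwd = 0
    while a - bwd >= 1 and b - bwd >= 1 and A[a - bwd - 1] == B[b - bwd - 1]:
        bwd += 1
    fwd = 0
    while a + fwd + 1 <= len(A) and b + fwd + 1 <= len(B) and A[a + fwd] == B[b + fwd]:
        fwd += 1
    mh = A[a - bwd : a + fwd]
    return mh, bwd, fwd


# ---------------------------------------------------------------------------
# Applying rearrangements


@dataclass
class RearrangementResult:
    reference: Genome  # possibly rewritten to realise microhomology
    sample: SampleGenome
    truth: TruthRecord


def _der_name(chrom: str) -> str:
    return f"der({chrom})"


def _translocation_constraints(spec: RearrangementSpec):
    """Breakpoint bookkeeping plus the base-constraint system for one spec.

    Raises InfeasibleSpec (via solve) when the requested features interlock
    into a contradiction — e.g. unequal microhomology on a fully balanced
    translocation, or microhomology runs coupled through an indel shorter
    than themselves.
    """
    aA, bA = spec.pos_a, spec.pos_a + spec.deletion_a - spec.duplication_a
    aB, bB = spec.pos_b, spec.pos_b + spec.deletion_b - spec.duplication_b
    cons = _BaseConstraints()
    _engineer_junction(cons, (spec.chrom_a, aA), (spec.chrom_b, bB + 1), spec.junction_ab)
    _engineer_junction(cons, (spec.chrom_b, aB), (spec.chrom_a, bA + 1), spec.junction_ba)
    return cons, (aA, bA, aB, bB)


def translocation_spec_is_feasible(spec: RearrangementSpec) -> bool:
    """Can the requested junction features coexist in any sequence?"""
    try:
        cons, _ = _translocation_constraints(spec)
        cons.solve({})
        return True
    except InfeasibleSpec:
        return False


def apply_rearrangement(
    genome: Genome, spec: RearrangementSpec
) -> RearrangementResult:
    """Apply one rearrangement; see :func:`apply_rearrangements`."""
    return apply_rearrangements(genome, [spec])


def apply_rearrangements(
    genome: Genome, specs: Sequence[RearrangementSpec]
) -> RearrangementResult:
    """Build the rearranged sample genome and its ground truth.

    At most one reciprocal translocation is supported per call (mirroring a
    two-way translocation carrier); any number of intrachromosomal decoys may
    be layered on top, provided they avoid the translocation breakpoints.
    The returned reference may differ from the input at a handful of bases
    around the breakpoints where junction features were engineered.
    """
    trans = [s for s in specs if s.kind == "reciprocal_translocation"]
    if len(trans) > 1:
        raise ValueError("at most one reciprocal translocation per sample")
    truth = TruthRecord(specs=list(specs))
    seqs = {c: genome.sequence(c) for c in genome.chromosomes}

    sample_chroms: Dict[str, SampleChromosome] = {
        c: SampleChromosome(c, [Segment(c, 1, genome.length(c))]) for c in genome.chromosomes
    }

    if trans:
        spec = trans[0]
        _validate_translocation(genome, spec)
        cons, (aA, bA, aB, bB) = _translocation_constraints(spec)
        current = {}
        for key in list(cons.parent) + list(cons.forbidden):
            chrom, pos = key
            if 1 <= pos <= len(seqs[chrom]):
                current[cons._find(key)] = seqs[chrom][pos - 1]
        assignment = cons.solve(current)
        edits: Dict[str, Dict[int, str]] = {}
        for (chrom, pos), base in assignment.items():
            if 1 <= pos <= len(seqs[chrom]):
                edits.setdefault(chrom, {})[pos] = base
        for chrom, ed in edits.items():
            s = list(seqs[chrom])
            for pos, base in ed.items():
                s[pos - 1] = base
            seqs[chrom] = "".join(s)

        reference = Genome(seqs)
        ins_ab, ins_ba = spec.junction_ab.insertion.upper(), spec.junction_ba.insertion.upper()

        der_a = SampleChromosome(
            _der_name(spec.chrom_a),
            [
                Segment(spec.chrom_a, 1, aA),
                Segment(None, novel=ins_ab),
                Segment(spec.chrom_b, bB + 1, genome.length(spec.chrom_b)),
            ],
        )
        der_b = SampleChromosome(
            _der_name(spec.chrom_b),
            [
                Segment(spec.chrom_b, 1, aB),
                Segment(None, novel=ins_ba),
                Segment(spec.chrom_a, bA + 1, genome.length(spec.chrom_a)),
            ],
        )
        del sample_chroms[spec.chrom_a], sample_chroms[spec.chrom_b]
        new_chroms: Dict[str, SampleChromosome] = {}
        for c in genome.chromosomes:
            if c == spec.chrom_a:
                new_chroms[der_a.name] = der_a
            elif c == spec.chrom_b:
                new_chroms[der_b.name] = der_b
            else:
                new_chroms[c] = sample_chroms[c]
        sample_chroms = new_chroms

        for der, (p_chrom, p_end, s_chrom, s_start, feats) in {
            der_a.name: (spec.chrom_a, aA, spec.chrom_b, bB + 1, spec.junction_ab),
            der_b.name: (spec.chrom_b, aB, spec.chrom_a, bA + 1, spec.junction_ba),
        }.items():
            mh, bwd, fwd = _measure_junction(reference, p_chrom, p_end, s_chrom, s_start, feats.insertion)
            if feats.insertion:
                if mh:
                    raise InfeasibleSpec(f"{der}: insertion junction acquired microhomology")
            elif len(mh) != feats.microhomology or fwd != 0:
                raise InfeasibleSpec(
                    f"{der}: engineered microhomology came out as {len(mh)} bp "
                    f"(requested {feats.microhomology}, forward extension {fwd})"
                )
            truth.junctions.append(
                TruthJunction(
                    derivative=der,
                    prefix_chrom=p_chrom,
                    prefix_end=p_end,
                    suffix_chrom=s_chrom,
                    suffix_start=s_start,
                    microhomology=mh,
                    insertion=feats.insertion.upper(),
                    sample_chrom=der,
                    sample_pos=p_end,  # prefix segment starts at sample position 1
                )
            )

        for chrom, a, b in ((spec.chrom_a, aA, bA), (spec.chrom_b, aB, bB)):
            if b > a:
                truth.indels.append(
                    ChromIndel(chrom, "deletion", reference.fetch(chrom, a + 1, b),
                               GenomicInterval(chrom, a + 1, b)))
            elif b < a:
                truth.indels.append(
                    ChromIndel(chrom, "duplication", reference.fetch(chrom, b + 1, a),
                               GenomicInterval(chrom, b + 1, a)))
            else:
                truth.indels.append(ChromIndel(chrom, "balanced", "", None))
    else:
        reference = genome

    sample = SampleGenome(reference, list(sample_chroms.values()))

    decoy_n = 0
    for spec in specs:
        if spec.kind == "reciprocal_translocation":
            continue
        decoy_n += 1
        name = spec.name or f"decoy_{decoy_n}"
        if spec.kind == "deletion":
            sample.splice_deletion(spec.chrom, spec.start, spec.end)
            truth.decoys.append(
                DecoySV(name, "deletion", GenomicInterval(spec.chrom, spec.start, spec.end), False)
            )
        elif spec.kind == "tandem_duplication":
            sample.splice_tandem_duplication(spec.chrom, spec.start, spec.end)
            truth.decoys.append(
                DecoySV(name, "insertion", GenomicInterval(spec.chrom, spec.start, spec.end), False)
            )
        elif spec.kind == "insertion":
            rng = np.random.default_rng((hash(name) & 0x7FFFFFFF))
            novel = "".join(BASES[i] for i in rng.integers(0, 4, size=spec.insert_length))
            sample.splice_insertion(spec.chrom, spec.start, novel)
            truth.decoys.append(
                DecoySV(name, "insertion",
                        GenomicInterval(spec.chrom, spec.start, spec.start + spec.insert_length), False)
            )
    return RearrangementResult(reference, sample, truth)


def _validate_translocation(genome: Genome, spec: RearrangementSpec) -> None:
    margin = 1000  # junction windows and guard bases must stay inside the chromosome
    for chrom, pos, d, u in (
        (spec.chrom_a, spec.pos_a, spec.deletion_a, spec.duplication_a),
        (spec.chrom_b, spec.pos_b, spec.deletion_b, spec.duplication_b),
    ):
        if chrom not in genome:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (margin + u < pos < genome.length(chrom) - margin - d):
            raise InfeasibleSpec(
                f"breakpoint {chrom}:{pos} too close to a chromosome end for "
                f"the requested features"
            )


# ---------------------------------------------------------------------------
# Mate-pair read simulation


def _truncated_normal(rng: np.random.Generator, n: int, mean: float, sd: float,
                      lo: float, hi: float) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 16))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return np.round(out).astype(int)


def simulate_mate_pairs(
    sample: SampleGenome,
    config: SimulationConfig,
    truth: Optional[TruthRecord] = None,
    seed: Optional[int] = None,
) -> Tuple[List[AlignedPair], TruthRecord]:
    """Draw mate-pair fragments from the sample genome and emit aligned pairs.

    Fragment placement is uniform; insert sizes follow the configured
    truncated normal. Each read is placed at its true reference coordinates
    (clipped to its longest single-segment match when it crosses a junction).
    PCR duplicates are re-emissions of already-drawn fragments under fresh
    pair ids; reads whose midpoint falls in a repeat region are flagged
    non-unique with probability 1 − 1/copies of the repeat motif.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = truth if truth is not None else TruthRecord()
    exp_left, exp_right = CONVENTIONS[config.convention]
    rl = config.read_length

    names = sample.names()
    lengths = np.array([sample.chromosomes[n].length for n in names], dtype=float)
    n_pairs = config.effective_pair_count(int(lengths.sum()))
    chrom_idx = rng.choice(len(names), size=n_pairs, p=lengths / lengths.sum())
    inserts = _truncated_normal(
        rng, n_pairs, config.insert_mean, config.insert_sd, config.insert_min, config.insert_max
    )
    starts = (rng.random(n_pairs) * (lengths[chrom_idx] - inserts + 1)).astype(int) + 1

    repeat_copies = {}
    for rr in config.repeat_regions:
        copies = (rr.end - rr.start + 1) // config.repeat_motif_length
        repeat_copies[rr] = copies

    junction_bounds = []  # (sample_chrom, span_lo, span_hi, key)
    for j in truth.junctions:
        chrom = sample.chromosomes.get(j.sample_chrom)
        if chrom is None:
            continue
        lo = j.sample_pos
        hi = j.sample_pos + len(j.insertion) + 1
        junction_bounds.append((j.sample_chrom, lo, hi, truth.junction_key(j)))
        truth.spanning_fragments.setdefault(truth.junction_key(j), [])

    def uniqueness(mate: MateAlignment) -> bool:
        mid = (mate.start + mate.end) // 2
        for rr, copies in repeat_copies.items():
            if rr.chrom == mate.chrom and rr.start <= mid <= rr.end and copies >= 2:
                if rng.random() < 1.0 - 1.0 / copies:
                    return False
        return True

    pairs: List[AlignedPair] = []
    fragments: List[Tuple[int, int, int]] = []  # chrom idx, start, insert
    width = len(str(n_pairs * 2 + 10))
    for i in range(n_pairs):
        ci, s, ins = int(chrom_idx[i]), int(starts[i]), int(inserts[i])
        chrom = sample.chromosomes[names[ci]]
        pair = _emit_pair(chrom, s, ins, rl, exp_left, exp_right, f"p{i:0{width}d}", uniqueness)
        if pair is None:
            continue
        pairs.append(pair)
        fragments.append((ci, s, ins))
        for jc, lo, hi, key in junction_bounds:
            if names[ci] == jc and s <= lo and s + ins - 1 >= hi:
                truth.spanning_fragments[key].append(pair.pair_id)

    n_dup = int(round(config.duplicate_fraction * len(pairs)))
    if n_dup and pairs:
        picks = rng.integers(0, len(pairs), size=n_dup)
        for k, pick in enumerate(picks):
            orig = pairs[int(pick)]
            dup_id = f"p{n_pairs + k:0{width}d}"
            pairs.append(AlignedPair(dup_id, orig.mate1, orig.mate2))
    return pairs, truth


def _emit_pair(chrom, s, ins, rl, exp_left, exp_right, pair_id, uniqueness):
    left = chrom.map_read(s, s + rl - 1)
    right = chrom.map_read(s + ins - rl, s + ins - 1)
    if left is None or right is None:
        return None
    lc, la, lb, lstrand = left
    rc, ra, rb, rstrand = right
    lread = MateAlignment(lc, la, lb, exp_left if lstrand == "+" else exp_right, True)
    rread = MateAlignment(rc, ra, rb, exp_right if rstrand == "+" else exp_left, True)
    lread = MateAlignment(lread.chrom, lread.start, lread.end, lread.strand, uniqueness(lread))
    rread = MateAlignment(rread.chrom, rread.start, rread.end, rread.strand, uniqueness(rread))
    return AlignedPair(pair_id, lread, rread)


# ---------------------------------------------------------------------------
# Known-SV catalogue


def make_known_catalogue(
    truth: TruthRecord,
    common_names: Sequence[str],
    seed: int = 0,
    jitter: int = 200,
) -> Tuple[List[FeatureRecord], TruthRecord]:
    """A DGV-style catalogue covering the decoys named in ``common_names``.

    Each listed decoy gets a catalogue record overlapping it by >= 80 % (one-
    sided, of the decoy); unlisted decoys and the engineered translocation
    junctions get none. Decoys are re-labelled with their catalogue membership.
    """
    rng = np.random.default_rng(seed)
    records: List[FeatureRecord] = []
    new_decoys: List[DecoySV] = []
    for d in truth.decoys:
        common = d.name in common_names
        new_decoys.append(DecoySV(d.name, d.sv_type, d.interval, common))
        if not common:
            continue
        width = d.interval.width
        pad = int(rng.integers(0, jitter + 1))
        shift = int(rng.integers(-min(jitter, width // 10), min(jitter, width // 10) + 1))
        start = max(1, d.interval.start + shift - pad)
        end = d.interval.end + shift + pad
        rec = FeatureRecord(
            GenomicInterval(d.interval.chrom, start, end),
            "known_sv",
            f"dgv_{d.name}",
            {"sv_type": d.sv_type},
        )
        # guarantee the advertised one-sided overlap despite jitter
        shared = rec.interval.shared_bases(d.interval)
        if shared / d.interval.width < 0.8:
            rec = FeatureRecord(d.interval, "known_sv", f"dgv_{d.name}", {"sv_type": d.sv_type})
        records.append(rec)
    truth.decoys = new_decoys
    return records, truth


# ---------------------------------------------------------------------------
# Random rearrangement specs (for property-style recovery tests)


def random_translocation_spec(
    rng: np.random.Generator,
    genome: Genome,
    chrom_a: Optional[str] = None,
    chrom_b: Optional[str] = None,
    max_feature: int = 10,
) -> RearrangementSpec:
    """A random reciprocal translocation with junction features in 0–10 bp.

    Samples until the feature combination is satisfiable: some combinations
    are structurally impossible (a fully balanced translocation forces equal
    microhomology at its two junctions, and indels shorter than an adjacent
    microhomology run can couple the two junctions into a contradiction).
    """
    chroms = genome.chromosomes
    if chrom_a is None or chrom_b is None:
        ia, ib = rng.choice(len(chroms), size=2, replace=False)
        chrom_a, chrom_b = chroms[int(ia)], chroms[int(ib)]
    pos_a = int(rng.integers(50_000, genome.length(chrom_a) - 50_000))
    pos_b = int(rng.integers(50_000, genome.length(chrom_b) - 50_000))

    def indel() -> Tuple[int, int]:
        r = rng.random()
        if r < 0.4:
            return int(rng.integers(1, max_feature + 1)), 0
        if r < 0.6:
            return 0, int(rng.integers(1, max_feature + 1))
        return 0, 0

    def features() -> JunctionFeatures:
        r = rng.random()
        if r < 0.4:
            return JunctionFeatures(microhomology=int(rng.integers(1, max_feature + 1)))
        if r < 0.6:
            n = int(rng.integers(1, max_feature + 1))
            ins = "".join(BASES[i] for i in rng.integers(0, 4, size=n))
            return JunctionFeatures(insertion=ins)
        return JunctionFeatures()

    for _ in range(200):
        del_a, dup_a = indel()
        del_b, dup_b = indel()
        jab, jba = features(), features()
        balanced = del_a == dup_a == del_b == dup_b == 0
        if balanced and not jab.insertion and not jba.insertion:
            jba = JunctionFeatures(microhomology=jab.microhomology)
        spec = RearrangementSpec(
            kind="reciprocal_translocation",
            chrom_a=chrom_a, pos_a=pos_a, chrom_b=chrom_b, pos_b=pos_b,
            junction_ab=jab, junction_ba=jba,
            deletion_a=del_a, duplication_a=dup_a,
            deletion_b=del_b, duplication_b=dup_b,
        )
        if translocation_spec_is_feasible(spec):
            return spec
    raise InfeasibleSpec("could not sample a feasible rearrangement spec")
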