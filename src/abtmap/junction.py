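"""Nucleotide-level refinement of translocation junctions.

A junction-spanning sequence (the in-silico analogue of a Sanger-sequenced
PCR amplicon across the derivative junction) is split-aligned against the two
partner reference flanks: the maximal prefix of the junction matching one
partner and the maximal suffix matching the other either overlap
(microhomology — the breakpoint placement is ambiguous over overlap+1
positions), leave a gap (untemplated insertion), or meet exactly (blunt
join).

Placement convention: where microhomology makes the breakpoint ambiguous, the
canonical placement anchors the shared bases to the *prefix* chromosome of
each junction. Under this convention the per-chromosome deletion and
duplication strings obtained by reconciling the two reciprocal derivatives
are independent of the microhomology lengths, and the reported breakpoint
interval widths follow the simple arithmetic deletion+2 / duplication /
balanced→2. The full ambiguity interval is reported alongside every call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import Breakpoint, Genome, GenomicInterval, revcomp
from .simulate import SampleGenome, TruthJunction


class UnanchoredJunctionError(ValueError):
    """The junction sequence could not be uniquely anchored on a flank."""


@dataclass(frozen=True)
class BreakpointCall:
    """A refined breakpoint: canonical placement plus its ambiguity interval."""

    chrom: str
    position: int
    ambiguity: GenomicInterval

    def __post_init__(self) -> None:
        if not self.ambiguity.contains(self.chrom, self.position):
            raise ValueError("canonical placement must lie inside the ambiguity interval")


@dataclass
class RefinedJunction:
    """One derivative junction at base-pair resolution."""

    derivative: str
    prefix: BreakpointCall  # last retained base of the prefix chromosome
    suffix: BreakpointCall  # first retained base of the suffix chromosome
    microhomology: str
    insertion: str

    def __post_init__(self) -> None:
        if self.microhomology and self.insertion:
            raise ValueError("microhomology and untemplated insertion are exclusive")
        if self.prefix.ambiguity.width != len(self.microhomology) + 1:
            raise ValueError("ambiguity interval width must be microhomology length + 1")


@dataclass(frozen=True)
class ChromReconciliation:
    """What happened to one original chromosome across both derivatives."""

    chrom: str
    kind: str  # deletion | duplication | balanced
    sequence: str  # read from the reference + strand
    interval: GenomicInterval  # Table-style breakpoint interval


@dataclass
class ReconciledTranslocation:
    """Both reciprocal junctions plus per-chromosome imbalances."""

    junction_ab: RefinedJunction
    junction_ba: RefinedJunction
    reconciliation: Dict[str, ChromReconciliation]

    @property
    def chromosomes(self) -> Tuple[str, str]:
        return self.junction_ab.prefix.chrom, self.junction_ab.suffix.chrom


@dataclass
class ConcordanceReport:
    members: List[str]
    verdict: str  # identical | discordant
    diffs: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Junction sequence extraction


def extract_junction_sequence(
    sample: SampleGenome,
    junction: TruthJunction,
    window: int = 400,
    error_rate: float = 0.0,
    seed: int = 0,
) -> str:
    """Window of derivative sequence centred on a junction.

    Stands in for the PCR amplicon spanning the reconstructed derivative
    junction. ``error_rate`` optionally injects base errors to exercise the
    mismatch-tolerant refinement mode. A window reaching past a chromosome
    end is truncated with a warning.
    """
    chrom = sample.chromosomes[junction.sample_chrom]
    seq = chrom.sequence(sample.reference)
    centre = junction.sample_pos + len(junction.insertion) // 2
    lo = centre - window // 2 + 1
    hi = lo + window - 1
    if lo < 1 or hi > len(seq):
        import warnings

        warnings.warn(
            f"junction window truncated at {junction.sample_chrom} boundary", stacklevel=2
        )
        lo, hi = max(1, lo), min(len(seq), hi)
    out = seq[lo - 1 : hi]
    if error_rate > 0:
        import numpy as np

        rng = np.random.default_rng(seed)
        bases = "ACGT"
        chars = list(out)
        for i in np.nonzero(rng.random(len(chars)) < error_rate)[0]:
            chars[int(i)] = bases[(bases.index(chars[int(i)]) + 1 + int(rng.integers(0, 3))) % 4]
        out = "".join(chars)
    return out


def junction_sample_locus(
    sample: SampleGenome, derivative: str, ref_chrom: str, ref_pos: int
) -> Optional[int]:
    """Derivative coordinate of a reference position (for prediction-guided extraction)."""
    chrom = sample.chromosomes.get(derivative)
    if chrom is None:
        return None
    return chrom.sample_position(ref_chrom, ref_pos)


# ---------------------------------------------------------------------------
# Split alignment


def _find_unique(haystack: str, needle: str) -> Optional[int]:
    p = haystack.find(needle)
    if p < 0:
        return None
    if haystack.find(needle, p + 1) >= 0:
        return None
    return p


def _extend_match(a: str, b: str, tolerant: bool, per: int = 50, tail: int = 8) -> int:
    """Length of the leading run of ``a`` matching ``b``.

    Exact by default. Tolerant mode allows roughly one mismatch per ``per``
    aligned bases (plus one), but the accepted extension must end in ``tail``
    consecutive matches — random sequence beyond the true junction matches a
    quarter of the time, so requiring an exact tail stops the extension from
    creeping past it.
    """
    n = min(len(a), len(b))
    if not tolerant:
        i = 0
        while i < n and a[i] == b[i]:
            i += 1
        return i
    good = 0
    mismatches = 0
    run = 0
    for i in range(n):
        if a[i] == b[i]:
            run += 1
            if mismatches <= (i + 1) // per + 1 and (run >= tail or run == i + 1):
                good = i + 1
        else:
            mismatches += 1
            run = 0
            if mismatches > n // per + 1:
                break
    return good


def refine_breakpoint(
    junction_seq: str,
    reference: Genome,
    prefix_chrom: str,
    prefix_region: GenomicInterval,
    suffix_chrom: str,
    suffix_region: GenomicInterval,
    prefix_strand: str = "+",
    suffix_strand: str = "+",
    anchor_k: int = 20,
    derivative: str = "",
    tolerant: bool = False,
) -> RefinedJunction:
    """Split-align a junction sequence against its two partner flanks.

    The first ``anchor_k`` bases must occur exactly once in the prefix search
    region and the last ``anchor_k`` exactly once in the suffix region;
    otherwise the junction is unanchored. Matching is exact by default; the
    tolerant mode (for error-bearing evidence) forgives one mismatch per 50
    matched bases.
    """
    J = junction_seq.upper()
    if len(J) < 2 * anchor_k:
        raise UnanchoredJunctionError(
            f"junction sequence ({len(J)} bp) shorter than two anchors ({2 * anchor_k} bp)"
        )

    sa = reference.fetch(prefix_chrom, prefix_region.start, prefix_region.end)
    if prefix_strand == "-":
        sa = revcomp(sa)
    p = _find_unique(sa, J[:anchor_k])
    if p is None:
        raise UnanchoredJunctionError(
            f"prefix anchor not found uniquely in {prefix_chrom}:{prefix_region.start}-{prefix_region.end}"
        )
    L = _extend_match(J, sa[p:], tolerant)

    sb = reference.fetch(suffix_chrom, suffix_region.start, suffix_region.end)
    if suffix_strand == "-":
        sb = revcomp(sb)
    q = _find_unique(sb, J[-anchor_k:])
    if q is None:
        raise UnanchoredJunctionError(
            f"suffix anchor not found uniquely in {suffix_chrom}:{suffix_region.start}-{suffix_region.end}"
        )
    q_end = q + anchor_k - 1  # offset (in sb) of J's last base
    R = _extend_match(J[::-1], sb[: q_end + 1][::-1], tolerant)

    def pos_a(offset: int) -> int:
        # reference position of sa[offset]
        if prefix_strand == "+":
            return prefix_region.start + offset
        return prefix_region.end - offset

    def pos_b(offset: int) -> int:
        if suffix_strand == "+":
            return suffix_region.start + offset
        return suffix_region.end - offset

    n = len(J)
    overlap = L + R - n
    if overlap >= 0:
        microhomology = J[n - R : L]
        insertion = ""
        split = L  # canonical: microhomology anchored to the prefix chromosome
        suffix_first_idx = L
    else:
        microhomology = ""
        insertion = J[L : n - R]
        split = L
        suffix_first_idx = n - R

    prefix_pos = pos_a(p + split - 1)
    suffix_pos = pos_b(q_end - (n - 1 - suffix_first_idx))

    # admissible split indices range over [n-R, L] when flanks overlap
    pre_positions = sorted((pos_a(p + n - R - 1), pos_a(p + L - 1)))
    suf_positions = sorted(
        (pos_b(q_end - (n - 1 - (n - R))), pos_b(q_end - (n - 1 - L)))
    ) if overlap >= 0 else None

    prefix_call = BreakpointCall(
        prefix_chrom,
        prefix_pos,
        GenomicInterval(prefix_chrom, pre_positions[0], pre_positions[1])
        if overlap > 0
        else GenomicInterval(prefix_chrom, prefix_pos, prefix_pos),
    )
    suffix_call = BreakpointCall(
        suffix_chrom,
        suffix_pos,
        GenomicInterval(suffix_chrom, suf_positions[0], suf_positions[1])
        if overlap > 0 and suf_positions
        else GenomicInterval(suffix_chrom, suffix_pos, suffix_pos),
    )
    return RefinedJunction(
        derivative=derivative,
        prefix=prefix_call,
        suffix=suffix_call,
        microhomology=microhomology,
        insertion=insertion,
    )


# ---------------------------------------------------------------------------
# Reconciliation of the two reciprocal derivatives


def _reconcile_chrom(
    chrom: str, last_retained: int, first_resumed: int, reference: Genome
) -> ChromReconciliation:
    a, s = last_retained, first_resumed
    if s == a + 1:
        return ChromReconciliation(chrom, "balanced", "", GenomicInterval(chrom, a, s))
    if s > a + 1:
        return ChromReconciliation(
            chrom, "deletion", reference.fetch(chrom, a + 1, s - 1), GenomicInterval(chrom, a, s)
        )
    return ChromReconciliation(
        chrom, "duplication", reference.fetch(chrom, s, a), GenomicInterval(chrom, s, a)
    )


def reconcile_derivatives(
    junction_ab: RefinedJunction, junction_ba: RefinedJunction, reference: Genome
) -> ReconciledTranslocation:
    """Combine the two reciprocal junctions into per-chromosome imbalances.

    Reference bases retained on neither derivative are a deletion (reported
    from the + strand); bases retained on both are a duplication. Sequence
    shared between the two *partner references* at one junction is
    microhomology; only this cross-derivative comparison can expose
    duplications, which single-junction evidence cannot distinguish from
    microhomology.
    """
    chrom_a = junction_ab.prefix.chrom
    chrom_b = junction_ab.suffix.chrom
    if (junction_ba.prefix.chrom, junction_ba.suffix.chrom) != (chrom_b, chrom_a):
        raise ValueError(
            "the two junctions do not describe a reciprocal pair: "
            f"{chrom_a}/{chrom_b} vs {junction_ba.prefix.chrom}/{junction_ba.suffix.chrom}"
        )
    rec = {
        chrom_a: _reconcile_chrom(
            chrom_a, junction_ab.prefix.position, junction_ba.suffix.position, reference
        ),
        chrom_b: _reconcile_chrom(
            chrom_b, junction_ba.prefix.position, junction_ab.suffix.position, reference
        ),
    }
    return ReconciledTranslocation(junction_ab, junction_ba, rec)


def breakpoint_interval_report(reconciled: ReconciledTranslocation) -> Dict[str, GenomicInterval]:
    """Per-chromosome breakpoint intervals, spanning from the last base
    retained by one derivative to the first base retained by the other."""
    return {c: r.interval for c, r in reconciled.reconciliation.items()}


# ---------------------------------------------------------------------------
# Family concordance


def compare_family(per_member: Dict[str, ReconciledTranslocation]) -> ConcordanceReport:
    """Are the refined junctions identical across members carrying the translocation?"""
    members = sorted(per_member)
    if len(members) < 2:
        raise ValueError("family comparison needs at least two members")
    for name in members:
        if per_member[name] is None:
            raise ValueError(f"member {name!r} is missing a refined junction")
    first = per_member[members[0]]
    diffs: List[str] = []
    for m in members[1:]:
        other = per_member[m]
        if other is None:
            raise ValueError(f"member {m!r} is missing a refined junction")
        for label, ja, jb in (
            ("junction_ab", first.junction_ab, other.junction_ab),
            ("junction_ba", first.junction_ba, other.junction_ba),
        ):
            for fieldname in ("prefix", "suffix"):
                pa, pb = getattr(ja, fieldname), getattr(jb, fieldname)
                if (pa.chrom, pa.position) != (pb.chrom, pb.position):
                    diffs.append(
                        f"{m}: {label}.{fieldname} {pb.chrom}:{pb.position} != "
                        f"{members[0]}'s {pa.chrom}:{pa.position}"
                    )
            if ja.microhomology != jb.microhomology:
                diffs.append(f"{m}: {label} microhomology {jb.microhomology!r} != {ja.microhomology!r}")
            if ja.insertion != jb.insertion:
                diffs.append(f"{m}: {label} insertion {jb.insertion!r} != {ja.insertion!r}")
        for chrom in first.reconciliation:
            ra = first.reconciliation[chrom]
            rb = other.reconciliation.get(chrom)
            if rb is None:
                diffs.append(f"{m}: no reconciliation for {chrom}")
                continue
            if (ra.kind, ra.sequence) != (rb.kind, rb.sequence):
                diffs.append(
                    f"{m}: {chrom} indel {rb.kind}:{rb.sequence!r} != {ra.kind}:{ra.sequence!r}"
                )
    return ConcordanceReport(members, "identical" if not diffs else "discordant", diffs)


# ---------------------------------------------------------------------------
# Junction rendering (three-line view: references top/bottom, junction middle)


def render_junction(
    refined: RefinedJunction, reference: Genome, flank: int = 30
) -> str:
    """Text rendering of a junction: prefix reference on top, junction sequence
    in the middle, suffix reference below; microhomology in [brackets],
    untemplated insertion in lower case."""
    a = refined.prefix.position
    s = refined.suffix.position
    mh, ins = refined.microhomology, refined.insertion
    pre = reference.fetch(refined.prefix.chrom, max(1, a - flank + 1), a)
    suf_end = min(reference.length(refined.suffix.chrom), s + flank - 1)
    suf = reference.fetch(refined.suffix.chrom, s, suf_end)
    # microhomology is the tail of the prefix flank under the canonical placement
    body = (pre[: -len(mh)] + f"[{mh}]") if mh else pre
    mid = body + ins.lower() + suf
    top = f"{refined.prefix.chrom}:{a}  " + pre + "-" * (len(mid) - len(pre))
    bottom = "-" * (len(mid) - len(suf)) + suf + f"  {refined.suffix.chrom}:{s}"
    return "\n".join([top, mid, bottom])
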