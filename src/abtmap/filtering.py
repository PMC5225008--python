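"""Reduction of SV predictions to credible, patient-specific candidates.

Three filters, applied in order: read-pair support (default: at least five
independent pairs after duplicate removal), overlap with a catalogue of known
common SVs (default: drop intrachromosomal predictions covered >= 80 % by a
same-type catalogue record), and family comparison (keep only the affected
member's predictions with no counterpart in any other member).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import FeatureRecord, GenomicInterval, overlap_fraction
from .detect import SVPrediction

LOW_SUPPORT = "low_support"
KNOWN_VARIANT = "known_variant"
SHARED_IN_FAMILY = "shared_in_family"
RETAINED = "retained"


@dataclass
class FilterReport:
    """Disposition of every input prediction through one filter stage."""

    stage: str
    input_count: int
    survivors: int
    dispositions: List[Tuple[str, str]] = field(default_factory=list)  # (name, reason)

    def __post_init__(self) -> None:
        if len(self.dispositions) != self.input_count:
            raise ValueError("dispositions must partition the input")
        retained = sum(1 for _, r in self.dispositions if r == RETAINED)
        if retained != self.survivors:
            raise ValueError("survivor count inconsistent with dispositions")


def filter_by_support(
    predictions: Sequence[SVPrediction], min_support: int = 5
) -> Tuple[List[SVPrediction], FilterReport]:
    """Keep predictions supported by at least ``min_support`` distinct pairs."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    survivors: List[SVPrediction] = []
    dispositions: List[Tuple[str, str]] = []
    for p in predictions:
        if p.support >= min_support:
            survivors.append(p)
            dispositions.append((p.name, RETAINED))
        else:
            dispositions.append((p.name, LOW_SUPPORT))
    return survivors, FilterReport("support", len(predictions), len(survivors), dispositions)


def filter_known(
    predictions: Sequence[SVPrediction],
    catalogue: Sequence[FeatureRecord],
    threshold: float = 0.8,
    mode: str = "of_a",
) -> Tuple[List[SVPrediction], FilterReport]:
    """Drop intrachromosomal predictions matching a known-SV catalogue.

    A prediction is removed iff a same-type catalogue record overlaps its
    affected span by >= threshold under the configured mode (``of_a``:
    fraction of the prediction covered; ``reciprocal``: both ways).
    Interchromosomal predictions (translocations) can never match an interval
    record and always survive.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    survivors: List[SVPrediction] = []
    dispositions: List[Tuple[str, str]] = []
    cat = [c for c in catalogue if c.kind == "known_sv"]
    for p in predictions:
        removed = False
        if p.interval_a.chrom == p.interval_b.chrom:
            span = p.span
            for rec in cat:
                if rec.attributes.get("sv_type") not in (None, p.sv_type):
                    continue
                if overlap_fraction(span, rec.interval, mode) >= threshold:
                    removed = True
                    break
        if removed:
            dispositions.append((p.name, KNOWN_VARIANT))
        else:
            survivors.append(p)
            dispositions.append((p.name, RETAINED))
    return survivors, FilterReport("known", len(predictions), len(survivors), dispositions)


def _same_event(a: SVPrediction, b: SVPrediction, tolerance: int) -> bool:
    """Do two predictions describe the same event, within positional jitter?

    Breakpoint estimates jitter between members even for identical events, so
    matching uses midpoint distance on both partners rather than exact
    coordinates.
    """
    if a.sv_type != b.sv_type:
        return False
    if (a.interval_a.chrom, a.interval_b.chrom) == (b.interval_a.chrom, b.interval_b.chrom):
        pairs = ((a.interval_a, b.interval_a), (a.interval_b, b.interval_b))
    elif (a.interval_a.chrom, a.interval_b.chrom) == (b.interval_b.chrom, b.interval_a.chrom):
        pairs = ((a.interval_a, b.interval_b), (a.interval_b, b.interval_a))
    else:
        return False
    return all(abs(x.midpoint - y.midpoint) <= tolerance for x, y in pairs)


def patient_specific(
    predictions_by_member: Dict[str, Sequence[SVPrediction]],
    affected: str,
    tolerance: int = 4000,
) -> Tuple[List[SVPrediction], FilterReport]:
    """Keep the affected member's predictions absent from every other member."""
    if affected not in predictions_by_member:
        raise ValueError(f"affected member {affected!r} not in the prediction map")
    if len(predictions_by_member) < 2:
        raise ValueError("patient-specific filtering needs at least two members")
    others = [
        p
        for member, preds in predictions_by_member.items()
        if member != affected
        for p in preds
    ]
    survivors: List[SVPrediction] = []
    dispositions: List[Tuple[str, str]] = []
    for p in predictions_by_member[affected]:
        if any(_same_event(p, o, tolerance) for o in others):
            dispositions.append((p.name, SHARED_IN_FAMILY))
        else:
            survivors.append(p)
            dispositions.append((p.name, RETAINED))
    return survivors, FilterReport(
        "patient_specific", len(predictions_by_member[affected]), len(survivors), dispositions
    )
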