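"""End-to-end orchestration: simulate → detect → filter → refine → annotate → report.

The pipeline mirrors a family study: every member carries the same reciprocal
translocation (plus member-specific decoy SVs), each member's mate-pair
library is detected and filtered independently, translocation junctions are
refined to the nucleotide and compared across members, and the decoy SV
stream is reduced to patient-specific candidates. All intermediates are
written as plain-text formats and the run is fully deterministic given the
seed.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import io as aio
from .annotate import (
    BreakpointAnnotation,
    FeatureIndex,
    MechanismCall,
    classify_mechanism,
    genes_at_breakpoint,
    repeats_at_breakpoint,
)
from .core import Breakpoint, FeatureRecord, Genome, GenomicInterval, interval_width, parse_interval
from .detect import AlignedPair, SVPrediction, cluster_discordant, dedupe_and_unique_filter
from .filtering import filter_by_support, filter_known, patient_specific
from .junction import (
    ConcordanceReport,
    ReconciledTranslocation,
    RefinedJunction,
    breakpoint_interval_report,
    compare_family,
    extract_junction_sequence,
    reconcile_derivatives,
    refine_breakpoint,
)
from .simulate import (
    DecoySV,
    RearrangementSpec,
    JunctionFeatures,
    SimulationConfig,
    TruthRecord,
    apply_rearrangements,
    generate_reference,
    make_known_catalogue,
    simulate_mate_pairs,
)

log = logging.getLogger("abtmap")


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class MemberConfig:
    name: str
    affected: bool = False


@dataclass
class DecoyConfig:
    name: str
    chrom: str
    start: int
    end: int
    members: List[str] = field(default_factory=list)  # members carrying it
    common: bool = False  # listed in the known-SV catalogue


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "abtmap_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    translocation: Optional[RearrangementSpec] = None
    decoys: List[DecoyConfig] = field(default_factory=list)
    members: List[MemberConfig] = field(default_factory=list)
    # detection
    distance: Optional[int] = None
    # filtering
    min_support: int = 5
    known_overlap: float = 0.8
    overlap_mode: str = "of_a"
    # junction refinement
    window: int = 400
    anchor_k: int = 20
    # annotation / mechanism
    flank: int = 500
    min_homology_length: int = 50
    min_identity: float = 0.9
    min_microhomology: int = 2
    cne_window: int = 1_000_000
    # optional tracks (BED/BED12 paths); synthesized when absent
    genes_track: Optional[str] = None
    repeats_track: Optional[str] = None
    cnes_track: Optional[str] = None

    def __post_init__(self) -> None:
        if self.members and len({m.name for m in self.members}) != len(self.members):
            raise ValueError("member names must be unique")

    @property
    def affected_member(self) -> str:
        for m in self.members:
            if m.affected:
                return m.name
        raise ValueError("no affected member configured")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = SimulationConfig(**raw.pop("simulation", {}))
        trans = raw.pop("translocation", None)
        if trans is not None:
            for key in ("junction_ab", "junction_ba"):
                if key in trans and isinstance(trans[key], dict):
                    trans[key] = JunctionFeatures(**trans[key])
            trans = RearrangementSpec(kind="reciprocal_translocation", **trans)
        members = [MemberConfig(**m) for m in raw.pop("members", [])]
        decoys = [DecoyConfig(**d) for d in raw.pop("decoys", [])]
        return cls(simulation=sim, translocation=trans, members=members, decoys=decoys, **raw)

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            return obj

        doc = plain(self)
        if doc.get("translocation"):
            doc["translocation"].pop("kind", None)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def demo_config(outdir: str | Path, seed: int = 1) -> PipelineConfig:
    """A small two-member family with one translocation and three decoy SVs."""
    sim = SimulationConfig(
        seed=seed,
        chromosome_lengths={"chr1": 1_000_000, "chr2": 700_000, "chr3": 500_000},
        duplicate_fraction=0.05,
        physical_coverage=10.0,
    )
    trans = RearrangementSpec(
        kind="reciprocal_translocation",
        chrom_a="chr1", pos_a=400_000, chrom_b="chr2", pos_b=300_000,
        junction_ab=JunctionFeatures(microhomology=1),
        junction_ba=JunctionFeatures(microhomology=2),
        deletion_a=3, deletion_b=3,
    )
    decoys = [
        DecoyConfig("decoy_common", "chr3", 100_000, 140_000,
                    members=["proband", "mother"], common=True),
        DecoyConfig("decoy_shared", "chr3", 250_000, 285_000,
                    members=["proband", "mother"], common=False),
        DecoyConfig("decoy_private", "chr3", 380_000, 420_000,
                    members=["proband"], common=False),
    ]
    return PipelineConfig(
        seed=seed,
        outdir=str(outdir),
        simulation=sim,
        translocation=trans,
        decoys=decoys,
        members=[MemberConfig("proband", affected=True), MemberConfig("mother")],
    )


# ---------------------------------------------------------------------------
# Result containers


REPORT_COLUMNS = [
    "member", "affected", "derivative", "chrom",
    "mps_junction", "mps_width_bp", "read_pairs",
    "breakpoint_interval", "breakpoint_width_bp",
    "disrupted_genes", "indel", "microhomology", "repeats",
    "mechanism", "family_verdict",
]


@dataclass
class MemberResult:
    name: str
    affected: bool
    pairs_file: Path
    predictions: List[SVPrediction]
    filter_reports: list
    reconciled: Optional[ReconciledTranslocation]
    truth: TruthRecord


@dataclass
class PipelineResult:
    config: PipelineConfig
    reference: Genome
    members: Dict[str, MemberResult]
    concordance: Optional[ConcordanceReport]
    patient_specific_svs: List[SVPrediction]
    report_rows: List[dict]
    outdir: Path


# ---------------------------------------------------------------------------
# Synthetic annotation tracks (used when the config names no track files)


def synthesize_tracks(
    reference: Genome, spec: RearrangementSpec, outdir: Path
) -> Tuple[Path, Path, Path]:
    """Gene/repeat/CNE tracks placed relative to the engineered breakpoints.

    A 6-exon minus-strand gene spans the chrom_b breakpoint (the breakpoint
    falls in its intron 1 in transcription order), a repeat overlaps the
    chrom_a breakpoint, and one CNE sits 400 kb from it.
    """
    b = spec.pos_b
    exon_w, intron_w = 200, 2000
    # minus-strand gene: transcription runs right-to-left, so intron 1 in
    # transcription order is the right-most intron in genomic coordinates;
    # the breakpoint lands mid-way through it
    gene_start = b - 4 * (exon_w + intron_w) - exon_w - intron_w // 2
    exons = []
    pos = gene_start
    for _ in range(6):
        exons.append(GenomicInterval(spec.chrom_b, pos, pos + exon_w - 1, "-"))
        pos += exon_w + intron_w
    gene = FeatureRecord(
        GenomicInterval(spec.chrom_b, exons[0].start, exons[-1].end, "-"),
        "gene", "GENE1", {"exons": exons},
    )
    genes_path = outdir / "genes.bed12"
    aio.write_bed12([gene], genes_path)

    a = spec.pos_a
    repeats = [
        FeatureRecord(GenomicInterval(spec.chrom_a, a - 120, a + 130), "repeat",
                      "SINE-MIR-MIRb", {"family": "SINE-MIR"}),
    ]
    repeats_path = outdir / "repeats.bed"
    aio.write_bed(repeats, repeats_path)

    cnes = [
        FeatureRecord(GenomicInterval(spec.chrom_a, max(1, a - 400_000), max(200, a - 400_000 + 180)),
                      "CNE", "CNE1"),
    ]
    cnes_path = outdir / "cnes.bed"
    aio.write_bed(cnes, cnes_path)
    return genes_path, repeats_path, cnes_path


# ---------------------------------------------------------------------------
# Pipeline


def _member_seed(base_seed: int, index: int) -> int:
    return (base_seed * 100_003 + 7919 * (index + 1)) % (2**31 - 1)


def _format_indel(rec) -> str:
    if rec.kind == "balanced":
        return "—"
    suffix = "del." if rec.kind == "deletion" else "dupl."
    return f"{len(rec.sequence)}bp-{rec.sequence} {suffix}"


def _match_prediction(
    predictions: Sequence[SVPrediction], prefix_chrom: str, suffix_chrom: str, position: int
) -> Optional[SVPrediction]:
    candidates = [
        p for p in predictions
        if p.sv_type == "translocation"
        and p.interval_a.chrom == prefix_chrom
        and p.interval_b.chrom == suffix_chrom
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda p: abs(p.interval_a.midpoint - position))


def run_pipeline(config: PipelineConfig, resume: bool = False) -> PipelineResult:
    """Run the full pipeline; every intermediate is written under the outdir.

    With ``resume=True`` existing output files are left untouched (stages
    recompute in memory but do not rewrite), so a rerun on a completed
    directory changes nothing.
    """
    if config.translocation is None:
        raise ValueError("pipeline config needs a translocation spec")
    if len(config.members) < 2:
        raise ValueError("pipeline needs at least two family members")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def emit(path: Path, writer) -> Path:
        if resume and path.exists():
            log.info("resume: keeping %s", path)
            return path
        writer(path)
        return path

    log.info("stage simulate: seed %d", config.seed)
    base_reference = generate_reference(config.simulation)
    member_results: Dict[str, MemberResult] = {}
    reference: Optional[Genome] = None
    catalogue_truth = TruthRecord(
        decoys=[
            DecoySV(d.name, "deletion", GenomicInterval(d.chrom, d.start, d.end), d.common)
            for d in config.decoys
        ]
    )
    catalogue, _ = make_known_catalogue(
        catalogue_truth, [d.name for d in config.decoys if d.common], seed=config.seed
    )
    emit(outdir / "known_svs.bed", lambda p: aio.write_bed(catalogue, p))

    samples = {}
    for idx, member in enumerate(config.members):
        specs: List[RearrangementSpec] = [config.translocation]
        for d in config.decoys:
            if member.name in d.members:
                specs.append(
                    RearrangementSpec(kind="deletion", chrom=d.chrom, start=d.start,
                                      end=d.end, name=d.name)
                )
        result = apply_rearrangements(base_reference, specs)
        if reference is None:
            reference = result.reference
            emit(outdir / "reference.fa", lambda p: aio.write_fasta(reference, p))
        samples[member.name] = result

        pairs, truth = simulate_mate_pairs(
            result.sample, config.simulation, result.truth,
            seed=_member_seed(config.seed, idx),
        )
        pairs_file = emit(
            outdir / f"{member.name}.pairs.tsv", lambda p: aio.write_pairs_tsv(pairs, p)
        )

        log.info("stage detect [%s]: %d pairs", member.name, len(pairs))
        usable = dedupe_and_unique_filter(pairs)
        predictions = cluster_discordant(
            usable, reference,
            convention=config.simulation.convention,
            insert_min=config.simulation.insert_min,
            insert_max=config.simulation.insert_max,
            distance=config.distance,
        )
        for p in predictions:
            p.name = f"{member.name}_{p.name}"
        emit(outdir / f"{member.name}.predictions.bedpe",
             lambda pth: aio.write_bedpe(predictions, pth, reference))

        log.info("stage filter [%s]: %d predictions", member.name, len(predictions))
        supported, rep_support = filter_by_support(predictions, config.min_support)
        known_pass, rep_known = filter_known(
            supported, catalogue, config.known_overlap, config.overlap_mode
        )
        for rep in (rep_support, rep_known):
            for name, reason in rep.dispositions:
                if reason != "retained":
                    log.info("filtered [%s] %s: %s", member.name, name, reason)
        member_results[member.name] = MemberResult(
            name=member.name, affected=member.affected, pairs_file=pairs_file,
            predictions=predictions, filter_reports=[rep_support, rep_known],
            reconciled=None, truth=truth,
        )
        rows = [
            {"stage": rep.stage, "prediction": name, "disposition": reason}
            for rep in (rep_support, rep_known)
            for name, reason in rep.dispositions
        ]
        emit(outdir / f"{member.name}.filter_report.tsv",
             lambda pth: aio.write_tsv(rows, pth, ["stage", "prediction", "disposition"]))

    assert reference is not None

    # family comparison on the post-catalogue survivors of the affected member
    survivors_by_member = {
        name: [p for p in mr.predictions
               if p.support >= config.min_support]
        for name, mr in member_results.items()
    }
    known_pass_affected, _ = filter_known(
        survivors_by_member[config.affected_member], catalogue,
        config.known_overlap, config.overlap_mode,
    )
    family_map = dict(survivors_by_member)
    family_map[config.affected_member] = known_pass_affected
    tolerance = config.distance if config.distance is not None else config.simulation.insert_max
    specific, rep_family = patient_specific(
        family_map, config.affected_member, tolerance=tolerance
    )
    specific = [p for p in specific if p.sv_type != "translocation"]
    for name, reason in rep_family.dispositions:
        if reason != "retained":
            log.info("filtered [family] %s: %s", name, reason)
    emit(outdir / "patient_specific.bedpe", lambda p: aio.write_bedpe(specific, p, reference))

    # junction refinement per member
    log.info("stage refine: window %d", config.window)
    spec = config.translocation
    slack = config.simulation.insert_max + config.window
    for member in config.members:
        mr = member_results[member.name]
        result = samples[member.name]
        junctions: List[RefinedJunction] = []
        for tj in result.truth.junctions:
            jseq = extract_junction_sequence(result.sample, tj, window=config.window)
            pred = _match_prediction(
                mr.predictions, tj.prefix_chrom, tj.suffix_chrom, tj.prefix_end
            )
            if pred is not None:
                region_a = GenomicInterval(
                    tj.prefix_chrom,
                    max(1, pred.interval_a.start - slack),
                    min(reference.length(tj.prefix_chrom), pred.interval_a.end + slack),
                )
                region_b = GenomicInterval(
                    tj.suffix_chrom,
                    max(1, pred.interval_b.start - slack),
                    min(reference.length(tj.suffix_chrom), pred.interval_b.end + slack),
                )
            else:
                log.warning("no cluster matched junction %s in %s", tj.derivative, member.name)
                region_a = GenomicInterval(
                    tj.prefix_chrom, max(1, tj.prefix_end - slack), tj.prefix_end + slack
                )
                region_b = GenomicInterval(
                    tj.suffix_chrom, max(1, tj.suffix_start - slack), tj.suffix_start + slack
                )
            refined = refine_breakpoint(
                jseq, reference, tj.prefix_chrom, region_a, tj.suffix_chrom, region_b,
                anchor_k=config.anchor_k, derivative=tj.derivative,
            )
            junctions.append(refined)
        ab = next(j for j in junctions if j.prefix.chrom == spec.chrom_a)
        ba = next(j for j in junctions if j.prefix.chrom == spec.chrom_b)
        mr.reconciled = reconcile_derivatives(ab, ba, reference)

    concordance = compare_family(
        {name: mr.reconciled for name, mr in member_results.items() if mr.reconciled}
    )
    log.info("family concordance: %s", concordance.verdict)

    # annotation tracks
    if config.genes_track and config.repeats_track and config.cnes_track:
        genes = (aio.read_bed12(config.genes_track)
                 if str(config.genes_track).endswith("bed12")
                 else aio.read_gff3(config.genes_track))
        repeats = aio.read_bed(config.repeats_track, kind="repeat")
        cnes = aio.read_bed(config.cnes_track, kind="CNE")
    else:
        gp, rp, cp = outdir / "genes.bed12", outdir / "repeats.bed", outdir / "cnes.bed"
        if not (resume and gp.exists() and rp.exists() and cp.exists()):
            synthesize_tracks(reference, spec, outdir)
        genes, repeats, cnes = aio.read_bed12(gp), aio.read_bed(rp, "repeat"), aio.read_bed(cp, "CNE")
    repeat_index = FeatureIndex(repeats)

    # Table-style report
    report_rows: List[dict] = []
    for member in config.members:
        mr = member_results[member.name]
        rec = mr.reconciled
        if rec is None:
            continue
        intervals = breakpoint_interval_report(rec)
        for junction in (rec.junction_ab, rec.junction_ba):
            chrom = junction.prefix.chrom
            bp_ivl = intervals[chrom]
            pred = _match_prediction(
                mr.predictions, chrom, junction.suffix.chrom, junction.prefix.position
            )
            disruptions = genes_at_breakpoint(bp_ivl, genes)
            reps = repeats_at_breakpoint(bp_ivl, repeat_index)
            mech = classify_mechanism(
                junction, reference,
                flank=config.flank,
                min_homology_length=config.min_homology_length,
                min_identity=config.min_identity,
                min_microhomology=config.min_microhomology,
            )
            report_rows.append(
                {
                    "member": member.name,
                    "affected": "yes" if member.affected else "no",
                    "derivative": junction.derivative,
                    "chrom": chrom,
                    "mps_junction": str(pred.interval_a) if pred else "",
                    "mps_width_bp": pred.interval_a.width if pred else "",
                    "read_pairs": pred.support if pred else 0,
                    "breakpoint_interval": str(bp_ivl),
                    "breakpoint_width_bp": bp_ivl.width,
                    "disrupted_genes": " & ".join(
                        f"{d.gene} ({d.region} {d.index})" for d in disruptions
                    ) or "—",
                    "indel": _format_indel(rec.reconciliation[chrom]),
                    "microhomology": junction.microhomology or "—",
                    "repeats": ", ".join(r.name for r in reps) or "—",
                    "mechanism": mech.label,
                    "family_verdict": concordance.verdict,
                }
            )
    emit(outdir / "report.tsv", lambda p: aio.write_tsv(report_rows, p, REPORT_COLUMNS))
    emit(outdir / "junctions.vcf", lambda p: write_vcf_bnd(
        {name: mr.reconciled for name, mr in member_results.items() if mr.reconciled},
        reference, p,
    ))
    emit(outdir / "effective_config.yaml", lambda p: config.to_yaml(p))

    return PipelineResult(
        config=config,
        reference=reference,
        members=member_results,
        concordance=concordance,
        patient_specific_svs=specific,
        report_rows=report_rows,
        outdir=outdir,
    )


# ---------------------------------------------------------------------------
# VCF breakend output


VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">
##INFO=<ID=EVENT,Number=1,Type=String,Description="Rearrangement event id">
##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Length of breakpoint microhomology">
##INFO=<ID=HOMSEQ,Number=1,Type=String,Description="Microhomology sequence">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf_bnd(
    reconciled_by_name: Dict[str, ReconciledTranslocation],
    reference: Genome,
    path: str | Path,
) -> None:
    """Emit every derivative junction as a reciprocal pair of VCF 4.2 breakends.

    The prefix-side record's ALT points rightward into the suffix chromosome
    (``t[chr:pos[``); the suffix-side record points leftward back
    (``]chr:pos]t``). Untemplated insertions ride along in ALT; microhomology
    goes to HOMLEN/HOMSEQ.
    """
    lines: List[str] = []
    for event, rec in sorted(reconciled_by_name.items()):
        for jname, j in (("ab", rec.junction_ab), ("ba", rec.junction_ba)):
            p_chrom, p_pos = j.prefix.chrom, j.prefix.position
            s_chrom, s_pos = j.suffix.chrom, j.suffix.position
            ref_p = reference.fetch(p_chrom, p_pos, p_pos)
            ref_s = reference.fetch(s_chrom, s_pos, s_pos)
            ins = j.insertion
            info_common = f"SVTYPE=BND;EVENT={event}_{jname}"
            if j.microhomology:
                info_common += f";HOMLEN={len(j.microhomology)};HOMSEQ={j.microhomology}"
            else:
                info_common += ";HOMLEN=0"
            id1, id2 = f"{event}_{jname}_1", f"{event}_{jname}_2"
            alt1 = f"{ref_p}{ins}[{s_chrom}:{s_pos}["
            alt2 = f"]{p_chrom}:{p_pos}]{ins}{ref_s}"
            lines.append(
                f"{p_chrom}\t{p_pos}\t{id1}\t{ref_p}\t{alt1}\t.\tPASS\t{info_common};MATEID={id2}"
            )
            lines.append(
                f"{s_chrom}\t{s_pos}\t{id2}\t{ref_s}\t{alt2}\t.\tPASS\t{info_common};MATEID={id1}"
            )
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("\n".join(lines) + ("\n" if lines else ""))


_BND_RE = re.compile(r"^(?P<t>[ACGTN]*)(?P<b1>[\[\]])(?P<chrom>[\w.]+):(?P<pos>\d+)(?P<b2>[\[\]])(?P<t2>[ACGTN]*)$")


def parse_vcf_bnd(path: str | Path) -> List[dict]:
    """Parse breakend records back out of a VCF written by :func:`write_vcf_bnd`."""
    out: List[dict] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, vid, ref, alt, _, _, info = line.rstrip("\n").split("\t")[:8]
            m = _BND_RE.match(alt)
            if not m:
                raise aio.FormatError(f"{path}: unparseable BND ALT {alt!r}")
            fields = dict(kv.partition("=")[::2] for kv in info.split(";") if "=" in kv)
            leading = bool(m.group("t"))
            inserted = (m.group("t")[1:] if leading else m.group("t2")[:-1])
            out.append(
                {
                    "id": vid,
                    "chrom": chrom,
                    "pos": int(pos),
                    "mate_chrom": m.group("chrom"),
                    "mate_pos": int(m.group("pos")),
                    "bracket": m.group("b1"),
                    "prefix_side": leading,
                    "insertion": inserted,
                    "homlen": int(fields.get("HOMLEN", 0)),
                    "homseq": fields.get("HOMSEQ", ""),
                    "mateid": fields.get("MATEID", ""),
                }
            )
    return out


# ---------------------------------------------------------------------------
# Bundled breakpoint-report fixture


def load_table_fixture() -> List[dict]:
    """The bundled 18-junction breakpoint report used for arithmetic checks."""
    with resources.files("abtmap.data").joinpath("table1_junctions.tsv").open() as fh:
        import csv

        return list(csv.DictReader(fh, delimiter="\t"))


def load_reported_svs() -> List[dict]:
    with resources.files("abtmap.data").joinpath("reported_svs.tsv").open() as fh:
        import csv

        return list(csv.DictReader(fh, delimiter="\t"))


def table1_fixture_check() -> dict:
    """Recompute every junction width in the bundled fixture from its coordinates.

    Returns the row count, any rows whose printed width disagrees with the
    coordinate arithmetic, and the min/max width summary (kb rounded to one
    decimal, the convention used for sub-100 kb sizes).
    """
    rows = load_table_fixture()
    mismatches = []
    widths = []
    for i, row in enumerate(rows, 1):
        ivl = parse_interval(row["junction_interval"])
        w = interval_width(ivl)
        widths.append(w)
        if w != int(row["junction_length_bp"]):
            mismatches.append(
                {"row": i, "interval": row["junction_interval"],
                 "printed": int(row["junction_length_bp"]), "computed": w}
            )
    return {
        "rows": len(rows),
        "mismatches": mismatches,
        "min_width_bp": min(widths),
        "max_width_bp": max(widths),
        "max_width_kb": round(max(widths) / 1000, 1),
        "widths": widths,
    }
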