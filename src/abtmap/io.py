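"""Readers and writers for the standard genomics formats the pipeline touches.

On disk, BED-family formats are 0-based half-open; everything in memory is
1-based fully closed. The conversion happens exactly once, here. Writers emit
records in deterministic order (declared chromosome order, then start) so
reruns are byte-identical.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import FeatureRecord, Genome, GenomicInterval
from .detect import AlignedPair, MateAlignment, SVPrediction


class FormatError(ValueError):
    """A file violated its format; message carries the path and line number."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> Genome:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise FormatError(f"{path}: no sequences found")
    return Genome(seqs)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(genome.sequence(c)), id=c, description="")
        for c in genome.chromosomes
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED (3 or 6 columns) <-> FeatureRecord

def read_bed(path: str | Path, kind: str = "repeat") -> List[FeatureRecord]:
    """Read BED3/BED6 into FeatureRecords of the given kind.

    The name field may carry extra key=value attributes after a '|'
    (e.g. ``del_1|sv_type=deletion``).
    """
    records: List[FeatureRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end0 <= start0:
                raise FormatError(f"{path}:{lineno}: end <= start")
            name = parts[3] if len(parts) > 3 else f"{kind}_{lineno}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            attrs: Dict[str, object] = {}
            if "|" in name:
                name, _, extra = name.partition("|")
                for kv in extra.split(";"):
                    if "=" in kv:
                        k, _, v = kv.partition("=")
                        attrs[k] = v
            records.append(
                FeatureRecord(
                    GenomicInterval(parts[0], start0 + 1, end0, strand), kind, name, attrs
                )
            )
    return records


def write_bed(
    records: Sequence[FeatureRecord], path: str | Path, genome: Optional[Genome] = None
) -> None:
    def sort_key(r: FeatureRecord):
        rank = genome.rank(r.interval.chrom) if genome and r.interval.chrom in genome else 0
        return (rank, r.interval.chrom, r.interval.start, r.interval.end, r.name)

    with open(path, "w") as fh:
        for r in sorted(records, key=sort_key):
            name = r.name
            extras = {k: v for k, v in r.attributes.items() if k != "exons"}
            if extras:
                name += "|" + ";".join(f"{k}={v}" for k, v in sorted(extras.items()))
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start - 1}\t{r.interval.end}"
                f"\t{name}\t0\t{r.interval.strand if r.interval.strand != '.' else '.'}\n"
            )


# ---------------------------------------------------------------------------
# BED12 gene models (blocks are exons)

def read_bed12(path: str | Path) -> List[FeatureRecord]:
    genes: List[FeatureRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED12 columns")
            chrom, start0, end0, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            exons = [
                GenomicInterval(chrom, start0 + off + 1, start0 + off + size, strand)
                for off, size in zip(offsets, sizes)
            ]
            genes.append(
                FeatureRecord(
                    GenomicInterval(chrom, start0 + 1, end0, strand),
                    "gene",
                    name,
                    {"exons": exons},
                )
            )
    return genes


def write_bed12(genes: Sequence[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda r: (r.interval.chrom, r.interval.start, r.name)):
            exons = g.attributes["exons"]
            start0 = g.interval.start - 1
            sizes = ",".join(str(e.width) for e in exons) + ","
            offsets = ",".join(str(e.start - 1 - start0) for e in exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.interval.chrom,
                        str(start0),
                        str(g.interval.end),
                        g.name,
                        "0",
                        g.interval.strand if g.interval.strand != "." else "+",
                        str(start0),
                        str(g.interval.end),
                        "0",
                        str(len(exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene models (gene + exon features, linked by Parent/ID)

def read_gff3(path: str | Path) -> List[FeatureRecord]:
    genes: Dict[str, dict] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs_raw = parts
            attrs = dict(
                kv.partition("=")[::2] for kv in attrs_raw.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attrs.get("ID", f"gene_{lineno}")
                genes[gid] = {
                    "name": attrs.get("Name", gid),
                    "interval": GenomicInterval(chrom, int(start), int(end), strand),
                    "exons": [],
                }
                order.append(gid)
            elif ftype == "exon":
                parent = attrs.get("Parent", "")
                # tolerate exons parented to an mRNA named <gene>.t1 etc.
                gid = parent.split(".")[0]
                if gid in genes:
                    genes[gid]["exons"].append(
                        GenomicInterval(chrom, int(start), int(end), strand)
                    )
    out = []
    for gid in order:
        g = genes[gid]
        exons = sorted(g["exons"], key=lambda e: e.start)
        out.append(FeatureRecord(g["interval"], "gene", g["name"], {"exons": exons}))
    return out


# ---------------------------------------------------------------------------
# BEDPE <-> SVPrediction

def write_bedpe(
    predictions: Sequence[SVPrediction], path: str | Path, genome: Optional[Genome] = None
) -> None:
    def sort_key(p: SVPrediction):
        ra = genome.rank(p.interval_a.chrom) if genome and p.interval_a.chrom in genome else 0
        return (ra, p.interval_a.chrom, p.interval_a.start, p.interval_b.chrom, p.interval_b.start)

    with open(path, "w") as fh:
        for p in sorted(predictions, key=sort_key):
            fh.write(
                "\t".join(
                    [
                        p.interval_a.chrom,
                        str(p.interval_a.start - 1),
                        str(p.interval_a.end),
                        p.interval_b.chrom,
                        str(p.interval_b.start - 1),
                        str(p.interval_b.end),
                        f"{p.name}|type={p.sv_type};pairs={','.join(p.pair_ids)}",
                        str(p.support),
                        p.orientation[0],
                        p.orientation[1],
                    ]
                )
                + "\n"
            )


def read_bedpe(path: str | Path) -> List[SVPrediction]:
    preds: List[SVPrediction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise FormatError(f"{path}:{lineno}: expected 10 BEDPE columns")
            name_field = parts[6]
            name, _, extra = name_field.partition("|")
            attrs = dict(kv.partition("=")[::2] for kv in extra.split(";") if "=" in kv)
            sv_type = attrs.get("type", "translocation")
            pair_ids = tuple(attrs["pairs"].split(",")) if attrs.get("pairs") else ()
            if not pair_ids:
                pair_ids = tuple(f"{name}_p{i}" for i in range(int(parts[7])))
            preds.append(
                SVPrediction(
                    sv_type=sv_type,
                    interval_a=GenomicInterval(parts[0], int(parts[1]) + 1, int(parts[2])),
                    interval_b=GenomicInterval(parts[3], int(parts[4]) + 1, int(parts[5])),
                    pair_ids=pair_ids,
                    orientation=(parts[8], parts[9]),
                    name=name,
                )
            )
    return preds


# ---------------------------------------------------------------------------
# AlignedPair TSV and SAM-text adapter

PAIR_COLUMNS = [
    "pair_id",
    "chrom1", "start1", "end1", "strand1", "unique1",
    "chrom2", "start2", "end2", "strand2", "unique2",
]


def write_pairs_tsv(pairs: Sequence[AlignedPair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PAIR_COLUMNS)
        for p in pairs:
            w.writerow(
                [
                    p.pair_id,
                    p.mate1.chrom, p.mate1.start, p.mate1.end, p.mate1.strand, int(p.mate1.unique),
                    p.mate2.chrom, p.mate2.start, p.mate2.end, p.mate2.strand, int(p.mate2.unique),
                ]
            )


def read_pairs_tsv(path: str | Path) -> List[AlignedPair]:
    pairs: List[AlignedPair] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 2):
            try:
                pairs.append(
                    AlignedPair(
                        row["pair_id"],
                        MateAlignment(
                            row["chrom1"], int(row["start1"]), int(row["end1"]),
                            row["strand1"], bool(int(row["unique1"])),
                        ),
                        MateAlignment(
                            row["chrom2"], int(row["start2"]), int(row["end2"]),
                            row["strand2"], bool(int(row["unique2"])),
                        ),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad pair record ({exc})") from exc
    return pairs


def read_sam_pairs(path: str | Path, min_mapq: int = 1) -> List[AlignedPair]:
    """Adapter: ingest SAM text into AlignedPairs.

    Mates are joined on query name; a mate with MAPQ 0 (or below ``min_mapq``)
    is treated as non-uniquely mapped. Secondary/supplementary records are
    ignored.
    """
    import pysam

    mates: Dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            mates.setdefault(rec.query_name, []).append(rec)
    pairs: List[AlignedPair] = []
    for name in sorted(mates):
        recs = mates[name]
        if len(recs) != 2:
            continue
        out = []
        for rec in recs:
            out.append(
                MateAlignment(
                    rec.reference_name,
                    rec.reference_start + 1,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                    rec.mapping_quality >= min_mapq,
                )
            )
        pairs.append(AlignedPair(name, out[0], out[1]))
    return pairs


# ---------------------------------------------------------------------------
# Generic TSV helpers (reports)

def write_tsv(rows: Sequence[dict], path: str | Path, columns: Sequence[str]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t", lineterminator="\n")
        w.writeheader()
        for row in rows:
            w.writerow(row)


def read_tsv(path: str | Path) -> List[dict]:
    with open(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
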