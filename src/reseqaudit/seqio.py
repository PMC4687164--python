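"""Readers and writers for the formats the audit touches.

FASTA and FASTQ go through Bio.SeqIO, SAM through pysam, GFF3 reading
through gffutils; the tabular reports are plain TSV written with pandas.
On-disk coordinates follow each format's native convention (GFF3 and
reported positions 1-based; SAM POS 1-based); everything in memory is
0-based half-open.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Iterator
from typing import TYPE_CHECKING

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.iterators import DataIterator

from .records import (
    AlignmentRecord,
    AuditSummary,
    CdsFeature,
    CoverageSummary,
    Discrepancy,
    GenomeRecord,
    OrthologSupport,
    ReadPair,
)

if TYPE_CHECKING:
    from .records import CodingImpact


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str, n_policy: str = "keep") -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    ``n_policy``: "keep" leaves N as-is; "map" converts any non-ACGT
    character to N; "reject" raises on characters outside {A,C,G,T,N}.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        if n_policy == "map":
            seq = "".join(c if c in "ACGT" else "N" for c in seq)
        elif set(seq) - set("ACGTN"):
            raise FormatError(f"{path}: record {rec.id!r} has non-ACGTN characters")
        records.append(GenomeRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str, width: int = 70) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        path,
        "fasta",
    )


# ---------------------------------------------------------------- GFF3


def read_gff3(path: str) -> list[CdsFeature]:
    """Read CDS features from GFF3, converting to 0-based half-open."""
    feats: list[CdsFeature] = []
    for f in DataIterator(path):
        if f.featuretype != "CDS":
            continue
        if f.start > f.end:
            raise FormatError(f"{path}: CDS with start > end at {f.seqid}:{f.start}")
        if f.strand not in "+-":
            raise FormatError(f"{path}: CDS with unknown strand {f.strand!r}")
        fid = f.attributes.get("ID", [f"{f.seqid}:{f.start}-{f.end}"])[0]
        product = f.attributes.get("product", [""])[0]
        phase = int(f.frame) if f.frame in ("0", "1", "2") else 0
        feats.append(
            CdsFeature(
                id=fid,
                genome_id=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand,
                phase=phase,
                product=product,
            )
        )
    return feats


def write_gff3(features: Iterable[CdsFeature], path: str) -> None:
    """Write CDS features as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                "\t".join(
                    [
                        f.genome_id,
                        "reseqaudit",
                        "CDS",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        str(f.phase),
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------- FASTQ


def read_fastq(path: str) -> Iterator[tuple[str, str, list[int]]]:
    """Stream (id, sequence, phred) tuples from a Phred+33 FASTQ file."""
    for rec in SeqIO.parse(path, "fastq"):
        yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]


def read_fastq_pairs(path1: str, path2: str) -> Iterator[ReadPair]:
    for (id1, s1, q1), (id2, s2, q2) in zip(read_fastq(path1), read_fastq(path2), strict=True):
        base = id1.removesuffix("/1")
        yield ReadPair(id=base, seq1=s1, seq2=s2, qual1=q1, qual2=q2)


def write_fastq_pairs(pairs: Iterable[ReadPair], path1: str, path2: str) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = "".join(chr(q + 33) for q in p.qual1)
            q2 = "".join(chr(q + 33) for q in p.qual2)
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{q2}\n")


# ---------------------------------------------------------------- SAM


def read_sam(path: str, genomes: list[GenomeRecord]) -> Iterator[AlignmentRecord]:
    """Stream mapped alignments from a SAM file (text only).

    SAM 1-based POS is converted to 0-based; hard clips are rejected,
    soft clips kept as S ops.
    """
    known = {g.id for g in genomes}
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            if aln.reference_name not in known:
                raise FormatError(
                    f"{path}: reference {aln.reference_name!r} not in provided genomes"
                )
            ops = []
            for code, length in aln.cigartuples:
                op = "MIDNSHP=X"[code]
                if op in "=X":
                    op = "M"
                if op not in "MIDS":
                    raise FormatError(f"{path}: unsupported CIGAR op {op!r}")
                ops.append((op, length))
            yield AlignmentRecord(
                read_id=aln.query_name,
                ref_id=aln.reference_name,
                ref_start=aln.reference_start,
                strand="-" if aln.is_reverse else "+",
                cigar=ops,
                seq=aln.query_sequence or "",
                edit_distance=aln.get_tag("NM") if aln.has_tag("NM") else 0,
            )


def write_sam(alignments: Iterable[AlignmentRecord], genomes: list[GenomeRecord], path: str) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": g.id, "LN": len(g)} for g in genomes],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        refs = {g.id: i for i, g in enumerate(genomes)}
        for a in alignments:
            s = pysam.AlignedSegment(out.header)
            s.query_name = a.read_id
            s.query_sequence = a.seq
            s.flag = 16 if a.strand == "-" else 0
            s.reference_id = refs[a.ref_id]
            s.reference_start = a.ref_start
            s.mapping_quality = 60
            s.cigartuples = [("MIDNSHP=X".index(op), n) for op, n in a.cigar]
            s.set_tag("NM", a.edit_distance)
            out.write(s)


# ---------------------------------------------------------------- reports


def _fmt_mn(s: OrthologSupport | None) -> str:
    if s is None or s.protein_matches is None:
        return "NF"
    return f"{s.protein_matches}/{s.protein_aligned_length}"


def write_reports(
    out_dir: str,
    discrepancies: list[Discrepancy],
    summary: AuditSummary,
    histogram: dict[int, int],
    corrected_genome: GenomeRecord,
    lifted_features: list[CdsFeature],
    impacts: list["CodingImpact"] | None = None,
    supports: list[OrthologSupport] | None = None,
    coverage: CoverageSummary | None = None,
) -> dict[str, str]:
    """Write the audit report bundle; returns {name: path}.

    The discrepancy table mirrors the published comparison table: 1-based
    position, allele, affected gene id(s), homopolymer length at the site,
    amino-acid lengths before/after correction, ortholog identity as "m/n",
    and the related-genome support verdict.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    by_pos_imp = {i.position: i for i in (impacts or [])}
    by_pos_sup = {s.position: s for s in (supports or [])}
    rows = []
    for d in discrepancies:
        imp = by_pos_imp.get(d.position)
        sup = by_pos_sup.get(d.position)
        rows.append(
            {
                "position": d.position + 1,
                "type": d.type,
                "allele": d.alt_allele if d.type != "deletion" else d.ref_allele,
                "gene_ids": ",".join(d.gene_ids),
                "region": d.region,
                "homopolymer_length": d.homopolymer_length,
                "aa_length_corrected": imp.new_protein_length if imp else "",
                "aa_lengths_reference": ",".join(map(str, imp.old_protein_lengths)) if imp else "",
                "effect": imp.effect if imp else "",
                "ortholog_identity": _fmt_mn(sup),
                "support": sup.verdict if sup else "",
                "depth": d.depth,
                "alt_fraction": f"{d.alt_fraction:.3f}",
            }
        )
    p = os.path.join(out_dir, "discrepancies.tsv")
    pd.DataFrame(
        rows,
        columns=[
            "position",
            "type",
            "allele",
            "gene_ids",
            "region",
            "homopolymer_length",
            "aa_length_corrected",
            "aa_lengths_reference",
            "effect",
            "ortholog_identity",
            "support",
            "depth",
            "alt_fraction",
        ],
    ).to_csv(p, sep="\t", index=False)
    paths["discrepancies"] = p

    p = os.path.join(out_dir, "homopolymer_histogram.tsv")
    pd.DataFrame(
        sorted(histogram.items()), columns=["run_length", "count"]
    ).to_csv(p, sep="\t", index=False)
    paths["histogram"] = p

    srows = [
        ("n_total", summary.n_total),
        ("n_insertions", summary.n_insertions),
        ("n_deletions", summary.n_deletions),
        ("n_substitutions", summary.n_substitutions),
        ("n_coding", summary.n_coding),
        ("fraction_coding_pct", f"{100 * summary.fraction_coding:.1f}"),
        ("n_run_gt4", summary.n_run_gt4),
        ("n_run_gt5", summary.n_run_gt5),
        ("fraction_run_gt4_pct", f"{100 * summary.fraction_run_gt4:.1f}"),
        ("corrected_genome_length", len(corrected_genome)),
    ]
    if coverage is not None:
        srows += [
            ("mean_depth", f"{coverage.mean_depth:.2f}"),
            ("sd_depth", f"{coverage.sd_depth:.2f}"),
            ("mean_read_length", f"{coverage.mean_read_length:.2f}"),
            ("n_mapped_reads", coverage.n_mapped_reads),
            ("pct_cds_full_breadth", f"{coverage.pct_cds_full_breadth:.2f}"),
            ("pct_cds_breadth60", f"{coverage.pct_cds_breadth60:.2f}"),
        ]
    if supports:
        tally = {"confirms_corrected": 0, "confirms_reference": 0, "neither": 0, "not_found": 0}
        for s in supports:
            tally[s.verdict] += 1
        srows += [(f"crossval_{k}", v) for k, v in tally.items()]
    p = os.path.join(out_dir, "summary.tsv")
    pd.DataFrame(srows, columns=["metric", "value"]).to_csv(p, sep="\t", index=False)
    paths["summary"] = p

    p = os.path.join(out_dir, "corrected.fasta")
    write_fasta([corrected_genome], p)
    paths["corrected_fasta"] = p
    p = os.path.join(out_dir, "corrected.gff3")
    write_gff3(lifted_features, p)
    paths["corrected_gff3"] = p
    return paths


def write_vcf(discrepancies: list[Discrepancy], genome: GenomeRecord, path: str) -> None:
    """Write discrepancies as a minimal VCF (left-aligned, anchor-base convention)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.id},length={len(genome)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for d in sorted(discrepancies, key=lambda d: d.position):
            if d.type == "substitution":
                pos, ref, alt = d.position + 1, d.ref_allele, d.alt_allele
            elif d.type == "insertion":
                # anchor base at the normalized anchor column
                pos = d.position + 1
                anchor = genome.sequence[d.position]
                ref, alt = anchor, anchor + d.alt_allele
            else:
                pos = d.position  # base before the deleted run
                anchor = genome.sequence[d.position - 1]
                ref, alt = anchor + d.ref_allele, anchor
            info = f"DP={d.depth};AF={d.alt_fraction:.3f}"
            fh.write(f"{genome.id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")
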