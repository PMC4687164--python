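"""Core domain records shared across the audit pipeline.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based, half-open.  On-disk formats keep
their native conventions (GFF3/SAM/VCF 1-based), converted at the I/O
boundary.  Insertions are anchored AFTER a reference column: an insertion
with ``position == p`` places its allele between reference positions ``p``
and ``p + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGTN")


@dataclass
class GenomeRecord:
    """A named nucleotide sequence, optionally circular."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"genome {self.id!r}: illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CdsFeature:
    """An annotated coding region (0-based half-open interval)."""

    id: str
    genome_id: str
    start: int
    end: int
    strand: str
    phase: int = 0
    product: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"CDS {self.id!r}: bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"CDS {self.id!r}: strand must be + or -, got {self.strand!r}")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"CDS {self.id!r}: phase must be 0/1/2")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ReadPair:
    """A paired-end read with per-base Phred scores."""

    id: str
    seq1: str
    seq2: str
    qual1: list[int]
    qual2: list[int]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id!r}: sequence/quality length mismatch")


@dataclass
class AlignmentRecord:
    """One read aligned to a reference (internal SAM-like representation).

    ``cigar`` is a list of ``(op, length)`` with op in {M, I, D, S}; M/D
    consume reference, M/I/S consume the read.
    """

    read_id: str
    ref_id: str
    ref_start: int
    strand: str
    cigar: list[tuple[str, int]]
    seq: str
    edit_distance: int = 0

    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    def read_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")

    def ref_end(self) -> int:
        return self.ref_start + self.ref_span()

    def __post_init__(self) -> None:
        if self.seq and self.read_span() != len(self.seq):
            raise ValueError(
                f"alignment {self.read_id!r}: CIGAR consumes {self.read_span()} "
                f"read bases but sequence has {len(self.seq)}"
            )


@dataclass
class Discrepancy:
    """A normalized single-site difference between reads-consensus and reference.

    For insertions ``position`` is the left-normalized anchor column (the
    insertion follows it) and ``ref_allele`` is empty.  For deletions
    ``ref_allele`` is the deleted reference string starting at ``position``.
    """

    ref_id: str
    position: int
    type: str  # insertion | deletion | substitution
    ref_allele: str
    alt_allele: str
    depth: int = 0
    alt_support: int = 0
    alt_fraction: float = 0.0
    homopolymer_base: str = ""
    homopolymer_length: int = 0
    region: str = ""  # coding | noncoding
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.type not in ("insertion", "deletion", "substitution"):
            raise ValueError(f"bad discrepancy type {self.type!r}")
        if self.type == "insertion" and (self.ref_allele or not self.alt_allele):
            raise ValueError("insertion requires empty ref_allele and non-empty alt_allele")

    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass
class TruthRecord:
    """Ground truth for one planted assembly error, in corrupted-assembly coordinates.

    ``type`` is the discrepancy as seen from reads vs the corrupted assembly
    (a planted deletion is observed as an insertion).  Indel positions are
    left-normalized anchors.
    """

    true_position: int
    type: str
    base: str
    run_length_at_site: int
    in_cds: bool
    affected_cds_ids: list[str] = field(default_factory=list)


@dataclass
class HomopolymerAnnotation:
    """A maximal single-base run on the reference."""

    base: str
    run_length: int
    run_start: int
    run_end: int


@dataclass
class AuditSummary:
    """Integer tallies over an annotated discrepancy set."""

    n_total: int = 0
    n_insertions: int = 0
    n_deletions: int = 0
    n_substitutions: int = 0
    n_coding: int = 0
    fraction_coding: float = 0.0
    counts_by_run_length: dict[int, int] = field(default_factory=dict)
    n_run_gt4: int = 0
    n_run_gt5: int = 0
    fraction_run_gt4: float = 0.0


@dataclass
class CodingImpact:
    """Coding consequence of applying the correction(s) at one site."""

    position: int
    old_gene_ids: list[str]
    effect: str  # frameshift_repair | stop_removed | gene_merge | synonymous | missense | intergenic | other
    old_protein_lengths: list[int] = field(default_factory=list)
    new_protein_length: int = 0
    new_protein: str = ""
    expected_ortholog_length: int | None = None


@dataclass
class TransferMatch:
    """Annotation-transfer score of a query protein against a reference protein."""

    query_cds_id: str
    reference_cds_id: str
    identity_fraction: float
    coverage_fraction: float
    combined_identity: float
    accepted: bool
    match_class: str  # perfect | length_mismatch | no_match


@dataclass
class OrthologSupport:
    """Which allele a related genome's homologous region supports."""

    position: int
    related_region_found: bool
    verdict: str  # confirms_corrected | confirms_reference | neither | not_found
    protein_matches: int | None = None
    protein_aligned_length: int | None = None
    protein_identical: bool | None = None


@dataclass
class CoverageSummary:
    """Genome-wide depth moments and per-CDS breadth statistics."""

    mean_depth: float
    sd_depth: float
    mean_read_length: float
    n_mapped_reads: int
    per_cds: list[tuple[str, float]]
    pct_cds_full_breadth: float
    pct_cds_breadth60: float
    min_depth: int
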