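"""Apply corrections, lift annotation, and classify coding consequences.

The central objects are the corrected genome, the coordinate map between
old and corrected coordinates, and per-site :class:`CodingImpact`
records: does a correction repair a frameshift, remove a premature stop,
or re-join a gene that the erroneous assembly had split in two?

Annotation transfer between the corrected genome and a reference
annotation is scored by *combined identity*: alignment identity times
the fraction of the reference protein covered, accepted at 0.25 (i.e.
50 % identity over 50 % of the length).  Statistical significance of a
hit is approximated by a Karlin–Altschul-style e-value proxy computed
from the alignment score; full extreme-value calibration is out of
scope and the proxy is declared as such.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from dataclasses import dataclass

from Bio import Align
from Bio.Seq import Seq

from .records import CdsFeature, CodingImpact, Discrepancy, GenomeRecord, TransferMatch
from .simgen import revcomp

logger = logging.getLogger(__name__)

START_CODONS = ("ATG", "GTG", "TTG")
TRANSLATION_TABLE = 11


class ContractError(ValueError):
    pass


# ---------------------------------------------------------------- coordinates


@dataclass
class CoordinateMap:
    """Piecewise-offset map from old reference to corrected coordinates.

    Built from normalized, non-conflicting discrepancies.  ``forward``
    maps an old boundary coordinate (0-based offset, so genome length is
    a valid input) to the corrected one; ``inverse`` goes back.
    """

    breakpoints: list[tuple[int, int]]  # (old_boundary, offset for coords >= boundary)
    total_offset: int

    @classmethod
    def from_discrepancies(cls, discrepancies: list[Discrepancy]) -> "CoordinateMap":
        events = []  # (old_boundary, delta)
        for d in sorted(discrepancies, key=lambda d: d.position):
            if d.type == "insertion":
                # allele sits between position and position+1
                events.append((d.position + 1, len(d.alt_allele)))
            elif d.type == "deletion":
                events.append((d.position + len(d.ref_allele), -len(d.ref_allele)))
        breakpoints = [(0, 0)]
        off = 0
        for b, delta in events:
            off += delta
            breakpoints.append((b, off))
        return cls(breakpoints=breakpoints, total_offset=off)

    def forward(self, old: int) -> int:
        i = bisect_right([b for b, _ in self.breakpoints], old) - 1
        return old + self.breakpoints[i][1]

    def inverse(self, new: int) -> int:
        # corrected-side breakpoints share the same offsets
        newpoints = [b + off for b, off in self.breakpoints]
        i = bisect_right(newpoints, new) - 1
        return new - self.breakpoints[i][1]


def apply_corrections(
    genome: GenomeRecord, discrepancies: list[Discrepancy]
) -> tuple[GenomeRecord, CoordinateMap]:
    """Apply normalized discrepancies to the genome, right to left.

    The corrected length always equals
    ``len(old) + sum(len(alt) - len(ref))``; a violation is a defect and
    raises.  Conflicting corrections at one site are rejected.
    """
    positions = [d.position for d in discrepancies]
    dup = {p for p in positions if positions.count(p) > 1}
    if dup:
        raise ContractError(f"conflicting corrections at site(s): {sorted(dup)}")
    seq = bytearray(genome.sequence.encode())
    for d in sorted(discrepancies, key=lambda d: d.position, reverse=True):
        if d.type == "substitution":
            seq[d.position : d.position + 1] = d.alt_allele.encode()
        elif d.type == "insertion":
            seq[d.position + 1 : d.position + 1] = d.alt_allele.encode()
        else:
            if seq[d.position : d.position + len(d.ref_allele)].decode() != d.ref_allele:
                raise ContractError(
                    f"deletion allele mismatch at {d.position}: "
                    f"expected {d.ref_allele!r}"
                )
            del seq[d.position : d.position + len(d.ref_allele)]
    cmap = CoordinateMap.from_discrepancies(discrepancies)
    expected = len(genome) + sum(d.length_change() for d in discrepancies)
    if len(seq) != expected:
        raise AssertionError(
            f"length conservation violated: {len(seq)} != {expected}"
        )
    corrected = GenomeRecord(id=genome.id, sequence=seq.decode(), circular=genome.circular)
    return corrected, cmap


def lift_features(features: list[CdsFeature], cmap: CoordinateMap) -> list[CdsFeature]:
    """Map feature boundaries through the coordinate map.

    A feature whose interior gained or lost bases changes length; a
    feature whose boundary falls inside a deleted stretch is lifted to
    the clamped coordinate and logged, never silently dropped.
    """
    out = []
    for f in features:
        start, end = cmap.forward(f.start), cmap.forward(f.end)
        if end <= start:
            logger.warning("feature %s collapsed by deletions; kept as 1 bp stub", f.id)
            end = start + 1
        out.append(
            CdsFeature(
                id=f.id,
                genome_id=f.genome_id,
                start=start,
                end=end,
                strand=f.strand,
                phase=f.phase,
                product=f.product,
            )
        )
    return out


# ---------------------------------------------------------------- translation


def cds_sequence(genome: GenomeRecord, feature: CdsFeature) -> str:
    seq = genome.sequence[feature.start : feature.end]
    return revcomp(seq) if feature.strand == "-" else seq


def translate(nt: str, table: int = TRANSLATION_TABLE) -> str:
    usable = nt[: len(nt) - len(nt) % 3]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # partial codons at fragment ends
        return str(Seq(usable).translate(table=table))


def annotated_protein_length(feature: CdsFeature) -> int:
    """Product length implied by the annotated interval (stop included)."""
    return max(len(feature) // 3 - 1, 0)


def find_orfs(
    seq: str, table: int = TRANSLATION_TABLE, min_aa: int = 30
) -> list[tuple[int, int]]:
    """All ORFs (start codon .. stop codon, half-open, stop included) on the
    forward strand of ``seq``; bacterial starts ATG/GTG/TTG."""
    stops = {"TAA", "TAG", "TGA"}
    orfs: list[tuple[int, int]] = []
    for frame in range(3):
        starts: list[int] = []
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in stops:
                orfs.extend(
                    (s, i + 3) for s in starts if (i + 3 - s) // 3 - 1 >= min_aa
                )
                starts.clear()
            elif codon in START_CODONS:
                starts.append(i)
    return orfs


# ---------------------------------------------------------------- impact


def _has_internal_stop(protein: str) -> bool:
    return "*" in protein.rstrip("*")


def assess_impact(
    old_genome: GenomeRecord,
    corrected_genome: GenomeRecord,
    old_features: list[CdsFeature],
    discrepancies: list[Discrepancy],
    cmap: CoordinateMap | None = None,
    expected_ortholog_lengths: dict[str, int] | None = None,
    length_tolerance: float = 0.05,
    table: int = TRANSLATION_TABLE,
) -> list[CodingImpact]:
    """Classify the coding consequence of each correction.

    Requires ``gene_ids`` to be filled (see hpcontext.annotate_regions).
    Classification, in order of precedence for indels:

    * ``gene_merge`` – at least two same-strand affected CDSs are
      contained in a single corrected open reading frame (naive ORF
      re-scan around the lifted locus);
    * ``stop_removed`` – the old annotated frame contains an internal
      stop codon that is absent after correction;
    * ``frameshift_repair`` – the correction restores the locus to a
      single ORF covering the annotated region (and matching the
      expected ortholog length within the tolerance, when provided);
    * substitutions are ``synonymous`` or ``missense``; sites outside
      any CDS are ``intergenic``; anything else is ``other``.
    """
    if cmap is None:
        cmap = CoordinateMap.from_discrepancies(discrepancies)
    by_id = {f.id: f for f in old_features}
    for f in old_features:
        if f.end > len(old_genome):
            raise ContractError(f"feature {f.id} outside genome bounds")
    expected_ortholog_lengths = expected_ortholog_lengths or {}
    impacts: list[CodingImpact] = []
    for d in discrepancies:
        if not d.gene_ids:
            impacts.append(CodingImpact(position=d.position, old_gene_ids=[], effect="intergenic"))
            continue
        feats = [by_id[g] for g in d.gene_ids if g in by_id]
        feats.sort(key=lambda f: f.start)
        strands = {f.strand for f in feats}
        old_proteins = [translate(cds_sequence(old_genome, f), table) for f in feats]
        old_lengths = [annotated_protein_length(f) for f in feats]
        expected = next(
            (expected_ortholog_lengths[f.id] for f in feats if f.id in expected_ortholog_lengths),
            None,
        )

        if d.type == "substitution":
            effect = _classify_substitution(old_genome, corrected_genome, cmap, feats[0], d, table)
            new_len = old_lengths[0]
            impacts.append(
                CodingImpact(
                    position=d.position,
                    old_gene_ids=[f.id for f in feats],
                    effect=effect,
                    old_protein_lengths=old_lengths,
                    new_protein_length=new_len,
                    expected_ortholog_length=expected,
                )
            )
            continue

        # indel: re-scan the corrected locus for the repaired ORF; the
        # margin is wide enough to expose a same-strand neighbour that a
        # repaired frameshift re-joins to this gene
        span0 = cmap.forward(min(f.start for f in feats))
        span1 = cmap.forward(max(f.end for f in feats))
        margin = 2000
        w0 = max(0, span0 - margin)
        w1 = min(len(corrected_genome), span1 + margin)
        window = corrected_genome.sequence[w0:w1]
        minus = len(strands) == 1 and feats[0].strand == "-"

        def to_window(a: int, b: int) -> tuple[int, int]:
            if minus:
                return len(window) - (b - w0), len(window) - (a - w0)
            return a - w0, b - w0

        if minus:
            window = revcomp(window)
            site = len(window) - 1 - (cmap.forward(d.position) - w0)
        else:
            site = cmap.forward(d.position) - w0
        lo, hi = to_window(span0, span1)
        orfs = [o for o in find_orfs(window, table) if o[0] <= site < o[1]]
        covering = [o for o in orfs if o[0] <= lo + 3 and o[1] >= hi - 3]
        if covering:
            # among ORFs covering the annotated span, the one whose
            # boundaries best match it (an upstream in-frame start would
            # otherwise absorb spurious N-terminal residues)
            best = min(covering, key=lambda o: abs(o[0] - lo) + abs(o[1] - hi))
        else:
            best = max(orfs, key=lambda o: o[1] - o[0], default=None)
        new_len = (best[1] - best[0]) // 3 - 1 if best else 0
        new_protein = translate(window[best[0] : best[1]], table).rstrip("*") if best else ""

        effect = "other"
        merged_feats = feats
        if best is not None and len(strands) == 1:
            # every same-strand annotated fragment contained in the
            # repaired ORF belongs to the merged gene, whether or not the
            # site itself touches it
            contained = []
            for f in old_features:
                if f.strand != feats[0].strand:
                    continue
                fl, fh = to_window(cmap.forward(f.start), cmap.forward(f.end))
                if best[0] <= fl + 3 and best[1] >= fh - 3:
                    contained.append(f)
            if len(contained) >= 2 and any(f.id in d.gene_ids for f in contained):
                effect = "gene_merge"
                merged_feats = sorted(contained, key=lambda f: f.start)
                old_lengths = [annotated_protein_length(f) for f in merged_feats]
                old_proteins = [
                    translate(cds_sequence(old_genome, f), table) for f in merged_feats
                ]
        if effect == "other" and best is not None:
            if any(_has_internal_stop(p) for p in old_proteins):
                if not _has_internal_stop(new_protein):
                    effect = "stop_removed"
            if effect == "other":
                covers = best[0] <= lo + 3 and best[1] >= hi - 3
                length_ok = (
                    expected is None
                    or abs(new_len - expected) <= length_tolerance * expected
                )
                if covers and length_ok and abs(d.length_change()) == 1:
                    effect = "frameshift_repair"
        impacts.append(
            CodingImpact(
                position=d.position,
                old_gene_ids=[f.id for f in merged_feats],
                effect=effect,
                old_protein_lengths=old_lengths,
                new_protein_length=new_len,
                new_protein=new_protein,
                expected_ortholog_length=expected,
            )
        )
    return impacts


def _classify_substitution(
    old_genome: GenomeRecord,
    corrected_genome: GenomeRecord,
    cmap: CoordinateMap,
    feat: CdsFeature,
    d: Discrepancy,
    table: int,
) -> str:
    if feat.strand == "+":
        codon_index = (d.position - feat.start) // 3
    else:
        codon_index = (feat.end - 1 - d.position) // 3
    old_p = translate(cds_sequence(old_genome, feat), table)
    new_feat = CdsFeature(
        id=feat.id,
        genome_id=feat.genome_id,
        start=cmap.forward(feat.start),
        end=cmap.forward(feat.end),
        strand=feat.strand,
    )
    new_p = translate(cds_sequence(corrected_genome, new_feat), table)
    if codon_index >= min(len(old_p), len(new_p)):
        return "other"
    if old_p[codon_index] == new_p[codon_index]:
        return "synonymous"
    if new_p[codon_index] == "*" or old_p[codon_index] == "*":
        return "other"
    return "missense"


# ---------------------------------------------------------------- transfer


def _glocal_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -1
    a.open_gap_score = -5
    a.extend_gap_score = -1
    a.end_deletion_score = 0  # reference flanks may stay unaligned for free
    return a


def combined_identity(
    query_protein: str,
    reference_protein: str,
    query_id: str = "query",
    reference_id: str = "reference",
    accept_threshold: float = 0.25,
    evalue_threshold: float = 1e-5,
) -> TransferMatch:
    """Score annotation transfer of a query protein onto a reference protein.

    ``identity_fraction`` is matches over the aligned reference span,
    ``coverage_fraction`` the aligned span over the reference length;
    a hit is accepted when their product reaches ``accept_threshold``
    (0.25 = 50 % identity over 50 % of the length) and the alignment
    clears the e-value proxy.
    """
    if not query_protein or not reference_protein:
        raise ContractError("empty protein sequence")
    aln = _glocal_aligner().align(reference_protein, query_protein)[0]
    tblocks = aln.aligned[0]
    if len(tblocks) == 0:
        return TransferMatch(query_id, reference_id, 0.0, 0.0, 0.0, False, "no_match")
    span = int(tblocks[-1][1] - tblocks[0][0])
    identities = int(aln.counts().identities)
    identity = identities / span if span else 0.0
    coverage = span / len(reference_protein)
    combined = identity * coverage
    bits = aln.score / 2.0  # match_score=2 ~ 2 bits per identity
    evalue_proxy = len(query_protein) * len(reference_protein) * 2.0 ** (-bits)
    accepted = combined >= accept_threshold and evalue_proxy <= evalue_threshold
    if not accepted:
        cls = "no_match"
    elif (
        identity == 1.0
        and coverage == 1.0
        and len(query_protein) == len(reference_protein)
    ):
        cls = "perfect"
    else:
        cls = "length_mismatch"
    return TransferMatch(
        query_cds_id=query_id,
        reference_cds_id=reference_id,
        identity_fraction=identity,
        coverage_fraction=coverage,
        combined_identity=combined,
        accepted=accepted,
        match_class=cls,
    )


def transfer_annotations(
    query_proteins: dict[str, str], reference_proteins: dict[str, str]
) -> dict[str, TransferMatch]:
    """Best reference match per query; ties broken by reference id order."""
    out: dict[str, TransferMatch] = {}
    for qid, qseq in query_proteins.items():
        best: TransferMatch | None = None
        for rid in sorted(reference_proteins):
            m = combined_identity(qseq, reference_proteins[rid], qid, rid)
            if best is None or m.combined_identity > best.combined_identity:
                best = m
        if best is not None:
            out[qid] = best
    return out
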