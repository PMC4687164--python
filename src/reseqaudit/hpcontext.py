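"""Homopolymer context annotation and discrepancy-set summaries.

Run length is measured on the uncorrected reference (the audited
assembly), matching how the discrepancy table reports "the number of the
same base occurring consecutively at the site".  For an insertion the
relevant run is the run of the inserted base immediately following the
left-normalized anchor; an inserted base matching neither neighbour is
conventionally assigned run length 1.
"""

from __future__ import annotations

from bisect import bisect_right

from .records import (
    AuditSummary,
    CdsFeature,
    Discrepancy,
    GenomeRecord,
    HomopolymerAnnotation,
)


class ContractError(ValueError):
    pass


def run_length_at(genome: GenomeRecord, position: int, base: str) -> HomopolymerAnnotation:
    """Maximal homopolymer run of ``base`` containing ``position``.

    If the reference base at ``position`` differs from ``base`` the run
    degenerates to length 1 at that site (convention for inserted bases
    matching neither neighbour).
    """
    if base not in "ACGT":
        raise ContractError(f"base must be one of ACGT, got {base!r}")
    seq = genome.sequence
    if not 0 <= position < len(seq):
        raise ContractError(f"position {position} outside genome of length {len(seq)}")
    if seq[position] != base:
        return HomopolymerAnnotation(base=base, run_length=1, run_start=position, run_end=position + 1)
    s = position
    while s > 0 and seq[s - 1] == base:
        s -= 1
    e = position + 1
    while e < len(seq) and seq[e] == base:
        e += 1
    return HomopolymerAnnotation(base=base, run_length=e - s, run_start=s, run_end=e)


def annotate_homopolymer(d: Discrepancy, genome: GenomeRecord) -> Discrepancy:
    """Fill homopolymer_base and homopolymer_length in place; returns d."""
    seq = genome.sequence
    if d.type == "insertion":
        base = d.alt_allele[-1]
        site = d.position + 1
        if site < len(seq) and seq[site] == base:
            ann = run_length_at(genome, site, base)
        else:
            ann = HomopolymerAnnotation(base=base, run_length=1, run_start=site, run_end=site + 1)
    else:
        base = seq[d.position]
        ann = run_length_at(genome, d.position, base) if base in "ACGT" else HomopolymerAnnotation(
            base="N", run_length=1, run_start=d.position, run_end=d.position + 1
        )
    d.homopolymer_base = ann.base
    d.homopolymer_length = ann.run_length
    return d


def annotate_regions(
    discrepancies: list[Discrepancy], cds_features: list[CdsFeature]
) -> list[Discrepancy]:
    """Fill region and gene_ids for each discrepancy (in place; returns list).

    A site is coding iff it lies within at least one CDS interval; for an
    insertion the site is the base following the anchor.  All overlapping
    CDS ids are recorded (a single site may hit both fragments of a
    split gene).
    """
    feats = sorted(cds_features, key=lambda f: f.start)
    starts = [f.start for f in feats]
    max_len = max((len(f) for f in feats), default=0)
    for d in discrepancies:
        site = d.position + 1 if d.type == "insertion" else d.position
        i = bisect_right(starts, site)
        # bounded backward scan: any overlapping feature starts within
        # max_len of the site
        hits = []
        j = i - 1
        while j >= 0 and feats[j].start > site - max_len:
            if feats[j].start <= site < feats[j].end:
                hits.append(feats[j].id)
            j -= 1
        hits.reverse()
        d.gene_ids = hits
        d.region = "coding" if hits else "noncoding"
    return discrepancies


def annotate(
    discrepancies: list[Discrepancy],
    genome: GenomeRecord,
    cds_features: list[CdsFeature],
) -> list[Discrepancy]:
    """Convenience: homopolymer context + coding region for every discrepancy."""
    for d in discrepancies:
        annotate_homopolymer(d, genome)
    return annotate_regions(discrepancies, cds_features)


def summarize(discrepancies: list[Discrepancy]) -> tuple[AuditSummary, dict[int, int]]:
    """Exact integer tallies plus the run-length histogram.

    ``n_run_gt4`` counts run lengths >= 5 and ``n_run_gt5`` run lengths
    >= 6; both are reported so either reading of "greater than" in a
    summary sentence can be checked.
    """
    hist: dict[int, int] = {}
    s = AuditSummary()
    for d in discrepancies:
        s.n_total += 1
        if d.type == "insertion":
            s.n_insertions += 1
        elif d.type == "deletion":
            s.n_deletions += 1
        else:
            s.n_substitutions += 1
        if d.region == "coding":
            s.n_coding += 1
        rl = d.homopolymer_length
        hist[rl] = hist.get(rl, 0) + 1
        if rl >= 5:
            s.n_run_gt4 += 1
        if rl >= 6:
            s.n_run_gt5 += 1
    s.counts_by_run_length = dict(sorted(hist.items()))
    if s.n_total:
        s.fraction_coding = s.n_coding / s.n_total
        s.fraction_run_gt4 = s.n_run_gt4 / s.n_total
    return s, s.counts_by_run_length
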