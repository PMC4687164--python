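"""Consensus discrepancy calling from the pileup.

The audit targets assembly errors in a clonal isolate, not polymorphism,
so calls are consensus-level: an alternative allele must be carried by a
clear majority (default 80 %) of the reads spanning the site at adequate
depth (default 10).  Indels are reported at their leftmost equivalent
position so that representations inside homopolymer runs compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mapper import Pileup
from .records import Discrepancy, GenomeRecord


class ConfigError(ValueError):
    pass


class ContractError(ValueError):
    pass


@dataclass
class CallThresholds:
    min_depth: int = 10
    min_alt_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.min_alt_fraction <= 0.5:
            raise ConfigError("min_alt_fraction must exceed 0.5 (consensus semantics)")
        if self.min_depth < 1:
            raise ConfigError("min_depth must be >= 1")


def normalize_indel(d: Discrepancy, genome: GenomeRecord) -> Discrepancy:
    """Shift an indel to its leftmost equivalent position (idempotent).

    Substitutions are returned unchanged.  For a deletion the stated
    reference allele must match the genome at the stated position.
    """
    if d.type == "substitution":
        return d
    seq = genome.sequence
    if d.type == "deletion":
        if seq[d.position : d.position + len(d.ref_allele)] != d.ref_allele:
            raise ContractError(
                f"deletion allele {d.ref_allele!r} does not match reference at {d.position}"
            )
        start, n = d.position, len(d.ref_allele)
        while start > 0 and seq[start - 1] == seq[start + n - 1]:
            start -= 1
        if start == d.position:
            return d
        return Discrepancy(
            ref_id=d.ref_id,
            position=start,
            type="deletion",
            ref_allele=seq[start : start + n],
            alt_allele="",
            depth=d.depth,
            alt_support=d.alt_support,
            alt_fraction=d.alt_fraction,
        )
    # insertion: anchor is the column the insertion follows; anchor 0 is
    # the leftmost representable position (no insertion "before" a genome)
    anchor, allele = d.position, d.alt_allele
    while anchor > 0 and seq[anchor] == allele[-1]:
        allele = allele[-1] + allele[:-1]
        anchor -= 1
    if anchor == d.position:
        return d
    return Discrepancy(
        ref_id=d.ref_id,
        position=anchor,
        type="insertion",
        ref_allele="",
        alt_allele=allele,
        depth=d.depth,
        alt_support=d.alt_support,
        alt_fraction=d.alt_fraction,
    )


def call_discrepancies(
    pileup: Pileup, thresholds: CallThresholds | None = None
) -> list[Discrepancy]:
    """Call consensus-level discrepancies from one pileup.

    At most one call is made per site: the highest-fraction allele wins,
    ties going to the lexicographically smallest allele.  N bases count
    toward depth but never toward an alternative allele.
    """
    th = thresholds or CallThresholds()
    genome = pileup.genome
    depth = pileup.depth
    candidates: dict[int, Discrepancy] = {}

    def consider(d: Discrepancy) -> None:
        prev = candidates.get(d.position)
        if prev is None:
            candidates[d.position] = d
            return
        key = (d.alt_fraction, -ord((d.alt_allele or d.ref_allele or "~")[0]))
        prev_key = (prev.alt_fraction, -ord((prev.alt_allele or prev.ref_allele or "~")[0]))
        if key > prev_key:
            candidates[d.position] = d

    # substitutions (vectorized over the genome)
    ref_codes = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    code_map = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code_map[b] = i
    ref_idx = code_map[ref_codes]
    acgt = pileup.base_counts[:, :4].copy()
    rows = np.arange(len(genome))
    valid = ref_idx < 4
    acgt[rows[valid], ref_idx[valid]] = 0  # mask the reference allele
    alt_idx = acgt.argmax(axis=1)  # ties -> smallest base, A<C<G<T
    alt_cnt = acgt[rows, alt_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, alt_cnt / np.maximum(depth, 1), 0.0)
    hits = np.flatnonzero((depth >= th.min_depth) & (frac >= th.min_alt_fraction) & (alt_cnt > 0))
    for pos in hits:
        pos = int(pos)
        consider(
            Discrepancy(
                ref_id=genome.id,
                position=pos,
                type="substitution",
                ref_allele=genome.sequence[pos],
                alt_allele="ACGT"[int(alt_idx[pos])],
                depth=int(depth[pos]),
                alt_support=int(alt_cnt[pos]),
                alt_fraction=float(frac[pos]),
            )
        )

    # insertions (events already left-normalized by the pileup)
    for anchor, counter in pileup.insertion_obs.items():
        d_at = int(depth[anchor])
        if d_at < th.min_depth:
            continue
        allele, count = min(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        support = min(count, d_at)
        frac_i = support / d_at
        if frac_i >= th.min_alt_fraction:
            consider(
                Discrepancy(
                    ref_id=genome.id,
                    position=int(anchor),
                    type="insertion",
                    ref_allele="",
                    alt_allele=allele,
                    depth=d_at,
                    alt_support=support,
                    alt_fraction=frac_i,
                )
            )

    # deletions (normalized events; per-column deletion_count stays
    # reserved for depth accounting)
    for (start, deleted), count in pileup.deletion_obs.items():
        d_at = int(depth[start])
        if d_at < th.min_depth:
            continue
        support = min(count, d_at)
        frac_d = support / d_at
        if frac_d >= th.min_alt_fraction:
            consider(
                Discrepancy(
                    ref_id=genome.id,
                    position=int(start),
                    type="deletion",
                    ref_allele=deleted,
                    alt_allele="",
                    depth=d_at,
                    alt_support=support,
                    alt_fraction=frac_d,
                )
            )

    calls = [normalize_indel(d, genome) for d in candidates.values()]
    calls.sort(key=lambda d: d.position)
    return calls


@dataclass
class CandidateRegion:
    kind: str  # low_depth | softclip_cluster
    start: int
    end: int
    evidence: float


def screen_large_indels(
    pileup: Pileup,
    min_len: int = 100,
    depth_fraction: float = 0.1,
    clip_fraction: float = 0.5,
) -> list[CandidateRegion]:
    """Screen for large structural differences between sample and reference.

    Flags (a) stretches of at least ``min_len`` columns whose depth falls
    below ``depth_fraction`` of the genome-wide median (deletion in the
    sample), and (b) columns where at least ``clip_fraction`` of the reads
    touching them are soft-clipped (insertion in the sample).  Returns an
    empty list on uniform coverage.
    """
    depth = pileup.depth
    median = float(np.median(depth))
    out: list[CandidateRegion] = []
    low = depth < depth_fraction * median if median > 0 else np.zeros_like(depth, bool)
    if low.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_len:
                out.append(
                    CandidateRegion("low_depth", int(s), int(e), float(depth[s:e].mean()))
                )
    clips = pileup.clip_count
    touching = depth + clips
    with np.errstate(divide="ignore", invalid="ignore"):
        cfrac = np.where(touching > 0, clips / np.maximum(touching, 1), 0.0)
    hot = np.flatnonzero((cfrac >= clip_fraction) & (clips >= 3))
    if hot.size:
        # merge adjacent hot columns into clusters
        breaks = np.flatnonzero(np.diff(hot) > 5)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [hot.size - 1]))
        for a, b in zip(starts, ends):
            s, e = int(hot[a]), int(hot[b]) + 1
            out.append(CandidateRegion("softclip_cluster", s, e, float(cfrac[s:e].max())))
    out.sort(key=lambda r: r.start)
    return out
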