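"""Lightweight seed-and-extend read mapper and pileup construction.

Adequate for synthetic data and small real datasets; for full-scale real
data, importing an externally produced SAM file through
:func:`reseqaudit.seqio.read_sam` is the recommended entry point and
feeds the identical pileup machinery.

Seeding uses non-overlapping read k-mers voting for reference diagonals;
extension is a banded edit-distance alignment (edlib) of the read
against the candidate window.  Indels inside homopolymer runs are
left-aligned against the reference before being counted in the pileup,
so every read's representation of the same event lands on one anchor
column regardless of where the aligner happened to place the gap.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field

import edlib
import numpy as np

from .records import AlignmentRecord, GenomeRecord
from .simgen import revcomp

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


class ConfigError(ValueError):
    pass


@dataclass
class MapParams:
    band: int = 16
    max_edit_fraction: float = 0.1
    discard_multimapped: bool = True
    max_candidates: int = 3
    rescue_softclip: bool = True


@dataclass
class KmerIndex:
    """Exact k-mer index over one or more genomes."""

    k: int
    positions: dict[str, list[tuple[str, int]]]
    genome_ids: list[str]


def build_index(genomes: list[GenomeRecord], k: int = 21) -> KmerIndex:
    """Index all overlapping k-mers without N; circular genomes also get
    the origin-spanning k-mers (positions taken modulo the length)."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > min(len(g) for g in genomes):
        raise ConfigError("k exceeds the shortest genome length")
    positions: dict[str, list[tuple[str, int]]] = {}
    for g in genomes:
        seq = g.sequence + (g.sequence[: k - 1] if g.circular else "")
        n_kmers = 0
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            positions.setdefault(kmer, []).append((g.id, i))
            n_kmers += 1
        if n_kmers == 0:
            logger.warning("genome %s produced no indexable k-mers", g.id)
    for hits in positions.values():
        hits.sort()
    return KmerIndex(k=k, positions=positions, genome_ids=[g.id for g in genomes])


def _cigar_from_edlib(cigar: str) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            op = "M" if ch in "=XM" else ch
            if out and out[-1][0] == op:
                out[-1] = (op, out[-1][1] + n)
            else:
                out.append((op, n))
            n = 0
    return out


def _candidate_diagonals(
    seq: str, index: KmerIndex, max_candidates: int, band: int
) -> list[tuple[int, str, int]]:
    """Vote reference diagonals with non-overlapping read k-mers.

    Returns up to ``max_candidates`` clusters as (votes, genome_id, diag),
    best first; diagonals within ``band`` of each other are merged.
    """
    k = index.k
    votes: Counter[tuple[str, int]] = Counter()
    for off in range(0, len(seq) - k + 1, k):
        for gid, pos in index.positions.get(seq[off : off + k], ()):
            votes[(gid, pos - off)] += 1
    if not votes:
        return []
    clustered: list[tuple[int, str, int]] = []
    for (gid, diag), n in sorted(votes.items()):
        if clustered and clustered[-1][1] == gid and diag - clustered[-1][2] <= band:
            v, g, d = clustered[-1]
            clustered[-1] = (v + n, g, d)
        else:
            clustered.append((n, gid, diag))
    clustered.sort(key=lambda t: (-t[0], t[1], t[2]))
    return clustered[:max_candidates]


def map_read(
    read_seq: str,
    index: KmerIndex,
    genomes: dict[str, GenomeRecord] | list[GenomeRecord],
    params: MapParams | None = None,
    read_id: str = "read",
) -> AlignmentRecord | None:
    """Map one read; returns None when unmapped or multi-mapped.

    Both strands are tried.  Ties are broken by leftmost reference
    position, then + strand; distinct equally-scoring loci are discarded
    as multi-mapped by default.
    """
    params = params or MapParams()
    if isinstance(genomes, list):
        genomes = {g.id: g for g in genomes}
    max_edit = math.ceil(params.max_edit_fraction * len(read_seq))
    hits: list[tuple[int, int, str, AlignmentRecord]] = []  # (dist, ref_start, strand, aln)
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        for _votes, gid, diag in _candidate_diagonals(
            seq, index, params.max_candidates, params.band
        ):
            g = genomes[gid]
            L = len(g)
            ext = g.sequence + (
                g.sequence[: len(seq) + 2 * params.band] if g.circular else ""
            )
            w0 = max(0, diag - params.band)
            w1 = diag + len(seq) + params.band
            window = ext[w0:w1]
            res = edlib.align(seq, window, mode="HW", task="path", k=max_edit)
            if res["editDistance"] < 0:
                continue
            start = w0 + res["locations"][0][0]
            aln = AlignmentRecord(
                read_id=read_id,
                ref_id=gid,
                ref_start=start % L if g.circular else start,
                strand=strand,
                cigar=_cigar_from_edlib(res["cigar"]),
                seq=seq,
                edit_distance=res["editDistance"],
            )
            hits.append((res["editDistance"], aln.ref_start, 0 if strand == "+" else 1, aln))
    if not hits:
        if params.rescue_softclip:
            return _rescue_clipped(read_seq, index, genomes, params, read_id)
        return None
    hits.sort(key=lambda t: t[:3])
    best = hits[0]
    if params.discard_multimapped:
        for other in hits[1:]:
            if other[0] == best[0] and abs(other[1] - best[1]) > len(read_seq):
                return None  # tied best score at a distinct locus
    return best[3]


def _rescue_clipped(
    read_seq: str,
    index: KmerIndex,
    genomes: dict[str, GenomeRecord],
    params: MapParams,
    read_id: str,
) -> AlignmentRecord | None:
    """Fallback for reads crossing a sequence absent from the reference:
    align the longest mappable prefix or suffix and soft-clip the rest."""
    L = len(read_seq)
    best: AlignmentRecord | None = None
    sub = MapParams(
        band=params.band,
        max_edit_fraction=params.max_edit_fraction,
        discard_multimapped=params.discard_multimapped,
        max_candidates=params.max_candidates,
        rescue_softclip=False,
    )
    for frac in (0.75, 0.5):
        m = int(L * frac)
        if m < 2 * index.k:
            break
        pre = map_read(read_seq[:m], index, genomes, sub, read_id)
        if pre is not None:
            pre.cigar.append(("S", L - m))
            pre.seq = read_seq if pre.strand == "+" else revcomp(read_seq)
            if pre.strand == "-":
                # clipped tail of the original read is the head of the rc read
                pre.cigar = [("S", L - m)] + pre.cigar[:-1]
            best = pre
            break
        suf = map_read(read_seq[L - m :], index, genomes, sub, read_id)
        if suf is not None:
            suf.cigar = [("S", L - m)] + suf.cigar
            suf.seq = read_seq if suf.strand == "+" else revcomp(read_seq)
            if suf.strand == "-":
                ops = suf.cigar[1:]
                ops.append(("S", L - m))
                suf.cigar = ops
            best = suf
            break
    if best is not None:
        if not _fold_noisy_flanks_into_clip(best):
            return None
        _extend_into_clips(best, genomes[best.ref_id])
    return best


def _fold_noisy_flanks_into_clip(aln: AlignmentRecord) -> bool:
    """Fold edit-dense terminal segments next to a soft clip into the clip.

    A banded sub-alignment happily absorbs a few foreign bases at its free
    end as short M/I/D runs; collapsing them leaves the clip at the last
    confidently aligned base.  Returns False if nothing alignable remains.
    """
    if aln.cigar and aln.cigar[-1][0] == "S":
        s = aln.cigar[-1][1]
        ops = aln.cigar[:-1]
        while ops and (ops[-1][0] in "ID" or (ops[-1][0] == "M" and ops[-1][1] < 10)):
            op, n = ops.pop()
            if op in "MI":
                s += n
        if not ops:
            return False
        aln.cigar = ops + [("S", s)]
    if aln.cigar and aln.cigar[0][0] == "S":
        s = aln.cigar[0][1]
        ops = aln.cigar[1:]
        shift = 0
        while ops and (ops[0][0] in "ID" or (ops[0][0] == "M" and ops[0][1] < 10)):
            op, n = ops.pop(0)
            if op in "MI":
                s += n
            if op in "MD":
                shift += n
        if not ops:
            return False
        aln.cigar = [("S", s)] + ops
        aln.ref_start += shift
    return True


def _extend_into_clips(aln: AlignmentRecord, genome: GenomeRecord) -> None:
    """Grow terminal M ops into adjacent soft clips while bases match the
    reference, so the remaining clip starts at the true junction."""
    seq, ref = aln.seq, genome.sequence
    if aln.cigar and aln.cigar[-1][0] == "S" and aln.cigar[-2][0] == "M":
        clip = aln.cigar[-1][1]
        qpos = len(seq) - clip
        rpos = aln.ref_end()
        grown = 0
        while clip > 0 and rpos < len(ref) and ref[rpos] == seq[qpos]:
            clip -= 1
            grown += 1
            rpos += 1
            qpos += 1
        if grown:
            aln.cigar[-2] = ("M", aln.cigar[-2][1] + grown)
            aln.cigar[-1] = ("S", clip)
            if clip == 0:
                aln.cigar.pop()
    if aln.cigar and aln.cigar[0][0] == "S" and aln.cigar[1][0] == "M":
        clip = aln.cigar[0][1]
        qpos = clip - 1
        rpos = aln.ref_start - 1
        grown = 0
        while clip > 0 and rpos >= 0 and ref[rpos] == seq[qpos]:
            clip -= 1
            grown += 1
            rpos -= 1
            qpos -= 1
        if grown:
            aln.cigar[0] = ("S", clip)
            aln.cigar[1] = ("M", aln.cigar[1][1] + grown)
            aln.ref_start -= grown
            if clip == 0:
                aln.cigar.pop(0)


# ---------------------------------------------------------------- pileup


@dataclass
class PileupColumn:
    ref_id: str
    position: int
    depth: int
    base_counts: dict[str, int]
    deletion_count: int
    insertion_observations: dict[str, int] = field(default_factory=dict)


class Pileup:
    """Column-wise summary of alignments against one genome.

    ``base_counts`` is an (L, 5) array over A,C,G,T,N; depth at a column
    is the number of reads whose alignment spans it (M or D).  Insertion
    and deletion events are counted at left-normalized anchors.
    """

    def __init__(self, genome: GenomeRecord):
        self.genome = genome
        L = len(genome)
        self.base_counts = np.zeros((L, 5), dtype=np.int32)
        self.deletion_count = np.zeros(L, dtype=np.int32)
        self.clip_count = np.zeros(L, dtype=np.int32)
        self.insertion_obs: dict[int, Counter[str]] = {}
        self.deletion_obs: dict[tuple[int, str], int] = {}
        self.n_alignments = 0
        self._ref = genome.sequence

    @property
    def depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=1) + self.deletion_count

    def _norm_insertion(self, anchor: int, allele: str) -> tuple[int, str]:
        ref = self._ref
        while anchor > 0 and ref[anchor] == allele[-1]:
            allele = allele[-1] + allele[:-1]
            anchor -= 1
        return anchor, allele

    def _norm_deletion(self, start: int, length: int) -> tuple[int, str]:
        ref = self._ref
        while start > 0 and ref[start - 1] == ref[start + length - 1]:
            start -= 1
        return start, ref[start : start + length]

    def add(self, aln: AlignmentRecord) -> None:
        L = len(self.genome)
        if not self.genome.circular and aln.ref_end() > L:
            raise ValueError(
                f"alignment {aln.read_id!r} overruns the end of linear genome {self.genome.id!r}"
            )
        codes = _CODE[np.frombuffer(aln.seq.encode(), dtype=np.uint8)]
        rpos, qpos = aln.ref_start, 0
        for i, (op, n) in enumerate(aln.cigar):
            if op == "M":
                cols = np.arange(rpos, rpos + n)
                if self.genome.circular:
                    cols %= L
                np.add.at(self.base_counts, (cols, codes[qpos : qpos + n]), 1)
                rpos += n
                qpos += n
            elif op == "D":
                cols = np.arange(rpos, rpos + n)
                if self.genome.circular:
                    cols %= L
                self.deletion_count[cols] += 1
                s, deleted = self._norm_deletion(rpos % L if self.genome.circular else rpos, n)
                self.deletion_obs[(s, deleted)] = self.deletion_obs.get((s, deleted), 0) + 1
                rpos += n
            elif op == "I":
                allele = aln.seq[qpos : qpos + n]
                anchor = (rpos - 1) % L if self.genome.circular else rpos - 1
                if "N" not in allele and anchor >= 0:
                    anchor, allele = self._norm_insertion(anchor, allele)
                    if anchor >= 0:
                        self.insertion_obs.setdefault(anchor, Counter())[allele] += 1
                qpos += n
            elif op == "S":
                col = rpos % L if self.genome.circular else min(rpos, L - 1)
                self.clip_count[col] += 1
                qpos += n
        self.n_alignments += 1

    def columns(self) -> Iterator[PileupColumn]:
        depth = self.depth
        for pos in np.flatnonzero(depth):
            pos = int(pos)
            counts = {
                "ACGTN"[j]: int(self.base_counts[pos, j])
                for j in range(5)
                if self.base_counts[pos, j]
            }
            ins = dict(self.insertion_obs.get(pos, {}))
            yield PileupColumn(
                ref_id=self.genome.id,
                position=pos,
                depth=int(depth[pos]),
                base_counts=counts,
                deletion_count=int(self.deletion_count[pos]),
                insertion_observations=ins,
            )


def build_pileup(
    alignments: Iterable[AlignmentRecord], genomes: list[GenomeRecord] | GenomeRecord
) -> dict[str, Pileup]:
    """Accumulate alignments into one Pileup per genome."""
    if isinstance(genomes, GenomeRecord):
        genomes = [genomes]
    piles = {g.id: Pileup(g) for g in genomes}
    for aln in alignments:
        piles[aln.ref_id].add(aln)
    return piles
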