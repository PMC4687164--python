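"""Per-base depth, genome-wide coverage moments, and per-CDS breadth.

Depth at a position counts the reads whose alignment spans it with an
M or D operation (a read deleted at a column still spans it); soft
clips never contribute.  Breadth of a CDS at threshold t is the
fraction of its positions with depth >= t.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

from .records import AlignmentRecord, CdsFeature, CoverageSummary, GenomeRecord


class ContractError(ValueError):
    pass


def depth_vector(
    alignments: Iterable[AlignmentRecord], genome: GenomeRecord
) -> np.ndarray:
    """Per-position spanning-read depth over the genome."""
    L = len(genome)
    diff = np.zeros(L + 1, dtype=np.int64)
    for a in alignments:
        s, e = a.ref_start, a.ref_end()
        if e <= L:
            diff[s] += 1
            diff[e] -= 1
        elif genome.circular:
            diff[s] += 1
            diff[L] -= 1
            diff[0] += 1
            diff[e - L] -= 1
        else:
            raise ContractError(
                f"alignment {a.read_id!r} overruns the end of linear genome {genome.id!r}"
            )
    return np.cumsum(diff[:-1])


def cds_breadth(
    depth: np.ndarray, features: list[CdsFeature], min_depth: int = 40
) -> tuple[list[tuple[str, float]], float, float]:
    """Per-CDS breadth fractions plus the two headline percentages.

    Returns (per_cds, pct_full_breadth, pct_breadth_ge_60): the
    percentage of CDSs covered at >= min_depth over 100 % of their
    positions, and over at least 60 %.
    """
    per_cds: list[tuple[str, float]] = []
    for f in features:
        if f.end > depth.size:
            raise ContractError(f"feature {f.id} outside genome bounds")
        frac = float(np.mean(depth[f.start : f.end] >= min_depth))
        per_cds.append((f.id, frac))
    if not per_cds:
        return per_cds, 0.0, 0.0
    fracs = np.array([fr for _, fr in per_cds])
    return (
        per_cds,
        100.0 * float(np.mean(fracs == 1.0)),
        100.0 * float(np.mean(fracs >= 0.6)),
    )


def summarize_coverage(
    alignments: list[AlignmentRecord],
    genome: GenomeRecord,
    features: list[CdsFeature],
    min_depth: int = 40,
) -> CoverageSummary:
    """Genome-wide moments (population SD over all positions) and breadth."""
    depth = depth_vector(alignments, genome)
    per_cds, pct_full, pct_60 = cds_breadth(depth, features, min_depth)
    read_lengths = [len(a.seq) for a in alignments]
    return CoverageSummary(
        mean_depth=float(depth.mean()),
        sd_depth=float(depth.std()),
        mean_read_length=float(np.mean(read_lengths)) if read_lengths else 0.0,
        n_mapped_reads=len(alignments),
        per_cds=per_cds,
        pct_cds_full_breadth=pct_full,
        pct_cds_breadth60=pct_60,
        min_depth=min_depth,
    )


def depth_to_bedgraph(depth: np.ndarray, genome_id: str, path: str) -> None:
    """Export the depth vector as bedGraph-style TSV (0-based half-open)."""
    changes = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate(([0], changes))
    ends = np.concatenate((changes, [depth.size]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{genome_id}\t{s}\t{e}\t{int(depth[s])}\n")
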