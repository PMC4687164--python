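"""Synthetic-data generator for the genome audit.

Produces a "true" genome with planted CDSs, a corrupted finished
assembly in which single bases have been deleted preferentially from
homopolymer runs (the dominant error mode of early long-read
basecalling), simulated paired-end reads from the true genome, and a
truth table for scoring.

The corrupted assembly plays the role of the published reference the
audit interrogates: reads simulated from the true genome, mapped onto
the corrupted assembly, should reveal each planted deletion as a
single-base insertion call.

Randomness: a single integer seed governs all stages.  Each stage
derives its own independent stream via ``numpy.random.SeedSequence``
spawned with a fixed per-stage key, so calling stages in a different
order cannot perturb reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import CdsFeature, GenomeRecord, ReadPair, TruthRecord

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_STAGE_KEYS = {"genome": 11, "corrupt": 23, "reads": 37}

#: Default mass over run lengths measured on the corrupted assembly at the
#: discrepancy site; shaped so that >90 % of planted errors sit in runs of
#: length >= 5 and ~85 % in runs >= 6, the spectrum typical of
#: homopolymer under-calling in early long-read assemblies of AT-rich
#: genomes.
DEFAULT_RUN_WEIGHTS = {4: 0.08, 5: 0.07, 6: 0.35, 7: 0.30, 8: 0.20}


class ConfigError(ValueError):
    """Raised when a simulation configuration is unsatisfiable."""


@dataclass
class SimulationConfig:
    genome_length: int = 200_000
    gc_target: float = 0.31
    homopolymer_bias: float = 0.2
    n_cds: int | None = None  # auto: one CDS slot per 1250 bp (~60 % coding)
    cds_length_range: tuple[int, int] = (100, 400)  # amino acids
    n_planted_errors: int = 100
    run_length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RUN_WEIGHTS)
    )
    substitution_fraction: float = 0.0
    read_length: int = 250
    mean_insert: int = 500
    insert_sd: int = 50
    coverage_target: float = 200.0
    per_base_error: float = 0.0
    circular: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cds is None:
            self.n_cds = max(0, self.genome_length // 1250)
        if not 0 < self.gc_target < 1:
            raise ConfigError("gc_target must be in (0, 1)")
        if self.coverage_target <= 0:
            raise ConfigError("coverage_target must be positive")
        if not 0 <= self.homopolymer_bias < 1:
            raise ConfigError("homopolymer_bias must be in [0, 1)")
        total = sum(self.run_length_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"run_length_weights must sum to 1 (got {total})")
        if not 0 <= self.substitution_fraction <= 1:
            raise ConfigError("substitution_fraction must be in [0, 1]")


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, _STAGE_KEYS[stage])))


def _codes_to_str(codes: np.ndarray) -> str:
    return codes.astype(np.uint8).tobytes().decode("ascii")


def _sample_backbone(rng: np.random.Generator, length: int, gc: float, bias: float) -> np.ndarray:
    """Markov-mixture base sampling: with probability ``bias`` repeat the
    previous base, else draw i.i.d. from the GC-target distribution.

    The repeat step preserves the marginal base distribution, so realized
    GC stays centred on the target while long homopolymer runs are
    enriched relative to i.i.d. sampling (bias=0 recovers exact i.i.d.).
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    iid = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    if bias > 0:
        repeat = rng.random(length) < bias
        repeat[0] = False
        # index of the most recent non-repeat draw, forward-filled
        src = np.where(~repeat, np.arange(length), -1)
        np.maximum.accumulate(src, out=src)
        return iid[src]
    return iid


def _sense_codons(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    """Sample ``n`` codons free of stops, weighted by per-base composition."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codons = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
    weights = np.array(
        [
            0.0 if cod in _STOPS else np.prod([p[_BASES.index(x)] for x in cod])
            for cod in codons
        ]
    )
    weights /= weights.sum()
    idx = rng.choice(len(codons), size=n, p=weights)
    return [codons[i] for i in idx]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_genome(config: SimulationConfig) -> tuple[GenomeRecord, list[CdsFeature]]:
    """Generate a true genome with ``n_cds`` planted non-overlapping CDSs.

    Each CDS is an ATG start, sampled sense codons (no in-frame stops),
    and a stop codon, planted on a random strand.  CDSs are placed in
    disjoint slots so they can never overlap.
    """
    rng = _rng(config, "genome")
    L = config.genome_length
    backbone = _sample_backbone(rng, L, config.gc_target, config.homopolymer_bias)
    seq = bytearray(backbone.tobytes())

    lo, hi = config.cds_length_range
    max_nt = 3 * hi + 3
    slot = L // max(config.n_cds, 1)
    if config.n_cds and slot < max_nt + 20:
        raise ConfigError(
            f"cannot fit {config.n_cds} CDSs of up to {hi} aa in {L} bp"
        )
    features: list[CdsFeature] = []
    for i in range(config.n_cds):
        aa = int(rng.integers(lo, hi + 1))
        nt = 3 * aa + 3
        offset = int(rng.integers(10, slot - nt - 9))
        start = i * slot + offset
        strand = "+" if rng.random() < 0.5 else "-"
        stop = _STOPS[int(rng.choice(3, p=[0.6, 0.2, 0.2]))]
        # interior drawn from the same persistence-biased process as the
        # backbone (real coding sequence shares the genome's homopolymer
        # spectrum), then in-frame stops are repaired with sense codons
        interior = _codes_to_str(
            _sample_backbone(rng, 3 * (aa - 1), config.gc_target, config.homopolymer_bias)
        )
        codons = [interior[j : j + 3] for j in range(0, len(interior), 3)]
        bad = [j for j, c in enumerate(codons) if c in _STOPS]
        if bad:
            repl = _sense_codons(rng, len(bad), config.gc_target)
            for j, c in zip(bad, repl):
                codons[j] = c
        cds = "ATG" + "".join(codons) + stop
        planted = cds if strand == "+" else revcomp(cds)
        seq[start : start + nt] = planted.encode()
        features.append(
            CdsFeature(
                id=f"SIM_{i:04d}",
                genome_id="sim_genome",
                start=start,
                end=start + nt,
                strand=strand,
                product=f"planted protein {i}",
            )
        )
    genome = GenomeRecord(
        id="sim_genome", sequence=seq.decode(), circular=config.circular
    )
    return genome, features


def _maximal_runs(seq: str) -> list[tuple[int, int, str]]:
    """All maximal homopolymer runs as (start, end, base), excluding N."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    boundaries = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(arr)]))
    return [
        (int(s), int(e), seq[s])
        for s, e in zip(starts, ends)
        if seq[s] != "N"
    ]


def corrupt_assembly(
    genome: GenomeRecord, cds: list[CdsFeature], config: SimulationConfig
) -> tuple[GenomeRecord, list[TruthRecord], list[CdsFeature]]:
    """Delete single bases from homopolymer runs to produce the "finished assembly".

    Run-length demand is drawn multinomially from ``run_length_weights``
    (keys are run lengths as measured on the corrupted assembly, so a key
    of ``r`` consumes a true-genome run of length ``r + 1``); runs are then
    chosen uniformly without replacement within each length class.
    Optional substitutions are placed outside runs.  Returns the corrupted
    genome, the truth table in corrupted-assembly coordinates (each planted
    deletion is recorded as the *insertion* the reads-vs-assembly audit
    should call, left-normalized), and the CDS annotation lifted onto the
    corrupted assembly.
    """
    rng = _rng(config, "corrupt")
    seq = genome.sequence
    L = len(seq)
    n_sub = int(round(config.n_planted_errors * config.substitution_fraction))
    n_del = config.n_planted_errors - n_sub

    runs = _maximal_runs(seq)
    # interior runs only: a deletion at the genome edge has no left anchor,
    # and on a linear genome read depth ramps down over the terminal
    # insert-length, so errors planted there would sit below any sensible
    # calling depth; circular genomes have no such edge
    edge = 0 if genome.circular else config.mean_insert
    pools: dict[int, list[tuple[int, int, str]]] = {}
    for s, e, b in runs:
        if s <= edge or e >= L - edge:
            continue
        pools.setdefault(e - s, []).append((s, e, b))

    lengths = sorted(config.run_length_weights)
    demand = rng.multinomial(n_del, [config.run_length_weights[r] for r in lengths])
    chosen: list[tuple[int, int, str]] = []
    shortfall = {}
    for r, want in zip(lengths, demand):
        pool = pools.get(r + 1, [])
        if len(pool) < want:
            shortfall[r + 1] = (want, len(pool))
            continue
        idx = rng.choice(len(pool), size=want, replace=False)
        chosen.extend(pool[i] for i in idx)
    if shortfall:
        detail = "; ".join(
            f"true run length {k}: need {w}, have {h}" for k, (w, h) in shortfall.items()
        )
        raise ConfigError(f"insufficient eligible homopolymer runs ({detail})")

    # substitutions at run-length-1 sites, away from selected runs
    sub_sites: list[tuple[int, str]] = []
    if n_sub:
        blocked = set()
        for s, e, _ in chosen:
            blocked.update(range(s - 1, e + 1))
        singles = [s for s, e, b in runs if e - s == 1 and 0 < s < L - 1 and s not in blocked]
        if len(singles) < n_sub:
            raise ConfigError("insufficient run-length-1 sites for substitutions")
        for i in rng.choice(len(singles), size=n_sub, replace=False):
            pos = singles[i]
            alt = _BASES[int(rng.choice([j for j in range(4) if _BASES[j] != seq[pos]]))]
            sub_sites.append((pos, alt))

    del_positions = sorted(s for s, _, _ in chosen)  # delete the first base of each run
    out = bytearray(seq.encode())
    for pos, alt in sub_sites:
        out[pos] = ord(alt)
    for pos in reversed(del_positions):
        del out[pos]
    corrupted = GenomeRecord(
        id=genome.id, sequence=out.decode(), circular=genome.circular
    )

    del_arr = np.array(del_positions, dtype=np.int64)

    def to_corrupted(true_pos: int) -> int:
        return true_pos - int(np.searchsorted(del_arr, true_pos))

    assembly_cds = [
        CdsFeature(
            id=f.id,
            genome_id=f.genome_id,
            start=to_corrupted(f.start),
            end=to_corrupted(f.end),
            strand=f.strand,
            phase=f.phase,
            product=f.product,
        )
        for f in cds
    ]

    truth: list[TruthRecord] = []
    for s, e, b in sorted(chosen):
        anchor = to_corrupted(s) - 1  # left-normalized insertion anchor
        site = anchor + 1  # first base of the (shrunken) run
        hits = [f.id for f in assembly_cds if f.start <= site < f.end]
        truth.append(
            TruthRecord(
                true_position=anchor,
                type="insertion",
                base=b,
                run_length_at_site=(e - s) - 1,
                in_cds=bool(hits),
                affected_cds_ids=hits,
            )
        )
    for pos, _alt in sorted(sub_sites):
        cpos = to_corrupted(pos)
        hits = [f.id for f in assembly_cds if f.start <= cpos < f.end]
        truth.append(
            TruthRecord(
                true_position=cpos,
                type="substitution",
                base=seq[pos],  # the allele the reads carry
                run_length_at_site=1,
                in_cds=bool(hits),
                affected_cds_ids=hits,
            )
        )
    truth.sort(key=lambda t: t.true_position)
    positions = [t.true_position for t in truth]
    if len(set(positions)) != len(positions):
        raise ConfigError("planted errors collide after normalization; use a new seed")
    return corrupted, truth, assembly_cds


def simulate_reads(genome: GenomeRecord, config: SimulationConfig) -> list[ReadPair]:
    """Simulate FR paired-end reads at ``coverage_target`` from ``genome``.

    Fragments are sampled uniformly (wrapping on circular genomes); each
    base is substituted independently at ``per_base_error`` and quality
    strings carry the Phred score implied by that rate.
    """
    rl = config.read_length
    if rl > config.mean_insert:
        raise ConfigError("read_length must not exceed mean_insert")
    if len(genome) <= config.mean_insert:
        raise ConfigError("genome shorter than mean_insert")
    rng = _rng(config, "reads")
    L = len(genome)
    n_pairs = int(round(config.coverage_target * L / (2 * rl)))
    if n_pairs == 0:
        return []
    q = 40 if config.per_base_error <= 0 else min(
        40, int(round(-10 * np.log10(config.per_base_error)))
    )
    arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    if genome.circular:
        arr = np.concatenate([arr, arr[: config.mean_insert + 4 * config.insert_sd]])
    inserts = np.clip(
        rng.normal(config.mean_insert, config.insert_sd, n_pairs).round().astype(int),
        rl,
        None,
    )
    if genome.circular:
        starts = rng.integers(0, L, n_pairs)
    else:
        starts = (rng.random(n_pairs) * (L - inserts + 1)).astype(int)
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    pairs: list[ReadPair] = []
    quals = [q] * rl
    for i in range(n_pairs):
        s, ins = int(starts[i]), int(inserts[i])
        frag = arr[s : s + ins]
        r1 = frag[:rl].copy()
        r2 = np.frombuffer(revcomp(_codes_to_str(frag)).encode(), dtype=np.uint8)[:rl].copy()
        if config.per_base_error > 0:
            for r in (r1, r2):
                hits = np.flatnonzero(rng.random(rl) < config.per_base_error)
                if hits.size:
                    shift = rng.integers(1, 4, hits.size)
                    cur = np.searchsorted(base_codes, r[hits])
                    r[hits] = base_codes[(cur + shift) % 4]
        pairs.append(
            ReadPair(
                id=f"sim_{i:07d}",
                seq1=_codes_to_str(r1),
                seq2=_codes_to_str(r2),
                qual1=quals,
                qual2=quals,
            )
        )
    return pairs


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    by_type: dict[str, tuple[int, int, int]]  # type -> (tp, fp, fn)


def score_recovery(calls, truth: list[TruthRecord]) -> RecoveryScore:
    """Score called discrepancies against the planted truth.

    A call matches a truth record iff normalized position, type, and
    allele agree.  Empty calls against empty truth score 1.0/1.0.
    """
    call_keys = {}
    for d in calls:
        allele = d.alt_allele if d.type != "deletion" else d.ref_allele
        key = (d.position, d.type, allele)
        if key[0] in {k[0] for k in call_keys}:
            raise ValueError(f"duplicate call position {d.position}; calls must be normalized")
        call_keys[key] = d
    truth_keys = {(t.true_position, t.type, t.base) for t in truth}
    if len(truth_keys) != len(truth):
        raise ValueError("duplicate truth positions; truth must be normalized")
    tp_keys = set(call_keys) & truth_keys
    fp_keys = set(call_keys) - truth_keys
    fn_keys = truth_keys - set(call_keys)
    by_type: dict[str, tuple[int, int, int]] = {}
    for typ in ("insertion", "deletion", "substitution"):
        by_type[typ] = (
            sum(1 for k in tp_keys if k[1] == typ),
            sum(1 for k in fp_keys if k[1] == typ),
            sum(1 for k in fn_keys if k[1] == typ),
        )
    tp, fp, fn = len(tp_keys), len(fp_keys), len(fn_keys)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    return RecoveryScore(precision, recall, tp, fp, fn, by_type)
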