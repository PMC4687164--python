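"""Shared fixtures: small synthetic bundles built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from reseqaudit.caller import CallThresholds
from reseqaudit.pipeline import SimulatedAudit, run_simulated_audit
from reseqaudit.records import CdsFeature, GenomeRecord
from reseqaudit.simgen import SimulationConfig


@pytest.fixture(scope="session")
def clean_bundle() -> SimulatedAudit:
    """Error-free reads at 50x over a 50 kb genome with 20 planted errors."""
    sim = SimulationConfig(
        genome_length=50_000,
        n_cds=40,
        n_planted_errors=20,
        coverage_target=50,
        per_base_error=0.0,
        seed=11,
    )
    return run_simulated_audit(sim, thresholds=CallThresholds())


@pytest.fixture(scope="session")
def noisy_bundle() -> SimulatedAudit:
    """Reads with a 0.2 % per-base error rate at 100x over 50 kb."""
    sim = SimulationConfig(
        genome_length=50_000,
        n_cds=40,
        n_planted_errors=20,
        coverage_target=100,
        per_base_error=0.002,
        seed=13,
    )
    return run_simulated_audit(sim)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)


def random_genome(rng: np.random.Generator, length: int, gc: float = 0.31) -> GenomeRecord:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return GenomeRecord(id="rand", sequence=seq)


BASES = list("ACGT")
STOPS = {"TAA", "TAG", "TGA"}

def build_merge_locus(rng):
    """A locus mirroring a RecQ-like split gene: a 1-bp deletion in the
    assembly truncates a 714 aa product into annotated 280 aa and 433 aa
    fragments; the repairing insertion merges them again."""
    def sense(n):
        out = []
        while len(out) < n:
            c = "".join(rng.choice(BASES, 3))
            if c not in STOPS:
                out.append(c)
        return out

    codons = ["ATG"] + sense(713) + ["TAA"]
    codons[280] = "GTA"  # deleting its G exposes an in-frame TAA
    codons[281] = "ACT"
    merged = "".join(codons)
    p0 = 500
    prefix = "".join(rng.choice(BASES, p0))
    suffix = "".join(rng.choice(BASES, 800))
    corrected_true = prefix + merged + suffix
    d_pos = p0 + 840
    assembly = GenomeRecord("asm", corrected_true[:d_pos] + corrected_true[d_pos + 1 :])
    frag_a = CdsFeature("geneA", "asm", p0, p0 + 843, "+")
    frag_b = CdsFeature("geneB", "asm", p0 + 843, p0 + 2145, "+")
    return assembly, corrected_true, frag_a, frag_b, d_pos
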