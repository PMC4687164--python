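"""Consensus calling, left-normalization, and the large-INDEL screen."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reseqaudit.caller import (
    CallThresholds,
    ConfigError,
    ContractError,
    call_discrepancies,
    normalize_indel,
    screen_large_indels,
)
from reseqaudit.mapper import Pileup, build_index, build_pileup, map_read
from reseqaudit.records import AlignmentRecord, Discrepancy, GenomeRecord


def exhaustive_leftmost_insertion(genome: str, anchor: int, allele: str) -> tuple[int, str]:
    """Oracle: smallest anchor whose insertion yields the same string."""
    target = genome[: anchor + 1] + allele + genome[anchor + 1 :]
    best = (anchor, allele)
    for a in range(anchor + 1):
        for rot in range(len(allele)):
            cand = allele[rot:] + allele[:rot]
            if genome[: a + 1] + cand + genome[a + 1 :] == target and a < best[0]:
                best = (a, cand)
    return best


class TestThresholds:
    def test_minority_fraction_rejected(self):
        with pytest.raises(ConfigError):
            CallThresholds(min_alt_fraction=0.5)


def _pileup_with_insertion(n_total=200, n_ins=198, allele="T"):
    genome = GenomeRecord("g", "ACGACGACGACGCAGCAGCA")  # no T: anchors stay put
    pile = Pileup(genome)
    reads_span = AlignmentRecord("r", "g", 2, "+", [("M", 10)], genome.sequence[2:12])
    for i in range(n_total):
        pile.add(reads_span)
    from collections import Counter

    pile.insertion_obs[5] = Counter({allele: n_ins})
    return genome, pile


class TestCalling:
    def test_strong_insertion_called(self):
        genome, pile = _pileup_with_insertion(200, 198)
        calls = call_discrepancies(pile)
        assert len(calls) == 1
        d = calls[0]
        assert d.type == "insertion" and d.alt_allele == "T" and d.position == 5

    def test_half_fraction_not_called(self):
        _, pile = _pileup_with_insertion(200, 100)
        assert call_discrepancies(pile) == []

    def test_low_depth_not_called(self):
        _, pile = _pileup_with_insertion(5, 5)
        assert call_discrepancies(pile) == []

    def test_substitution_called_and_tie_break_lexicographic(self):
        genome = GenomeRecord("g", "AAAAAAAAAA")
        pile = Pileup(genome)
        read_g = AlignmentRecord("r", "g", 0, "+", [("M", 10)], "AAAAGAAAAA")
        read_c = AlignmentRecord("r", "g", 0, "+", [("M", 10)], "AAAACAAAAA")
        for _ in range(10):
            pile.add(read_g)
            pile.add(read_c)
        # 50/50 G and C at site 4: below consensus fraction, no call
        assert call_discrepancies(pile) == []
        for _ in range(80):
            pile.add(read_c)
        calls = call_discrepancies(pile)
        assert len(calls) == 1 and calls[0].alt_allele == "C" and calls[0].position == 4

    def test_planted_deletions_recovered_exactly(self, clean_bundle):
        """Error-free 50x synthetic data: calls equal the truth table."""
        s = clean_bundle.score
        assert s.precision == 1.0 and s.recall == 1.0
        assert all(d.type == "insertion" for d in clean_bundle.result.discrepancies)


class TestNormalize:
    def test_homopolymer_insertion_shifts_to_run_start(self):
        g = GenomeRecord("g", "CAAAT")
        d = Discrepancy("g", 3, "insertion", "", "A")
        n = normalize_indel(d, g)
        assert n.position == 0 and n.alt_allele == "A"

    def test_already_leftmost_idempotent(self):
        g = GenomeRecord("g", "CAAAT")
        d = Discrepancy("g", 0, "insertion", "", "A")
        assert normalize_indel(d, g).position == 0
        assert normalize_indel(normalize_indel(d, g), g).position == 0

    def test_no_equal_neighbor_unchanged(self):
        g = GenomeRecord("g", "CAAAT")
        d = Discrepancy("g", 2, "insertion", "", "G")
        assert normalize_indel(d, g).position == 2

    def test_deletion_allele_mismatch_rejected(self):
        g = GenomeRecord("g", "CAAAT")
        with pytest.raises(ContractError):
            normalize_indel(Discrepancy("g", 1, "deletion", "G", ""), g)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=5, max_size=40),
        anchor=st.integers(min_value=0, max_value=38),
        allele=st.text(alphabet="ACGT", min_size=1, max_size=3),
    )
    def test_normalization_matches_exhaustive_oracle(self, seq, anchor, allele):
        anchor = min(anchor, len(seq) - 2)
        g = GenomeRecord("g", seq)
        d = Discrepancy("g", anchor, "insertion", "", allele)
        n = normalize_indel(d, g)
        oracle_pos, oracle_allele = exhaustive_leftmost_insertion(seq, anchor, allele)
        assert n.position == oracle_pos
        # the normalized representation produces the identical string
        assert (
            seq[: n.position + 1] + n.alt_allele + seq[n.position + 1 :]
            == seq[: anchor + 1] + allele + seq[anchor + 1 :]
        )


class TestLargeIndelScreen:
    def test_uniform_coverage_empty(self, clean_bundle):
        assert clean_bundle.result.large_indels == []

    def test_low_depth_region_flagged(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), 5_000))
        genome = GenomeRecord("g", seq)
        alns = []
        i = 0
        for s in range(0, 4_750, 10):
            if 2_000 <= s <= 2_500:
                continue  # a 500 bp hole: the sample lacks this region
            for _ in range(3):
                alns.append(
                    AlignmentRecord(f"r{i}", "g", s, "+", [("M", 250)], seq[s : s + 250])
                )
                i += 1
        pile = build_pileup(alns, genome)["g"]
        regions = [r for r in screen_large_indels(pile) if r.kind == "low_depth"]
        assert regions and any(2_200 <= (r.start + r.end) // 2 <= 2_600 for r in regions)

    def test_softclip_cluster_at_insertion_junction(self):
        """Reads from a genome carrying 500 bp absent from the reference
        pile up soft clips at the junction."""
        rng = np.random.default_rng(13)
        left = "".join(rng.choice(list("ACGT"), 3_000))
        right = "".join(rng.choice(list("ACGT"), 3_000))
        novel = "".join(rng.choice(list("ACGT"), 500))
        sample = left + novel + right
        reference = GenomeRecord("ref", left + right)
        idx = build_index([reference])
        alns = []
        for s in range(2_000, 3_400, 25):
            read = sample[s : s + 250]
            a = map_read(read, idx, [reference], read_id=f"r{s}")
            if a is not None:
                alns.append(a)
        pile = build_pileup(alns, reference)["ref"]
        clusters = [r for r in screen_large_indels(pile) if r.kind == "softclip_cluster"]
        assert clusters
        assert any(abs(r.start - 3_000) < 60 for r in clusters)
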