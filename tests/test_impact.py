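"""Correction application, coordinate liftover, coding impact, transfer scoring."""

import numpy as np
import pytest

from reseqaudit.impact import (
    ContractError,
    CoordinateMap,
    apply_corrections,
    assess_impact,
    combined_identity,
    find_orfs,
    lift_features,
    translate,
)
from reseqaudit.records import CdsFeature, Discrepancy, GenomeRecord

from conftest import build_merge_locus

BASES = list("ACGT")
STOPS = {"TAA", "TAG", "TGA"}


def ins(pos, allele="T", ref_id="g"):
    return Discrepancy(ref_id, pos, "insertion", "", allele)


def dele(pos, ref_allele, ref_id="g"):
    return Discrepancy(ref_id, pos, "deletion", ref_allele, "")


def sub(pos, ref, alt, ref_id="g"):
    return Discrepancy(ref_id, pos, "substitution", ref, alt)


class TestApplyCorrections:
    def test_empty_list_identity(self):
        g = GenomeRecord("g", "ACGTACGT")
        corr, cmap = apply_corrections(g, [])
        assert corr.sequence == g.sequence and cmap.total_offset == 0
        assert cmap.forward(5) == 5

    def test_single_insertion_offsets(self):
        g = GenomeRecord("g", "ACGTACGTAC")
        corr, cmap = apply_corrections(g, [ins(5)])
        assert len(corr) == 11
        assert corr.sequence == "ACGTAC" + "T" + "GTAC"
        for old in range(6):
            assert cmap.forward(old) == old
        for old in range(6, 10):
            assert cmap.forward(old) == old + 1
        # flanking substrings locate where the map says
        assert corr.sequence[cmap.forward(6) : cmap.forward(10)] == g.sequence[6:10]

    def test_conflicting_sites_rejected(self):
        g = GenomeRecord("g", "ACGTACGT")
        with pytest.raises(ContractError, match="conflicting"):
            apply_corrections(g, [ins(3), sub(3, "T", "A")])

    def test_length_conservation_random(self, rng):
        seq = "".join(rng.choice(BASES, 2_000))
        g = GenomeRecord("g", seq)
        ds = []
        for pos in rng.choice(1_900, 25, replace=False):
            pos = int(pos) + 1
            kind = rng.integers(0, 3)
            if kind == 0:
                ds.append(ins(pos, rng.choice(BASES)))
            elif kind == 1:
                ds.append(dele(pos, seq[pos]))
            else:
                alt = rng.choice([b for b in BASES if b != seq[pos]])
                ds.append(sub(pos, seq[pos], alt))
        corr, cmap = apply_corrections(g, ds)
        delta = sum(d.length_change() for d in ds)
        assert len(corr) == len(g) + delta
        assert cmap.total_offset == delta


class TestLiftFeatures:
    G = GenomeRecord("g", "ACGTACGTACGTACGTACGT")

    def test_feature_upstream_unchanged(self):
        _, cmap = apply_corrections(self.G, [ins(15)])
        f = CdsFeature("f", "g", 2, 8, "+")
        lf = lift_features([f], cmap)[0]
        assert (lf.start, lf.end) == (2, 8)

    def test_feature_containing_insertion_grows(self):
        _, cmap = apply_corrections(self.G, [ins(10)])
        f = CdsFeature("f", "g", 5, 15, "+")
        lf = lift_features([f], cmap)[0]
        assert lf.start == 5 and lf.end == 16

    def test_round_trip_through_inverse(self, rng):
        seq = "".join(rng.choice(BASES, 1_000))
        g = GenomeRecord("g", seq)
        ds = [ins(int(p)) for p in sorted(rng.choice(900, 10, replace=False) + 10)]
        _, cmap = apply_corrections(g, ds)
        for b in rng.integers(0, 1_000, 200):
            assert cmap.inverse(cmap.forward(int(b))) == int(b)

class TestAssessImpact:
    def test_split_gene_merges_with_fragment_lengths(self, rng):
        from reseqaudit.caller import normalize_indel
        from reseqaudit.hpcontext import annotate_regions

        assembly, corrected_true, fa, fb, d_pos = build_merge_locus(rng)
        # sanity: fragment A really encodes a 280 aa product ending in a stop
        ta = translate(assembly.sequence[fa.start : fa.end])
        assert len(ta) - 1 == 280 and ta.endswith("*") and "*" not in ta[:-1]
        d = normalize_indel(ins(d_pos - 1, "G", "asm"), assembly)
        annotate_regions([d], [fa, fb])
        corr, cmap = apply_corrections(assembly, [d])
        assert corr.sequence == corrected_true
        imp = assess_impact(assembly, corr, [fa, fb], [d], cmap)[0]
        assert imp.effect == "gene_merge"
        assert imp.old_gene_ids == ["geneA", "geneB"]
        assert imp.old_protein_lengths == [280, 433]
        assert imp.new_protein_length == 714

    def test_synonymous_third_position(self):
        # CDS: ATG AAA TAA; AAA->AAG both encode Lys
        g = GenomeRecord("g", "CC" + "ATGAAATAA" + "GG")
        f = CdsFeature("f", "g", 2, 11, "+")
        d = sub(7, "A", "G")
        d.gene_ids = ["f"]
        d.region = "coding"
        corr, cmap = apply_corrections(g, [d])
        imp = assess_impact(g, corr, [f], [d], cmap)[0]
        assert imp.effect == "synonymous"

    def test_missense_first_position(self):
        g = GenomeRecord("g", "CC" + "ATGAAATAA" + "GG")
        f = CdsFeature("f", "g", 2, 11, "+")
        d = sub(5, "A", "C")  # AAA (Lys) -> CAA (Gln)
        d.gene_ids = ["f"]
        d.region = "coding"
        corr, cmap = apply_corrections(g, [d])
        imp = assess_impact(g, corr, [f], [d], cmap)[0]
        assert imp.effect == "missense"

    def test_no_corrections_only_intergenic(self):
        g = GenomeRecord("g", "ACGT" * 50)
        d = ins(100)
        d.gene_ids = []
        imp = assess_impact(g, apply_corrections(g, [d])[0], [], [d])[0]
        assert imp.effect == "intergenic"


class TestFindOrfs:
    def test_simple_orf(self):
        seq = "CC" + "ATG" + "AAA" * 40 + "TAA" + "GG"
        orfs = find_orfs(seq, min_aa=30)
        assert (2, 2 + 3 + 120 + 3) in orfs

    def test_every_start_reported(self):
        seq = "ATG" + "GTG" + "AAA" * 40 + "TAG"
        orfs = find_orfs(seq, min_aa=30)
        assert len([o for o in orfs if o[1] == len(seq)]) == 2


class TestCombinedIdentity:
    def test_identical_proteins_perfect(self):
        p = "MKLVIDEPQRSTWYACGHMKLVIDEPQRSTWYACGH" * 10
        m = combined_identity(p, p)
        assert m.combined_identity == 1.0 and m.match_class == "perfect" and m.accepted

    def test_boundary_half_identity_half_coverage_accepted(self):
        rng = np.random.default_rng(42)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        ref = "".join(rng.choice(aas, 400))
        # query = first half of the reference with every second residue mutated
        q = list(ref[:200])
        for i in range(0, 200, 2):
            q[i] = "W" if q[i] != "W" else "Y"
        query = "".join(q)
        m = combined_identity(query, ref)
        assert m.identity_fraction == pytest.approx(0.5)
        assert m.coverage_fraction == pytest.approx(0.5)
        assert m.combined_identity == pytest.approx(0.25)
        assert m.accepted

    def test_forty_percent_identity_rejected(self):
        rng = np.random.default_rng(43)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        ref = "".join(rng.choice(aas, 400))
        q = list(ref[:200])
        # mutate 120 of 200 -> 40 % identity over 50 % coverage = 0.20
        for i in list(range(0, 200, 2)) + list(range(1, 40, 2)):
            q[i] = "W" if q[i] != "W" else "Y"
        query = "".join(q)
        m = combined_identity(query, ref)
        assert m.combined_identity < 0.25 and not m.accepted

    def test_empty_sequence_rejected(self):
        with pytest.raises(ContractError):
            combined_identity("", "MKL")
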