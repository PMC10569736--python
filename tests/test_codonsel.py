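"""Degeneracy classification, pathway averaging, Ka/Ks and the z-test."""

import math
from itertools import permutations, product

import numpy as np
import pytest
from Bio.Data.CodonTable import unambiguous_dna_by_id

from phagekit.codonsel import (
    SENSE_CODONS,
    CodonAlignment,
    classify_degeneracy,
    codon_ztest,
    pairwise_kaks,
)
from phagekit.errors import (
    ClassificationError,
    DegenerateVarianceError,
    InvalidInputError,
)
from phagekit.synthesize import SimulationConfig, sim_codon_alignment

_CODE = unambiguous_dna_by_id[1]
_STOPS = set(_CODE.stop_codons)


def oracle_degeneracy(codon):
    """Independent re-derivation from the genetic code."""
    out = []
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut not in _STOPS and \
                    _CODE.forward_table[mut] == _CODE.forward_table[codon]:
                syn += 1
        out.append(4 if syn == 3 else (0 if syn == 0 else 2))
    return tuple(out)


class TestDegeneracy:
    def test_known_codons(self):
        assert classify_degeneracy("GGG") == (0, 0, 4)
        assert classify_degeneracy("ATG") == (0, 0, 0)  # Met has no synonyms

    def test_whole_table_matches_oracle(self):
        for codon in SENSE_CODONS:
            assert classify_degeneracy(codon) == oracle_degeneracy(codon)

    def test_stop_and_ambiguity_are_errors(self):
        with pytest.raises(ClassificationError):
            classify_degeneracy("TAA")
        with pytest.raises(ClassificationError):
            classify_degeneracy("ANG")


def oracle_pathway_counts(c1, c2):
    """Brute-force mean over stop-free pathways of per-class ts/tv tallies."""
    purines = set("AG")

    def klass(codon, pos):
        return {0: 0, 2: 1, 4: 2}[oracle_degeneracy(codon)[pos]]

    diffs = [i for i in range(3) if c1[i] != c2[i]]
    tallies = []
    for order in permutations(diffs):
        cur = c1
        acc = np.zeros(6)
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                ok = False
                break
            ts = (cur[pos] in purines) == (c2[pos] in purines)
            off = 0 if ts else 3
            acc[off + klass(cur, pos)] += 0.5
            acc[off + klass(nxt, pos)] += 0.5
            cur = nxt
        if ok:
            tallies.append(acc)
    return np.mean(tallies, axis=0) if tallies else None


def test_pathway_averaging_matches_enumeration_for_all_multistep_pairs():
    """Every 2- and 3-difference sense-codon pair, against brute force."""
    from phagekit.codonsel import _pathway_average

    checked = 0
    for c1, c2 in product(SENSE_CODONS, SENSE_CODONS):
        ndiff = sum(a != b for a, b in zip(c1, c2))
        if ndiff < 2:
            continue
        expected = oracle_pathway_counts(c1, c2)
        got = _pathway_average(c1, c2)
        if expected is not None:
            np.testing.assert_allclose(got, expected, atol=1e-12)
            checked += 1
    assert checked > 3000


class TestPairwiseKaks:
    def test_identical_sequences_have_zero_rates(self):
        seq = "ATGGCTAAA" * 5
        _, kaks = pairwise_kaks(seq, seq)
        assert kaks.Ka == 0.0 and kaks.Ks == 0.0 and kaks.valid

    def test_single_fourfold_transition_hand_oracle(self):
        # 9 x GCT (Ala) background plus one GGA/GGG fourfold transition
        a = "GCT" * 9 + "GGA"
        b = "GCT" * 9 + "GGG"
        sites, kaks = pairwise_kaks(a, b)
        # site counts: GCT -> (2,0,1); GGA,GGG -> (2,0,1)
        assert sites.L0 == pytest.approx(20.0)
        assert sites.L2 == pytest.approx(0.0)
        assert sites.L4 == pytest.approx(10.0)
        assert kaks.Ka == 0.0
        # per-class K2P at fourfold sites: P4 = 1/10, Q4 = 0
        p4 = 1.0 / 10.0
        a4 = 0.5 * math.log(1 / (1 - 2 * p4)) - 0.25 * math.log(1.0)
        k4 = a4 + 0.0
        ks_expected = (0.0 + 10.0 * k4) / (0.0 / 3 + 10.0)
        assert kaks.Ks == pytest.approx(ks_expected, rel=1e-12)
        assert kaks.Ks > 0

    def test_symmetry_in_arguments(self):
        aln = sim_codon_alignment(
            SimulationConfig(seed=5, n_sequences=2, n_codons=200,
                             omega=0.5, branch_length=0.15))
        a, b = aln.codon_rows
        _, k1 = pairwise_kaks(a, b)
        _, k2 = pairwise_kaks(b, a)
        assert k1.valid and k2.valid
        assert k1.Ka == pytest.approx(k2.Ka, rel=1e-12)
        assert k1.Ks == pytest.approx(k2.Ks, rel=1e-12)

    def test_gapped_codons_are_dropped_pairwise(self):
        a = "ATGGCTAAA"
        b = "ATG---AAA"
        sites, kaks = pairwise_kaks(a, b)
        assert sites.L0 + sites.L2 + sites.L4 == pytest.approx(6.0)  # 2 codons

    def test_internal_stop_rejected(self):
        with pytest.raises(InvalidInputError):
            CodonAlignment(["a", "b"], ["ATGTAAAAA", "ATGTAAAAA"])


class TestZTest:
    def test_identical_alignment_has_no_information(self):
        aln = CodonAlignment(["a", "b", "c"], ["ATGGCTAAA"] * 3)
        with pytest.raises(DegenerateVarianceError):
            codon_ztest(aln, "two_sided", seed=0)

    def test_seeded_reproducibility(self):
        aln = sim_codon_alignment(SimulationConfig(seed=2, omega=0.5))
        r1 = codon_ztest(aln, "two_sided", seed=3)
        r2 = codon_ztest(aln, "two_sided", seed=3)
        assert r1.z_statistic == r2.z_statistic and r1.p_value == r2.p_value

    def test_alternative_tails_are_consistent(self):
        aln = sim_codon_alignment(SimulationConfig(seed=6, omega=0.2))
        lt = codon_ztest(aln, "dN_lt_dS", seed=1)
        gt = codon_ztest(aln, "dN_gt_dS", seed=1)
        two = codon_ztest(aln, "two_sided", seed=1)
        assert lt.p_value + gt.p_value == pytest.approx(1.0)
        assert two.p_value == pytest.approx(2 * min(lt.p_value, gt.p_value))
        assert lt.mean_dN < lt.mean_dS  # purifying regime

    def test_unknown_alternative_rejected(self):
        aln = sim_codon_alignment(SimulationConfig(seed=2))
        with pytest.raises(InvalidInputError):
            codon_ztest(aln, "greater", seed=0)

    def test_purifying_simulation_recovers_omega(self):
        aln = sim_codon_alignment(
            SimulationConfig(seed=42, omega=0.2, n_codons=3000))
        res = codon_ztest(aln, "dN_lt_dS", seed=7)
        assert res.mean_dN / res.mean_dS == pytest.approx(0.2, abs=0.1)
        assert res.p_value < 0.05
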