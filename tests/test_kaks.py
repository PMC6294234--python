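"""Ka/Ks estimator: Jukes-Cantor closed form, Nei-Gojobori counting
against an independent brute-force pathway enumerator, codon alignment."""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_sense_codons
from hgtscreen import kaks
from hgtscreen.io_formats import SequenceRecord

# --------------------------------------------------------------------------
# independent NG86 oracle (written from the definitions, not the package
# tables: Biopython genetic code, per-site change classification, explicit
# pathway enumeration)

from Bio.Data.CodonTable import unambiguous_dna_by_id

_CODE = unambiguous_dna_by_id[1]
_STOPS = set(_CODE.stop_codons)


def _aa(codon):
    return "*" if codon in _STOPS else _CODE.forward_table[codon]


def oracle_site_counts(codon):
    s = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in _STOPS and _aa(mut) == _aa(codon):
                s += 1.0 / 3.0
    return s, 3.0 - s


def oracle_pair_counts(a, b):
    diffs = [p for p in range(3) if a[p] != b[p]]
    if not diffs:
        return 0.0, 0.0
    tot_s = tot_n = 0.0
    n_ok = 0
    for order in itertools.permutations(diffs):
        cur, s, n, ok = a, 0.0, 0.0, True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            tot_s, tot_n, n_ok = tot_s + s, tot_n + n, n_ok + 1
    if n_ok == 0:
        return None
    return tot_s / n_ok, tot_n / n_ok


def oracle_ng86(seq_a, seq_b):
    S = N = Sd = Nd = 0.0
    for k in range(len(seq_a) // 3):
        ca, cb = seq_a[3 * k : 3 * k + 3], seq_b[3 * k : 3 * k + 3]
        if ca in _STOPS or cb in _STOPS:
            continue
        pair = oracle_pair_counts(ca, cb)
        if pair is None:
            continue
        sa, na = oracle_site_counts(ca)
        sb, nb = oracle_site_counts(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += pair[0]
        Nd += pair[1]
    return S, N, Sd, Nd


# --------------------------------------------------------------------------


class TestJukesCantor:
    def test_matches_closed_form(self):
        for p in [0.0, 0.01, 0.1, 0.3, 0.5, 0.7, 0.7499]:
            expected = -0.75 * math.log(1 - 4 * p / 3)
            assert abs(kaks.jc_correct(p) - expected) < 1e-12

    def test_reference_value(self):
        assert abs(kaks.jc_correct(0.3) - 0.38312) < 5e-6

    def test_zero(self):
        assert kaks.jc_correct(0.0) == 0.0

    def test_saturation_boundary(self):
        with pytest.raises(kaks.SaturationError):
            kaks.jc_correct(0.75)
        with pytest.raises(ValueError):
            kaks.jc_correct(-0.01)


class TestNG86:
    def test_identical_codon(self):
        assert kaks.ng86_counts("AAA", "AAA")[2:] == (0.0, 0.0)

    def test_single_synonymous_path(self):
        # Lys AAA -> Lys AAG: the single pathway is synonymous
        S, N, Sd, Nd = kaks.ng86_counts("AAA", "AAG")
        assert Sd == pytest.approx(1.0) and Nd == pytest.approx(0.0)

    def test_matches_bruteforce_enumerator_on_random_pairs(self, rng):
        for _ in range(50):
            a = random_sense_codons(rng, 100)
            b = random_sense_codons(rng, 100)
            got = kaks.ng86_counts(a, b)
            want = oracle_ng86(a, b)
            assert np.allclose(got, want, atol=1e-9)

    def test_symmetry(self, rng):
        a = random_sense_codons(rng, 60)
        b = random_sense_codons(rng, 60)
        assert kaks.ng86_counts(a, b) == kaks.ng86_counts(b, a)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10**9))
    def test_site_count_conservation(self, seed):
        # S + N == 3 x (codon columns compared), fuzzed over random pairs
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 40))
        a = random_sense_codons(r, n)
        b = random_sense_codons(r, n)
        res = kaks.ka_ks(a, b)
        assert res.S + res.N == pytest.approx(
            3.0 * res.n_codons_compared, abs=1e-6
        )

    def test_gap_codons_excluded_pairwise(self):
        S, N, Sd, Nd = kaks.ng86_counts("AAA---GGG", "AAAGGGGGG")
        S2, N2, _, _ = kaks.ng86_counts("AAAGGG", "AAAGGG")
        assert S + N == pytest.approx(6.0)  # the gap column dropped


class TestKaKs:
    def test_identical_sequences(self, rng):
        a = random_sense_codons(rng, 50)
        res = kaks.ka_ks(a, a)
        assert res.Ka == 0.0 and res.Ks == 0.0
        assert math.isnan(res.ratio)  # undefined at Ks == 0

    def test_composition_with_jc(self):
        # a pair engineered to have Sd/S = known fraction gives
        # Ks == jc_correct(Sd/S) exactly
        a = "AAA" * 30
        b = "AAG" * 4 + "AAA" * 26
        res = kaks.ka_ks(a, b)
        assert res.Ks == pytest.approx(kaks.jc_correct(res.pS), abs=1e-12)
        assert res.pS == pytest.approx(4.0 / res.S)

    def test_simulated_omega_recovered(self):
        # sequences simulated at omega=0.2: mean Ka/Ks near the truth
        from hgtscreen.trio import simulate_trio

        ratios = []
        for seed in range(30):
            aln = simulate_trio(500, 2.0, 0.2, 0.2, [0.15, 0.15, 0.15], seed)
            res = kaks.ka_ks(aln.rows[0], aln.rows[1])
            ratios.append(res.ratio)
        assert 0.15 < np.mean(ratios) < 0.25

    def test_saturation_flagged(self, rng):
        a = random_sense_codons(rng, 200)
        b = random_sense_codons(rng, 200)  # unrelated: synonymous sites saturate
        res = kaks.ka_ks(a, b)
        assert res.saturated_s and res.Ks == np.inf


class TestAlignCodons:
    def _rec(self, i, seq):
        return SequenceRecord(f"s{i}", "", seq)

    def test_identical_sequences_no_gaps(self, rng):
        s = random_sense_codons(rng, 40)
        aln = kaks.align_codons([self._rec(1, s), self._rec(2, s)])
        assert aln.rows[0] == aln.rows[1] == s

    def test_clean_codon_deletion_single_gap_column(self, rng):
        # a 3-nt deletion appears as exactly one gap codon; oracle =
        # protein NW on the short pair (deleting one residue must realign
        # all others perfectly)
        s = random_sense_codons(rng, 40)
        k = 17
        deleted = s[: 3 * k] + s[3 * (k + 1) :]
        aln = kaks.align_codons([self._rec(1, s), self._rec(2, deleted)])
        assert aln.rows[0] == s
        assert aln.rows[1].count("-") == 3
        gap_at = aln.rows[1].index("---")
        assert gap_at % 3 == 0
        without_gap = aln.rows[1].replace("---", "")
        assert without_gap == deleted

    def test_trailing_partial_codon_trimmed(self, rng):
        s = random_sense_codons(rng, 30)
        with pytest.warns(UserWarning, match="trimmed"):
            aln = kaks.align_codons([self._rec(1, s + "AC"), self._rec(2, s)])
        assert aln.length == len(s)

    def test_internal_stop_rejected(self, rng):
        s = random_sense_codons(rng, 30)
        bad = s[:30] + "TAA" + s[33:]
        with pytest.raises(ValueError, match="stop"):
            kaks.align_codons([self._rec(1, bad), self._rec(2, s)])

    def test_three_way_alignment_shapes(self, rng):
        seqs = [random_sense_codons(rng, 30) for _ in range(3)]
        aln = kaks.align_codons([self._rec(i, s) for i, s in enumerate(seqs)])
        assert len({len(r) for r in aln.rows}) == 1
        assert aln.length % 3 == 0
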