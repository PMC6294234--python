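"""Genomic reconstruction: gap filling against simulated truth, splice
verification, ORF integrity, intron conservation, coverage diagnostics."""

import numpy as np
import pytest

import hgtscreen as hs
from hgtscreen.reconstruct import (
    GapFillParams,
    coverage_contamination_check,
    fill_gap,
    intron_position_conservation,
    orf_integrity,
    splice_check,
)
from hgtscreen.simulate import ReadModelConfig, generate_reads, _evolve_nucs


def _dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _reads(template, depth=30.0, seed=0, error=0.0, insert=500):
    rm = ReadModelConfig(depth=depth, error_rate=error)
    return generate_reads(
        template, rm, np.random.default_rng(seed), insert=insert
    )


class TestFillGap:
    def test_closes_simulated_gap_exactly(self, rng):
        left = _dna(rng, 400)
        gap = _dna(rng, 200)
        right = _dna(rng, 400)
        reads = _reads(left + gap + right, depth=30, seed=1)
        res = fill_gap(left, right, reads)
        assert res.closed and not res.ambiguous
        assert res.gap_seq == gap

    def test_adjacent_exons_close_quickly(self, rng):
        left = _dna(rng, 400)
        right = _dna(rng, 400)
        reads = _reads(left + right, depth=30, seed=2)
        res = fill_gap(left, right, reads)
        assert res.closed and res.gap_seq == ""
        assert res.iterations <= 2

    def test_duplicated_locus_raises_ambiguity(self, rng):
        # two ~97%-identical copies: mixed reads hit a branch point
        left = _dna(rng, 400)
        gap = _dna(rng, 300)
        right = _dna(rng, 400)
        tpl = left + gap + right
        dup = _evolve_nucs(tpl, 0.03, np.random.default_rng(9))
        reads = _reads(tpl, depth=25, seed=3) + _reads(dup, depth=25, seed=4)
        res = fill_gap(left, right, reads)
        assert (not res.closed and res.ambiguous) or res.gap_seq == gap
        assert not res.closed  # equal-support branch point must not close

    def test_no_reads_stays_open(self, rng):
        res = fill_gap(_dna(rng, 100), _dna(rng, 100), [])
        assert not res.closed and res.iterations <= 1

    def test_deterministic(self, rng):
        left, gap, right = _dna(rng, 300), _dna(rng, 150), _dna(rng, 300)
        reads = _reads(left + gap + right, depth=25, seed=5)
        r1 = fill_gap(left, right, reads)
        r2 = fill_gap(left, right, list(reads))
        assert (r1.closed, r1.gap_seq) == (r2.closed, r2.gap_seq)

    def test_dna_mode_hgt_genes_close_from_dataset(self):
        """Every dna-mode transferred gene's introns are recovered exactly
        from 30x error-free genomic reads (truth = simulator sequence)."""
        cfg = hs.default_scenario(seed=31, n_vertical=2, n_hgt=1)
        data = hs.simulate_dataset(cfg)
        lid = data.truth.hgt_locus_ids()[0]
        region, exons, _ = data.parasite_gene_region(lid)
        reads = data.reads([lid], kind="genomic")[lid]
        for i in range(len(exons) - 1):
            (a1, b1), (a2, b2) = exons[i], exons[i + 1]
            res = fill_gap(region[a1:b1], region[a2:b2], reads)
            assert res.closed
            assert res.gap_seq == region[b1:a2]


class TestSpliceCheck:
    def _gene(self, rng):
        cfg = hs.default_scenario(seed=41, n_vertical=2, n_hgt=1)
        data = hs.simulate_dataset(cfg)
        lid = data.truth.hgt_locus_ids()[0]
        region, exons, transcript = data.parasite_gene_region(lid)
        return region, exons, transcript

    def test_spliced_transcript_reads_confirm_all_introns(self, rng):
        region, exons, transcript = self._gene(rng)
        mreads = _reads(transcript, depth=20, seed=6, insert=200)
        statuses = splice_check(region, exons, mreads)
        assert statuses and all(s.spliced for s in statuses)

    def test_genomic_reads_confirm_nothing(self, rng):
        region, exons, transcript = self._gene(rng)
        greads = _reads(region, depth=20, seed=7, insert=500)
        statuses = splice_check(region, exons, greads)
        assert statuses and not any(s.spliced for s in statuses)

    def test_anchor_contract_short_side_not_counted(self, rng):
        region, exons, transcript = self._gene(rng)
        # a read covering the junction with only 9 nt on the right side
        left_end = exons[0][1]
        cds_pos = left_end - exons[0][0]
        frag = transcript[cds_pos - 60 : cds_pos + 9]
        statuses = splice_check(region, exons, [frag])
        assert not statuses[0].spliced


class TestOrfIntegrity:
    def _cds(self, rng, n=100):
        from conftest import random_sense_codons

        return random_sense_codons(rng, n)

    def test_self_is_intact(self, rng):
        cds = self._cds(rng)
        rep = orf_integrity(cds, cds)
        assert rep.intact and rep.premature_stops == 0

    def test_point_nonsense_mutation_detected(self, rng):
        cds = "ATG" + "GAA" * 50 + "CCT" * 49
        mutated = cds[:90] + "TAA" + cds[93:]
        rep = orf_integrity(mutated, cds)
        assert rep.premature_stops == 1 and not rep.intact

    def test_two_nt_deletion_is_one_frameshift(self, rng):
        cds = self._cds(rng, 120)
        mutated = cds[:150] + cds[152:]
        rep = orf_integrity(mutated, cds)
        assert rep.frameshift_indels == 1

    def test_clean_codon_deletion_not_frameshift(self, rng):
        cds = self._cds(rng, 120)
        mutated = cds[:150] + cds[153:]
        rep = orf_integrity(mutated, cds)
        assert rep.frameshift_indels == 0

    def test_missense_substitutions_not_damage(self, rng):
        # amino-acid-changing substitutions alone leave the ORF intact
        cds = "ATG" + "GAA" * 80
        mutated = "ATG" + "GAA" * 40 + "GCA" + "GAA" * 39
        rep = orf_integrity(mutated, cds)
        assert rep.intact


class TestIntronConservation:
    def test_dna_mode_transfer_shares_all_positions(self):
        cfg = hs.default_scenario(seed=51, n_vertical=2, n_hgt=1)
        data = hs.simulate_dataset(cfg)
        e = data.truth.entry(data.truth.hgt_locus_ids()[0])
        donor_model, _ = data.host_gene_model(e.donor_tip, e.family)
        shared, total = intron_position_conservation(
            (e.cds_seq, e.intron_positions), donor_model
        )
        assert total == len(donor_model.introns)
        assert shared == total

    def test_mrna_mode_transfer_shares_none(self):
        cfg = hs.default_scenario(seed=52, n_vertical=2, n_hgt=1)
        cfg.hgt_events[0].mode = "mrna"
        data = hs.simulate_dataset(cfg)
        e = data.truth.entry(data.truth.hgt_locus_ids()[0])
        donor_model, _ = data.host_gene_model(e.donor_tip, e.family)
        shared, total = intron_position_conservation(
            (e.cds_seq, []), donor_model
        )
        assert shared == 0 and total > 0

    def test_gene_against_itself(self):
        cfg = hs.default_scenario(seed=53, n_vertical=2, n_hgt=1)
        data = hs.simulate_dataset(cfg)
        m, _ = data.host_gene_model("H1", 0)
        shared, total = intron_position_conservation(m, m)
        assert shared == total == len(m.introns)


class TestCoverage:
    def _genes(self, rng, n=4, length=1500):
        return {f"g{i}": _dna(rng, length) for i in range(n)}

    def test_equal_depth_not_flagged(self, rng):
        hgt = self._genes(rng, 2)
        bg = {f"b{i}": _dna(rng, 1500) for i in range(2)}
        reads = []
        for i, (gid, seq) in enumerate({**hgt, **bg}.items()):
            reads += _reads(seq, depth=10, seed=10 + i)
        profiles, flagged = coverage_contamination_check(hgt, bg, reads)
        assert not flagged
        meds = [p.depth_at_identity[100] for p in profiles.values()]
        assert max(meds) < 1.2 * min(meds) / 0.8  # within ~20%

    def test_unintegrated_contaminant_flagged(self, rng):
        hgt = self._genes(rng, 2)
        bg = {f"b{i}": _dna(rng, 1500) for i in range(2)}
        reads = []
        for i, (gid, seq) in enumerate(bg.items()):
            reads += _reads(seq, depth=10, seed=20 + i)
        for i, (gid, seq) in enumerate(hgt.items()):
            reads += _reads(seq, depth=0.7, seed=30 + i)
        _, flagged = coverage_contamination_check(hgt, bg, reads)
        assert flagged

    def test_depth_monotone_across_identity_tiers(self, rng):
        genes = self._genes(rng, 2)
        reads = []
        for i, (gid, seq) in enumerate(genes.items()):
            reads += _reads(seq, depth=10, seed=40 + i, error=0.01)
        profiles, _ = coverage_contamination_check(
            {}, genes, reads
        ) if False else coverage_contamination_check(
            {"g0": genes["g0"]}, {"g1": genes["g1"]}, reads
        )
        for p in profiles.values():
            d = p.depth_at_identity
            assert d[100] <= d[95] <= d[90]

    def test_wgd_duplicate_inflates_relaxed_tiers(self):
        """A ~7%-diverged duplicate roughly doubles depth when identity is
        relaxed from 100% to >90%."""
        cfg = hs.wgd_scenario(seed=61)
        data = hs.simulate_dataset(cfg)
        lid = data.truth.hgt_locus_ids()[0]
        region, _, _ = data.parasite_gene_region(lid)
        reads = data.reads([lid], kind="genomic")[lid]
        profiles, _ = coverage_contamination_check(
            {lid: region}, {"bg": region[::-1].translate(
                str.maketrans("ACGT", "TGCA"))}, reads
        )
        d = profiles[lid].depth_at_identity
        assert d[90] >= 1.7 * d[100]

    def test_empty_background_rejected(self, rng):
        with pytest.raises(ValueError):
            coverage_contamination_check({"g": _dna(rng, 500)}, {}, [])
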