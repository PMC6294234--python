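"""Synthetic-data generator: determinism, divergence calibration,
transfer-injection semantics and read generation."""

import numpy as np
import pytest

import hgtscreen as hs
from hgtscreen.kaks import ka_ks
from hgtscreen.simulate import (
    ReadModelConfig,
    build_genomic,
    build_species_tree,
    generate_reads,
)


def two_taxon_config(seed, d_each=0.1, n_codons=300):
    return hs.SimConfig(
        seed=seed,
        host_tree=f"(A:{d_each},B:{d_each})hostroot;",
        outer_tree="(hosts:0.0,(outgroup:0.0,parasite:0.0)op:0.0)root;",
        n_families=1,
        n_codons=n_codons,
        rate_range=(1.0, 1.0),
    )


class TestEvolveFamily:
    def test_zero_branch_length_identical(self):
        cfg = two_taxon_config(3, d_each=0.0)
        fam = hs.evolve_family(cfg, 0)
        assert fam.cds("A") == fam.cds("B") == fam.cds("hostroot")

    def test_negative_branch_length_rejected(self):
        cfg = two_taxon_config(3)
        cfg.host_tree = "(A:-0.1,B:0.1)hostroot;"
        with pytest.raises(ValueError, match="negative"):
            build_species_tree(cfg)

    def test_same_seed_identical_output(self):
        f1 = hs.evolve_family(two_taxon_config(9), 0)
        f2 = hs.evolve_family(two_taxon_config(9), 0)
        assert f1.cds("A") == f2.cds("A")
        assert f1.introns["A"] == f2.introns["A"]

    def test_different_seeds_differ(self):
        f1 = hs.evolve_family(two_taxon_config(9), 0)
        f2 = hs.evolve_family(two_taxon_config(10), 0)
        assert f1.cds("A") != f2.cds("A")

    def test_mean_ks_matches_branch_length(self):
        # two taxa at total synonymous path 0.2: the mean NG86/JC Ks over
        # 200 replicate families recovers it within 3 standard errors
        vals = []
        for seed in range(200):
            fam = hs.evolve_family(two_taxon_config(seed), 0)
            vals.append(ka_ks(fam.cds("A"), fam.cds("B")).Ks)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.2) < 3 * se

    def test_ks_monotone_in_divergence(self):
        # mean Ks strictly increases with simulated synonymous divergence
        means = []
        for d in (0.05, 0.15, 0.3, 0.45, 0.6):
            vals = [
                ka_ks(
                    (f := hs.evolve_family(two_taxon_config(s, d / 2), 0)).cds(
                        "A"
                    ),
                    f.cds("B"),
                ).Ks
                for s in range(25)
            ]
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestInjectHgt:
    def _cfg(self, mode, age=0.5, donor="H1", seed=4):
        cfg = hs.default_scenario(seed=seed, n_vertical=2, n_hgt=1)
        cfg.hgt_events = [hs.HgtEvent(2, donor, age, mode)]
        return cfg

    def test_age_zero_terminal_equals_donor_tip(self):
        data = hs.simulate_dataset(self._cfg("dna", age=0.0))
        e = data.truth.entry("locus0002h")
        assert e.cds_seq == data.families[2].cds("H1")

    def test_dna_mode_preserves_intron_positions(self):
        data = hs.simulate_dataset(self._cfg("dna"))
        e = data.truth.entry("locus0002h")
        fam = data.families[2]
        assert e.intron_positions == fam.intron_positions
        # splicing the truth structure reproduces the transferred CDS
        genomic, exons = e.genomic_seq, None
        spliced = "".join(
            e.genomic_seq[a:b]
            for a, b in _exons_from_truth(e)
        )
        assert spliced == e.cds_seq

    def test_mrna_mode_intronless_with_polya(self):
        cfg = self._cfg("mrna")
        data = hs.simulate_dataset(cfg)
        e = data.truth.entry("locus0002h")
        assert e.intron_positions == []
        rec = next(
            r for r in data.parasite_transcripts if r.id == "locus0002h"
        )
        assert rec.seq.endswith("A" * cfg.polya_len)

    def test_bad_age_fraction_rejected(self):
        with pytest.raises(ValueError, match="age_fraction"):
            hs.simulate_dataset(self._cfg("dna", age=1.5))

    def test_vertical_homolog_retained(self):
        data = hs.simulate_dataset(self._cfg("dna"))
        ids = {r.id for r in data.parasite_transcripts}
        assert {"locus0002", "locus0002h"} <= ids

    def test_expected_donor_ks_tracks_truth(self):
        vals = []
        for seed in range(40):
            data = hs.simulate_dataset(self._cfg("dna", seed=seed))
            e = data.truth.entry("locus0002h")
            vals.append(
                ka_ks(e.cds_seq, data.families[2].cds(e.donor_tip)).Ks
            )
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - 0.05) < 3 * se + 0.01


def _exons_from_truth(e):
    exons, prev, off = [], 0, 0
    for pos, ln in zip(e.intron_positions, e.intron_lengths):
        exons.append((off, off + pos - prev))
        off += pos - prev + ln
        prev = pos
    exons.append((off, off + len(e.cds_seq) - prev))
    return exons


class TestBuildGenomic:
    def test_splice_inverse(self, rng):
        from conftest import random_sense_codons

        cds = random_sense_codons(rng, 50)
        genomic, exons = build_genomic(cds, [30, 90], ["GTAAAG", "GTCCAG"])
        assert "".join(genomic[a:b] for a, b in exons) == cds


class TestReads:
    def test_error_free_reads_are_exact_substrings(self, rng):
        tpl = "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, 2000)]
        )
        rm = ReadModelConfig(depth=30.0, error_rate=0.0)
        reads = generate_reads(tpl, rm, np.random.default_rng(0), insert=500)
        from hgtscreen._codon import revcomp

        assert reads
        for r in reads:
            assert r.seq in tpl or revcomp(r.seq) in tpl

    def test_zero_depth_rejected(self):
        rm = ReadModelConfig(depth=0.0)
        with pytest.raises(ValueError):
            generate_reads("A" * 1000, rm, np.random.default_rng(0))

    def test_template_shorter_than_insert_skipped(self):
        rm = ReadModelConfig(depth=10.0)
        with pytest.warns(UserWarning, match="skipped"):
            assert generate_reads("A" * 100, rm, np.random.default_rng(0)) == []

    def test_mean_depth_matches_request(self, rng):
        # depth 20 over 10 kb: realized mean per-base depth within 10%
        tpl = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
        rm = ReadModelConfig(depth=20.0)
        reads = generate_reads(tpl, rm, np.random.default_rng(5), insert=500)
        cov = np.zeros(len(tpl))
        # oracle: accumulate per-base coverage from the emitted reads by
        # locating each read in the template
        from hgtscreen._codon import revcomp

        for r in reads:
            s = r.seq if r.seq in tpl else revcomp(r.seq)
            i = tpl.find(s)
            cov[i : i + len(s)] += 1
        assert 18.0 <= cov.mean() <= 22.0

    def test_read_length_and_pairing(self):
        rm = ReadModelConfig(depth=5.0)
        reads = generate_reads("ACGT" * 300, rm, np.random.default_rng(1))
        assert len(reads) % 2 == 0
        assert {len(r.seq) for r in reads} == {90}


class TestDatasetDeterminism:
    def test_same_seed_bitwise_identical_emission(self, tmp_path):
        cfg = hs.default_scenario(seed=21, n_vertical=3, n_hgt=1)
        d1 = hs.simulate_dataset(cfg).emit(tmp_path / "a")
        d2 = hs.simulate_dataset(cfg).emit(tmp_path / "b")
        f1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        f2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert f1 == f2
        for rel in f1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_truth_marks_every_event_once(self):
        cfg = hs.default_scenario(seed=2, n_vertical=5, n_hgt=3)
        data = hs.simulate_dataset(cfg)
        assert len(data.truth.hgt_locus_ids()) == 3

    def test_duplicate_event_family_rejected(self):
        cfg = hs.default_scenario(seed=2, n_vertical=5, n_hgt=1)
        cfg.hgt_events = cfg.hgt_events * 2
        with pytest.raises(ValueError, match="more than one"):
            hs.simulate_dataset(cfg)

    def test_emitted_gene_models_splice_consistently(self, tmp_path):
        from hgtscreen import io_formats as io

        cfg = hs.default_scenario(seed=21, n_vertical=3, n_hgt=1)
        out = hs.simulate_dataset(cfg).emit(tmp_path)
        genome = io.read_sequences(out / "H1_genome.fa")
        models = io.read_gene_models(out / "H1_genes.gff3", genome)
        chroms = {r.id: r.seq for r in genome}
        assert models
        for m in models:
            assert m.splice(chroms[m.chromosome]) == m.cds_seq
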