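"""The synthetic-data generators: determinism, structure, and truth records."""

import numpy as np
import pytest

from tescan.cmet import tally_mutations
from tescan.match_scan import reverse_complement, scan_region
from tescan.simulate import (
    DivergenceSimConfig,
    GenomeSimConfig,
    LibrarySimConfig,
    TEFamilySpec,
    default_genome_config,
    default_library_config,
    evolve_pair,
    simulate_genome,
    simulate_srna_library,
)
from tescan.srna_db import build_database


class TestSimulateGenome:
    def test_no_tes_pure_background(self):
        cfg = GenomeSimConfig(seed=1, genome_length=5_000, te_catalogue=(), gene_count=0)
        region, features, truth = simulate_genome(cfg)
        assert len(region) == 5_000
        assert features == [] and truth["insertions"] == []

    def test_fixed_seed_reproducible(self):
        out1 = simulate_genome(default_genome_config(9))
        out2 = simulate_genome(default_genome_config(9))
        assert out1[0].sequence == out2[0].sequence
        assert out1[1] == out2[1]

    def test_nesting_depth_capped(self):
        catalogue = [TEFamilySpec("Gypsy", "Sabrina", 12, (500, 800), ltr_length=100)]
        cfg = GenomeSimConfig(
            seed=3, genome_length=20_000, te_catalogue=catalogue,
            nesting_probability=1.0, max_nesting_depth=4, gene_count=0,
        )
        _, features, truth = simulate_genome(cfg)
        levels = [f.nesting_level for f in features]
        assert max(levels) <= 4
        assert max(levels) >= 2  # nesting probability 1 actually nests
        for f in features:
            if f.parent_id is not None:
                parent = next(g for g in features if g.feature_id == f.parent_id)
                assert f.nesting_level == parent.nesting_level + 1
                assert parent.start <= f.start and f.end <= parent.end

    def test_ltr_subfeatures_identical_at_birth(self):
        cfg = GenomeSimConfig(
            seed=5, genome_length=10_000,
            te_catalogue=[TEFamilySpec("Copia", "Angela", 1, (2_000, 2_400), ltr_length=250)],
            gene_count=0, nesting_probability=0.0, per_copy_mutation_rate=0.0,
        )
        region, features, _ = simulate_genome(cfg)
        (feat,) = features
        ltr5 = next(s for s in feat.subfeatures if s.kind == "LTR5")
        ltr3 = next(s for s in feat.subfeatures if s.kind == "LTR3")
        assert (
            region.sequence[ltr5.start : ltr5.end]
            == region.sequence[ltr3.start : ltr3.end]
        )

    def test_tir_subfeatures_inverted(self):
        cfg = GenomeSimConfig(
            seed=6, genome_length=5_000,
            te_catalogue=[TEFamilySpec("Mariner", "Thalos", 1, (180, 220), tir_length=60)],
            gene_count=0, nesting_probability=0.0, per_copy_mutation_rate=0.0,
        )
        region, features, _ = simulate_genome(cfg)
        (feat,) = features
        tir5 = next(s for s in feat.subfeatures if s.kind == "TIR5")
        tir3 = next(s for s in feat.subfeatures if s.kind == "TIR3")
        assert region.sequence[tir3.start : tir3.end] == reverse_complement(
            region.sequence[tir5.start : tir5.end]
        )


class TestSimulateLibrary:
    def test_empty_library(self, sim_genome):
        region, features, _ = sim_genome
        reads, truth = simulate_srna_library(
            region, features, LibrarySimConfig(seed=1, total_reads=0)
        )
        assert reads == [] and truth["reads"] == []

    def test_deterministic(self, sim_genome):
        region, features, _ = sim_genome
        cfg = LibrarySimConfig(seed=11, total_reads=500)
        r1, _ = simulate_srna_library(region, features, cfg)
        r2, _ = simulate_srna_library(region, features, cfg)
        assert r1 == r2

    def test_genomic_reads_are_substrings(self, sim_genome, sim_library):
        region, _, _ = sim_genome
        reads, truth = sim_library
        for read, row in zip(reads[:300], truth["reads"][:300]):
            if row["origin"] == "nongenomic":
                continue
            s, L = row["start"], row["length"]
            window = region.sequence[s : s + L]
            expected = window if row["strand"] == "+" else reverse_complement(window)
            assert read.sequence == expected

    def test_scanner_recovers_every_genomic_read(self, sim_genome, sim_library, sim_db):
        """Sensitivity is 100% by construction: every genomic read's true
        origin must appear in the scan hits."""
        region, _, _ = sim_genome
        reads, truth = sim_library
        hits = {(h.start, h.length, h.strand) for h in scan_region(sim_db, region)}
        for row in truth["reads"]:
            if row["origin"] == "nongenomic":
                continue
            assert (row["start"], row["length"], row["strand"]) in hits

    def test_length_mixture_converges(self, sim_genome):
        region, features, _ = sim_genome
        cfg = LibrarySimConfig(seed=77, total_reads=100_000)
        reads, truth = simulate_srna_library(region, features, cfg)
        # each read's 24-nt probability depends on its origin (Mariner TEs
        # use the 21-nt-dominated mixture); the realized aggregate share
        # must converge to the origin-conditional expectation within 1%.
        superfamily = {f.feature_id: f.superfamily for f in features}
        expected = []
        for row in truth["reads"]:
            if row["origin"] in ("te_subregion", "te_body"):
                mariner = superfamily.get(row["feature_id"]) == "Mariner"
                expected.append(cfg.mariner_24_share if mariner else cfg.te_24_share)
            else:
                expected.append(cfg.global_24_share)
        realized = np.mean([row["length"] == 24 for row in truth["reads"]])
        assert abs(realized - np.mean(expected)) < 0.01

    def test_mariner_reads_21nt_biased(self, sim_genome):
        region, features, _ = sim_genome
        cfg = LibrarySimConfig(seed=78, total_reads=30_000)
        reads, truth = simulate_srna_library(region, features, cfg)
        mariner_feats = {
            f.feature_id for f in features if f.superfamily == "Mariner"
        }
        m_lengths = [
            row["length"] for row in truth["reads"] if row["feature_id"] in mariner_feats
        ]
        assert len(m_lengths) > 300
        share21 = np.mean([L == 21 for L in m_lengths])
        sd = np.sqrt(0.54 * 0.46 / len(m_lengths))
        assert abs(share21 - 0.54) < 4 * sd


class TestEvolvePair:
    def test_zero_age_identical(self):
        pair, _ = evolve_pair(DivergenceSimConfig(seed=1, ancestor_length=2_000, age_years=0.0))
        assert pair.seq_a == pair.seq_b

    def test_deterministic(self):
        cfg = DivergenceSimConfig(seed=4, ancestor_length=3_000, indel_rate=0.002)
        p1, _ = evolve_pair(cfg)
        p2, _ = evolve_pair(cfg)
        assert p1 == p2

    def test_truth_equals_tally_without_indels(self):
        cfg = DivergenceSimConfig(
            seed=8, ancestor_length=20_000,
            methylated_strata=[(0, 10_000)], pms_transition_multiplier=10.0,
        )
        pair, truth = evolve_pair(cfg)
        assert tally_mutations(pair) == truth["tally_total"]

    def test_truth_matches_tally_with_indels(self):
        cfg = DivergenceSimConfig(seed=9, ancestor_length=10_000, indel_rate=0.005)
        pair, truth = evolve_pair(cfg)
        t = tally_mutations(pair)
        assert t == truth["tally_total"]
        assert t.columns_excluded_by_gap > 0

    def test_no_elevation_when_multiplier_is_one(self):
        """With m = 1 the PMS transition frequencies of the nominally
        methylated and unmethylated strata are statistically
        indistinguishable (two-proportion test, alpha 0.01)."""
        from scipy.stats import norm

        rejections = 0
        for rep in range(10):
            L = 30_000
            cfg = DivergenceSimConfig(
                seed=1000 + rep, ancestor_length=L,
                pms_transition_multiplier=1.0, methylated_strata=[(0, L // 2)],
            )
            pair, _ = evolve_pair(cfg)
            t1 = tally_mutations(pair, columns=slice(0, L // 2))
            t2 = tally_mutations(pair, columns=slice(L // 2, L))
            n1, x1, _ = t1.pooled()
            n2, x2, _ = t2.pooled()
            p_pool = (x1 + x2) / (n1 + n2)
            se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
            z = (x1 / n1 - x2 / n2) / se
            if abs(z) > norm.ppf(0.995):
                rejections += 1
        assert rejections <= 2

    def test_stratified_truth_partitions_columns(self):
        cfg = DivergenceSimConfig(
            seed=12, ancestor_length=8_000, methylated_strata=[(2_000, 5_000)],
        )
        _, truth = evolve_pair(cfg)
        total = truth["tally_total"]
        meth = truth["tally_by_stratum"]["methylated"]
        other = truth["tally_by_stratum"]["other"]
        assert meth + other == total
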