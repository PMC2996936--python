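"""Feature attribution, density/decile profiling, and the statistical tests."""

import math

import numpy as np
import pytest

from tescan.match_scan import GenomicRegion, MatchHit, scan_region
from tescan.srna_db import build_database
from tescan.simulate import write_gff3
from tescan.te_profile import (
    DecileProfile,
    FeatureAnnotation,
    SubFeature,
    TEClassification,
    TERecord,
    assign_hits,
    decile_profile,
    filter_te_database,
    group_density_comparison,
    parse_te_header,
    pearson_correlation,
    profile_feature,
    read_gff3,
    uniformity_test,
)
from .conftest import make_reads


def make_hit(start, length=21, total=1, region="r", strand="+"):
    return MatchHit(region, start, length, strand, "A" * length, (("L1", total),), total)


def te(fid, start, end, level=0, parent=None, superfamily="Gypsy"):
    return FeatureAnnotation(
        fid, "r", start, end, "TE", "I", superfamily, "fam", level, parent
    )


class TestAssignHits:
    def test_no_annotations_all_intergenic(self):
        hits = [make_hit(5), make_hit(50)]
        res = assign_hits(hits, [])
        assert res.by_feature["intergenic"] == hits

    def test_innermost_wins_under_nesting(self):
        gypsy = te("gypsy1", 0, 5000, level=0)
        mite = FeatureAnnotation(
            "mite1", "r", 1000, 1200, "TE", "II", "Mariner", "Thalos", 2, "gypsy1"
        )
        hit = make_hit(1050)
        res = assign_hits([hit], [gypsy, mite])
        assert res.by_feature["mite1"] == [hit]
        assert res.by_feature["gypsy1"] == []

    def test_gene_bucket(self):
        gene = FeatureAnnotation("g1", "r", 100, 600, "gene")
        hits = [make_hit(150), make_hit(200)]
        res = assign_hits(hits, [gene, te("te1", 1000, 2000)])
        assert len(res.by_feature["g1"]) == 2
        assert res.by_feature["te1"] == []

    def test_boundary_straddle_by_start(self):
        feat = te("te1", 100, 115)
        hit = make_hit(105, length=21)  # footprint 105-126 straddles the 3' edge
        res = assign_hits([hit], [feat])
        assert res.by_feature["te1"] == [hit]
        assert res.boundary_hits == [("te1", hit)]

    def test_conservation(self, sim_db, sim_genome):
        region, features, _ = sim_genome
        hits = scan_region(sim_db, region)
        res = assign_hits(hits, features)
        assert sum(len(v) for v in res.by_feature.values()) == len(hits)


class TestProfileFeature:
    def test_zero_hits_flagged(self):
        p = profile_feature(te("t", 0, 100), [])
        assert p.zero_total and p.counts_per_bp == 0.0 and p.pct_21 == 0.0

    def test_density_at_annotated_te_scale(self):
        feat = te("all_tes", 0, 220_511)
        p = profile_feature(feat, [make_hit(10, total=70_808)])
        assert round(p.counts_per_bp, 2) == 0.32

    def test_size_class_shares(self):
        hits = (
            [make_hit(i, length=21, total=1) for i in range(54)]
            + [make_hit(i, length=24, total=1) for i in range(27)]
            + [make_hit(i, length=22, total=1) for i in range(19)]
        )
        p = profile_feature(te("t", 0, 1000), hits)
        assert p.pct_21 == pytest.approx(54.0)
        assert p.pct_24 == pytest.approx(27.0)


class TestDecileProfile:
    def test_uniform_tiling_gives_equal_bins(self):
        feat = te("t", 0, 1000)
        hits = [make_hit(s, total=2) for s in range(0, 1000, 100)]
        prof = decile_profile(feat, hits)
        assert (prof.bins == 2).all()

    def test_floor_arithmetic(self):
        feat = te("t", 300, 500)  # 200 bp element
        hits = [make_hit(305, total=4), make_hit(472, total=6)]
        prof = decile_profile(feat, hits)
        expected = np.zeros(10, dtype=int)
        expected[0], expected[8] = 4, 6
        assert (prof.bins == expected).all()

    def test_bins_conserve_filtered_total(self):
        feat = te("t", 0, 400)
        hits = [make_hit(s, length=21 if s % 2 else 24, total=3) for s in range(0, 380, 7)]
        prof24 = decile_profile(feat, hits, srna_length_filter=24)
        expected = sum(h.total_count for h in hits if h.length == 24)
        assert prof24.total == expected

    def test_symmetric_tir_mite(self):
        """A MITE of two perfect TIRs: all mass terminal and mirror-symmetric."""
        rng = np.random.default_rng(7)
        tir = "".join(rng.choice(list("ACGT"), size=60))
        rc = tir.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        spacer = "".join(rng.choice(list("ACGT"), size=180))
        element = GenomicRegion("mite", tir + spacer + rc)
        windows = [tir[i : i + 21] for i in range(len(tir) - 20)]
        db = build_database([make_reads(windows)])
        hits = scan_region(db, element)
        prof = decile_profile(element, hits)
        n = len(element)
        for h in hits:
            # every 5' TIR hit has a mirror hit at the reflected footprint
            assert any(h2.start == n - h.end for h2 in hits)
        assert prof.bins[2:8].sum() == 0
        assert prof.bins[:2].sum() == prof.bins[8:].sum() > 0

    def test_short_element_rejected(self):
        with pytest.raises(ValueError):
            decile_profile(te("t", 0, 9), [])


class TestUniformityTest:
    def test_perfectly_uniform(self):
        res = uniformity_test(DecileProfile("e", np.full(10, 50)))
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("k,df", [(2, 7), (1, 8), (0, 9)])
    def test_terminal_merging_degrees_of_freedom(self, k, df):
        res = uniformity_test(DecileProfile("e", np.arange(10) + 1.0), k)
        assert res.df == df

    def test_terminal_concentration_chi_square(self):
        # closed form: total 200, exp 20/bin; 2*(80^2/20) + 8*(20^2/20) = 800
        bins = np.array([100, 0, 0, 0, 0, 0, 0, 0, 0, 100])
        res = uniformity_test(DecileProfile("e", bins))
        assert res.statistic == pytest.approx(800.0)
        assert res.p_value < 1e-4

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            uniformity_test(DecileProfile("e", np.zeros(10)))


class TestGroupComparison:
    def test_identical_groups(self):
        res = group_density_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_welch_closed_form(self):
        a, b = [10.0, 11.0, 12.0], [0.1, 0.2, 0.1]
        res = group_density_comparison(a, b)
        # independent Welch arithmetic
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1) / 3, np.var(b, ddof=1) / 3
        t_expected = (ma - mb) / math.sqrt(va + vb)
        df_expected = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        assert res.statistic == pytest.approx(t_expected)
        assert res.df == pytest.approx(df_expected)
        # with n=3 per group Welch df is ~2, so even t~19 leaves p ~ 3e-3
        assert res.p_value < 0.01

    def test_one_sided_direction(self):
        top, lower = [3.0, 4.0, 5.0], [1.0, 1.5, 2.0]
        greater = group_density_comparison(top, lower, sidedness="greater")
        two = group_density_comparison(top, lower)
        assert greater.p_value == pytest.approx(two.p_value / 2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_density_comparison([1.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = pearson_correlation(x, [2 * v + 1 for v in x])
        assert res.estimate == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        res = pearson_correlation([1, 2, 3], [3, 2, 1])
        assert res.estimate == pytest.approx(-1.0)

    def test_covariance_formula_oracle(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = pearson_correlation(x, y)
        r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res.estimate == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1, 2, 3])


class TestRepeatHeaders:
    @pytest.mark.parametrize(
        "header,te_class,superfamily,family",
        [
            (">RLC_Taes_Angela_A605-1 complete", "I", "Copia", "Angela"),
            (">DTT_Taes_Thalos_42j2-9 complete", "II", "Mariner", "Thalos"),
            (">RLG_Ttur_Sabrina_1 complete", "I", "Gypsy", "Sabrina"),
            (">DTC_Aeta_Caspar_2 fragment", "II", "CACTA", "Caspar"),
        ],
    )
    def test_code_table(self, header, te_class, superfamily, family):
        c = parse_te_header(header)
        assert (c.te_class, c.superfamily, c.family) == (te_class, superfamily, family)

    def test_garbage_header_never_crashes(self):
        c = parse_te_header(">!! not a repeat header")
        assert c.te_class == "unknown" and c.superfamily == "unknown"

    def test_genus_and_completeness(self):
        c = parse_te_header(">RLC_Taes_Angela_A605-1 complete element")
        assert c.genus == "Triticum" and c.completeness == "complete"
        c2 = parse_te_header(">RLC_Hvul_BARE1_1 incomplete")
        assert c2.genus == "Hordeum" and c2.completeness == "incomplete"


class TestFilterTEDatabase:
    @staticmethod
    def rec(rid, completeness="complete", genus="Triticum", seq="ACGT"):
        return TERecord(
            rid, TEClassification("I", "Copia", "fam", completeness, genus), seq
        )

    def test_staged_attrition(self):
        records = [
            self.rec("a", completeness="incomplete"),
            self.rec("b", completeness="incomplete"),
            self.rec("c", genus="Hordeum"),
            self.rec("d", seq="ACNGT"),
            self.rec("e"),
        ]
        survivors, report = filter_te_database(records)
        assert (report.after_complete, report.after_genus, report.after_ambiguous) == (3, 2, 1)
        assert [r.id for r in survivors] == ["e"]

    def test_identity_when_disabled(self):
        records = [self.rec("a", completeness="unknown", genus="unknown", seq="NNN")]
        survivors, _ = filter_te_database(
            records, complete_only=False, genera=None, exclude_ambiguous=False
        )
        assert survivors == records

    def test_clean_records_all_survive(self):
        records = [self.rec(f"r{i}") for i in range(4)]
        survivors, report = filter_te_database(records)
        assert len(survivors) == 4
        assert all(not v for v in report.failed.values())


def test_gff3_round_trip(tmp_path, sim_genome):
    region, features, _ = sim_genome
    path = tmp_path / "ann.gff3"
    write_gff3(region, features, path)
    loaded = {f.feature_id: f for f in read_gff3(path)}
    assert set(loaded) == {f.feature_id for f in features}
    for f in features:
        g = loaded[f.feature_id]
        assert (g.start, g.end, g.category) == (f.start, f.end, f.category)
        assert (g.te_class, g.superfamily, g.family) == (f.te_class, f.superfamily, f.family)
        assert (g.nesting_level, g.parent_id) == (f.nesting_level, f.parent_id)
        got_subs = sorted((s.kind, s.start, s.end) for s in g.subfeatures)
        want_subs = sorted(
            (s.kind, s.start, s.end) for s in f.subfeatures if s.kind != "internal"
        )
        assert got_subs == want_subs
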