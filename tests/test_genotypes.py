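"""Cleaning, imputation, consensus, filtering and differentiation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rilgp import genotypes as gt
from rilgp import simdata
from rilgp.simdata import SimConfig
from rilgp.types import GenotypeMatrix, PopulationMap

NA = np.nan


def _popmap():
    return PopulationMap(
        {"R1": "A", "R2": "A", "R3": "B", "R4": "B"},
        {"A": ("P1", "P2"), "B": ("P2", "P3")},
    )


def _matrix(values, lines, variants, provenance="rnaseq"):
    return GenotypeMatrix(
        pd.DataFrame(values, index=lines, columns=variants, dtype=float),
        provenance=provenance,
    )


class TestConsensus:
    @pytest.mark.parametrize(
        "calls, expected",
        [
            ([0, 0, 2], 0.0),  # major allele wins
            ([2, 2], 2.0),
            ([0, 2], NA),  # tie -> missing
            ([NA, NA], NA),
            ([NA, 2, 2, 0], 2.0),
            ([1, 1, 0], 1.0),
        ],
    )
    def test_examples(self, calls, expected):
        got = gt.consensus_duplicates(calls)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gt.consensus_duplicates([])

    def test_by_line_matches_scalar_rule(self, rng):
        samples = [f"s{i}" for i in range(6)]
        line_of = pd.Series(["L1", "L1", "L1", "L2", "L3", "L3"], index=samples)
        obs = pd.DataFrame(
            rng.choice([0.0, 1.0, 2.0, np.nan], size=(6, 40)),
            index=samples, columns=[f"v{j}" for j in range(40)],
        )
        out = gt.consensus_by_line(obs, line_of)
        for line in ["L1", "L2", "L3"]:
            block = obs.loc[line_of[line_of == line].index]
            for v in obs.columns:
                want = gt.consensus_duplicates(block[v])
                got = out.data.loc[line, v]
                assert (np.isnan(want) and np.isnan(got)) or want == got


class TestCleanCalls:
    def setup_method(self):
        #            v1   v2   v3   v4
        self.m = _matrix(
            [
                [0, 0, 0, NA],  # P1 (v4 has missing parental call)
                [2, 0, 2, 0],  # P2
                [2, 2, 0, 0],  # P3
                [1, 0, 2, 0],  # R1: het at v1
                [0, 2, 0, 0],  # R2: v2=2 inconsistent (parents 0/0)
                [2, 1, 2, 2],  # R3: het at v2, v3=2 ok (P2=2)
                [NA, 2, 1, 0],  # R4
            ],
            ["P1", "P2", "P3", "R1", "R2", "R3", "R4"],
            ["v1", "v2", "v3", "v4"],
        )

    def test_heterozygous_set_to_missing(self):
        out = gt.clean_calls(self.m, _popmap())
        assert np.isnan(out.data.loc["R1", "v1"])
        assert np.isnan(out.data.loc["R3", "v2"])

    def test_parent_inconsistent_set_to_missing(self):
        out = gt.clean_calls(self.m, _popmap())
        assert np.isnan(out.data.loc["R2", "v2"])  # pop A parents both 0

    def test_missing_parental_call_drops_variant(self):
        out = gt.clean_calls(self.m, _popmap())
        assert "v4" not in out.data.columns

    def test_consistent_calls_and_parents_untouched(self):
        out = gt.clean_calls(self.m, _popmap())
        assert out.data.loc["R1", "v3"] == 2
        assert out.data.loc["P2", "v1"] == 2

    def test_raw_mode_skips_cleaning(self):
        out = gt.clean_calls(self.m, _popmap(), raw=True)
        pd.testing.assert_frame_equal(out.data, self.m.data)

    def test_missing_lines_rejected_by_name(self):
        bad = GenotypeMatrix(self.m.data.drop(index="R2"))
        with pytest.raises(ValueError, match="R2"):
            gt.clean_calls(bad, _popmap())

    def test_never_unmasks_and_call_count_nonincreasing(self):
        out = gt.clean_calls(self.m, _popmap())
        before = self.m.data[out.data.columns]
        was_missing = before.isna()
        assert out.data[was_missing].isna().all().all()
        assert out.data.notna().sum().sum() <= before.notna().sum().sum()


class TestMedianImpute:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([0, 0, 2, NA], 0.0),
            ([2, 2, NA, 0, 2], 2.0),
            ([0, 2, NA, NA], 0.0),  # even-count tie -> lower value
        ],
    )
    def test_population_median_examples(self, column, expected):
        lines = [f"R{i}" for i in range(1, len(column) + 1)]
        pm = PopulationMap({l: "A" for l in lines}, {"A": ("P1", "P2")})
        m = GenotypeMatrix(pd.DataFrame({"v1": column}, index=lines, dtype=float))
        out = gt.median_impute(m, pm, drop_monomorphic=False)
        filled = out.data["v1"][pd.isna(pd.Series(column, index=lines, dtype=float))]
        assert (filled == expected).all()

    def test_no_missing_and_only_homozygous_after(self, sim):
        line_calls = gt.consensus_by_line(sim.observed, sim.expression.genotype)
        cleaned = gt.clean_calls(line_calls, sim.popmap)
        out = gt.median_impute(cleaned, sim.popmap)
        assert out.n_missing == 0
        assert np.isin(out.data.to_numpy(), [0.0, 2.0]).all()

    def test_population_without_calls_uses_cross_population_median(self):
        pm = _popmap()
        m = _matrix(
            [[0, 0], [2, 0], [2, 2], [0, 0], [0, 2], [NA, 2], [NA, 0]],
            ["P1", "P2", "P3", "R1", "R2", "R3", "R4"],
            ["v1", "v2"],
        )
        out = gt.median_impute(m, pm, drop_monomorphic=False)
        # pop B has no observed call at v1: cross-population median of
        # {0,2,2,0,0} = 0
        assert out.data.loc["R3", "v1"] == 0.0


class TestIntersectWGS:
    def _tables(self):
        rna_vt = pd.DataFrame(
            {"chrom": ["c1"] * 3, "pos": [1, 5, 9],
             "ref": ["A", "C", "G"], "alt": ["T", "G", "A"]},
            index=["r1", "r2", "r3"],
        )
        wgs_vt = pd.DataFrame(
            {"chrom": ["c1"] * 3, "pos": [5, 9, 12],
             "ref": ["C", "A", "T"], "alt": ["G", "G", "C"]},
            index=["w1", "w2", "w3"],
        )
        return rna_vt, wgs_vt

    def test_position_intersection(self):
        rna_vt, wgs_vt = self._tables()
        m = _matrix([[0, 0, 2], [2, 2, 0], [0, 2, 2]],
                    ["P1", "P2", "R1"], ["r1", "r2", "r3"])
        wgs = _matrix([[0], [2]], ["P1", "P2"], ["w1"], "wgs_consensus")
        wgs = _matrix([[0, 2], [2, 0]], ["P1", "P2"], ["w1", "w2"],
                      "wgs_consensus")
        out, vt = gt.intersect_wgs(m, rna_vt, wgs, wgs_vt)
        # pos 5 matches alleles; pos 9 alleles mismatch (G/A vs A/G -> swap)
        assert "r2" in out.data.columns and "r1" not in out.data.columns

    def test_allele_swap_harmonized(self):
        rna_vt, wgs_vt = self._tables()
        m = _matrix([[0, 0], [2, 2], [0, 2]], ["P1", "P2", "R1"], ["r2", "r3"])
        wgs = _matrix([[0, 2], [2, 0]], ["P1", "P2"], ["w1", "w2"],
                      "wgs_consensus")
        out, vt = gt.intersect_wgs(m, rna_vt, wgs, wgs_vt)
        # r3 (G->A) vs w2 (A->G): ref/alt swapped, WGS dosages flipped
        assert out.data.loc["P1", "r3"] == 2.0 - wgs.data.loc["P1", "w2"]

    def test_empty_intersection_warns(self):
        rna_vt = pd.DataFrame(
            {"chrom": ["c1"], "pos": [1], "ref": ["A"], "alt": ["T"]},
            index=["r1"],
        )
        wgs_vt = pd.DataFrame(
            {"chrom": ["c2"], "pos": [1], "ref": ["A"], "alt": ["T"]},
            index=["w1"],
        )
        m = _matrix([[0], [2]], ["P1", "P2"], ["r1"])
        wgs = _matrix([[0], [2]], ["P1", "P2"], ["w1"], "wgs_consensus")
        with pytest.warns(UserWarning, match="empty"):
            out, _ = gt.intersect_wgs(m, rna_vt, wgs, wgs_vt)
        assert out.data.shape[1] == 0


class TestImputeFromParents:
    def test_flank_rules(self):
        pm = PopulationMap({"R1": "A"}, {"A": ("P1", "P2")})
        vt = pd.DataFrame(
            {"chrom": ["c1"] * 5, "pos": [10, 20, 30, 40, 50]},
            index=[f"v{i}" for i in range(5)],
        )
        # P1 all 0, P2 all 2; R1 observed A-side at v0,v1,v4=A? craft:
        m = _matrix(
            [
                [0, 0, 0, 0, 0],  # P1
                [2, 2, 2, 2, 2],  # P2
                [0, NA, 0, NA, 2],  # R1
            ],
            ["P1", "P2", "R1"],
            list(vt.index),
        )
        out = gt.impute_from_parents(m, vt, pm)
        # v1 flanked by parent-1 alleles on both sides -> 0
        assert out.data.loc["R1", "v1"] == 0.0
        # v3 flanks disagree (v2 from P1, v4 from P2) -> median fallback,
        # population median of observed {0,0,2} = 0
        assert out.data.loc["R1", "v3"] == 0.0
        assert out.n_missing == 0

    def test_recovery_on_synthetic_data(self):
        cfg = SimConfig(n_variants=5000, n_chromosomes=3, n_transcripts=100,
                        pop_sizes=(20, 20, 20), seed=13)
        rng = np.random.default_rng(13)
        parents = simdata.simulate_parents(cfg, rng)
        geno, popmap = simdata.simulate_genotypes(cfg, rng, parents)
        truth = geno.data.copy()
        masked = truth.copy()
        hide = rng.random(masked.shape) < 0.1
        hide[:3] = False  # keep parents complete
        masked = masked.mask(hide)
        out = gt.impute_from_parents(
            GenotypeMatrix(masked), parents.variants, popmap
        )
        rils = popmap.ril_lines
        got = out.data.loc[rils].to_numpy()
        want = truth.loc[rils].to_numpy()
        hidden = hide[3:] & (want != 1)  # het truth can never be recovered
        acc = (got[hidden] == want[hidden]).mean()
        assert acc >= 0.95


class TestFunctionalFilter:
    def test_cds_keeps_only_missense(self, sim):
        line_calls = gt.consensus_by_line(sim.observed, sim.expression.genotype)
        out = gt.functional_filter(line_calls, sim.variants, "CDS",
                                   drop_monomorphic=False)
        classes = sim.variants.loc[out.data.columns, "effect_class"]
        assert (classes == "missense_variant").all()
        assert (sim.variants["effect_class"] == "synonymous_variant").any()

    def test_reg_distance_bound(self):
        vt = pd.DataFrame(
            {
                "effect_class": ["upstream_gene_variant",
                                 "downstream_gene_variant",
                                 "upstream_gene_variant",
                                 "missense_variant"],
                "distance_bp": [4000, 5000, 6000, 0],
            },
            index=["v1", "v2", "v3", "v4"],
        )
        m = _matrix([[0, 0, 0, 0], [2, 2, 2, 2]], ["a", "b"],
                    ["v1", "v2", "v3", "v4"])
        out = gt.functional_filter(m, vt, "Reg")
        assert list(out.data.columns) == ["v1", "v2"]  # 6000 > 5000 excluded

    def test_unknown_class_rejected(self, sim):
        with pytest.raises(ValueError, match="unknown"):
            gt.functional_filter(
                GenotypeMatrix(sim.observed.iloc[:2, :2]), sim.variants, "UTR"
            )


class TestQualityFilter:
    def _setup(self):
        vt = pd.DataFrame(
            {"MAF": [0.01, 0.10, 0.40], "DP": [1.0, 2.0, 3.0],
             "QUAL": [10.0, 20.0, 30.0], "NS": [0, 3, 10]},
            index=["v1", "v2", "v3"],
        )
        m = _matrix([[0, 0, 0], [2, 2, 2]], ["a", "b"], ["v1", "v2", "v3"])
        return m, vt

    def test_strength_zero_keeps_everything(self):
        m, vt = self._setup()
        for crit in gt.QUALITY_CRITERIA:
            assert gt.quality_filter(m, vt, crit, 0.0).data.shape[1] == 3

    def test_maf_midpoint_threshold(self):
        m, vt = self._setup()
        out = gt.quality_filter(m, vt, "MAF", 0.5)
        # threshold 0.01 + 0.5*(0.40-0.01) = 0.205 -> only 0.40 survives
        assert list(out.data.columns) == ["v3"]

    def test_ns_filters_from_high_end_down(self):
        m, vt = self._setup()
        out = gt.quality_filter(m, vt, "NS", 1.0)
        assert list(out.data.columns) == ["v1"]  # threshold 0, keep NS <= 0

    def test_identical_values_warn(self):
        m, vt = self._setup()
        vt = vt.assign(DP=[2.0, 2.0, 2.0])
        with pytest.warns(UserWarning, match="identical"):
            gt.quality_filter(m, vt, "DP", 0.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(0, 100, allow_nan=False), min_size=2,
                        max_size=30),
        criterion=st.sampled_from(gt.QUALITY_CRITERIA),
    )
    def test_retained_count_monotone_in_strength(self, values, criterion):
        ids = [f"v{i}" for i in range(len(values))]
        vt = pd.DataFrame({c: values for c in gt.QUALITY_CRITERIA}, index=ids)
        m = _matrix([[0] * len(ids), [2] * len(ids)], ["a", "b"], ids)
        counts = [
            gt.quality_filter(m, vt, criterion, s).data.shape[1]
            for s in np.linspace(0, 1, 11)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCombineAndStandard:
    def test_intersection_examples(self):
        m = _matrix([[0] * 4, [2] * 4], ["a", "b"], list("wxyz"))
        out = gt.combine_filters(m, {"w", "x", "y"}, {"x", "y", "z"})
        assert set(out.data.columns) == {"x", "y"}
        same = gt.combine_filters(m, {"w", "x"}, {"w", "x"})
        assert set(same.data.columns) == {"w", "x"}

    def test_combination_is_subset_of_members(self, rng):
        ids = [f"v{i}" for i in range(50)]
        m = _matrix(rng.choice([0.0, 2.0], size=(4, 50)),
                    ["a", "b", "c", "d"], ids)
        a = set(rng.choice(ids, 30, replace=False))
        b = set(rng.choice(ids, 25, replace=False))
        out = set(gt.combine_filters(m, a, b).data.columns)
        assert out <= a and out <= b
        assert len(out) <= min(len(a), len(b))

    def test_empty_intersection_warns(self):
        m = _matrix([[0, 0], [2, 2]], ["a", "b"], ["v1", "v2"])
        with pytest.warns(UserWarning, match="empty"):
            out = gt.combine_filters(m, {"v1"}, {"v2"})
        assert out.data.shape[1] == 0

    def test_standard_filter_strict_boundaries(self):
        lines = [f"R{i}" for i in range(10)]
        data = pd.DataFrame(
            {
                "v_miss20": [NA, NA] + [0.0] * 4 + [2.0] * 4,  # missing 20%
                "v_maf05": [1.0] + [0.0] * 9,  # MAF exactly 0.05
                "v_good": [0.0] * 5 + [2.0] * 5,  # MAF 0.5, no missing
            },
            index=lines,
        )
        out = gt.standard_filter(GenotypeMatrix(data))
        assert list(out.data.columns) == ["v_good"]


class TestGst:
    def _pm(self, n_per_pop):
        lines = [f"A{i}" for i in range(n_per_pop)] + [
            f"B{i}" for i in range(n_per_pop)
        ]
        pops = {l: ("A" if l.startswith("A") else "B") for l in lines}
        return lines, PopulationMap(pops, {"A": ("P1", "P2"), "B": ("P2", "P3")})

    def test_fixed_difference_gives_one(self):
        lines, pm = self._pm(4)
        m = _matrix([[0.0]] * 4 + [[2.0]] * 4, lines, ["v"])
        per, multi = gt.gst(m, pm)
        assert per["v"] == pytest.approx(1.0)
        assert multi == pytest.approx(1.0)

    def test_equal_frequencies_give_zero(self):
        lines, pm = self._pm(4)
        m = _matrix([[0.0], [0.0], [2.0], [2.0]] * 2, lines, ["v"])
        per, multi = gt.gst(m, pm)
        assert per["v"] == pytest.approx(0.0)

    def test_hand_oracle_half_vs_fixed(self):
        # p1 = 0.5, p2 = 1.0: H_S = 0.25, H_T = 0.375, G_st = 1/3
        lines, pm = self._pm(4)
        m = _matrix([[0.0], [0.0], [2.0], [2.0]] + [[2.0]] * 4, lines, ["v"])
        per, multi = gt.gst(m, pm)
        assert per["v"] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_monomorphic_undefined_and_range(self, sim):
        line_calls = gt.consensus_by_line(sim.observed, sim.expression.genotype)
        cleaned = gt.median_impute(gt.clean_calls(line_calls, sim.popmap),
                                   sim.popmap)
        per, multi = gt.gst(cleaned, sim.popmap)
        vals = per.dropna()
        assert ((vals >= -1e-12) & (vals <= 1 + 1e-12)).all()
        assert 0 <= multi <= 1

    def test_single_population_rejected(self):
        m = _matrix([[0.0], [2.0]], ["A0", "A1"], ["v"])
        pm = PopulationMap({"A0": "A", "A1": "A"}, {"A": ("P1", "P2")})
        with pytest.raises(ValueError):
            gt.gst(m, pm)


def test_cleaning_chain_is_identity_on_error_free_calls():
    cfg = SimConfig(n_variants=600, n_transcripts=300, pop_sizes=(15, 15, 15),
                    genotyping_error_rate=0.0, missing_rate=0.0,
                    depth_per_count=5.0, array_size=50, seed=21)
    sim = simdata.simulate_study(cfg)
    line_calls = gt.consensus_by_line(sim.observed, sim.expression.genotype)
    cleaned = gt.clean_calls(line_calls, sim.popmap)
    imputed = gt.median_impute(cleaned, sim.popmap)
    truth = sim.genotypes.data[imputed.data.columns]
    # identity up to residual-heterozygous truth (masked by design) and
    # monomorphic-variant removal
    rils = sim.popmap.ril_lines
    got = imputed.data.loc[rils].to_numpy()
    want = truth.loc[rils].to_numpy()
    hom = want != 1
    assert (got[hom] == want[hom]).mean() > 0.999
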