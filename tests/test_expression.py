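"""Count filtering, normalization and differential-expression tests."""

import numpy as np
import pandas as pd
import pytest

import rilgp
from rilgp import simdata
from rilgp import expression as xpr
from rilgp.types import ExpressionMatrix


def _toy_expr(counts: dict, blocks=None, geno=None) -> ExpressionMatrix:
    df = pd.DataFrame(counts)
    df.index = [f"t{i}" for i in range(len(df))]
    samples = list(df.columns)
    blocks = blocks or {s: "b1" for s in samples}
    geno = geno or {s: s for s in samples}
    return ExpressionMatrix(df, pd.Series(blocks), pd.Series(geno))


class TestDetectionFilter:
    def test_two_percent_boundary_inclusive(self):
        counts = {f"s{i}": [1 if i < 2 else 0, 1, 0] for i in range(100)}
        expr = _toy_expr(counts)
        out = xpr.detection_filter(expr, 0.02)
        assert "t0" in out.counts.index  # nonzero in exactly 2 of 100
        assert "t2" not in out.counts.index  # all-zero dropped

    def test_below_boundary_dropped(self):
        counts = {f"s{i}": [1 if i < 1 else 0, 1] for i in range(100)}
        out = xpr.detection_filter(_toy_expr(counts), 0.02)
        assert "t0" not in out.counts.index  # 1% < 2%

    def test_commutes_with_sample_reordering(self, sim):
        a = xpr.detection_filter(sim.expression)
        rev = sim.expression.subset_samples(sim.expression.samples[::-1])
        b = xpr.detection_filter(rev)
        assert list(a.counts.index) == list(b.counts.index)


class TestCpm:
    def test_arithmetic_and_column_sums(self):
        expr = _toy_expr({"a": [4, 2_000_000 - 4]})
        expr.library_sizes = pd.Series({"a": 2e6})
        out = xpr.cpm(expr)
        assert out.loc["t0", "a"] == pytest.approx(2.0)
        assert out.sum(axis=0)["a"] == pytest.approx(1e6)

    def test_scale_invariance(self):
        a = _toy_expr({"a": [10, 30, 60]})
        b = _toy_expr({"a": [20, 60, 120]})
        pd.testing.assert_frame_equal(xpr.cpm(a), xpr.cpm(b))

    def test_zero_library_excluded_with_warning(self):
        expr = _toy_expr({"a": [1, 2], "b": [0, 0]})
        with pytest.warns(UserWarning, match="zero-library"):
            out = xpr.cpm(expr)
        assert list(out.columns) == ["a"]


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        expr = _toy_expr({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert (xpr.tmm_factors(expr) == 1.0).all()

    def test_library_scaling_absorbed(self):
        expr = _toy_expr(
            {"a": [10, 20, 30, 40, 500, 1000],
             "b": [20, 40, 60, 80, 1000, 2000]}
        )
        np.testing.assert_allclose(xpr.tmm_factors(expr).to_numpy(), 1.0,
                                   atol=1e-12)

    def test_matches_brute_force_oracle(self):
        # independent oracle: explicit M/A computation, rank trimming and
        # inverse-variance weighting on a crafted 8-transcript table
        counts = pd.DataFrame(
            {"a": [100, 200, 300, 50, 80, 1000, 10, 400],
             "b": [120, 180, 900, 55, 60, 1100, 30, 350]},
        )
        expr = _toy_expr({c: counts[c].tolist() for c in counts})
        got = xpr.tmm_factors(expr, reference="a")

        ya, yb = counts["a"].to_numpy(float), counts["b"].to_numpy(float)
        la, lb = ya.sum(), yb.sum()
        m = np.log2((yb / lb) / (ya / la))
        a = 0.5 * np.log2((yb / lb) * (ya / la))
        w = (lb - yb) / (lb * yb) + (la - ya) / (la * ya)
        n = len(m)
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        keep = (rm > n * 0.3) & (rm <= n * 0.7) & (ra > n * 0.05) & (ra <= n * 0.95)
        fb = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
        fa = 1.0
        gm = np.exp(np.mean(np.log([fa, fb])))
        np.testing.assert_allclose(
            got.to_numpy(), [fa / gm, fb / gm], rtol=1e-10
        )

    def test_geometric_mean_is_one(self, sim):
        f = xpr.tmm_factors(sim.expression)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            xpr.tmm_factors(_toy_expr({"a": [1, 2]}))


class TestEMM:
    def test_balanced_design_equals_raw_means(self, rng):
        # every genotype in every block: orthogonality
        samples, blocks, geno = [], {}, {}
        for b in range(3):
            for g in range(4):
                s = f"s{b}{g}"
                samples.append(s)
                blocks[s] = f"b{b}"
                geno[s] = f"g{g}"
        counts = pd.DataFrame(
            rng.integers(10, 1000, size=(5, len(samples))), columns=samples
        )
        counts.index = [f"t{i}" for i in range(5)]
        expr = ExpressionMatrix(counts, pd.Series(blocks), pd.Series(geno))
        resp = xpr.cpm(expr)
        adj = xpr.emm_adjust(expr, response=resp)
        raw = resp.T.groupby(pd.Series(geno)).mean().T
        np.testing.assert_allclose(
            adj.to_numpy(), raw[adj.columns].to_numpy(), atol=1e-6
        )

    def test_block_offset_leaves_contrasts_invariant(self, rng):
        # additive offset on one block must not move genotype differences
        samples = [f"s{i}" for i in range(12)]
        blocks = pd.Series({s: f"b{i % 3}" for i, s in enumerate(samples)})
        geno = pd.Series({s: f"g{i % 4}" for i, s in enumerate(samples)})
        base = rng.normal(100, 5, size=(3, 12))
        counts = pd.DataFrame(np.ones((3, 12)), columns=samples,
                              index=[f"t{i}" for i in range(3)])
        expr = ExpressionMatrix(counts, blocks, geno)
        resp = pd.DataFrame(base, columns=samples, index=counts.index)
        shifted = resp.copy()
        shifted.loc[:, blocks[blocks == "b1"].index] += 7.0
        a = xpr.emm_adjust(expr, response=resp)
        b = xpr.emm_adjust(expr, response=shifted)
        da = a.to_numpy() - a.to_numpy()[:, :1]
        db = b.to_numpy() - b.to_numpy()[:, :1]
        np.testing.assert_allclose(da, db, atol=1e-6)

    def test_single_block_falls_back_to_raw_means(self):
        expr = _toy_expr({"a": [10.0], "b": [30.0]},
                         geno={"a": "g1", "b": "g2"})
        with pytest.warns(UserWarning, match="fewer than 2 blocks"):
            adj = xpr.emm_adjust(expr)
        assert adj.shape == (1, 2)


class TestDEG:
    def test_all_zero_transcript_gets_p_one(self, sim):
        expr = sim.expression
        counts = expr.counts.copy()
        counts.iloc[0] = 0
        zeroed = ExpressionMatrix(counts, expr.blocks, expr.genotype)
        res = xpr.deg_lrt(zeroed)
        assert res.table["pvalue"].iloc[0] == 1.0
        assert not res.table["significant"].iloc[0]

    def test_statistic_nonnegative_and_fdr_above_p(self, sim):
        res = xpr.deg_lrt(xpr.detection_filter(sim.expression))
        assert (res.table["stat"] >= 0).all()
        assert (res.table["fdr"] >= res.table["pvalue"] - 1e-12).all()
        assert res.table["pvalue"].between(0, 1).all()

    def test_strong_shift_detected(self, sim):
        expr = xpr.detection_filter(sim.expression)
        counts = expr.counts.copy()
        # 10-fold genotype-specific shift on a well-expressed transcript
        t = counts.mean(axis=1).idxmax()
        pop = sim.popmap.populations[0]
        members = set(sim.popmap.lines_of(pop))
        cols = [s for s in expr.samples if expr.genotype[s] in members]
        counts.loc[t, cols] = counts.loc[t, cols] * 10
        res = xpr.deg_lrt(
            ExpressionMatrix(counts, expr.blocks, expr.genotype)
        )
        assert res.table.loc[t, "fdr"] < 1e-4

    def test_no_replicates_rejected(self):
        expr = _toy_expr({"a": [1, 2], "b": [3, 4]},
                         geno={"a": "g1", "b": "g2"})
        with pytest.raises(ValueError, match="replicated"):
            xpr.estimate_dispersion(expr)


class TestBH:
    def test_adjusted_values_match_explicit_step_up(self, rng):
        # independent oracle: the step-up recursion written out directly
        p = rng.uniform(size=200)
        n = p.size
        order = np.argsort(p)
        ranked = p[order] * n / np.arange(1, n + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        want = np.empty(n)
        want[order] = np.minimum(ranked, 1.0)
        np.testing.assert_allclose(xpr.bh_adjust(p), want, rtol=1e-12)


class TestThresholdScan:
    def test_threshold_in_grid_and_argmax_property(self, sim):
        expr = xpr.detection_filter(sim.expression)
        scan = xpr.cpm_threshold_scan(expr, n_candidates=10)
        assert scan.threshold in set(scan.counts.index)
        assert scan.counts[scan.threshold] >= scan.counts[0.0]
        assert scan.counts[scan.threshold] == scan.counts.max()

    def test_tie_breaks_to_smallest_threshold(self):
        # constant-count scan: every threshold ties, smallest wins
        rng = np.random.default_rng(0)
        counts = {f"s{i}": rng.integers(50, 150, size=20).tolist()
                  for i in range(12)}
        geno = {f"s{i}": ("p1" if i < 6 else f"g{i}") for i in range(12)}
        expr = _toy_expr(counts, geno=geno)
        scan = xpr.cpm_threshold_scan(expr, n_candidates=5)
        ties = scan.counts[scan.counts == scan.counts.max()]
        assert scan.threshold == ties.index.min()

    def test_empty_grid_rejected(self, sim):
        with pytest.raises(ValueError):
            xpr.cpm_threshold_scan(sim.expression, n_candidates=0)


def test_per_gene_aggregation_conserves_counts(sim):
    tr = list(sim.expression.counts.index)
    gene_of = pd.Series({t: f"g{int(i // 4)}" for i, t in enumerate(tr)})
    agg = xpr.aggregate_per_gene(sim.expression, gene_of)
    assert agg.counts.to_numpy().sum() == sim.expression.counts.to_numpy().sum()
    assert agg.counts.shape[0] == len(set(gene_of))
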