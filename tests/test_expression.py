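"""CPM filtering, differential expression, Venn, quadrants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tftri.config import SimConfig
from tftri.containers import CountMatrix
from tftri import expression as expr, simulate as sim


def _cm(counts, groups, pairs=None, lib=None):
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    df.index.name = "gene_id"
    return CountMatrix(
        df,
        pd.Series(groups),
        pd.Series(pairs) if pairs else None,
        pd.Series(lib) if lib else None,
    )


class TestCpmFilter:
    def test_three_of_six_rule(self):
        # cpm = 1.5 in exactly three samples -> kept; all-zero -> removed
        lib = {c: 1_000_000.0 for c in "abcdef"}
        counts = {c: [0, 0] for c in "abcdef"}
        for c in "abc":
            counts[c][0] = 2  # cpm 2 > 1 in 3 of 6
        cm = _cm(counts, {c: "A" for c in "abc"} | {c: "B" for c in "def"}, lib=lib)
        kept = expr.cpm_filter(cm)
        assert list(kept.gene_ids) == ["g0"]

    def test_strictly_greater_than_threshold(self):
        lib = {c: 1_000_000.0 for c in "abcdef"}
        counts = {c: [1] for c in "abcdef"}  # cpm exactly 1 everywhere
        cm = _cm(counts, {c: "A" for c in "abc"} | {c: "B" for c in "def"}, lib=lib)
        assert len(expr.cpm_filter(cm).gene_ids) == 0

    def test_zero_library_raises(self):
        cm = _cm({"a": [1], "b": [1]}, {"a": "A", "b": "B"}, lib={"a": 0.0, "b": 10.0})
        with pytest.raises(ValueError, match="library size"):
            expr.cpm_filter(cm)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 6), st.integers(1, 500))
    def test_monotone_adding_counts_never_drops_a_kept_gene(self, gene_row, extra):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 30, size=(7, 6))
        cols = list("abcdef")
        groups = {c: "A" for c in "abc"} | {c: "B" for c in "def"}
        lib = {c: 50_000.0 for c in cols}
        cm1 = _cm({c: base[:, j] for j, c in enumerate(cols)}, groups, lib=lib)
        bumped = base.copy()
        bumped[gene_row] += extra
        cm2 = _cm({c: bumped[:, j] for j, c in enumerate(cols)}, groups, lib=lib)
        kept1 = set(expr.cpm_filter(cm1).gene_ids)
        kept2 = set(expr.cpm_filter(cm2).gene_ids)
        if f"g{gene_row}" in kept1:
            assert f"g{gene_row}" in kept2


class TestDeTest:
    def test_identical_groups_null(self):
        counts = {c: [100, 50, 10] for c in "abcd"}
        cm = _cm(counts, {"a": "A", "b": "A", "c": "B", "d": "B"})
        de = expr.de_test(cm, "two_group", group_a="A", group_b="B")
        assert np.allclose(de["log2fc"], 0)
        assert not de["passes"].any()
        assert (de["direction"] == "none").all()

    def test_fold_change_threshold_prints_as_038(self):
        assert f"{np.log2(1.3):.2f}" == "0.38"

    def test_fc_boundary_inclusive(self):
        """A gene sitting exactly at |log2fc| = log2(1.3) passes the FC gate."""
        rng = np.random.default_rng(0)
        base = rng.integers(500, 1000, size=20)
        tau = np.log2(1.3)
        a = np.round(base * 1.3).astype(int)
        counts = {"a1": a, "a2": a, "b1": base, "b2": base}
        lib = {c: 10_000.0 for c in counts}
        cm = _cm(counts, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, lib=lib)
        de = expr.de_test(cm, "two_group", group_a="A", group_b="B",
                          center_log2fc=False, var_model="per_gene")
        near = de[np.abs(de["log2fc"]) >= tau]
        assert (near.loc[near["p"] < 0.05, "passes"]).all()

    def test_planted_four_fold_gene_detected(self):
        """A 4-fold gene at mean 200, dispersion 0.05, n = 3 vs 3 is called
        in >= 80% of seeded simulations."""
        hits = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(1000 + seed)
            size = 1 / 0.05
            null = rng.negative_binomial(size, size / (size + 200), size=(60, 6))
            gene = np.concatenate([
                rng.negative_binomial(size, size / (size + 800), size=3),
                rng.negative_binomial(size, size / (size + 200), size=3),
            ])
            counts = np.vstack([gene, null])
            cols = ["a1", "a2", "a3", "b1", "b2", "b3"]
            lib = {c: 60_000.0 for c in cols}
            cm = _cm({c: counts[:, j] for j, c in enumerate(cols)},
                     {c: ("A" if c.startswith("a") else "B") for c in cols}, lib=lib)
            de = expr.de_test(cm, "two_group", group_a="A", group_b="B", center_log2fc=False)
            hits += bool(de.loc[de["gene_id"] == "g0", "passes"].iloc[0])
        assert hits >= 0.8 * n_sims

    def test_paired_design_detects_knockdown(self):
        cfg = SimConfig(seed=7, n_genes=300, genome_size=3_000_000)
        ann = sim.simulate_annotation(cfg)
        _, kd, truth = sim.simulate_counts(cfg, ann)
        de = expr.de_test(kd, "paired", criterion="fdr")
        t = truth.set_index("gene_id").loc[de["gene_id"]]
        tgt = t["is_e2f1_target"].to_numpy()
        down = (de["direction"] == "down").to_numpy()
        assert (down & tgt).sum() >= 0.8 * tgt.sum()

    def test_null_p_values_uniform(self):
        """With no planted effect the pooled p distribution is ~uniform."""
        ps = []
        for seed in range(40):
            cfg = SimConfig(seed=500 + seed, n_genes=500, genome_size=5_000_000, frac_deg=0.0)
            ann = sim.simulate_annotation(cfg)
            basal, _, _ = sim.simulate_counts(cfg, ann)
            de = expr.de_test(expr.cpm_filter(basal), "two_group", group_a="A", group_b="B")
            ps.append(de["p"].to_numpy())
        ks = stats.kstest(np.concatenate(ps), "uniform").statistic
        assert ks < 0.1

    def test_degenerate_gene_p_one(self):
        counts = {"a1": [0, 5], "a2": [0, 7], "b1": [0, 4], "b2": [0, 9]}
        cm = _cm(counts, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        de = expr.de_test(cm, "two_group", group_a="A", group_b="B",
                          var_model="per_gene", center_log2fc=False)
        assert de.loc[de["gene_id"] == "g0", "p"].iloc[0] == 1.0


class TestVenn:
    def test_printed_sga_repression_figures(self):
        v = expr.venn_from_counts(846, 878, 540)
        assert v["n_exclusive_A"] == 306
        assert v["pct_exclusive_A"] == 36.2

    def test_common_recovered_from_exclusive(self):
        v = expr.venn_from_counts(880, 660, 388)
        assert v["n_exclusive_A"] == 492
        assert v["pct_exclusive_A"] == 55.9

    def test_disjoint_sets(self):
        v = expr.venn_summarize({"a", "b"}, {"c"})
        assert v["n_common"] == 0 and v["pct_exclusive_A"] == 100.0

    def test_empty_total_reports_not_available(self):
        assert expr.venn_summarize(set(), {"x"})["pct_exclusive_A"] is None

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 40)), st.sets(st.integers(0, 40)))
    def test_totals_conserved(self, a, b):
        v = expr.venn_summarize(a, b)
        assert v["n_total_A"] == v["n_common"] + v["n_exclusive_A"]
        assert v["n_total_B"] == v["n_common"] + v["n_exclusive_B"]


def _quad_tables(basal_rows, kd_rows):
    basal = pd.DataFrame(basal_rows, columns=["gene_id", "log2fc", "p", "fdr"])
    kd = pd.DataFrame(kd_rows, columns=["gene_id", "log2fc", "p", "fdr"])
    return basal, kd


class TestQuadrants:
    tau = np.log2(1.3)

    def test_up_down_assignment(self):
        basal, kd = _quad_tables([("g", 0.5, 0.01, 0.01)], [("g", -0.5, 0.01, 0.01)])
        q = expr.quadrant_classify(basal, kd)
        assert q["quadrant"].iloc[0] == "up-down"

    def test_below_cutoff_unassigned(self):
        basal, kd = _quad_tables([("g", 0.5, 0.01, 0.01)], [("g", 0.2, 0.01, 0.01)])
        assert expr.quadrant_classify(basal, kd)["quadrant"].iloc[0] == "unassigned"

    def test_boundary_inclusive(self):
        basal, kd = _quad_tables(
            [("g", self.tau, 0.01, 0.01)], [("g", self.tau, 0.01, 0.01)]
        )
        assert expr.quadrant_classify(basal, kd)["quadrant"].iloc[0] == "up-up"

    def test_missing_gene_unassigned(self):
        basal, kd = _quad_tables([("g", 1.0, 0.001, 0.001)], [("h", -1.0, 0.001, 0.001)])
        q = expr.quadrant_classify(basal, kd).set_index("gene_id")
        assert (q["quadrant"] == "unassigned").all()

    def test_insignificant_unassigned(self):
        basal, kd = _quad_tables([("g", 1.0, 0.2, 0.5)], [("g", -1.0, 0.001, 0.001)])
        assert expr.quadrant_classify(basal, kd)["quadrant"].iloc[0] == "unassigned"


class TestQuadrantEnrichment:
    def test_balanced_table_p_one(self):
        qt = pd.DataFrame(
            {
                "gene_id": list("abcd"),
                "basal_log2fc": [1, 1, -1, -1],
                "kd_log2fc": [1, -1, 1, -1],
                "basal_sig": True,
                "kd_sig": True,
                "quadrant": ["up-up", "up-down", "down-up", "down-down"],
            }
        )
        qe = expr.quadrant_enrichment(qt)
        assert np.allclose(qe["p"], 1.0)

    def test_concentrated_quadrant_significant(self, rng):
        """All assigned genes in one quadrant against a uniform background."""
        n = 400
        bfc = rng.normal(0, 1, n)
        kfc = rng.normal(0, 1, n)
        assigned = np.zeros(n, bool)
        sector = (bfc >= 0) & (kfc < 0)
        assigned[np.where(sector)[0][:40]] = True
        quad = np.where(assigned, "up-down", "unassigned")
        qt = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "basal_log2fc": bfc,
                "kd_log2fc": kfc,
                "basal_sig": assigned,
                "kd_sig": assigned,
                "quadrant": quad,
            }
        )
        qe = expr.quadrant_enrichment(qt).set_index("quadrant")
        assert qe.loc["up-down", "p"] < 1e-3

    def test_no_assigned_raises(self):
        qt = pd.DataFrame(
            {
                "gene_id": ["a"],
                "basal_log2fc": [0.1],
                "kd_log2fc": [0.1],
                "basal_sig": [False],
                "kd_sig": [False],
                "quadrant": ["unassigned"],
            }
        )
        with pytest.raises(ValueError):
            expr.quadrant_enrichment(qt)


class TestIntersect:
    def test_order_preserved(self):
        assert expr.intersect_gene_list(["c", "a", "b"], {"b", "c", "d"}) == ["c", "b"]

    def test_empty_reference(self):
        assert expr.intersect_gene_list(["a"], set()) == []

    def test_planted_mito_degs_recovered(self, small_bundle):
        truth = small_bundle.truth
        degs = truth.loc[truth["is_deg_up_groupA"] | truth["is_deg_down_groupA"], "gene_id"]
        mito = set(truth.loc[truth["is_mito"], "gene_id"])
        expected = [g for g in degs if g in mito]
        assert expr.intersect_gene_list(list(degs), mito) == expected
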