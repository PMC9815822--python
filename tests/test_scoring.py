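"""Unit and property tests for normalization, filtering, CS/dCS and ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import make_count_table
from dcscreen import (
    SgRNARecord,
    average_clone_cs,
    clone_concordance,
    dcs,
    gene_cs,
    initial_filter,
    log2fc,
    normalize,
    paired_filter,
    top_candidates,
)
from dcscreen.scoring import GeneScoreTable

ONE_BG = [("t0", "WT", "initial", 0.0), ("t1", "WT", "final", 14.0)]


def score_table(background, cs_map, n_sgrna=4):
    tab = pd.DataFrame(
        {"cs": list(cs_map.values()), "n_sgrna": n_sgrna},
        index=pd.Index(list(cs_map.keys()), name="gene"),
    )
    return GeneScoreTable(background, tab)


class TestNormalize:
    def test_all_zero_single_sample_becomes_pseudocount(self):
        t = make_count_table([[0], [0]], ["A", "A"], [("t0", "WT", "initial", 0.0)])
        norm = normalize(t, pseudocount=1)
        assert norm.values.to_numpy().tolist() == [[1.0], [1.0]]

    def test_forced_arithmetic_two_samples(self):
        # pseudocounted totals 30 and 60, target 45 -> scale by 1.5 and 0.75
        t = make_count_table([[9, 39], [19, 19]], ["A", "A"], ONE_BG)
        norm = normalize(t, pseudocount=1)
        assert norm.values["t0"].tolist() == [15.0, 30.0]
        assert norm.values["t1"].tolist() == [30.0, 15.0]

    def test_identical_columns_reduce_to_pseudocount_shift(self):
        t = make_count_table([[10, 10], [30, 30]], ["A", "A"], ONE_BG)
        norm = normalize(t, pseudocount=1)
        assert norm.values["t0"].tolist() == norm.values["t1"].tolist() == [11.0, 31.0]

    def test_zero_pseudocount_with_empty_column_rejected(self):
        t = make_count_table([[0, 5], [0, 5]], ["A", "A"], ONE_BG)
        with pytest.raises(ValueError, match="zero pseudocounted total"):
            normalize(t, pseudocount=0)

    @settings(max_examples=50, derandomize=True)
    @given(
        arrays(np.int64, (6, 3), elements=st.integers(min_value=0, max_value=10000))
    )
    def test_column_sums_equal_and_values_positive(self, mat):
        t = make_count_table(
            mat, ["A"] * 3 + ["B"] * 3,
            [("s1", "WT", "initial", 0.0), ("s2", "WT", "final", 14.0),
             ("s3", "KO", "initial", 0.0)],
        )
        norm = normalize(t, pseudocount=1)
        sums = norm.values.sum(axis=0).to_numpy()
        np.testing.assert_allclose(sums, sums[0], rtol=1e-9)
        assert (norm.values.to_numpy() > 0).all()
        assert sums[0] == pytest.approx((mat + 1).sum() / 3, rel=1e-12)


class TestInitialFilter:
    def test_read_floor_boundary(self):
        # 4 guides per gene; one gene has a guide at 49 reads, the other at 50
        genes = ["A"] * 4 + ["B"] * 4
        init = [49, 60, 60, 60, 50, 60, 60, 60]
        t = make_count_table([[c, c] for c in init], genes, ONE_BG)
        retained, per_gene = initial_filter(t, "t0")
        assert "sg001" not in retained          # 49 reads: below the floor
        assert "sg005" in retained              # exactly 50: retained
        assert per_gene == {"A": 3, "B": 4}
        # gene A dropped to 3 informative guides -> whole gene removed
        assert all(g not in retained for g in ("sg002", "sg003", "sg004"))

    def test_gene_floor_boundary(self):
        genes = ["A"] * 4 + ["B"] * 3
        t = make_count_table([[100, 100]] * 7, genes, ONE_BG)
        retained, _ = initial_filter(t, "t0")
        assert {g for g in retained} == {"sg001", "sg002", "sg003", "sg004"}

    def test_no_op_when_everything_passes(self):
        genes = ["A"] * 4 + ["B"] * 4
        t = make_count_table([[100, 1]] * 8, genes, ONE_BG)
        retained, _ = initial_filter(t, "t0")
        assert retained == {f"sg{i + 1:03d}" for i in range(8)}

    def test_filter_applies_to_raw_not_final_counts(self):
        # final counts are all tiny; only the initial sample matters
        genes = ["A"] * 4
        t = make_count_table([[100, 0]] * 4, genes, ONE_BG)
        retained, _ = initial_filter(t, "t0")
        assert len(retained) == 4

    def test_requires_initial_timepoint(self):
        t = make_count_table([[100, 100]] * 4, ["A"] * 4, ONE_BG)
        with pytest.raises(ValueError, match="not an initial"):
            initial_filter(t, "t1")
        with pytest.raises(KeyError):
            initial_filter(t, "nope")

    def test_monotonicity_in_both_thresholds(self):
        rng = np.random.default_rng(23)
        genes = [f"G{i // 5}" for i in range(60)]
        mat = rng.integers(0, 200, size=(60, 2))
        t = make_count_table(mat, genes, ONE_BG)
        gene_of = t.gene_of
        prev = None
        for min_reads in (0, 25, 50, 100, 200):
            retained, _ = initial_filter(t, "t0", min_reads=min_reads, min_sgrna=1)
            if prev is not None:
                assert retained <= prev
            prev = retained
        prev_genes = None
        for min_sgrna in (1, 2, 3, 4, 5):
            retained, _ = initial_filter(t, "t0", min_reads=30, min_sgrna=min_sgrna)
            n_genes = len({gene_of[g] for g in retained})
            if prev_genes is not None:
                assert n_genes <= prev_genes
            prev_genes = n_genes


class TestPairedFilter:
    @staticmethod
    def two_bg_tables(wt_init, ko_init, n_extra_pass=4):
        """One probe guide with given initial counts plus a padding gene."""
        genes = ["PROBE"] * 4 + ["PAD"] * n_extra_pass
        mk = lambda probe: make_count_table(
            [[probe, 10]] + [[100, 10]] * 3 + [[100, 10]] * n_extra_pass,
            genes,
            [("t0", "BG", "initial", 0.0), ("t1", "BG", "final", 14.0)],
        )
        wt, ko = mk(wt_init), mk(ko_init)
        return {"WT": wt, "KO": ko}, {"WT": "t0", "KO": "t0"}

    def test_all_threshold_combinations_against_brute_force(self):
        # brute-force oracle: retained iff >= 50 raw initial reads in EVERY bg
        for wt0 in (40, 60):
            for ko0 in (40, 60):
                tables, inits = self.two_bg_tables(wt0, ko0)
                retained = paired_filter(tables, inits, min_sgrna=3)
                expected = wt0 >= 50 and ko0 >= 50
                assert ("sg001" in retained) == expected, (wt0, ko0)

    def test_low_in_one_background_is_dropped(self):
        tables, inits = self.two_bg_tables(60, 40)
        assert "sg001" not in paired_filter(tables, inits, min_sgrna=3)

    def test_adequate_everywhere_is_retained(self):
        tables, inits = self.two_bg_tables(60, 60)
        assert "sg001" in paired_filter(tables, inits, min_sgrna=3)

    def test_degenerate_identical_tables_match_single_background_filter(self):
        rng = np.random.default_rng(11)
        genes = [f"G{i // 4}" for i in range(40)]
        mat = rng.integers(0, 150, size=(40, 2))
        t = make_count_table(mat, genes, ONE_BG)
        single, _ = initial_filter(t, "t0")
        paired = paired_filter({"WT": t, "KO": t}, {"WT": "t0", "KO": "t0"})
        assert paired == single

    def test_gene_floor_reapplied_after_pairing(self):
        # guide sg001 is low in WT only; pairing leaves gene A with 3 guides,
        # so the whole gene drops even though KO saw it adequately
        genes = ["A"] * 4 + ["PAD"] * 4
        samples = [("t0", "BG", "initial", 0.0), ("t1", "BG", "final", 14.0)]
        wt = make_count_table([[40, 1]] + [[100, 1]] * 7, genes, samples)
        ko = make_count_table([[100, 1]] * 8, genes, samples)
        retained = paired_filter({"WT": wt, "KO": ko}, {"WT": "t0", "KO": "t0"})
        assert retained == {"sg005", "sg006", "sg007", "sg008"}

    def test_disjoint_guide_sets_rejected(self):
        from dcscreen import CountTable, SampleMeta

        a = make_count_table([[100, 1]] * 4, ["A"] * 4, ONE_BG)
        guides = [SgRNARecord(f"zz{i}", "B") for i in range(4)]
        counts = pd.DataFrame(
            np.full((4, 2), 100, dtype=np.int64),
            index=pd.Index([g.sgrna_id for g in guides], name="sgrna_id"),
            columns=["t0", "t1"],
        )
        b = CountTable(guides, [SampleMeta(*s) for s in ONE_BG], counts)
        with pytest.raises(ValueError, match="disjoint"):
            paired_filter({"WT": a, "KO": b}, {"WT": "t0", "KO": "t0"})


class TestLog2FC:
    def test_definition(self):
        # equal column totals so depth factors cancel guide-by-guide
        t = make_count_table([[10, 10], [20, 40], [40, 20]], ["A"] * 3, ONE_BG)
        norm = normalize(t, pseudocount=0)
        fc = log2fc(norm, "t0", "t1")
        assert fc["sg001"] == pytest.approx(0.0)
        assert fc["sg002"] == pytest.approx(1.0)
        assert fc["sg003"] == pytest.approx(-1.0)

    def test_pseudocount_keeps_dropout_finite(self):
        # 99 reads dropping to 0 with pseudocount 1 and equal depth
        t = make_count_table([[99, 0], [0, 99]], ["A", "B"], ONE_BG)
        norm = normalize(t, pseudocount=1)
        fc = log2fc(norm, "t0", "t1")
        assert fc["sg001"] == pytest.approx(math.log2(1 / 100), abs=1e-12)
        assert np.isfinite(fc).all()

    def test_background_mismatch_rejected(self):
        t = make_count_table(
            [[10, 10]], ["A"],
            [("t0", "WT", "initial", 0.0), ("k1", "KO", "final", 14.0)],
        )
        norm = normalize(t)
        with pytest.raises(ValueError, match="different backgrounds"):
            log2fc(norm, "t0", "k1")

    def test_scale_invariance_of_one_sample(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(1, 500, size=(12, 2))
        genes = [f"G{i // 4}" for i in range(12)]
        t = make_count_table(mat, genes, ONE_BG)
        fc = log2fc(normalize(t, pseudocount=2), "t0", "t1")
        scaled = mat.copy()
        scaled[:, 1] *= 7
        t2 = make_count_table(scaled, genes, ONE_BG)
        # pseudocount scaled along with the sample keeps invariance exact
        pc = t2.counts.astype(float)
        pc["t0"] += 2
        pc["t1"] += 14
        totals = pc.sum(axis=0)
        values = pc * (totals.mean() / totals)
        fc2 = np.log2(values["t1"] / values["t0"])
        np.testing.assert_allclose(fc2, fc, atol=1e-12)


class TestGeneCS:
    lib = [SgRNARecord(f"A_sg{i}", "A") for i in range(1, 3)] + [
        SgRNARecord("B_sg1", "B")
    ]

    def test_mean_of_guides(self):
        fc = {"A_sg1": -1.0, "A_sg2": -3.0, "B_sg1": 0.7}
        table = gene_cs(fc, self.lib, set(fc), background="WT")
        assert table.table.loc["A", "cs"] == pytest.approx(-2.0)
        assert table.table.loc["A", "n_sgrna"] == 2
        assert table.table.loc["B", "cs"] == pytest.approx(0.7)
        assert table.table.loc["B", "n_sgrna"] == 1

    def test_unretained_genes_absent(self):
        fc = {"A_sg1": -1.0, "A_sg2": -3.0, "B_sg1": 0.7}
        table = gene_cs(fc, self.lib, {"A_sg1", "A_sg2"})
        assert "B" not in table.table.index

    def test_empty_retained_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gene_cs({"A_sg1": 0.0}, self.lib, set())

    def test_matches_loop_oracle_on_random_instance(self):
        rng = np.random.default_rng(99)
        lib = [SgRNARecord(f"G{i:02d}_sg{j}", f"G{i:02d}")
               for i in range(20) for j in range(4)]
        fc = pd.Series(rng.normal(size=80), index=[g.sgrna_id for g in lib])
        retained = set(rng.choice([g.sgrna_id for g in lib], size=60, replace=False))
        table = gene_cs(fc, lib, retained)
        for gene in table.table.index:
            vals = [fc[g.sgrna_id] for g in lib
                    if g.gene == gene and g.sgrna_id in retained]
            assert table.table.loc[gene, "cs"] == pytest.approx(
                sum(vals) / len(vals), abs=1e-12
            )
            assert table.table.loc[gene, "n_sgrna"] == len(vals)


class TestCloneAveraging:
    def test_mean_and_min_support(self):
        a = score_table("KO1", {"A": -1.0, "B": 0.5}, n_sgrna=4)
        b = score_table("KO2", {"A": -2.0, "B": 0.5}, n_sgrna=5)
        avg = average_clone_cs([a, b])
        assert avg.table.loc["A", "cs"] == pytest.approx(-1.5)
        assert avg.table.loc["A", "n_sgrna"] == 4

    def test_idempotent_on_identical_clones(self):
        a = score_table("KO1", {"A": -1.0, "B": 0.5})
        avg = average_clone_cs([a, a])
        pd.testing.assert_series_equal(
            avg.table["cs"], a.table["cs"], check_names=False
        )

    def test_gene_missing_from_one_clone_excluded(self):
        a = score_table("KO1", {"A": -1.0, "B": 0.5})
        b = score_table("KO2", {"A": -2.0})
        avg = average_clone_cs([a, b])
        assert list(avg.table.index) == ["A"]

    def test_disjoint_gene_sets_rejected(self):
        a = score_table("KO1", {"A": -1.0})
        b = score_table("KO2", {"B": -2.0})
        with pytest.raises(ValueError, match="shared"):
            average_clone_cs([a, b])


class TestDCS:
    def test_printed_formula_orientation(self):
        test = score_table("EV", {"MARCH5": -2.0})
        ref = score_table("ATAD1plus", {"MARCH5": -0.5})
        d = dcs(test, ref)
        assert d.table.loc["MARCH5", "dcs"] == pytest.approx(-1.5)

    def test_self_comparison_is_zero(self):
        t = score_table("X", {"A": -1.0, "B": 2.0})
        d = dcs(t, t)
        assert (d.table["dcs"] == 0).all()

    @settings(max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-10, 10, allow_nan=False),
                st.floats(-10, 10, allow_nan=False),
            ),
            min_size=1, max_size=30,
        )
    )
    def test_antisymmetry(self, pairs):
        genes = {f"G{i}": p for i, p in enumerate(pairs)}
        a = score_table("A", {g: p[0] for g, p in genes.items()})
        b = score_table("B", {g: p[1] for g, p in genes.items()})
        forward = dcs(a, b).table["dcs"]
        backward = dcs(b, a).table["dcs"]
        assert (forward == -backward).all()

    def test_rank_one_is_most_negative(self):
        d = dcs(score_table("T", {"A": -3.0, "B": -1.0, "C": 0.0}),
                score_table("R", {"A": 0.0, "B": 0.0, "C": 0.0}))
        assert d.table.loc["A", "rank"] == 1
        assert sorted(d.table["rank"]) == [1, 2, 3]


class TestTopCandidates:
    def make(self, cs_map):
        return dcs(score_table("T", cs_map),
                   score_table("R", {g: 0.0 for g in cs_map}))

    def test_smallest_k_ascending(self):
        d = self.make({"A": -3.0, "B": -1.0, "C": 0.0})
        assert top_candidates(d, 2) == ["A", "B"]

    def test_tie_broken_lexicographically(self):
        d = self.make({"B": -1.0, "A": -1.0})
        assert top_candidates(d, 1) == ["A"]

    def test_k_too_large_rejected(self):
        d = self.make({"A": -1.0})
        with pytest.raises(ValueError, match="exceeds"):
            top_candidates(d, 2)


class TestCloneConcordance:
    def make_pair(self, x, y):
        genes = [f"G{i}" for i in range(len(x))]
        a = dcs(score_table("A", dict(zip(genes, x))),
                score_table("R", {g: 0.0 for g in genes}))
        b = dcs(score_table("B", dict(zip(genes, y))),
                score_table("R", {g: 0.0 for g in genes}))
        return a, b

    def test_self_correlation_is_one(self):
        x = [1.0, -2.0, 0.5, 3.0]
        a, b = self.make_pair(x, x)
        r, p, n = clone_concordance(a, b)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_negation_gives_minus_one(self):
        x = [1.0, -2.0, 0.5, 3.0]
        a, b = self.make_pair(x, [-v for v in x])
        r, _, _ = clone_concordance(a, b)
        assert r == pytest.approx(-1.0)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(size=50)
        a, b = self.make_pair(list(x), list(y))
        r, p, n = clone_concordance(a, b)
        # closed-form Pearson r and two-sided t-test with n-2 df
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        t_stat = r_oracle * math.sqrt((n - 2) / (1 - r_oracle**2))
        from scipy.stats import t as tdist
        p_oracle = 2 * tdist.sf(abs(t_stat), n - 2)
        assert r == pytest.approx(r_oracle, abs=1e-10)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_insufficient_overlap_rejected(self):
        a, b = self.make_pair([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match=">= 3"):
            clone_concordance(a, b)

    def test_zero_variance_rejected(self):
        a, b = self.make_pair([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero variance"):
            clone_concordance(a, b)
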