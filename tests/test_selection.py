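"""Candidate selection: range rule oracle, strategy gates, merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from granulosig.config import AnalysisConfig
from granulosig.dge import fit_dge
from granulosig.io import ExpressionMatrix, GeneSet, GeneSetCollection
from granulosig.selection import (
    merge_selection,
    range_percentile_rule,
    select_strategy1,
    select_strategy2,
    select_strategy3,
    strategy1_pool,
)
from granulosig.simulate import study_config, simulate_cohort


def range_rule_oracle(high, low):
    """Independent recomputation: quantiles + comparisons from scratch."""
    q75_low = float(np.percentile(low, 75))
    q25_high = float(np.percentile(high, 25))
    return (min(high) > q75_low) and (max(low) < q25_high)


class TestRangePercentileRule:
    def test_separated_ranges_pass(self):
        # Q75(low)=2.5 < min(high)=10; Q25(high)=10.5 > max(low)=3
        assert range_percentile_rule([10, 11, 12], [1, 2, 3]) is True

    def test_interleaved_ranges_fail(self):
        # min(high)=2 <= Q75(low)=6
        assert range_percentile_rule([2, 5, 9], [1, 4, 8]) is False

    def test_identical_vectors_fail(self):
        v = [3.0, 4.0, 5.0]
        assert range_percentile_rule(v, v) is False

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            range_percentile_rule([1, 2], [1, 2, 3])

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            n1, n2 = rng.integers(3, 12, size=2)
            shift = rng.uniform(0, 3)
            high = rng.normal(shift, 1, n1)
            low = rng.normal(0, 1, n2)
            if high.mean() < low.mean():
                high, low = low, high
            assert range_percentile_rule(high, low) == range_rule_oracle(high, low)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=10),
        st.lists(st.floats(-50, 50), min_size=3, max_size=10),
    )
    def test_oracle_agreement_property(self, a, b):
        high, low = (a, b) if np.mean(a) >= np.mean(b) else (b, a)
        assert range_percentile_rule(high, low) == range_rule_oracle(high, low)


def dge_table_from_means(means):
    """Minimal DGE table for gate tests: rows of (sepsis, SIRS, presurgical)
    linear means, all flagged DEG."""
    rows = []
    for i, (sep, sirs, pre) in enumerate(means):
        def fold(a, b):
            r = a / b
            return max(r, 1 / r)

        rows.append(
            {
                "gene_id": f"G{i}",
                "mean_sepsis": sep,
                "mean_SIRS": sirs,
                "mean_presurgical": pre,
                "sepsis_vs_SIRS_fold": fold(sep, sirs),
                "SIRS_vs_presurgical_fold": fold(sirs, pre),
                "sepsis_vs_presurgical_fold": fold(sep, pre),
                "sepsis_vs_SIRS_deg": True,
                "SIRS_vs_presurgical_deg": True,
                "sepsis_vs_presurgical_deg": True,
                "sepsis_vs_SIRS_q": 0.01,
                "sepsis_vs_SIRS_p": 0.001,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


class TestStrategy2:
    def test_large_sepsis_fold_with_flat_sirs_selected(self):
        table = dge_table_from_means([(10, 4, 3.8)])  # 2.5x and 1.053x
        assert select_strategy2(table) == ["G0"]

    def test_both_gates_fail(self):
        table = dge_table_from_means([(10, 6, 3.8)])  # 1.67x and 1.58x
        assert select_strategy2(table) == []

    def test_flat_gene_rejected(self):
        table = dge_table_from_means([(5, 5, 5)])
        assert select_strategy2(table) == []

    def test_invariant_to_global_rescaling(self, study_cohort):
        _, cohort = study_cohort
        table = fit_dge(cohort.expr, cohort.samples)
        scaled = ExpressionMatrix(cohort.expr.data * 37.0)
        table_scaled = fit_dge(scaled, cohort.samples)
        assert select_strategy2(table) == select_strategy2(table_scaled)


class TestStrategy1:
    def test_no_degs_empty_selection(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.lognormal(4, 0.1, (20, 9)),
            index=[f"G{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(9)],
        )
        expr = ExpressionMatrix(df)
        samples = pd.Series(
            ["presurgical"] * 3 + ["SIRS"] * 3 + ["sepsis"] * 3,
            index=df.columns,
        )
        table = fit_dge(expr, samples)
        assert not table["sepsis_vs_SIRS_deg"].any()
        assert select_strategy1(table, expr, samples) == []

    def test_exclusion_drops_without_promotion(self, study_cohort):
        cfg, cohort = study_cohort
        table = fit_dge(cohort.expr, cohort.samples)
        base_cfg = AnalysisConfig()
        base = select_strategy1(table, cohort.expr, cohort.samples, base_cfg)
        assert len(base) >= base_cfg.strategy1_top_k
        dropped = base[base_cfg.strategy1_top_k - 1]  # the rank-50 gene
        excl_cfg = AnalysisConfig(exclusion_list=(dropped,))
        trimmed = select_strategy1(table, cohort.expr, cohort.samples, excl_cfg)
        # the excluded gene vanishes and no new gene is promoted into top-k
        top_base = set(base[: base_cfg.strategy1_top_k])
        top_trim = [g for g in trimmed if g in top_base]
        assert dropped not in trimmed
        assert set(top_trim) == top_base - {dropped}
        assert len(top_trim) == base_cfg.strategy1_top_k - 1

    def test_matches_brute_force_oracle(self, study_cohort):
        """Independently coded re-implementation of the full rule chain."""
        cfg, cohort = study_cohort
        table = fit_dge(cohort.expr, cohort.samples)
        acfg = AnalysisConfig()
        got = select_strategy1(table, cohort.expr, cohort.samples, acfg)
        assert got == strategy1_oracle(table, cohort.expr, cohort.samples, acfg)


def strategy1_oracle(table, expr, samples, acfg):
    degs = table[table["sepsis_vs_SIRS_deg"]]
    by_sep = degs["mean_sepsis"].sort_values(ascending=False, kind="mergesort")
    by_sirs = degs["mean_SIRS"].sort_values(ascending=False, kind="mergesort")
    pool = set(by_sep.index[: acfg.strategy1_pool_size]) | set(
        by_sirs.index[: acfg.strategy1_pool_size]
    )
    ranked = sorted(
        pool,
        key=lambda g: (
            table.loc[g, "sepsis_vs_SIRS_q"],
            table.loc[g, "sepsis_vs_SIRS_p"],
            g,
        ),
    )
    chosen = [
        g for g in ranked[: acfg.strategy1_top_k] if g not in acfg.exclusion_list
    ]
    sep_ids = samples.index[samples == "sepsis"]
    sirs_ids = samples.index[samples == "SIRS"]
    for g in ranked:
        if g in chosen or g in acfg.exclusion_list:
            continue
        a = expr.data.loc[g, sep_ids].to_numpy()
        b = expr.data.loc[g, sirs_ids].to_numpy()
        high, low = (a, b) if a.mean() >= b.mean() else (b, a)
        if min(high) > np.percentile(low, 75) and max(low) < np.percentile(high, 25):
            chosen.append(g)
    return chosen


class TestStrategy3:
    def test_pool_intersection(self):
        lys = GeneSetCollection()
        lys.add(GeneSet("lysosome", "hLGDB", frozenset(["G1", "G3"])))
        selected, new = select_strategy3(
            ["G0", "G1", "G2", "G3", "G4"], lys, already_selected=[]
        )
        assert selected == ["G1", "G3"]
        assert new == ["G1", "G3"]

    def test_all_already_selected_yields_no_new(self):
        lys = GeneSetCollection()
        lys.add(GeneSet("lysosome", "hLGDB", frozenset(["G1"])))
        selected, new = select_strategy3(["G1"], lys, already_selected=["G1"])
        assert selected == ["G1"] and new == []

    def test_shortlist_split_14_overlap_10_adds_4(self):
        pool = [f"P{i}" for i in range(100)]
        lysosomal = pool[:14]
        already = pool[:10] + [f"X{i}" for i in range(40)]
        lys = GeneSetCollection()
        lys.add(GeneSet("lysosome", "hLGDB", frozenset(lysosomal)))
        selected, new = select_strategy3(pool, lys, already)
        assert len(selected) == 14
        assert len(new) == 4


class TestMergeSelection:
    def test_disjoint_lists(self):
        sel = merge_selection(["a", "b"], ["c", "d", "e"], ["f", "g", "h", "i"])
        assert len(sel.union) == 9

    def test_identical_lists(self):
        sel = merge_selection(["a", "b"], ["a", "b"], ["a", "b"])
        assert sel.union == ["a", "b"]
        assert sel.table.all().all()

    def test_strategy_sizes_reproduce_shortlist_arithmetic(self):
        # 55 + 54 with 9 shared, strategy 3 adding 4 new -> 104 selected
        s1 = [f"A{i}" for i in range(55)]
        s2 = s1[:9] + [f"B{i}" for i in range(45)]
        s3 = s1[:5] + s2[9:14] + [f"C{i}" for i in range(4)]
        sel = merge_selection(s1, s2, s3)
        assert len(sel.union) == 104
        assert sel.genes_by_strategy(1) == s1


def test_selection_is_deterministic(study_cohort):
    cfg, cohort = study_cohort
    table = fit_dge(cohort.expr, cohort.samples)
    acfg = AnalysisConfig()
    first = select_strategy1(table, cohort.expr, cohort.samples, acfg)
    second = select_strategy1(table, cohort.expr, cohort.samples, acfg)
    assert first == second
    assert select_strategy2(table, acfg) == select_strategy2(table, acfg)


def test_strategy1_pool_is_union_of_two_top_lists(study_cohort):
    cfg, cohort = study_cohort
    table = fit_dge(cohort.expr, cohort.samples)
    acfg = AnalysisConfig()
    pool = strategy1_pool(table, acfg)
    degs = table[table["sepsis_vs_SIRS_deg"]]
    top_sep = set(
        degs.sort_values("mean_sepsis", ascending=False, kind="mergesort")
        .head(acfg.strategy1_pool_size)
        .index
    )
    top_sirs = set(
        degs.sort_values("mean_SIRS", ascending=False, kind="mergesort")
        .head(acfg.strategy1_pool_size)
        .index
    )
    assert set(pool) == top_sep | top_sirs
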