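"""Differential expression: ANOVA/contrast behaviour, BH properties, Venn."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from granulosig.config import AnalysisConfig
from granulosig.dge import (
    CONTRAST_NAMES,
    deg_summary,
    fit_dge,
    venn_partition,
)
from granulosig.io import ExpressionMatrix
from granulosig.simulate import study_config, simulate_cohort


def bh_oracle(p):
    """Hand-coded Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def make_expr(log2_values, sample_prefix="s"):
    arr = np.atleast_2d(np.asarray(log2_values, dtype=float))
    df = pd.DataFrame(
        2.0**arr,
        index=[f"G{i}" for i in range(arr.shape[0])],
        columns=[f"{sample_prefix}{j}" for j in range(arr.shape[1])],
    )
    return ExpressionMatrix(df)


def make_samples(n_pre, n_sirs, n_sep, sample_prefix="s"):
    labels = ["presurgical"] * n_pre + ["SIRS"] * n_sirs + ["sepsis"] * n_sep
    return pd.Series(
        labels,
        index=[f"{sample_prefix}{j}" for j in range(len(labels))],
        name="group",
    )


class TestFitDge:
    def test_constant_gene_has_p_one_and_unit_fold(self):
        expr = make_expr([[3.0] * 12])
        samples = make_samples(4, 4, 4)
        table = fit_dge(expr, samples)
        row = table.iloc[0]
        assert row["F_p"] == 1.0
        for c in CONTRAST_NAMES:
            assert row[f"{c}_fold"] == 1.0
            assert row[f"{c}_p"] == 1.0
            assert not row[f"{c}_deg"]

    def test_group_with_too_few_samples_rejected(self):
        expr = make_expr([[1.0] * 5])
        samples = make_samples(1, 2, 2)
        with pytest.raises(Exception, match="presurgical"):
            fit_dge(expr, samples)

    def test_sepsis_shift_detected_and_verified_by_permutation_oracle(self):
        # log2 group means (0, 0, delta) with delta=2, sigma=0.5, n=4 each:
        # both sepsis contrasts significant, SIRS vs presurgical not.
        rng = np.random.default_rng(11)
        delta = 2.0
        x = np.concatenate(
            [rng.normal(0, 0.5, 4), rng.normal(0, 0.5, 4), rng.normal(delta, 0.5, 4)]
        )
        expr = make_expr([x])
        samples = make_samples(4, 4, 4)
        table = fit_dge(expr, samples)
        row = table.iloc[0]
        assert row["sepsis_vs_SIRS_p"] < 0.01
        assert row["sepsis_vs_presurgical_p"] < 0.01
        assert row["SIRS_vs_presurgical_p"] > 0.05

        # permutation oracle on the pooled-t statistic for each contrast
        groups = {"presurgical": x[:4], "SIRS": x[4:8], "sepsis": x[8:]}
        rng = np.random.default_rng(5)
        for (g1, g2), name in zip(
            [("sepsis", "presurgical"), ("SIRS", "presurgical"), ("sepsis", "SIRS")],
            ["sepsis_vs_presurgical", "SIRS_vs_presurgical", "sepsis_vs_SIRS"],
        ):
            pooled = np.concatenate([groups[g1], groups[g2]])
            t_obs = abs(sps.ttest_ind(groups[g1], groups[g2]).statistic)
            n_perm = 20000
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                t = abs(sps.ttest_ind(perm[:4], perm[4:]).statistic)
                count += t >= t_obs - 1e-12
            p_perm = count / n_perm
            # permutation p and t p agree within Monte-Carlo error plus the
            # small-sample normality gap
            assert table.iloc[0][f"{name}_p"] == pytest.approx(p_perm, abs=0.03)

    def test_two_group_anova_equals_pooled_t_squared(self):
        # with two of three groups sharing identical values the three-group
        # ANOVA degenerates; check the algebraic F = t^2 identity on a
        # clean two-group fit instead, via the contrast machinery
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 8)
        t, p_t = sps.ttest_ind(x[:4], x[4:])
        f, p_f = sps.f_oneway(x[:4], x[4:])
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)
        # and our contrast p equals the scipy pooled t p within the pipeline
        expr = make_expr([np.concatenate([x[:4], x[:4], x[4:]])])
        samples = make_samples(4, 4, 4)
        table = fit_dge(expr, samples)
        t_sp, p_sp = sps.ttest_ind(x[:4], x[4:])
        assert table.iloc[0]["sepsis_vs_SIRS_p"] == pytest.approx(p_sp)

    def test_fold_change_is_linear_mean_ratio_with_direction(self):
        expr = ExpressionMatrix(
            pd.DataFrame(
                [[4.0, 4.0, 4.0, 4.0, 10.0, 10.0]],
                index=["G0"],
                columns=[f"s{j}" for j in range(6)],
            )
        )
        samples = make_samples(2, 2, 2)
        table = fit_dge(expr, samples)
        row = table.iloc[0]
        assert row["sepsis_vs_SIRS_fold"] == pytest.approx(2.5)
        assert row["sepsis_vs_SIRS_direction"] == 1
        assert row["SIRS_vs_presurgical_fold"] == pytest.approx(1.0)


class TestBenjaminiHochberg:
    def test_q_matches_hand_step_up_example(self):
        assert bh_oracle([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_pipeline_q_matches_oracle_and_dominates_p(self):
        rng = np.random.default_rng(0)
        expr = make_expr(rng.normal(5, 1, size=(40, 12)))
        samples = make_samples(4, 4, 4)
        table = fit_dge(expr, samples)
        for c in CONTRAST_NAMES:
            p = table[f"{c}_p"].to_numpy()
            q = table[f"{c}_q"].to_numpy()
            assert np.all(q >= p - 1e-12)
            assert q == pytest.approx(bh_oracle(p))

    def test_gene_order_does_not_change_q(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.normal(5, 1, size=(30, 12)))
        samples = make_samples(4, 4, 4)
        t1 = fit_dge(expr, samples)
        shuffled = ExpressionMatrix(expr.data.sample(frac=1, random_state=4))
        t2 = fit_dge(shuffled, samples)
        for c in CONTRAST_NAMES:
            pd.testing.assert_series_equal(
                t1[f"{c}_q"].sort_index(), t2[f"{c}_q"].sort_index()
            )


class TestVennPartition:
    def test_exclusive_region_assignment(self):
        rng = np.random.default_rng(2)
        expr = make_expr(
            np.vstack(
                [
                    np.concatenate([rng.normal(0, 0.2, 8), rng.normal(4, 0.2, 4)]),
                    rng.normal(0, 0.2, 12),
                ]
            )
        )
        samples = make_samples(4, 4, 4)
        table = fit_dge(expr, samples)
        part = venn_partition(table)
        # G0 differs only in sepsis: DEG in both sepsis contrasts
        assert "G0" in part.region("sepsis_vs_SIRS", "sepsis_vs_presurgical")
        # regions are disjoint and cover all DEGs
        all_genes = [g for genes in part.regions.values() for g in genes]
        assert len(all_genes) == len(set(all_genes))
        n_any = int(
            (table[[f"{c}_deg" for c in CONTRAST_NAMES]].any(axis=1)).sum()
        )
        assert part.n_deg == n_any

    def test_no_degs_all_regions_empty(self):
        # identical group profiles: every contrast is exactly null
        rng = np.random.default_rng(3)
        block = rng.normal(0, 1, size=(20, 4))
        expr = make_expr(np.hstack([block, block, block]))
        samples = make_samples(4, 4, 4)
        part = venn_partition(fit_dge(expr, samples))
        assert part.n_deg == 0

    def test_planted_sepsis_effects_land_in_both_sepsis_regions(self):
        cfg = study_config(n_genes=1500, n_planted=30, seed=5)
        cohort = simulate_cohort(cfg)
        table = fit_dge(cohort.expr, cohort.samples)
        part = venn_partition(table)
        planted = [g for g, _, _ in cfg.planted_genes]
        both = set(
            part.region("sepsis_vs_SIRS", "sepsis_vs_presurgical")
            + part.region(
                "sepsis_vs_SIRS", "sepsis_vs_presurgical", "SIRS_vs_presurgical"
            )
        )
        hits = sum(g in both for g in planted)
        assert hits >= 0.8 * len(planted)
        # sepsis-only effects without SIRS change should concentrate in the
        # region lacking SIRS-vs-presurgical membership
        sepsis_only = part.region("sepsis_vs_SIRS", "sepsis_vs_presurgical")
        assert sum(g in sepsis_only for g in planted) >= 0.5 * len(planted)


def test_null_cohort_controls_fdr():
    """With equal compositions and 10% planted genes, the realized FDR of
    the sepsis-vs-SIRS contrast stays near its nominal level."""
    false, discoveries = 0, 0
    for seed in range(20):
        from granulosig.simulate import CohortConfig

        n_genes = 300
        planted = [(f"HK{i + 1:05d}", "sepsis", 4.0) for i in range(30)]
        cfg = CohortConfig(
            n_genes=n_genes,
            n_per_group={"presurgical": 8, "SIRS": 10, "sepsis": 10},
            sigma_tech=0.3,
            planted_genes=planted,
            seed=seed,
        )
        cohort = simulate_cohort(cfg)
        table = fit_dge(cohort.expr, cohort.samples)
        hits = set(table.index[table["sepsis_vs_SIRS_deg"]])
        truth = {g for g, _, _ in planted}
        discoveries += len(hits)
        false += len(hits - truth)
    assert discoveries > 0
    assert false / discoveries <= 0.10


def test_deg_summary_percentages_consistent(study_cohort):
    _, cohort = study_cohort
    table = fit_dge(cohort.expr, cohort.samples)
    s = deg_summary(table)
    assert 0 < s["deg_fraction_pct"] < 100
    part = venn_partition(table)
    assert s["n_deg"] == part.n_deg
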