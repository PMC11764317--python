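import numpy as np
import pandas as pd
import pytest
from scipy import stats

from delscape.errors import ModelError
from delscape.model import (
    bonferroni_adjust,
    build_design,
    estimate_stratum_fc,
    fit_geneset_anova,
    interaction_test,
    run_pathway_screen,
    signed_fold_change,
)
from delscape.simulate import simulate_model_table


def single_gene_table(rng, n_tumor=8, n_healthy=6, shift=1.0):
    rows = []
    for i in range(n_tumor):
        rows.append(
            dict(sample_id=f"T{i}", patient_id=f"T{i}", gene="G1",
                 y=shift + rng.normal(), tissue=1, mut=0)
        )
    for i in range(n_healthy):
        rows.append(
            dict(sample_id=f"H{i}", patient_id=f"H{i}", gene="G1",
                 y=rng.normal(), tissue=0, mut=0)
        )
    return pd.DataFrame(rows)


class TestSignedFoldChange:
    @pytest.mark.parametrize("d,fc", [(1.0, 2.0), (0.0, 1.0), (-1.0, -2.0)])
    def test_convention(self, d, fc):
        assert signed_fold_change(d) == pytest.approx(fc)

    def test_involution_symmetry(self):
        for d in np.linspace(-5, 5, 41):
            assert signed_fold_change(d) == pytest.approx(-signed_fold_change(-d)) or d == 0


class TestBonferroni:
    def test_examples(self):
        assert bonferroni_adjust([0.001] * 50)[0] == pytest.approx(0.05)
        assert bonferroni_adjust([0.1, 0.5]) == [pytest.approx(0.2), 1.0]

    def test_rank_preserving(self):
        ps = [0.3, 0.01, 0.2, 0.005]
        adj = bonferroni_adjust(ps)
        assert np.argsort(adj).tolist() == np.argsort(ps).tolist()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5])


class TestDesign:
    def test_columns_for_two_genes(self):
        rng = np.random.default_rng(0)
        table = simulate_model_table({(0, 0): 1.0, (1, 0): 2.0, (0, 1): 0.5, (1, 1): 1.5},
                                     3, 2, 2, 1.0, rng)
        X, y, ref = build_design(table, include_exposure=True)
        assert ref == "G001"
        assert list(X.columns) == [
            "const", "tissue", "gene[G002]", "tissue:gene[G002]",
            "tissue:mut", "tissue:as_high", "tissue:mut:as_high",
        ]

    def test_single_gene_aliased_columns_dropped(self):
        rng = np.random.default_rng(1)
        fit = fit_geneset_anova(single_gene_table(rng))
        assert "tissue:mut" in fit.dropped_columns  # mut constant at 0
        assert set(fit.columns) == {"const", "tissue"}

    def test_single_tissue_class_rejected(self):
        rng = np.random.default_rng(2)
        table = single_gene_table(rng, n_healthy=0)
        table = table[table.tissue == 1]
        with pytest.raises(ModelError):
            fit_geneset_anova(table)

    def test_empty_stratum_named(self):
        rng = np.random.default_rng(3)
        table = simulate_model_table({(0, 0): 1.0, (1, 0): 2.0, (0, 1): 0.5, (1, 1): 1.5},
                                     3, 2, 2, 1.0, rng)
        table = table[~((table.mut == 1) & (table.as_high == 1) & (table.tissue == 1))]
        with pytest.raises(ModelError, match="mut=1"):
            fit_geneset_anova(table, include_exposure=True)


class TestSingleGeneEquivalence:
    def test_t_contrast_equals_pooled_two_sample_t(self):
        """With one gene and no carrier term, the tissue contrast reproduces
        the pooled-variance two-sample t-test exactly."""
        rng = np.random.default_rng(42)
        table = single_gene_table(rng, n_tumor=9, n_healthy=7, shift=0.8)
        fit = fit_geneset_anova(table)
        fc = estimate_stratum_fc(fit, mut=0)
        tumor = table.loc[table.tissue == 1, "y"]
        healthy = table.loc[table.tissue == 0, "y"]
        t_stat, p_ref = stats.ttest_ind(tumor, healthy, equal_var=True)
        assert fc.log2_fc / fc.se == pytest.approx(t_stat, rel=1e-10)
        f_ratio, p = interaction_test(fit, "tissue")
        assert f_ratio == pytest.approx(t_stat**2, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)

    def test_duplicated_rows_same_estimates(self):
        rng = np.random.default_rng(5)
        table = single_gene_table(rng)
        fit1 = fit_geneset_anova(table)
        fit2 = fit_geneset_anova(pd.concat([table, table], ignore_index=True))
        d1 = estimate_stratum_fc(fit1, mut=0).log2_fc
        d2 = estimate_stratum_fc(fit2, mut=0).log2_fc
        assert d1 == pytest.approx(d2, rel=1e-12)


class TestStratumFC:
    def test_recovers_planted_shifts(self):
        effects = {(0, 0): 2.0, (1, 0): 2.5, (0, 1): 0.3, (1, 1): 1.0}
        rng = np.random.default_rng(7)
        table = simulate_model_table(effects, 40, 40, 10, 1.0, rng)
        fit = fit_geneset_anova(table, include_exposure=True)
        for (m, a), d in effects.items():
            est = estimate_stratum_fc(fit, m, a)
            assert est.log2_fc == pytest.approx(d, abs=4 * est.se)
            assert est.ci_low <= est.fc <= est.ci_high or est.fc in (est.ci_low, est.ci_high)

    def test_ci_straddling_zero_changes_sign(self):
        """A contrast near zero yields a signed interval like (-1.2, 1.1)."""
        rng = np.random.default_rng(8)
        table = simulate_model_table({(0, 0): 0.0, (1, 0): 0.0, (0, 1): 0.0, (1, 1): 0.0},
                                     4, 4, 3, 1.0, rng)
        fit = fit_geneset_anova(table, include_exposure=True)
        est = estimate_stratum_fc(fit, 0, 0)
        assert est.ci_low < 0 < est.ci_high
        assert abs(est.ci_low) >= 1 and est.ci_high >= 1

    def test_n_cases_counts_patients(self):
        rng = np.random.default_rng(9)
        table = simulate_model_table({(0, 0): 1.0, (1, 0): 1.0, (0, 1): 1.0, (1, 1): 1.0},
                                     5, 3, 2, 1.0, rng)
        fit = fit_geneset_anova(table, include_exposure=True)
        assert all(estimate_stratum_fc(fit, m, a).n_cases == 5
                   for m in (0, 1) for a in (0, 1))

    def test_absent_stratum_rejected(self):
        rng = np.random.default_rng(10)
        fit = fit_geneset_anova(simulate_model_table({(0, 0): 1.0, (1, 0): 1.0,
                                                      (0, 1): 1.0, (1, 1): 1.0},
                                                     3, 2, 2, 1.0, rng),
                                include_exposure=True)
        with pytest.raises(ModelError):
            estimate_stratum_fc(fit, 1)  # missing as_high for exposure fit


class TestInteractionTest:
    def test_unknown_term_rejected(self):
        rng = np.random.default_rng(11)
        fit = fit_geneset_anova(single_gene_table(rng))
        with pytest.raises(ModelError):
            interaction_test(fit, "nonsense")

    def test_absent_term_rejected(self):
        rng = np.random.default_rng(12)
        fit = fit_geneset_anova(single_gene_table(rng))  # gene terms aliased away
        with pytest.raises(ModelError):
            interaction_test(fit, "tissue:gene")

    def test_power_against_large_interaction(self):
        """A one-log2-unit three-way interaction at n=40/stratum is detected
        at p < 1e-6 in nearly every replicate."""
        rng = np.random.default_rng(13)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            effects = {(0, 0): 1.0, (1, 0): 1.0, (0, 1): 1.0, (1, 1): 2.0}
            table = simulate_model_table(effects, 40, 40, 10, 1.0, rng)
            fit = fit_geneset_anova(table, include_exposure=True)
            _, p = interaction_test(fit, "tissue:mut:as_high")
            hits += p < 1e-6
        assert hits >= int(0.95 * n_rep)


class TestPathwayScreen:
    def test_interacting_set_ranks_first(self, cohort):
        from delscape import expression
        from delscape.classify import gene_del_status, subtype_associated_dels
        from delscape.classify import DelKey

        events = [
            (rec[0], DelKey(rec[1], rec[2], rec[3], rec[4]))
            for rec in cohort.planted["events"]["tumor"]
        ]
        healthy = [
            (rec[0], DelKey(rec[1], rec[2], rec[3], rec[4]))
            for rec in cohort.planted["events"]["healthy"]
        ]
        associated = subtype_associated_dels(events, cohort.manifest, "BCC", healthy)
        dm = gene_del_status(associated, events, cohort.gene_map, cohort.manifest, "BCC")
        mat = expression.log2_transform(
            expression.cpm(expression.ExpressionMatrix(cohort.counts))
        )
        results = run_pathway_screen(
            mat, cohort.gene_sets, cohort.manifest, dm, "APC",
            exposure_threshold=cohort.truth.uacr_median,
        )
        assert results[0].gene_set in {"INFLAMED_TCELL", "TGFB_SIGNALING"}
        null = next(r for r in results if r.gene_set == "NULL_PATHWAY")
        assert null.bonferroni_p > 0.05
        assert all(r.bonferroni_p == pytest.approx(min(1.0, 3 * r.interaction_p))
                   for r in results)

    def test_duplicate_set_gives_identical_rows(self, cohort):
        from delscape import expression
        from delscape.classify import DelKey, gene_del_status, subtype_associated_dels

        events = [
            (rec[0], DelKey(rec[1], rec[2], rec[3], rec[4]))
            for rec in cohort.planted["events"]["tumor"]
        ]
        healthy = [
            (rec[0], DelKey(rec[1], rec[2], rec[3], rec[4]))
            for rec in cohort.planted["events"]["healthy"]
        ]
        associated = subtype_associated_dels(events, cohort.manifest, "BCC", healthy)
        dm = gene_del_status(associated, events, cohort.gene_map, cohort.manifest, "BCC")
        mat = expression.log2_transform(
            expression.cpm(expression.ExpressionMatrix(cohort.counts))
        )
        twice = [cohort.gene_sets[0], cohort.gene_sets[0]]
        r1, r2 = run_pathway_screen(mat, twice, cohort.manifest, dm, "APC")
        assert r1.interaction_p == r2.interaction_p
        assert [s.fc for s in r1.strata] == [s.fc for s in r2.strata]

    def test_four_strata_with_configured_counts(self):
        """With the manifest built to hold (11, 6, 5, 4) patients per
        (exposure × carrier) subgroup, the screen reports exactly those n."""
        from delscape import expression
        from delscape.classify import DelKey, gene_del_status, subtype_associated_dels
        from delscape.simulate import SyntheticTruth, generate_cohort

        counts = {(0, 1): 11, (1, 1): 6, (0, 0): 5, (1, 0): 4}
        c = generate_cohort(SyntheticTruth(seed=5, stratum_counts=counts))
        events = [
            (rec[0], DelKey(rec[1], rec[2], rec[3], rec[4]))
            for rec in c.planted["events"]["tumor"]
        ]
        healthy = [
            (rec[0], DelKey(rec[1], rec[2], rec[3], rec[4]))
            for rec in c.planted["events"]["healthy"]
        ]
        associated = subtype_associated_dels(events, c.manifest, "BCC", healthy)
        dm = gene_del_status(associated, events, c.gene_map, c.manifest, "BCC")
        mat = expression.log2_transform(
            expression.cpm(expression.ExpressionMatrix(c.counts))
        )
        (result, *_) = run_pathway_screen(
            mat, c.gene_sets[:1], c.manifest, dm, "APC",
            exposure_threshold=c.truth.uacr_median,
        )
        observed = {(s.mut, s.as_high): s.n_cases for s in result.strata}
        assert observed == counts
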