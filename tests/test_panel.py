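"""Panel assembly, evaluation arithmetic and the bootstrap CI."""

import dataclasses
import logging

import numpy as np
import pandas as pd
import pytest

import glupanel as g
from glupanel.roc import HGG_LOW


def _matrix(delta_rows, genes, samples):
    return g.ExpressionMatrix(
        pd.DataFrame(delta_rows, index=genes, columns=samples)
    )


def _clinical(samples, cohorts):
    return pd.DataFrame({"sample_id": samples, "cohort": cohorts})


@pytest.fixture
def separable():
    """One gene separating 3 HGG (low ΔCt) from 3 MET perfectly."""
    samples = [f"s{i}" for i in range(6)]
    matrix = _matrix([[1.0, 2.0, 3.0, 6.0, 7.0, 8.0]], ["GRIA2"], samples)
    clinical = _clinical(samples, ["HGG"] * 3 + ["MET"] * 3)
    return matrix, clinical


class TestBuildPanel:
    def test_perfect_gene_enters_alone_with_j_one(self, separable):
        matrix, clinical = separable
        screen = g.screen_genes(matrix, clinical, alpha=0.2)
        panel = g.build_panel(matrix, clinical, screen)
        assert panel.genes == ["GRIA2"]
        assert panel.cutpoints[0].youden_j == pytest.approx(1.0)

    def test_unattainable_gate_empties_panel(self, separable, caplog):
        matrix, clinical = separable
        screen = g.screen_genes(matrix, clinical, alpha=0.2)
        with caplog.at_level(logging.WARNING):
            panel = g.build_panel(matrix, clinical, screen, auc_gate=1.0)
        assert panel.genes == []

    def test_default_cohort_recovers_configured_panel(self, default_matrix):
        """At study size the seven strong-effect genes pass the 0.8 gate and
        the two weak differential genes stay outside."""
        matrix, clinical = default_matrix
        screen = g.screen_genes(matrix, clinical)
        panel = g.build_panel(matrix, clinical, screen, auc_gate=0.8)
        assert set(panel.genes) == set(g.PANEL_GENES)
        gated_out = set(panel.candidates.loc[~panel.candidates["in_panel"], "gene"])
        assert not set(g.BELOW_GATE_GENES) & set(panel.genes)
        # every panel member really exceeded the gate on this matrix
        assert (panel.candidates.loc[panel.candidates["in_panel"], "auc"] > 0.8).all()


class TestEvaluatePanel:
    def test_single_perfect_gene(self, separable):
        matrix, clinical = separable
        panel = g.PanelModel(
            [g.GeneCutpoint("GRIA2", 4.5, HGG_LOW, 1.0, 1.0, 1.0)]
        )
        report = g.evaluate_panel(panel, matrix, clinical)
        assert report.total_accuracy_pct == pytest.approx(100.0)
        assert report.concordance == {1: 6}

    def test_right_plus_wrong_gene_average_to_half(self, separable):
        """One always-correct and one always-wrong gene: 50% total accuracy
        and every sample has exactly one concordant gene."""
        samples = [f"s{i}" for i in range(6)]
        matrix = _matrix(
            [[1, 2, 3, 6, 7, 8], [6, 7, 8, 1, 2, 3]], ["A", "B"], samples
        )
        clinical = _clinical(samples, ["HGG"] * 3 + ["MET"] * 3)
        panel = g.PanelModel(
            [
                g.GeneCutpoint("A", 4.5, HGG_LOW, 1.0, 1.0, 1.0),
                g.GeneCutpoint("B", 4.5, HGG_LOW, 1.0, 1.0, 1.0),
            ]
        )
        report = g.evaluate_panel(panel, matrix, clinical)
        assert report.total_accuracy_pct == pytest.approx(50.0)
        assert report.concordance == {1: 6}

    def test_abstentions_leave_denominator(self, separable):
        matrix, clinical = separable
        matrix.delta_ct.iloc[0, 0] = np.nan
        panel = g.PanelModel(
            [g.GeneCutpoint("GRIA2", 4.5, HGG_LOW, 1.0, 1.0, 1.0)]
        )
        report = g.evaluate_panel(panel, matrix, clinical)
        row = report.per_gene.iloc[0]
        assert row["n_hgg"] == 2 and row["n_met"] == 3
        assert report.total_accuracy_pct == pytest.approx(100.0)
        assert report.concordance == {1: 5, 0: 1}
        assert (report.predictions["prediction"] == "abstain").sum() == 1

    def test_invariant_to_gene_order_and_sample_ids(self, default_matrix):
        matrix, clinical = default_matrix
        screen = g.screen_genes(matrix, clinical)
        panel = g.build_panel(matrix, clinical, screen)
        base = g.evaluate_panel(panel, matrix, clinical)

        reordered = g.PanelModel(list(reversed(panel.cutpoints)), panel.auc_gate)
        assert g.evaluate_panel(
            reordered, matrix, clinical
        ).total_accuracy_pct == pytest.approx(base.total_accuracy_pct)

        rename = {s: f"x_{s}" for s in matrix.samples}
        renamed_matrix = g.ExpressionMatrix(
            matrix.delta_ct.rename(columns=rename), matrix.housekeeping_gene
        )
        renamed_clinical = clinical.assign(
            sample_id=clinical["sample_id"].map(rename)
        )
        assert g.evaluate_panel(
            panel, renamed_matrix, renamed_clinical
        ).total_accuracy_pct == pytest.approx(base.total_accuracy_pct)

    def test_concordance_counts_cover_all_samples(self, default_matrix):
        matrix, clinical = default_matrix
        screen = g.screen_genes(matrix, clinical)
        panel = g.build_panel(matrix, clinical, screen)
        report = g.evaluate_panel(panel, matrix, clinical)
        assert sum(report.concordance.values()) == 55
        assert max(report.concordance) <= len(panel.genes)


class TestReportFromCounts:
    def test_accuracy_arithmetic(self):
        per_gene, total = g.report_from_counts({"A": (3, 4, 1, 2)})
        assert per_gene.iloc[0]["accuracy_pct"] == pytest.approx(100 * 4 / 6)
        assert total == pytest.approx(100 * 4 / 6)

    def test_total_is_unweighted_mean(self):
        _, total = g.report_from_counts(
            {"A": (4, 4, 2, 2), "B": (0, 4, 0, 2)}
        )
        assert total == pytest.approx(50.0)


class TestBootstrapCI:
    def _default_panel(self, default_matrix):
        matrix, clinical = default_matrix
        screen = g.screen_genes(matrix, clinical)
        return g.build_panel(matrix, clinical, screen), matrix, clinical

    def test_perfect_panel_has_degenerate_ci(self, separable):
        matrix, clinical = separable
        panel = g.PanelModel(
            [g.GeneCutpoint("GRIA2", 4.5, HGG_LOW, 1.0, 1.0, 1.0)]
        )
        ci = g.bootstrap_accuracy_ci(panel, matrix, clinical, n_boot=200, seed=0)
        assert ci == (100.0, 100.0)

    def test_deterministic_under_seed(self, default_matrix):
        panel, matrix, clinical = self._default_panel(default_matrix)
        ci1 = g.bootstrap_accuracy_ci(panel, matrix, clinical, n_boot=400, seed=9)
        ci2 = g.bootstrap_accuracy_ci(panel, matrix, clinical, n_boot=400, seed=9)
        assert ci1 == ci2

    def test_ci_brackets_apparent_accuracy(self, default_matrix):
        panel, matrix, clinical = self._default_panel(default_matrix)
        report = g.evaluate_panel(panel, matrix, clinical)
        low, high = g.bootstrap_accuracy_ci(
            panel, matrix, clinical, n_boot=1000, seed=0
        )
        assert low <= report.total_accuracy_pct <= high

    def test_width_shrinks_with_sample_size(self):
        """Bootstrap consistency: CI width decreases roughly like 1/sqrt(n)."""
        widths = []
        for factor in (1, 4, 16):
            cfg = g.paper_default_config(seed=5)
            cfg = dataclasses.replace(
                cfg, n_hgg=35 * factor, n_met=20 * factor
            )
            table, clinical = g.generate_dataset(cfg)
            matrix = g.compute_delta_ct(table)
            screen = g.screen_genes(matrix, clinical)
            panel = g.build_panel(matrix, clinical, screen)
            low, high = g.bootstrap_accuracy_ci(
                panel, matrix, clinical, n_boot=500, seed=5
            )
            widths.append(high - low)
        assert widths[0] > widths[1] > widths[2]

    def test_too_few_resamples_rejected(self, separable):
        matrix, clinical = separable
        panel = g.PanelModel(
            [g.GeneCutpoint("GRIA2", 4.5, HGG_LOW, 1.0, 1.0, 1.0)]
        )
        with pytest.raises(ValueError):
            g.bootstrap_accuracy_ci(panel, matrix, clinical, n_boot=50, seed=0)
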