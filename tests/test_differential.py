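"""Differential calling: hand-checked arithmetic, gates, BH, antisymmetry."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hifmeth.containers import BetaMatrix, ExpressionMatrix
from hifmeth.differential import (
    CtTable,
    contrast_expression,
    contrast_methylation,
    ddct_fold_change,
    filter_de,
    filter_dm,
)


def _matrix(cls, rows: dict, conditions=("A", "B"), reps=3):
    cols, design = [], []
    for cond in conditions:
        for r in range(1, reps + 1):
            cols.append(f"{cond}_r{r}")
            design.append((f"{cond}_r{r}", cond, r))
    values = pd.DataFrame(rows, index=cols).T
    design = pd.DataFrame(design, columns=["sample", "condition", "replicate"]).set_index("sample")
    return cls(values=values, design=design)


class TestContrastExpression:
    def test_identical_groups_give_zero_fc(self):
        m = _matrix(ExpressionMatrix, {"g1": [5, 5, 5, 5, 5, 5]})
        rec = contrast_expression(m, "A", "B")
        assert rec.at["g1", "log2fc"] == 0
        assert rec.at["g1", "direction"] == "none"
        assert rec.at["g1", "p_value"] == 1.0

    def test_hand_computed_fold_change(self):
        """(4,4,4) vs (8,8,8) with pseudocount 1: log2(9/5)."""
        m = _matrix(ExpressionMatrix, {"g1": [4, 4, 4, 8, 8, 8]})
        rec = contrast_expression(m, "A", "B")
        assert rec.at["g1", "log2fc"] == pytest.approx(np.log2(9 / 5), abs=1e-9)
        assert rec.at["g1", "log2fc"] == pytest.approx(0.8479969, abs=1e-6)

    @pytest.mark.parametrize("method", ["moderated", "welch"])
    def test_antisymmetry_under_group_swap(self, method, expression):
        fwd = contrast_expression(expression, "shCTR_NX", "shCTR_HYP", method=method)
        rev = contrast_expression(expression, "shCTR_HYP", "shCTR_NX", method=method)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], atol=1e-12)

    def test_missing_group_rejected(self, expression):
        with pytest.raises(ValueError):
            contrast_expression(expression, "shCTR_NX", "nope")

    def test_bh_monotone_in_p_ranking(self, expression):
        rec = contrast_expression(expression, "shCTR_NX", "shHIF1A_NX")
        ordered = rec.sort_values("p_value")
        assert (np.diff(ordered["q_value"].to_numpy()) >= -1e-15).all()


class TestFilterDe:
    def _records(self, **kw):
        base = {"log2fc": 1.0, "p_value": 0.001, "q_value": 0.01, "direction": "up"}
        base.update(kw)
        return pd.DataFrame(base, index=["g1"])

    def test_exact_threshold_excluded(self):
        assert len(filter_de(self._records(log2fc=0.5))) == 0

    def test_above_threshold_retained_up(self):
        kept = filter_de(self._records(log2fc=2.62046))
        assert kept.entries.at["g1", "direction"] == "up"

    def test_fdr_gate(self):
        assert len(filter_de(self._records(log2fc=3.0, q_value=0.2))) == 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_de(self._records(), lfc_threshold=-1)


class TestContrastMethylation:
    def test_flat_probe(self):
        b = _matrix(BetaMatrix, {"p1": [0.5] * 6})
        rec = contrast_methylation(b, "A", "B")
        assert rec.at["p1", "delta_beta"] == 0
        assert rec.at["p1", "state"] == "none"

    def test_hand_computed_delta(self):
        b = _matrix(BetaMatrix, {"p1": [0.2, 0.2, 0.2, 0.5, 0.5, 0.5]})
        rec = contrast_methylation(b, "A", "B")
        assert rec.at["p1", "delta_beta"] == pytest.approx(0.3, abs=1e-12)

    def test_swap_negates_delta(self, beta):
        fwd = contrast_methylation(beta, "shCTR_NX", "shCTR_HYP")
        rev = contrast_methylation(beta, "shCTR_HYP", "shCTR_NX")
        np.testing.assert_allclose(fwd["delta_beta"], -rev["delta_beta"], atol=1e-12)
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], atol=1e-12)


class TestFilterDm:
    def _records(self, delta, q=0.01):
        return pd.DataFrame(
            {"delta_beta": [delta], "p_value": [q], "q_value": [q], "state": ["none"]},
            index=["p1"],
        )

    def test_exact_threshold_excluded(self):
        assert len(filter_dm(self._records(0.2))) == 0

    @pytest.mark.parametrize(
        "delta,state", [(0.22139292, "hyper"), (-0.24969157, "hypo")]
    )
    def test_states_assigned(self, delta, state):
        out = filter_dm(self._records(delta))
        assert out.at["p1", "state"] == state

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            filter_dm(self._records(0.3), delta_threshold=1.5)


class TestDdct:
    def _table(self, target_test, target_cal, ref=20.0):
        rows = []
        for cond, tct in (("cal", target_cal), ("test", target_test)):
            rows.append(("GOI", f"s_{cond}", cond, tct))
            rows.append(("ACTB", f"s_{cond}", cond, ref))
        ct = pd.DataFrame(rows, columns=["gene", "sample", "condition", "ct"])
        return CtTable(ct=ct, reference_gene="ACTB", calibrator_condition="cal")

    def test_no_change_is_one(self):
        assert ddct_fold_change(self._table(25, 25), "GOI", "test") == pytest.approx(1.0)

    def test_one_cycle_doubles(self):
        assert ddct_fold_change(self._table(24, 25), "GOI", "test") == pytest.approx(2.0)

    def test_hand_computed(self):
        """dCT 5 in test vs 7 in calibrator -> 2^-(-2) = 4."""
        assert ddct_fold_change(self._table(25, 27), "GOI", "test") == pytest.approx(4.0)

    def test_missing_reference_rejected(self):
        ct = pd.DataFrame(
            [("GOI", "s1", "test", 25.0)], columns=["gene", "sample", "condition", "ct"]
        )
        with pytest.raises(ValueError, match="reference"):
            CtTable(ct=ct, reference_gene="ACTB", calibrator_condition="cal")


class TestRecoveryAndNull:
    def test_planted_de_recovered(self, sim_config, truth, expression):
        """Sensitivity >= 0.9 for planted |log2FC| = 2 at triplicates."""
        rec = contrast_expression(expression, "shCTR_HYP", "shHIF1A_HYP")
        kept = filter_de(rec, contrast_label="hif1a_hyp")
        planted = {
            g
            for g, c in truth.gene_class.items()
            if c in ("exclusive_hypoxia", "hif1a_target_concordant", "hif1a_target_discordant")
        }
        sens = len(kept.genes & planted) / len(planted)
        assert sens >= 0.9

    def test_planted_dm_recovered(self, truth, beta):
        rec = contrast_methylation(beta, "shCTR_NX", "shCTR_HYP")
        kept = filter_dm(rec)
        planted = set(truth.probes_in_class("hypoxia_hyper")) | set(
            truth.probes_in_class("hypoxia_hypo")
        ) | set(truth.probes_in_class("common_inverted"))
        sens = len(set(kept.index) & planted) / len(planted)
        assert sens >= 0.9
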