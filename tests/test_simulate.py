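"""Generator contracts: determinism, class sizes, planted contrasts."""

from __future__ import annotations

import numpy as np
import pytest

from hifmeth.containers import CONDITIONS
from hifmeth.simulate import (
    SimulationConfig,
    plant_truth,
    simulate_cohort,
    simulate_expression,
    simulate_marker_tracks,
    simulate_methylation,
)


def _group_mean_log2(expr, condition):
    cols = expr.condition_samples(condition)
    return np.log2(expr.values[cols].to_numpy() + 1e-9).mean(axis=1)


class TestPlantTruth:
    def test_zero_fractions_give_all_null(self):
        cfg = SimulationConfig(
            n_genes=50, n_probes=60, gene_class_fractions={},
            probe_class_fractions={}, n_enhancer_independent=0,
            n_enhancer_dependent=0, seed=1,
        )
        t = plant_truth(cfg)
        assert set(t.gene_class.values()) == {"null"}
        assert set(t.probe_class.values()) == {"null"}

    def test_same_seed_same_truth(self):
        cfg = SimulationConfig(n_genes=200, n_probes=300, seed=11)
        a, b = plant_truth(cfg), plant_truth(cfg)
        assert a.gene_class == b.gene_class
        assert a.probe_class == b.probe_class
        assert a.enhancer_targets == b.enhancer_targets
        assert a.gene_coords.equals(b.gene_coords)

    def test_fraction_yields_exact_count(self):
        cfg = SimulationConfig(
            n_genes=1000, n_probes=100,
            gene_class_fractions={"hif1a_target_concordant": 0.10},
            probe_class_fractions={}, n_enhancer_independent=0,
            n_enhancer_dependent=0, seed=7,
        )
        t = plant_truth(cfg)
        assert len(t.genes_in_class("hif1a_target_concordant")) == 100

    def test_overfull_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(
                gene_class_fractions={"exclusive_normoxia": 0.7, "exclusive_hypoxia": 0.5}
            )

    def test_classes_disjoint_and_enhancers_subset(self, truth, sim_config):
        assert set(truth.enhancer_probes) <= set(truth.probe_class)
        # every probe has exactly one class by construction of the mapping
        assert len(truth.probe_class) == sim_config.n_probes


class TestSimulateExpression:
    def test_deterministic_and_nonnegative(self, sim_config, truth, expression):
        again = simulate_expression(sim_config, truth)
        assert expression.values.equals(again.values)
        assert (expression.values.to_numpy() >= 0).all()

    def test_planted_contrasts_realized(self, sim_config, truth, expression):
        """Each class's defining contrast shows the configured log2 effect."""
        e = sim_config.effect_log2fc
        se = sim_config.expression_noise_sd * np.sqrt(2 / sim_config.replicates_per_condition)
        m = {c: _group_mean_log2(expression, c) for c in CONDITIONS}
        genes = list(truth.gene_class)
        idx = {g: i for i, g in enumerate(genes)}

        for g in truth.genes_in_class("exclusive_hypoxia"):
            i, s = idx[g], truth.gene_sign[g]
            assert m["shHIF1A_HYP"][i] - m["shCTR_HYP"][i] == pytest.approx(s * e, abs=3 * se)
            assert m["shHIF1A_NX"][i] - m["shCTR_NX"][i] == pytest.approx(0, abs=3 * se)
        for g in truth.genes_in_class("hif1a_target_discordant"):
            i = idx[g]
            d_nx = m["shHIF1A_NX"][i] - m["shCTR_NX"][i]
            d_hyp = m["shHIF1A_HYP"][i] - m["shCTR_HYP"][i]
            assert np.sign(d_nx) == -np.sign(d_hyp)
        for g in truth.genes_in_class("hypoxia_independent_target"):
            i, s = idx[g], truth.gene_sign[g]
            assert m["shCTR_HYP"][i] - m["shCTR_NX"][i] == pytest.approx(s * e, abs=3 * se)
            assert np.sign(m["shHIF1A_HYP"][i] - m["shCTR_HYP"][i]) == s

    def test_single_replicate_rejected(self, truth, sim_config):
        cfg = SimulationConfig(
            n_genes=sim_config.n_genes, n_probes=sim_config.n_probes,
            replicates_per_condition=1, seed=3,
        )
        with pytest.raises(ValueError, match="replicates"):
            simulate_expression(cfg, truth)


class TestSimulateMethylation:
    def test_beta_in_unit_interval(self, beta):
        arr = beta.values.to_numpy()
        assert arr.min() >= 0 and arr.max() <= 1

    def test_manifest_partitions(self, manifest, sim_config):
        assert len(manifest) == sim_config.n_probes
        assert manifest["cgi_feature"].isin(["island", "shore", "shelf", "open_sea"]).all()
        igr = manifest["gene_feature"] == "IGR"
        assert (manifest.loc[igr, "gene_id"].isna()).all()
        assert (manifest.loc[~igr, "gene_id"].notna()).all()

    def test_planted_shifts_realized(self, sim_config, truth, beta):
        d = sim_config.effect_delta_beta
        cols = {c: beta.condition_samples(c) for c in CONDITIONS}
        mean = {c: beta.values[cols[c]].mean(axis=1) for c in CONDITIONS}
        hyper = truth.probes_in_class("hypoxia_hyper")
        db = (mean["shCTR_HYP"] - mean["shCTR_NX"]).loc[hyper]
        assert db.mean() == pytest.approx(d, abs=0.03)
        for p in truth.probes_in_class("common_inverted"):
            a = mean["shCTR_HYP"][p] - mean["shCTR_NX"][p]
            b = mean["shHIF1A_HYP"][p] - mean["shCTR_HYP"][p]
            assert np.sign(a) == -np.sign(b)


class TestSimulateMarkerTracks:
    def test_enhancer_probes_covered_everywhere(self, sim_config, truth, tracks):
        for p in truth.enhancer_probes:
            chrom = truth.probe_coords.at[p, "chrom"]
            pos = int(truth.probe_coords.at[p, "pos"])
            for cl in sim_config.cell_lines:
                n = sum(
                    1
                    for t in tracks
                    if t.cell_line == cl
                    and (
                        (t.intervals["chrom"] == chrom)
                        & (t.intervals["start"] <= pos)
                        & (pos < t.intervals["end"])
                    ).any()
                )
                assert n >= 4

    def test_interval_sanity(self, tracks, sim_config):
        for t in tracks:
            iv = t.intervals
            assert (iv["start"] < iv["end"]).all()
            assert (iv["start"] >= 0).all()

    def test_no_tracks_without_cell_lines(self, truth, sim_config):
        cfg = SimulationConfig(
            n_genes=sim_config.n_genes, n_probes=sim_config.n_probes,
            cell_lines=(), seed=3,
        )
        with pytest.raises(ValueError, match="cell line"):
            simulate_marker_tracks(cfg, truth)


class TestSimulateCohort:
    def test_default_cohort_sizes(self, cohort):
        counts = cohort.risk.value_counts()
        assert counts["low"] == 40 and counts["high"] == 56

    def test_signature_genes_separate_classes(self, sim_config, truth, cohort):
        low = cohort.risk.index[cohort.risk == "low"]
        high = cohort.risk.index[cohort.risk == "high"]
        gap = (
            cohort.values.loc[sorted(truth.signature_genes), high].mean(axis=1)
            - cohort.values.loc[sorted(truth.signature_genes), low].mean(axis=1)
        )
        assert (gap.abs() > sim_config.signature_separation / 2).all()
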