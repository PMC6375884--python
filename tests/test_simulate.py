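"""Synthetic-data generators: determinism, planted means, coupling."""

import numpy as np
import pandas as pd
import pytest

import memoryseq as m


class TestExpressionSimulator:
    def test_determinism(self):
        cfg = m.SimulationConfig(n_genes=100, seed=42)
        t1, g1 = m.simulate_expression(cfg)
        t2, g2 = m.simulate_expression(m.SimulationConfig(n_genes=100, seed=42))
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        pd.testing.assert_frame_equal(g1, g2)
        t3, _ = m.simulate_expression(m.SimulationConfig(n_genes=100, seed=43))
        assert not t3.counts.equals(t1.counts)

    def test_null_effect_gives_flat_means(self):
        cfg = m.SimulationConfig(n_genes=50, effect_size=0.0, seed=1)
        _, truth = m.simulate_expression(cfg)
        for cond in cfg.conditions:
            np.testing.assert_allclose(truth[f"mean_{cond}"], cfg.baseline_mean)

    def test_law_of_large_numbers_on_planted_shape(self):
        # shape id 18 has steps (+1,-1,0): values (0,1,0,0), so S1 mean is
        # baseline * 2^effect = 400 and the others stay at 100
        cfg = m.SimulationConfig(n_genes=1, n_replicates=10_000,
                                 profile_mixture={18: 1.0},
                                 effect_size=2.0, baseline_mean=100.0,
                                 nb_dispersion=0.05, seed=3)
        table, truth = m.simulate_expression(cfg)
        assert truth["mean_S1"].iloc[0] == pytest.approx(400.0)
        assert truth["mean_R3"].iloc[0] == pytest.approx(100.0)
        for cond, mu in (("R0", 100.0), ("S1", 400.0), ("R3", 100.0), ("S4", 100.0)):
            x = table.counts[table.samples_for(cond)].to_numpy(float).ravel()
            se = x.std(ddof=1) / np.sqrt(x.size)
            assert abs(x.mean() - mu) < 3 * se

    def test_dosage_genes_identical_at_baseline_and_first_stress(self):
        cfg = m.SimulationConfig(n_genes=200, profile_mixture={13: 0.5, 15: 0.5},
                                 seed=5)
        _, truth = m.simulate_expression(cfg)
        np.testing.assert_allclose(truth["mean_R0"], truth["mean_S1"])
        assert (truth["category"] == "dosage").all()

    def test_memory_truth_follows_value_vectors(self):
        _, truth = m.simulate_expression(m.SimulationConfig(n_genes=300, seed=6))
        differs = ((truth["value_R3"] != truth["value_S1"])
                   | (truth["value_S4"] != truth["value_S1"]))
        expected = (truth["shape_id"] != m.FLAT_SHAPE) & differs
        pd.testing.assert_series_equal(truth["is_memory"], expected,
                                       check_names=False)

    @pytest.mark.parametrize("bad", [
        {"profile_mixture": {m.FLAT_SHAPE: 0.5, 25: 0.4}},     # sums to 0.9
        {"profile_mixture": {m.FLAT_SHAPE: 1.5, 25: -0.5}},    # negative
        {"nb_dispersion": -0.1},
        {"n_genes": 0},
        {"profile_mixture": {99: 1.0}},                        # unknown shape
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            m.simulate_expression(m.SimulationConfig(**bad))

    def test_poisson_limit_at_zero_dispersion(self):
        cfg = m.SimulationConfig(n_genes=2000, nb_dispersion=0.0,
                                 profile_mixture={m.FLAT_SHAPE: 1.0}, seed=9)
        table, _ = m.simulate_expression(cfg)
        x = table.counts.to_numpy(float)
        # Poisson: variance == mean (index of dispersion ~ 1)
        assert x.var() / x.mean() == pytest.approx(1.0, abs=0.05)


class TestMethylomeSimulator:
    def test_determinism_and_truth_uniqueness(self, planted_methylome):
        cfg, cyt_a, cyt_b, truth = planted_methylome
        a2, b2, t2 = m.simulate_methylome(cfg)
        pd.testing.assert_frame_equal(cyt_a, a2)
        pd.testing.assert_frame_equal(cyt_b, b2)
        assert truth["dmr_id"].is_unique
        # planted intervals are disjoint
        s = truth.sort_values("start")
        assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_null_delta_draws_identical_distributions(self):
        cfg = m.MethylomeSimConfig(genome_length=50_000, n_dmrs=0, dmr_delta=0.0,
                                   n_cytosines_per_context={"CG": 3000},
                                   seed=11)
        cyt_a, cyt_b, truth = m.simulate_methylome(cfg)
        assert truth.empty
        la = cyt_a["meth"].sum() / (cyt_a["meth"] + cyt_a["unmeth"]).sum()
        lb = cyt_b["meth"].sum() / (cyt_b["meth"] + cyt_b["unmeth"]).sum()
        assert la == pytest.approx(0.6, abs=0.02)
        assert lb == pytest.approx(0.6, abs=0.02)

    def test_zero_depth_gives_uncovered_windows(self):
        cfg = m.MethylomeSimConfig(genome_length=20_000, depth_mean=0.0,
                                   n_dmrs=0,
                                   n_cytosines_per_context={"CG": 500}, seed=2)
        cyt_a, cyt_b, _ = m.simulate_methylome(cfg)
        assert (cyt_a["meth"] + cyt_a["unmeth"]).sum() == 0
        stats = m.test_windows(m.pool_windows(cyt_a, cyt_b))
        assert not stats["testable"].any()

    def test_planted_delta_recovered_in_pooled_window(self):
        cfg = m.MethylomeSimConfig(genome_length=50_000, n_dmrs=5, dmr_delta=0.5,
                                   depth_mean=30.0, dmr_width=200,
                                   baseline_level={"CG": 0.3},
                                   n_cytosines_per_context={"CG": 5000}, seed=13)
        cyt_a, cyt_b, truth = m.simulate_methylome(cfg)
        for rec in truth.itertuples():
            ma, ua, _ = m.pool_window(cyt_a, (rec.start, rec.end), rec.context)
            mb, ub, _ = m.pool_window(cyt_b, (rec.start, rec.end), rec.context)
            diff = mb / (mb + ub) - ma / (ma + ua)
            # binomial error at ~20 cytosines x depth 30 is ~0.02
            assert diff == pytest.approx(rec.delta, abs=0.08)

    def test_infeasible_configs_rejected(self):
        with pytest.raises(ValueError):
            m.simulate_methylome(m.MethylomeSimConfig(genome_length=100,
                                                      dmr_width=200))
        with pytest.raises(ValueError):
            # neither hyper (>1) nor hypo (<0) is feasible at this baseline
            m.simulate_methylome(m.MethylomeSimConfig(
                dmr_delta=0.8, baseline_level={"CG": 0.4, "CHG": 0.4, "CHH": 0.4}))


class TestLinkageSimulator:
    @pytest.mark.parametrize("sign", [1, -1])
    def test_noise_free_coupling_gives_exact_correlation(self, sign,
                                                         planted_expression,
                                                         planted_methylome):
        _, table, expr_truth = planted_expression
        _, _, _, dmr_truth = planted_methylome
        levels, genes, links = m.simulate_linkage(
            table, expr_truth, dmr_truth,
            m.LinkageSimConfig(link_sign=sign, noise_sd=0.0, seed=21))
        linked = links[links["true_sign"] != 0]
        assert len(linked) == round(0.8 * len(dmr_truth))
        res = m.correlate_linkage(levels, table.fpkm(), linked)
        np.testing.assert_allclose(res["correlation"], sign, atol=1e-9)
        assert res["linked"].all()

    def test_linked_genes_are_placed_in_promoter_zone(self, planted_expression,
                                                      planted_methylome):
        _, table, expr_truth = planted_expression
        _, cyt_a, cyt_b, dmr_truth = planted_methylome
        levels, genes, links = m.simulate_linkage(
            table, expr_truth, dmr_truth, m.LinkageSimConfig(seed=22))
        pairs = m.associate_dmr_gene(dmr_truth, genes)
        merged = pairs.merge(links[links["true_sign"] != 0],
                             on=["dmr_id", "gene_id"])
        assert len(merged) == (links["true_sign"] != 0).sum()
        assert (merged["zone"] == "promoter").all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            m.LinkageSimConfig(link_sign=0).validate()
        with pytest.raises(ValueError):
            m.LinkageSimConfig(baseline=0.9, amplitude=0.2).validate()
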