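"""The synthetic-data generators: planted structure, determinism, round-trip
of every written format, and downstream recoverability."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import regscan.io as io
from regscan import (SimConfig, simulate_categories, simulate_expression,
                     simulate_pbm, simulate_promoters)
from regscan.enrichment import hypergeometric_enrichment, results_to_frame
from regscan.expression import ExpressionTable, concordance_filter, fold_changes, stage_means
from regscan.pbm import profile_from_measurements
from regscan.scan import extract_upstream, scan_windows
from regscan.synthetic import (TruthRecord, simulate_bundle, truth_motif,
                               write_gene_models)


class TestSimConfigValidation:
    def test_defaults_valid(self):
        SimConfig()

    @pytest.mark.parametrize("kwargs", [
        dict(n_bound_probes=0),
        dict(probe_replicates=1),
        dict(concordant_fraction=1.5),
        dict(zero_inflation=-0.1),
        dict(driver_folds=(0.9, 5.0)),
        dict(driver_folds=(5.0, 2.0)),
        dict(stage_names=("a", "b")),
        dict(sites_per_gene_range=(3, 1)),
        dict(truth_motif_width=99),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestSimulatePbm:
    def test_zero_affinity_removes_bound_background_difference(self):
        cfg = SimConfig(seed=2, n_bound_probes=150, n_background_probes=150,
                        affinity_scale=0.0, noise_sd=0.3)
        probes, _ = simulate_pbm(cfg)
        logf = np.log(probes["fluorescence"])
        bound = logf[~probes["is_background"]]
        bg = logf[probes["is_background"]]
        # identical in expectation: means within a few standard errors
        se = np.sqrt(bound.var() / len(bound) + bg.var() / len(bg))
        assert abs(bound.mean() - bg.mean()) < 4 * se

    def test_noise_free_bound_probes_exceed_background(self):
        cfg = SimConfig(seed=3, n_bound_probes=40, n_background_probes=40,
                        affinity_scale=1.0, noise_sd=0.0)
        probes, _ = simulate_pbm(cfg)
        bg_max = probes.loc[probes["is_background"], "fluorescence"].max()
        bound = probes.loc[~probes["is_background"]]
        # probes carrying a sampled motif site score far above any background
        assert bound["fluorescence"].max() > bg_max
        assert (bound.groupby("sequence")["fluorescence"].max() >= bg_max * 0.99).all()

    def test_replicate_structure(self, small_config):
        probes, _ = simulate_pbm(small_config)
        per_seq = probes.groupby(["sequence", "array"]).size()
        assert (per_seq == small_config.probe_replicates).all()
        assert probes["array"].nunique() == small_config.n_arrays

    def test_bound_mean_z_dominates_background(self):
        cfg = SimConfig(seed=1, n_bound_probes=200, n_background_probes=300,
                        affinity_scale=2.0, noise_sd=0.3)
        probes, _ = simulate_pbm(cfg)
        profile = profile_from_measurements(probes)
        bound_mean = profile.z[~profile.is_background].mean()
        bg_mean = profile.z[profile.is_background].mean()
        assert bound_mean > 2 * abs(bg_mean)
        assert bound_mean > 2.0

    def test_fluorescence_positive(self, small_config):
        probes, _ = simulate_pbm(small_config)
        assert (probes["fluorescence"] > 0).all()


class TestSimulateExpression:
    def test_driver_folds_exact_without_noise(self):
        cfg = SimConfig(seed=4, n_genes=60, noise_sd=0.0, driver_folds=(2.3, 5.0))
        table, truth = simulate_expression(cfg)
        means = stage_means(ExpressionTable(table))
        fc = fold_changes(means, truth.driver_gene_id, "aggregative")
        assert fc["filopodic"] == pytest.approx(2.3)
        assert fc["cystic"] == pytest.approx(5.0)

    def test_all_concordant_limit_fully_recovered(self):
        cfg = SimConfig(seed=5, n_genes=80, concordant_fraction=1.0,
                        zero_inflation=0.0, noise_sd=0.0)
        table, truth = simulate_expression(cfg)
        res = concordance_filter(stage_means(ExpressionTable(table)))
        assert set(res.kept_genes) == truth.concordant_gene_ids
        assert len(res.kept_genes) == 80

    def test_recovery_precision_and_recall(self):
        cfg = SimConfig(seed=7, n_genes=1000, concordant_fraction=0.15, noise_sd=0.05)
        table, truth = simulate_expression(cfg)
        res = concordance_filter(stage_means(ExpressionTable(table)))
        kept = set(res.kept_genes)
        tp = len(kept & truth.concordant_gene_ids)
        assert tp / len(kept) >= 0.9
        assert tp / len(truth.concordant_gene_ids) >= 0.9

    def test_zero_inflation_zeroes_all_replicates(self):
        cfg = SimConfig(seed=6, n_genes=200, zero_inflation=0.3, noise_sd=0.2)
        table, _ = simulate_expression(cfg)
        per_cell = table.groupby(["gene_id", "stage"])["fpkm"]
        n_zero = (per_cell.max() == 0).sum()
        partially_zero = ((per_cell.min() == 0) & (per_cell.max() > 0)).sum()
        assert n_zero > 0
        assert partially_zero == 0

    def test_fpkm_non_negative(self, small_config):
        table, _ = simulate_expression(small_config)
        assert (table["fpkm"] >= 0).all()

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            simulate_expression(SimConfig(expression_replicates=1, n_genes=10))


class TestSimulatePromoters:
    def test_implants_recovered_by_extraction_on_both_strands(self, kb_pfm):
        cfg = SimConfig(seed=8, n_genes=30)
        genome, models, truth = simulate_promoters(cfg, kb_pfm)
        windows = {w.gene_id: w for w in extract_upstream(genome, models, window=500)}
        consensus = kb_pfm.consensus()
        strands = {m.gene_id: m.strand for m in models}
        assert set(strands.values()) == {"+", "-"}
        for gene, sites in truth.implanted_sites.items():
            seq = windows[gene].sequence
            for offset, strand in sites:
                expected = consensus if strand == "+" else io.reverse_complement(consensus)
                assert seq[offset:offset + 10] == expected

    def test_no_implant_null_gives_near_zero_hits(self, kb_pfm):
        cfg = SimConfig(seed=9, n_genes=40, sites_per_gene_range=(0, 0))
        genome, models, truth = simulate_promoters(cfg, kb_pfm)
        windows = extract_upstream(genome, models, window=500)
        result = scan_windows(windows, kb_pfm, threshold_p=1e-4)
        assert sum(result.counts.values()) <= 3  # ~2*491*1e-4*40 expected hits

    def test_site_counts_match_truth(self, kb_pfm):
        cfg = SimConfig(seed=3, n_genes=50, sites_per_gene_range=(1, 4))
        genome, models, truth = simulate_promoters(cfg, kb_pfm)
        windows = extract_upstream(genome, models, window=500)
        result = scan_windows(windows, kb_pfm, threshold_p=1e-4)
        matches = sum(result.counts[g] == len(sites)
                      for g, sites in truth.implanted_sites.items())
        assert matches / len(truth.implanted_sites) >= 0.95

    def test_overfull_implant_request_rejected(self):
        cfg = SimConfig(promoter_length=30, sites_per_gene_range=(4, 4))
        with pytest.raises(ValueError, match="exceeds promoter_length"):
            simulate_promoters(cfg)


class TestSimulateCategories:
    def test_extreme_effect_puts_enriched_category_first(self):
        cfg = SimConfig(seed=10, n_genes=400, concordant_fraction=0.2,
                        enriched_category_effect=1e6, n_categories=10)
        _, truth_e = simulate_expression(cfg)
        genes = [f"g{i:05d}" for i in range(400)]
        cats, truth_c = simulate_categories(cfg, truth_e, genes)
        results = results_to_frame(hypergeometric_enrichment(
            sorted(truth_e.concordant_gene_ids), genes, cats))
        assert results.iloc[0]["category_id"] == truth_c.enriched_category_id

    def test_effect_five_detected_in_most_seeds(self):
        detected = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = SimConfig(seed=11 + seed, n_genes=500, concordant_fraction=0.15,
                            enriched_category_effect=5.0, n_categories=20)
            _, te = simulate_expression(cfg)
            genes = [f"g{i:05d}" for i in range(500)]
            cats, tc = simulate_categories(cfg, te, genes)
            results = hypergeometric_enrichment(sorted(te.concordant_gene_ids),
                                                genes, cats)
            by_id = {r.category_id: r for r in results}
            if by_id[tc.enriched_category_id].bh_adjusted_p < 0.05:
                detected += 1
        assert detected / n_seeds >= 0.9

    def test_map_covers_requested_categories(self, small_config):
        _, te = simulate_expression(small_config)
        genes = [f"g{i:05d}" for i in range(small_config.n_genes)]
        cats, tc = simulate_categories(small_config, te, genes)
        assert cats["category_id"].nunique() == small_config.n_categories + 1
        assert tc.enriched_category_id in set(cats["category_id"])


class TestDeterminismAndRoundTrip:
    def test_same_seed_bit_identical_different_seed_not(self, small_config):
        p1, _ = simulate_pbm(small_config)
        p2, _ = simulate_pbm(dataclasses.replace(small_config))
        pd.testing.assert_frame_equal(p1, p2)
        p3, _ = simulate_pbm(dataclasses.replace(small_config, seed=99))
        assert not p1["fluorescence"].equals(p3["fluorescence"])

    def test_expression_streams_independent_of_pbm(self, small_config):
        e1, _ = simulate_expression(small_config)
        simulate_pbm(small_config)  # consuming the PBM stream must not matter
        e2, _ = simulate_expression(small_config)
        pd.testing.assert_frame_equal(e1, e2)

    def test_bundle_round_trips_losslessly(self, small_config, tmp_path):
        truth = simulate_bundle(small_config, tmp_path)
        probes = io.read_probe_table(tmp_path / "probes.tsv")
        assert set(probes.columns) == set(io.PROBE_COLUMNS)
        expr = io.read_expression_table(tmp_path / "expression.tsv")
        orig_expr, _ = simulate_expression(small_config)
        pd.testing.assert_frame_equal(
            expr, orig_expr, check_exact=False, rtol=1e-12)
        genome = io.read_fasta(tmp_path / "genome.fa")
        orig_genome, models, _ = simulate_promoters(
            small_config, truth.truth_pfm,
            sorted(orig_expr["gene_id"].unique()))
        assert genome == orig_genome
        back = TruthRecord.from_json(tmp_path / "truth.json")
        assert back.concordant_gene_ids == truth.concordant_gene_ids
        assert back.implanted_sites == truth.implanted_sites
        assert back.driver_gene_id == truth.driver_gene_id
        np.testing.assert_allclose(back.truth_pfm.frequencies,
                                   truth.truth_pfm.frequencies)

    def test_gene_model_writers_agree(self, small_config, tmp_path):
        from regscan.scan import read_bed6_genes, read_gff3_genes
        genome, models, _ = simulate_promoters(small_config, truth_motif(10),
                                               [f"g{i:05d}" for i in range(20)])
        write_gene_models(models, tmp_path / "g.gff3", tmp_path / "g.bed")
        key = lambda m: m.gene_id
        from_gff = sorted(read_gff3_genes(tmp_path / "g.gff3"), key=key)
        from_bed = sorted(read_bed6_genes(tmp_path / "g.bed"), key=key)
        assert from_gff == from_bed == sorted(models, key=key)
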