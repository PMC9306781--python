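import dataclasses

import numpy as np
import pandas as pd
import pytest

from pleioscan import simulate as sim
from pleioscan.simulate import SimConfig


class TestMakeTruth:
    def test_class_fractions_forced_by_rounding(self):
        cfg = SimConfig(
            n_chromosomes=1, chromosome_length=5_000_000,
            prop_parallel=0.05, prop_single=0.10, seed=3,
        )
        truth = sim.make_truth(cfg)
        counts = truth["true_class"].value_counts()
        assert counts["parallel"] == 5
        assert counts["single_pair_outlier"] == 10
        assert counts["background"] == 85

    def test_no_parallel_when_prop_zero(self):
        cfg = SimConfig(prop_parallel=0.0, n_chromosomes=1,
                        chromosome_length=5_000_000, seed=1)
        truth = sim.make_truth(cfg)
        assert (truth["selected_pairs"].map(len) < 2).all()

    def test_selected_pair_cardinality_invariants(self, tiny_config):
        truth = sim.make_truth(tiny_config)
        for cls, sel in zip(truth["true_class"], truth["selected_pairs"]):
            if cls == "parallel":
                assert 2 <= len(sel) <= 4
            elif cls == "single_pair_outlier":
                assert len(sel) == 1
            else:
                assert len(sel) == 0
            assert len(set(sel)) == len(sel)

    def test_same_seed_identical_tables(self, tiny_config):
        t1 = sim.make_truth(tiny_config)
        t2 = sim.make_truth(tiny_config)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="must not exceed 1"):
            SimConfig(prop_parallel=0.6, prop_single=0.5)


class TestSimulateGenotypes:
    def test_selected_windows_have_higher_fst_across_seeds(self):
        """Windows with elevated Balding–Nichols F show higher window F_ST.

        Checked over 20 seeds: the mean window F_ST of selected windows
        exceeds the background mean in every replicate.
        """
        from pleioscan import pipeline

        wins = 0
        for seed in range(20):
            cfg = SimConfig(
                n_pairs=2, n_diploids_per_population=24, n_chromosomes=1,
                chromosome_length=2_500_000, snps_per_window=4,
                F_selected=0.5, F_background=0.02,
                prop_parallel=0.3, prop_single=0.0,
                parallel_pairs_min=2, parallel_pairs_max=2, seed=seed,
            )
            truth = sim.make_truth(cfg)
            ds = sim.simulate_genotypes(truth, cfg)
            fstm = pipeline.scan_dataset(ds, cfg.grid(), min_sites=1)
            selected = (truth["true_class"] == "parallel").to_numpy()
            mean_sel = np.nanmean(fstm.to_numpy()[selected])
            mean_back = np.nanmean(fstm.to_numpy()[~selected])
            wins += mean_sel > mean_back
        assert wins == 20

    def test_null_construction_no_class_difference(self):
        """F_selected = F_background: class window means indistinguishable."""
        from scipy import stats

        from pleioscan import pipeline

        pvals = []
        for seed in range(15):
            cfg = SimConfig(
                n_pairs=2, n_chromosomes=1, chromosome_length=2_500_000,
                snps_per_window=4, F_selected=0.05, F_background=0.05,
                prop_parallel=0.3, prop_single=0.0,
                parallel_pairs_min=2, parallel_pairs_max=2, seed=seed + 100,
            )
            truth = sim.make_truth(cfg)
            ds = sim.simulate_genotypes(truth, cfg)
            fstm = pipeline.scan_dataset(ds, cfg.grid(), min_sites=1)
            selected = (truth["true_class"] == "parallel").to_numpy()
            col = fstm.iloc[:, 0].to_numpy()
            pvals.append(
                stats.mannwhitneyu(col[selected], col[~selected]).pvalue
            )
        # no systematic enrichment of small p-values
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_determinism_and_counts_shape(self, tiny_config):
        truth = sim.make_truth(tiny_config)
        d1 = sim.simulate_genotypes(truth, tiny_config)
        d2 = sim.simulate_genotypes(truth, tiny_config)
        np.testing.assert_array_equal(d1.counts, d2.counts)
        n = tiny_config.n_diploids_per_population
        assert (d1.counts.sum(axis=-1) == n).all()

    def test_invalid_fixation_index_rejected(self):
        with pytest.raises(ValueError, match="fixation"):
            SimConfig(F_selected=1.0)
        with pytest.raises(ValueError, match="fixation"):
            SimConfig(F_background=0.0)


class TestSimulateQtl:
    def test_empty_when_probability_zero(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, qtl_window_prob=0.0)
        truth = sim.make_truth(cfg)
        assert len(sim.simulate_qtl_table(truth, cfg)) == 0

    def test_null_effect_equal_class_means(self):
        diffs = []
        for seed in range(30):
            cfg = SimConfig(
                n_chromosomes=1, chromosome_length=10_000_000,
                pleiotropy_effect=1.0, qtl_window_prob=1.0,
                duplicate_qtl_frac=0.0, seed=seed,
            )
            truth = sim.make_truth(cfg)
            q = sim.simulate_qtl_table(truth, cfg)
            counts = q.groupby(q["trait"].str.extract(r"w(\d+)_")[0].astype(int))[
                "trait"
            ].nunique()
            par = truth["true_class"] == "parallel"
            diffs.append(
                counts[counts.index[counts.index.isin(np.flatnonzero(par))]].mean()
                - counts[~counts.index.isin(np.flatnonzero(par))].mean()
            )
        assert abs(np.mean(diffs)) < 0.1

    def test_implanted_class_means_scale_with_effect(self):
        """lambda_base 0.5 -> background mean 1.5; effect 2 -> parallel 3.0."""
        par_means, non_means = [], []
        for seed in range(50):
            cfg = SimConfig(
                n_chromosomes=1, chromosome_length=10_000_000,
                qtl_window_prob=1.0, duplicate_qtl_frac=0.0, seed=seed,
            )
            truth = sim.make_truth(cfg)
            q = sim.simulate_qtl_table(truth, cfg)
            widx = q["trait"].str.extract(r"w(\d+)_")[0].astype(int)
            counts = q.groupby(widx)["trait"].nunique()
            par = set(np.flatnonzero(truth["true_class"] == "parallel"))
            is_par = counts.index.isin(list(par))
            par_means.append(counts[is_par].mean())
            non_means.append(counts[~is_par].mean())
        assert np.mean(par_means) == pytest.approx(3.0, abs=0.1)
        assert np.mean(non_means) == pytest.approx(1.5, abs=0.05)

    def test_confidence_intervals_contained_in_window(self, tiny_config):
        truth = sim.make_truth(tiny_config)
        q = sim.simulate_qtl_table(truth, tiny_config)
        grid = tiny_config.grid()
        mid = ((q["ci_start"] + q["ci_end"]) // 2).astype(int)
        widx = grid.locate(q["chrom"].to_numpy(), mid.to_numpy())
        starts = grid.windows["start"].to_numpy()[widx]
        ends = grid.windows["end"].to_numpy()[widx]
        assert ((q["ci_start"] >= starts) & (q["ci_end"] < ends)).all()

    def test_duplicates_share_trait_and_window_differ_in_pve(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, duplicate_qtl_frac=0.5,
                                  qtl_window_prob=0.8)
        truth = sim.make_truth(cfg)
        q = sim.simulate_qtl_table(truth, cfg)
        dups = q[q.duplicated(subset="trait", keep=False)]
        assert len(dups) > 0
        for trait, grp in dups.groupby("trait"):
            assert grp["pve"].nunique() == len(grp)


class TestSimulateExpression:
    def test_shared_module_high_loadings_correlate(self):
        cfg = SimConfig(
            n_chromosomes=1, chromosome_length=500_000, n_genes=2,
            n_samples=100, n_modules=1, loading_low=0.99, loading_high=0.99,
            hub_effect=0.0, prop_parallel=0.0, prop_single=0.0, seed=8,
        )
        truth = sim.make_truth(cfg)
        expr, _ = sim.simulate_expression(truth, cfg)
        logm = np.log2(expr + 1)
        r = np.corrcoef(logm.to_numpy())[0, 1]
        assert r > 0.9  # population value w1*w2 = 0.98

    def test_zero_loadings_give_near_zero_connectivity(self):
        from pleioscan import coexpression as cx

        cfg = SimConfig(
            n_chromosomes=1, chromosome_length=5_000_000, n_genes=60,
            n_samples=200, n_modules=5, loading_low=0.0, loading_high=0.0,
            hub_effect=0.0, prop_parallel=0.0, prop_single=0.0, seed=9,
        )
        truth = sim.make_truth(cfg)
        expr, _ = sim.simulate_expression(truth, cfg)
        logm = cx.preprocess_expression(expr, variance_quantile=0.0)
        k = cx.total_connectivity(logm, 6)
        assert k.mean() < 0.05

    def test_null_hub_effect_equal_window_connectivity(self):
        from pleioscan import coexpression as cx

        diffs = []
        for seed in range(10):
            cfg = SimConfig(
                n_chromosomes=1, chromosome_length=5_000_000, n_genes=400,
                n_samples=30, n_modules=8, hub_effect=0.0, seed=seed,
            )
            truth = sim.make_truth(cfg)
            expr, genes = sim.simulate_expression(truth, cfg)
            logm = cx.preprocess_expression(expr)
            k = cx.total_connectivity(logm, 6)
            wc = cx.window_connectivity(k, genes, cfg.grid())
            par = (truth["true_class"] == "parallel").to_numpy()
            diffs.append(np.nanmean(wc[par]) - np.nanmean(wc[~par]))
        # class difference consistent with zero across replicates
        from scipy import stats

        assert stats.ttest_1samp(diffs, 0.0).pvalue > 0.01

    def test_hub_effect_overflow_rejected(self):
        with pytest.raises(ValueError, match="loading"):
            SimConfig(loading_high=0.99, hub_effect=0.02)


class TestSimulateTracks:
    def test_ds_truncation_bounds(self, tiny_config):
        truth = sim.make_truth(tiny_config)
        _, ds_frame, _ = sim.simulate_tracks(truth, tiny_config)
        assert ((ds_frame["ds"] > 0) & (ds_frame["ds"] < 2)).all()

    def test_map_monotone_and_mean_rate(self, tiny_config):
        truth = sim.make_truth(tiny_config)
        gmap, _, _ = sim.simulate_tracks(truth, tiny_config)
        for _, grp in gmap.groupby("chrom"):
            assert (np.diff(grp["cM"]) >= 0).all()
        total_cm = gmap.groupby("chrom")["cM"].max().sum()
        total_mbp = tiny_config.n_chromosomes * tiny_config.chromosome_length / 1e6
        assert total_cm / total_mbp == pytest.approx(4.0, rel=0.4)

    def test_gene_count_mean_close_to_target(self):
        cfg = SimConfig(n_chromosomes=1, chromosome_length=50_000_000, seed=4)
        truth = sim.make_truth(cfg)
        _, _, genes = sim.simulate_tracks(truth, cfg)
        mean = len(genes) / cfg.n_windows
        assert mean == pytest.approx(3.1, abs=0.2)

    def test_fixture_files_byte_identical_across_writes(self, tiny_config, tmp_path):
        truth = sim.make_truth(tiny_config)
        for sub in ("a", "b"):
            d = tmp_path / sub
            d.mkdir()
            ds = sim.simulate_genotypes(truth, tiny_config)
            ds.write_counts_tsv(d / "counts.tsv")
            ds.write_vcf(d / "vcf")
            sim.write_truth_tsv(truth, d / "truth.tsv")
        for name in ("counts.tsv", "truth.tsv", "vcf/pair01.vcf"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_truth_tsv_roundtrip(self, tiny_config, tmp_path):
        truth = sim.make_truth(tiny_config)
        sim.write_truth_tsv(truth, tmp_path / "truth.tsv")
        back = sim.read_truth_tsv(tmp_path / "truth.tsv")
        assert (back["true_class"] == truth["true_class"]).all()
        assert (back["selected_pairs"] == truth["selected_pairs"]).all()
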