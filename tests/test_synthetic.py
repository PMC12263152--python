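"""Generator contracts: determinism, planted structure, filter decoys."""

import dataclasses
import math

import numpy as np
import pytest

from scoliogen import snp2gene as s2g
from scoliogen.synthetic import (
    SimConfig,
    TraceParams,
    TrajectoryParams,
    case_carrier_rate,
    gen_bilateral_traces,
    gen_cohort,
    gen_gene_models,
    gen_gwas_inputs,
    gen_trajectory,
)
from scoliogen.weighting import AF_MAX, assign_weights, compute_gene_burden, filter_ultra_rare


class TestGeneModels:
    def test_minimal_case(self):
        cfg = SimConfig(seed=0, n_genes=1, causal_gene="G0001")
        (gene,) = gen_gene_models(cfg)
        assert gene.end > gene.start

    def test_determinism(self, small_cfg):
        assert gen_gene_models(small_cfg) == gen_gene_models(small_cfg)

    def test_spans_pairwise_disjoint(self):
        cfg = SimConfig(seed=1, n_genes=50, causal_gene="G0001")
        genes = gen_gene_models(cfg)
        assert len(genes) == 50
        # brute-force pairwise interval sweep
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                a, b = genes[i], genes[j]
                assert a.end <= b.start or b.end <= a.start

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimConfig(target_or=-1)
        with pytest.raises(ValueError):
            SimConfig(baseline_carrier_rate=1.5)


class TestGwasInputs:
    def test_block_size_one_means_no_ld(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, ld_block_size=1)
        genes = gen_gene_models(cfg)
        snps, ld, _, _ = gen_gwas_inputs(cfg, genes)
        assert ld.pairs() == {}
        sig = [s for s in snps if s.pvalue < 5e-8]
        pruned = s2g.prune_independent(sig, ld)
        assert pruned == sorted(sig, key=lambda s: (s.pvalue, s.rsid))

    def test_planted_eqtl_recovers_causal_gene(self, small_cfg):
        genes = gen_gene_models(small_cfg)
        snps, ld, eqtls, _ = gen_gwas_inputs(small_cfg, genes)
        sig = [s for s in snps if s.pvalue < 5e-8]
        block = s2g.expand_to_blocks(s2g.prune_independent(sig, ld), snps, ld)
        mapped = s2g.map_eqtl(block, eqtls)
        assert small_cfg.causal_gene in mapped

    def test_decoy_interactions_never_map(self, small_cfg):
        genes = gen_gene_models(small_cfg)
        snps, _, _, interactions = gen_gwas_inputs(small_cfg, genes)
        decoys = [ia for ia in interactions if ia.fdr > 1e-6]
        assert decoys  # the generator plants sub-threshold decoys
        mapped = s2g.map_chromatin(snps, decoys, genes)
        assert len(mapped) == 0

    def test_determinism(self, small_cfg):
        genes = gen_gene_models(small_cfg)
        a = gen_gwas_inputs(small_cfg, genes)
        b = gen_gwas_inputs(small_cfg, genes)
        assert a[0] == b[0] and a[2] == b[2] and a[3] == b[3]
        assert a[1].pairs() == b[1].pairs()


class TestOddsInversion:
    def test_null_or_keeps_rates_equal(self):
        assert case_carrier_rate(0.01, 1.0) == pytest.approx(0.01)

    def test_closed_form_example(self):
        # odds(p1) = 4 * 0.01/0.99 -> p1 ~ 0.0388
        assert case_carrier_rate(0.01, 4.0) == pytest.approx(0.03883, abs=1e-5)

    def test_brute_force_frequency_estimate(self):
        p1 = case_carrier_rate(0.01, 4.0)
        rng = np.random.default_rng(12345)
        n = 100_000
        carriers = rng.random(n) < p1
        phat = carriers.mean()
        se = math.sqrt(p1 * (1 - p1) / n)
        assert abs(phat - p1) < 4 * se

    def test_degenerate_rate_rejected(self):
        with pytest.raises(ValueError):
            case_carrier_rate(1.0, 2.0)


class TestCohort:
    def test_null_or_equal_rates(self):
        cfg = SimConfig(seed=2, n_genes=4, n_cases=3000, n_controls=3000,
                        target_or=1.0, baseline_carrier_rate=0.05,
                        causal_gene="G0001")
        genes = gen_gene_models(cfg)
        variants, geno, pheno = gen_cohort(cfg, genes)
        q = filter_ultra_rare(variants, genotypes=geno)
        bm = compute_gene_burden(geno, assign_weights(q),
                                 genes=[g.gene_id for g in genes])
        carrier = bm.gene_burdens("G0001") > 0
        rate_case = carrier[pheno.status].mean()
        rate_ctrl = carrier[~pheno.status].mean()
        se = math.sqrt(2 * 0.05 * 0.95 / 3000)
        assert abs(rate_case - rate_ctrl) < 4 * se

    def test_af_violating_decoys_removed_by_filter(self, small_cfg):
        genes = gen_gene_models(small_cfg)
        variants, geno, _ = gen_cohort(small_cfg, genes)
        bad_af = [v for v in variants if v.popmax_af > AF_MAX]
        bad_ac = [v for v in variants if v.cohort_ac > 3]
        assert bad_af and bad_ac  # decoys are planted
        kept = {v.variant_id for v in filter_ultra_rare(variants, genotypes=geno)}
        assert not kept & {v.variant_id for v in bad_af + bad_ac}

    def test_burden_from_full_pipeline_determinism(self, small_cfg):
        genes = gen_gene_models(small_cfg)
        v1, g1, p1 = gen_cohort(small_cfg, genes)
        v2, g2, p2 = gen_cohort(small_cfg, genes)
        assert v1 == v2
        assert np.array_equal(g1.counts, g2.counts)
        assert np.array_equal(p1.status, p2.status)

    def test_genotypes_are_allele_counts(self, small_cfg):
        genes = gen_gene_models(small_cfg)
        _, geno, pheno = gen_cohort(small_cfg, genes)
        assert set(np.unique(geno.counts)) <= {0, 1, 2}
        assert pheno.n_cases == small_cfg.n_cases
        assert pheno.n_controls == small_cfg.n_controls


class TestTraces:
    def test_frame_count(self):
        cfg = SimConfig(seed=0, trace_params=TraceParams(fps=10, duration_s=60))
        trace, _ = gen_bilateral_traces(cfg)
        assert trace.time.size == 600

    def test_ground_truth_respects_rates(self):
        cfg = SimConfig(seed=8, trace_params=TraceParams(f_left=0.5, f_right=0.5,
                                                         duration_s=300.0))
        _, truth = gen_bilateral_traces(cfg)
        # Poisson(150) count within 5 sd
        assert abs(truth.left_times.size - 150) < 5 * math.sqrt(150)

    def test_determinism(self, small_cfg):
        t1, e1 = gen_bilateral_traces(small_cfg)
        t2, e2 = gen_bilateral_traces(small_cfg)
        assert np.array_equal(t1.left, t2.left)
        assert np.array_equal(e1.left_times, e2.left_times)

    def test_intensities_positive(self, small_cfg):
        trace, _ = gen_bilateral_traces(small_cfg)
        assert trace.left.min() > 0 and trace.right.min() > 0


class TestTrajectory:
    def test_zero_bias_zero_noise_is_straight(self):
        cfg = SimConfig(
            seed=0, trajectory_params=TrajectoryParams(n_steps=10, noise_sd_deg=0.0)
        )
        traj = gen_trajectory(cfg, turn_bias_deg_per_step=0.0)
        assert np.allclose(traj["y"], 0.0)
        assert np.all(np.diff(traj["x"]) > 0)

    def test_constant_bias_square_like_path(self):
        from scoliogen.coordination import turning_statistics

        cfg = SimConfig(
            seed=0, trajectory_params=TrajectoryParams(n_steps=5, noise_sd_deg=0.0)
        )
        traj = gen_trajectory(cfg, turn_bias_deg_per_step=90.0)
        s = turning_statistics(traj)
        assert s.relative_angle_deg == pytest.approx(360.0)

    def test_mean_turn_matches_bias(self):
        from scoliogen.coordination import turning_statistics

        cfg = SimConfig(
            seed=4,
            trajectory_params=TrajectoryParams(n_steps=1000, noise_sd_deg=1.0),
        )
        traj = gen_trajectory(cfg, turn_bias_deg_per_step=5.0)
        s = turning_statistics(traj)
        mean_turn = s.relative_angle_deg / s.n_turns
        se = 1.0 / math.sqrt(s.n_turns)
        assert abs(mean_turn - 5.0) < 3 * se
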