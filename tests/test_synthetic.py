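"""Generator checks: Hardy-Weinberg genotypes, liability model, label noise, I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from genesieve.association import EncodedMatrix
from genesieve.synthetic import (
    CohortConfig,
    contiguous_topology,
    draw_mafs,
    inject_label_noise,
    sample_genotypes,
    simulate_cohort,
    simulate_phenotype,
    write_cohort,
)
from genesieve.vcfqc import read_vcf, run_qc


class TestSampleGenotypes:
    def test_hwe_proportions_pass_goodness_of_fit(self):
        # maf 0.2 -> expected genotype frequencies (0.64, 0.32, 0.04)
        g = sample_genotypes([0.2], n_samples=10_000, seed=7)
        expected = np.array([0.64, 0.32, 0.04]) * 10_000
        observed = np.bincount(g.values[:, 0], minlength=3)
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01
        # pooled across several variants the fit should be even tighter
        g5 = sample_genotypes(np.full(5, 0.2), n_samples=10_000, seed=8)
        pooled = np.bincount(g5.values.ravel(), minlength=3)
        _, p = stats.chisquare(pooled, expected * 5)
        assert p > 0.01

    def test_symmetric_maf_half(self):
        g = sample_genotypes([0.5], n_samples=20_000, seed=0)
        freqs = np.bincount(g.values[:, 0], minlength=3) / 20_000
        assert np.allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)

    def test_vanishing_maf_gives_all_reference(self):
        g = sample_genotypes([1e-9], n_samples=500, seed=0)
        assert (g.values == 0).all()

    @pytest.mark.parametrize("bad", [0.0, -0.1, 0.6, 1.0])
    def test_maf_outside_range_rejected(self, bad):
        with pytest.raises(ValueError):
            sample_genotypes([bad], n_samples=10, seed=0)

    def test_same_seed_bit_identical(self):
        a = sample_genotypes([0.1, 0.3], 100, seed=5)
        b = sample_genotypes([0.1, 0.3], 100, seed=5)
        assert np.array_equal(a.values, b.values)


class TestMafSpectrum:
    def test_log_uniform_within_bounds(self, rng):
        maf = draw_mafs(5000, 0.005, 0.5, rng)
        assert maf.min() >= 0.005 and maf.max() <= 0.5
        # log-uniform: median of log(maf) near the midpoint of the log-range
        mid = (np.log(0.005) + np.log(0.5)) / 2
        assert abs(np.median(np.log(maf)) - mid) < 0.1


class TestLiabilityModel:
    def test_null_effects_give_pure_noise_liability(self):
        cfg = CohortConfig(n_cases=50, n_controls=50, n_variants=40, n_genes=10,
                           n_causal_genes=5, effect_sd=0.0, seed=2)
        g = sample_genotypes(np.full(40, 0.3), 400, seed=2)
        topo = contiguous_topology(40, 10, variant_ids=g.variant_ids)
        truth = simulate_phenotype(g, topo, cfg)
        assert np.allclose(truth.genetic_liability, 0.0)

    def test_prevalence_half_threshold_is_median(self):
        cfg = CohortConfig(n_cases=50, n_controls=50, n_variants=40, n_genes=10,
                           n_causal_genes=5, prevalence=0.5, seed=2)
        g = sample_genotypes(np.full(40, 0.3), 1000, seed=2)
        topo = contiguous_topology(40, 10, variant_ids=g.variant_ids)
        truth = simulate_phenotype(g, topo, cfg)
        assert truth.threshold == pytest.approx(np.median(truth.liability))
        assert abs(truth.true_label.mean() - 0.5) < 0.01

    def test_strong_effects_make_genetics_predictive(self, small_cohort):
        auc = roc_auc_score(small_cohort.truth.true_label,
                            small_cohort.truth.genetic_liability)
        assert auc > 0.9

    def test_pool_too_small_raises(self):
        cfg = CohortConfig(n_cases=50, n_controls=50, n_variants=40, n_genes=10,
                           n_causal_genes=5, prevalence=0.3, seed=2)
        g = sample_genotypes(np.full(40, 0.3), 60, seed=2)
        topo = contiguous_topology(40, 10, variant_ids=g.variant_ids)
        truth = simulate_phenotype(g, topo, cfg)
        with pytest.raises(ValueError, match="enlarge"):
            inject_label_noise(truth, 0.1, 0.0, seed=1, n_cases=50, n_controls=50)


class TestLabelNoise:
    def _truth(self, n=2000, seed=4):
        cfg = CohortConfig(n_cases=10, n_controls=10, n_variants=40, n_genes=10,
                           n_causal_genes=5, prevalence=0.4, seed=seed)
        g = sample_genotypes(np.full(40, 0.3), n, seed=seed)
        topo = contiguous_topology(40, 10, variant_ids=g.variant_ids)
        return simulate_phenotype(g, topo, cfg)

    def test_zero_rates_identity(self):
        truth = self._truth()
        cohort, _ = inject_label_noise(truth, 0.0, 0.0, seed=1,
                                       n_cases=300, n_controls=500)
        assert not cohort.flipped.any()
        assert np.array_equal(cohort.true_label, cohort.observed_label)
        assert (cohort.observed_label == 1).sum() == 300
        assert (cohort.observed_label == 0).sum() == 500

    @pytest.mark.parametrize(
        "rate,pool,expected",
        [(0.19, 4969, 944), (0.0034, 6245, 21), (0.10, 1200, 120)],
    )
    def test_flip_counts_round_rate_times_pool(self, rate, pool, expected):
        assert int(np.rint(rate * pool)) == expected

    def test_flipped_mask_is_label_xor_and_counts_exact(self):
        truth = self._truth()
        cohort, _ = inject_label_noise(truth, 0.10, 0.02, seed=9,
                                       n_cases=300, n_controls=400)
        assert np.array_equal(cohort.flipped,
                              cohort.true_label != cohort.observed_label)
        case_pool = cohort.observed_label == 1
        ctrl_pool = cohort.observed_label == 0
        assert cohort.flipped[case_pool].sum() == 30   # round(0.10 * 300)
        assert cohort.flipped[ctrl_pool].sum() == 8    # round(0.02 * 400)
        # flipped members of the case pool are genetically controls
        assert (cohort.true_label[case_pool & cohort.flipped] == 0).all()

    def test_bad_rate_rejected(self):
        truth = self._truth()
        with pytest.raises(ValueError):
            inject_label_noise(truth, 1.5, 0.0, seed=0, n_cases=10, n_controls=10)


class TestSimulateCohort:
    def test_same_seed_bit_identical_cohort(self):
        cfg = CohortConfig(n_cases=100, n_controls=100, n_variants=60, n_genes=20,
                           n_causal_genes=5, seed=11)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert np.array_equal(a.genotypes.values, b.genotypes.values)
        assert a.genotypes.sample_ids == b.genotypes.sample_ids
        assert np.array_equal(a.truth.observed_label, b.truth.observed_label)
        assert np.array_equal(a.truth.flipped, b.truth.flipped)
        assert a.topology.table.equals(b.topology.table)

    def test_pool_sizes_and_composition(self, small_cohort):
        t = small_cohort.truth
        assert (t.observed_label == 1).sum() == 300 * 0 + small_cohort.config.n_cases
        assert t.flipped.sum() == round(0.10 * small_cohort.config.n_cases)
        assert t.flipped[t.observed_label == 0].sum() == 0


class TestContiguousTopology:
    def test_block_assignment_formula(self):
        topo = contiguous_topology(10, 4)
        expected = (np.arange(10) * 4) // 10
        assert np.array_equal(topo.gene_index, expected)

    def test_permuted_assignment_preserves_block_sizes(self):
        plain = contiguous_topology(50, 7)
        perm = contiguous_topology(50, 7, permute=True, seed=3)
        assert sorted(np.bincount(plain.gene_index)) == sorted(np.bincount(perm.gene_index))
        perm.validate()


class TestWriteCohort:
    def test_vcf_round_trip_recovers_genotypes(self, tmp_path):
        values = np.array([[0, 1, 2, -1, 0], [2, 0, 1, 1, -1]] * 5, dtype=np.int8)
        geno = EncodedMatrix(values=values,
                             sample_ids=[f"S{i}" for i in range(10)],
                             variant_ids=[f"v{j}" for j in range(5)])
        topo = contiguous_topology(5, 2, variant_ids=geno.variant_ids)
        truth_labels = np.array([1, 0] * 5, dtype=np.int8)
        from genesieve.synthetic import CohortTruth
        truth = CohortTruth(
            sample_ids=geno.sample_ids,
            true_label=truth_labels, observed_label=truth_labels.copy(),
            flipped=np.zeros(10, bool),
            liability=np.zeros(10), genetic_liability=np.zeros(10),
            causal_gene_ids=[], gene_effects=np.zeros(2),
        )
        paths = write_cohort(geno, truth, topo, tmp_path / "toy", seed=0)
        cohort = read_vcf(paths["vcf"])
        assert cohort.sample_ids == geno.sample_ids
        from genesieve.association import encode_additive
        enc = encode_additive(cohort.records, cohort.sample_ids)
        assert np.array_equal(enc.values, values)
        pheno = pd.read_csv(paths["phenotypes"], sep="\t")
        assert np.array_equal(pheno["label"].to_numpy(), truth_labels)

    def test_default_depths_survive_qc_and_low_dp_sites_are_removed(self, tmp_path):
        cfg = CohortConfig(n_cases=30, n_controls=30, n_variants=50, n_genes=10,
                           n_causal_genes=3, seed=6)
        sim = simulate_cohort(cfg)
        clean = write_cohort(sim.genotypes, sim.truth, sim.topology,
                             tmp_path / "clean", seed=1)
        cohort, log = run_qc(read_vcf(clean["vcf"]))
        assert len(cohort.records) == 50  # thresholds untriggered

        noisy = write_cohort(sim.genotypes, sim.truth, sim.topology,
                             tmp_path / "noisy", low_dp_fraction=0.10, seed=1)
        cohort, log = run_qc(read_vcf(noisy["vcf"]))
        dropped = set(log.loc[log["verdict"] == "drop", "variant_id"])
        assert dropped == set(noisy["low_dp_variants"])
        assert len(noisy["low_dp_variants"]) == 5
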