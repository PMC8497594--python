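"""The synthetic-data generator: determinism, recovery of its own parameters."""

import numpy as np
import pytest

from wgdkit.divergence import estimate_ka_ks_codons
from wgdkit.popgen import diversity_summary
from wgdkit.seqalign import translate_cds
from wgdkit.simulate import (
    CoverageModel,
    SimulationConfig,
    evolve_codon_sequence,
    random_cds,
    simulate_coalescent_sample,
    simulate_coverage_and_labels,
    simulate_family_ages,
    simulate_wgd_dataset,
)


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(class_proportions={"drought_up": 0.5, "background": 0.6})

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError):
            SimulationConfig(retention_prob={"drought_up": 1.4, "background": 0.5})

    def test_wgd_ks_below_outgroup_ks(self):
        with pytest.raises(ValueError, match="outgroup_ks"):
            SimulationConfig(wgd_ks=1.2, outgroup_ks=1.0)

    def test_required_classes(self):
        with pytest.raises(ValueError, match="drought_up"):
            SimulationConfig(
                class_proportions={"a": 1.0},
                retention_prob={"a": 0.5},
                omega={"a": 0.2},
            )


class TestEvolveCodonSequence:
    def test_zero_divergence_is_identity(self, rng):
        cds = random_cds(50, rng)
        assert evolve_codon_sequence(cds, 0.0, 0.2, rng) == cds

    def test_no_internal_stops_ever(self, rng):
        from wgdkit.codons import validate_cds

        cds = random_cds(100, rng)
        for _ in range(5):
            cds = evolve_codon_sequence(cds, 0.5, 1.0, rng)
            validate_cds(cds)

    def test_purifying_limit_preserves_protein(self, rng):
        cds = random_cds(200, rng)
        out = evolve_codon_sequence(cds, 0.4, 0.0, rng)
        assert translate_cds(out) == translate_cds(cds)

    def test_large_sequence_recovers_ks_and_omega(self):
        rng = np.random.default_rng(42)
        cds = random_cds(10_000, rng)
        out = evolve_codon_sequence(cds, 0.3, 0.2, rng)
        est = estimate_ka_ks_codons(
            [cds[i : i + 3] for i in range(0, len(cds), 3)],
            [out[i : i + 3] for i in range(0, len(out), 3)],
        )
        assert est.ks == pytest.approx(0.3, abs=0.03)
        assert est.omega == pytest.approx(0.2, abs=0.05)

    def test_stop_codon_input_rejected(self, rng):
        with pytest.raises(ValueError, match="stop"):
            evolve_codon_sequence("ATGTAAAAA", 0.1, 0.2, rng)


class TestSimulateWgdDataset:
    def test_fixed_seed_reproduces_everything(self):
        cfg = SimulationConfig(seed=11, n_ancestral_genes=60)
        d1, d2 = simulate_wgd_dataset(cfg), simulate_wgd_dataset(cfg)
        assert d1.ingroup_cds == d2.ingroup_cds
        assert d1.outgroup_cds == d2.outgroup_cds
        assert d1.hits.equals(d2.hits)
        assert d1.ingroup_genes.equals(d2.ingroup_genes)
        assert d1.truth.genes.equals(d2.truth.genes)

    def test_full_retention_maps_every_gene_twice(self, full_retention_dataset):
        d = full_retention_dataset
        assert len(d.truth.pairs) == len(d.outgroup_genes)
        per_subject = d.hits.groupby("subject").size()
        assert (per_subject == 2).all()

    def test_zero_retention_single_copies(self):
        cfg = SimulationConfig(
            seed=5,
            n_ancestral_genes=80,
            retention_prob={"drought_up": 0.0, "background": 0.0},
            tandem_rate=0.0,
            decoy_hit_rate=0.0,
        )
        d = simulate_wgd_dataset(cfg)
        assert len(d.truth.pairs) == 0
        assert len(d.ingroup_genes) == 80

    def test_realized_retention_within_binomial_error(self):
        cfg = SimulationConfig(
            seed=21,
            n_ancestral_genes=2000,
            retention_prob={"drought_up": 0.8, "background": 0.5},
        )
        d = simulate_wgd_dataset(cfg)
        g = d.truth.genes
        for cls, p in (("drought_up", 0.8), ("background", 0.5)):
            sub = g[g["class"] == cls]
            se = np.sqrt(p * (1 - p) / len(sub))
            assert abs(sub["retained"].mean() - p) < 3 * se

    def test_every_gene_appears_once_in_truth(self, small_dataset):
        g = small_dataset.truth.genes
        assert g["ancestral_id"].is_unique
        assert len(g) == small_dataset.config.n_ancestral_genes

    def test_retained_pairs_reference_existing_genes(self, small_dataset):
        d = small_dataset
        for pr in d.truth.pairs.itertuples(index=False):
            assert pr.dup1 in d.ingroup_cds and pr.dup2 in d.ingroup_cds


class TestSimulateFamilyAges:
    def test_zero_sd_gives_constant_ages(self, rng):
        ages = simulate_family_ages(66.0, 10, 0.0, rng)
        assert np.allclose(ages.medians, 66.0)

    def test_mean_age_within_clt_bound(self):
        ages = simulate_family_ages(66.0, 204, 3.0, np.random.default_rng(8))
        assert abs(ages.medians.mean() - 66.0) < 3 * 3.0 / np.sqrt(204)

    def test_all_ages_positive(self, rng):
        ages = simulate_family_ages(2.0, 500, 5.0, rng)
        assert (ages.medians > 0).all()

    def test_too_few_families_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_family_ages(66.0, 1, 3.0, rng)


class TestSimulateCoalescent:
    def test_determinism(self):
        m1 = simulate_coalescent_sample(10, 5.0, 500, np.random.default_rng(4))
        m2 = simulate_coalescent_sample(10, 5.0, 500, np.random.default_rng(4))
        assert np.array_equal(m1, m2)

    def test_columns_are_biallelic_01(self, rng):
        m = simulate_coalescent_sample(12, 8.0, 300, rng)
        assert set(np.unique(m)) <= {0, 1}

    def test_tiny_theta_limit(self, rng):
        m = simulate_coalescent_sample(10, 1e-9, 200, rng)
        assert m.sum() == 0

    def test_n_below_two_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_coalescent_sample(1, 5.0, 100, rng)

    def test_mean_segregating_sites_matches_watterson(self):
        # E[S] = theta * a1; independent check of the whole tree+mutation layer
        theta, n, reps = 5.0, 20, 400
        a1 = sum(1.0 / i for i in range(1, n))
        rng = np.random.default_rng(17)
        s = [diversity_summary(simulate_coalescent_sample(n, theta, 2000, rng)).S for _ in range(reps)]
        se = np.std(s, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(s) - theta * a1) < 3 * se

    def test_mean_segregating_sites_matches_msprime_oracle(self):
        # same quantity from the field-standard coalescent simulator
        import msprime

        theta, n, reps = 5.0, 20, 400
        rng = np.random.default_rng(23)
        mine = np.mean([simulate_coalescent_sample(n, theta, 2000, rng).sum(axis=0).astype(bool).sum() for _ in range(reps)])
        # n haploid lineages on the standard coalescent time scale: n/2
        # diploid samples with N = 1/2 (pairwise coalescence rate 1)
        anc = msprime.sim_ancestry(
            samples=n // 2, ploidy=2, population_size=0.5, num_replicates=reps, random_seed=5
        )
        ref = []
        for i, ts in enumerate(anc):
            mts = msprime.sim_mutations(ts, rate=theta / 2.0, discrete_genome=False, random_seed=10 + i)
            ref.append(mts.num_sites)
        combined_se = np.sqrt(np.var(ref) / reps * 2)
        assert abs(mine - np.mean(ref)) < 4 * combined_se


class TestCoverageAndLabels:
    def _genes(self, n=400):
        import pandas as pd

        rng = np.random.default_rng(3)
        cls = rng.choice(["drought_up", "background"], size=n, p=[0.2, 0.8])
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)], "class": cls})

    def test_fractions_in_unit_interval(self, rng):
        cov, labels = simulate_coverage_and_labels(self._genes(), 5, SimulationConfig(), rng)
        assert ((cov.to_numpy() >= 0) & (cov.to_numpy() <= 1)).all()

    def test_up_labels_follow_class_rates(self):
        genes = self._genes(4000)
        cfg = SimulationConfig(de_rates={"drought_up": 0.3, "background": 0.04})
        cov, labels = simulate_coverage_and_labels(genes, 3, cfg, np.random.default_rng(9))
        merged = genes.merge(labels, on="gene_id")
        up = merged.groupby("class")["direction"].apply(lambda s: (s == "up").mean())
        assert up["drought_up"] == pytest.approx(0.3, abs=0.05)
        assert up["background"] == pytest.approx(0.04, abs=0.02)

    def test_degenerate_ambiguity_all_present(self, rng):
        from wgdkit.popgen import gene_presence_filter

        cfg = SimulationConfig(
            coverage_model=CoverageModel(absent_rate=0.0, ambiguity_alpha=1e-4, ambiguity_beta=100)
        )
        cov, _ = simulate_coverage_and_labels(self._genes(50), 4, cfg, rng)
        presence, conserved = gene_presence_filter(cov)
        assert len(conserved) == 50
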