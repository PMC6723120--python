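"""Generator contracts: determinism, LD structure, Mendelian inheritance,
eQTL architecture, and trait heritability."""

import numpy as np
import pandas as pd
import pytest

from ensemblemap.covariates import compute_kinship, compute_mds_pcs
from ensemblemap.simulate import (
    SimulationConfig,
    apply_trait_to_panel,
    place_genes,
    simulate_expression,
    simulate_nam_families,
    simulate_panel,
    simulate_trait,
)


def _adjacent_r2(panel, max_pairs=1000):
    """Squared correlation between adjacent polymorphic variants."""
    d = panel.dosages
    keep = d.std(axis=0) > 0
    chrom = panel.variants["chrom"].to_numpy()
    r2 = []
    for j in range(panel.n_variants - 1):
        if len(r2) >= max_pairs:
            break
        if chrom[j] != chrom[j + 1] or not (keep[j] and keep[j + 1]):
            continue
        r2.append(np.corrcoef(d[:, j], d[:, j + 1])[0, 1] ** 2)
    return np.array(r2)


class TestPanel:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(seed=5, n_panel=40, n_variants=200, n_genes=20)
        p1, l1 = simulate_panel(cfg)
        p2, l2 = simulate_panel(cfg)
        np.testing.assert_array_equal(p1.dosages, p2.dosages)
        pd.testing.assert_series_equal(l1, l2)

    def test_fully_inbred(self):
        cfg = SimulationConfig(seed=6, n_panel=30, n_variants=150, n_genes=15)
        panel, _ = simulate_panel(cfg)
        assert set(np.unique(panel.dosages)) <= {0.0, 2.0}

    def test_free_recombination_kills_adjacent_ld(self):
        cfg = SimulationConfig(seed=7, n_panel=200, n_variants=1200, n_genes=20,
                               recomb_prob=0.5, n_subpopulations=1, fst=0.0)
        panel, _ = simulate_panel(cfg)
        r2 = _adjacent_r2(panel)
        assert len(r2) >= 500
        assert np.mean(r2) < 0.05

    def test_zero_recombination_copies_founder_haplotypes(self):
        cfg = SimulationConfig(seed=8, n_panel=60, n_variants=200, n_genes=10,
                               recomb_prob=0.0, n_subpopulations=1, fst=0.0,
                               n_founders=8)
        panel, _ = simulate_panel(cfg)
        for chrom in panel.variants["chrom"].unique():
            cols = (panel.variants["chrom"] == chrom).to_numpy()
            haplotypes = {tuple(row) for row in panel.dosages[:, cols]}
            assert len(haplotypes) <= cfg.n_founders

    def test_mds_separates_divergent_subpopulations(self):
        cfg = SimulationConfig(seed=9, n_panel=100, n_variants=500, n_genes=20,
                               n_subpopulations=2, fst=0.3)
        panel, labels = simulate_panel(cfg)
        pcs = compute_mds_pcs(panel, k=2)
        codes = (labels == labels.unique()[0]).astype(float).to_numpy()
        r = np.corrcoef(pcs["PC1"].to_numpy(), codes)[0, 1]
        assert abs(r) > 0.9

    def test_too_few_variants_rejected(self):
        with pytest.raises(ValueError, match="variants"):
            simulate_panel(SimulationConfig(seed=1, n_variants=10, n_genes=20))


class TestNamFamilies:
    @staticmethod
    @pytest.fixture(scope="class")
    def nam():
        cfg = SimulationConfig(seed=10, n_panel=20, n_variants=400, n_genes=20,
                               n_families=3, n_per_family=200)
        founders, _ = simulate_panel(cfg)
        panel, fams = simulate_nam_families(cfg, founders)
        return cfg, founders, panel, fams

    def test_offspring_dosage_is_one_parent_dosage(self, nam):
        cfg, founders, panel, fams = nam
        common = founders.dosages[0]
        for f in range(cfg.n_families):
            other = founders.dosages[f + 1]
            rows = (fams == f"fam{f + 1:02d}").to_numpy()
            kids = panel.dosages[rows]
            ok = (kids == common) | (kids == other)
            assert ok.all()

    def test_parents_identical_means_offspring_fixed(self, nam):
        cfg, founders, panel, fams = nam
        same = founders.dosages[0] == founders.dosages[1]
        rows = (fams == "fam01").to_numpy()
        kids = panel.dosages[np.ix_(rows, same)]
        np.testing.assert_array_equal(kids, np.tile(founders.dosages[0][same], (rows.sum(), 1)))

    def test_segregating_sites_near_half_frequency(self, nam):
        cfg, founders, panel, fams = nam
        seg = founders.dosages[0] != founders.dosages[1]
        rows = (fams == "fam01").to_numpy()
        freq = panel.dosages[np.ix_(rows, seg)].mean(axis=0) / 2.0
        # binomial: sd of per-site frequency is 0.5/sqrt(200) ~ 0.035
        assert abs(freq.mean() - 0.5) < 0.02
        assert (np.abs(freq - 0.5) < 5 * 0.5 / np.sqrt(cfg.n_per_family)).mean() > 0.99

    def test_within_family_kinship_exceeds_cross_family(self, nam):
        cfg, founders, panel, fams = nam
        k = compute_kinship(panel).values
        same = (fams.to_numpy()[:, None] == fams.to_numpy()[None, :])
        off_diag = ~np.eye(len(fams), dtype=bool)
        assert k[same & off_diag].mean() > k[~same].mean()

    def test_family_labels_partition(self, nam):
        cfg, founders, panel, fams = nam
        assert len(fams) == panel.n_individuals
        assert sorted(fams.value_counts()) == [cfg.n_per_family] * cfg.n_families

    def test_non_inbred_founders_rejected(self, nam):
        cfg, founders, panel, fams = nam
        het = founders.dosages.copy()
        het[0, 0] = 1.0
        from ensemblemap.containers import GenotypePanel
        bad = GenotypePanel(founders.individuals,
                            founders.variants.drop(columns="maf"), het)
        with pytest.raises(ValueError, match="inbred"):
            simulate_nam_families(cfg, bad)


class TestExpression:
    def test_null_genes_uncorrelated_with_genotype(self):
        cfg = SimulationConfig(seed=11, n_panel=100, n_variants=300, n_genes=20,
                               cis_eqtl_effect_size=0.0, n_hidden_confounders=0,
                               subpop_expr_shift_sd=0.0, n_tissues=1,
                               dropout_rate=0.0, frac_low_expressed=0.0)
        panel, subpops = simulate_panel(cfg)
        genes = place_genes(cfg)
        tensor, cis, _ = simulate_expression(cfg, panel, genes, subpops)
        assert np.abs(cis).max() == 0.0
        x = tensor.matrix("kernel").to_numpy()
        d = panel.imputed_dosages()
        keep = d.std(axis=0) > 0
        zd = (d[:, keep] - d[:, keep].mean(0)) / d[:, keep].std(0)
        zx = (x.T - x.T.mean(0)) / x.T.std(0)
        r = zx.T @ zd / cfg.n_panel
        # Bonferroni-style normal bound for ~20x300 null correlations
        assert np.abs(r).max() < 5.5 / np.sqrt(cfg.n_panel)

    def test_strong_cis_variant_is_top_eqtl(self):
        hits = 0
        n_rep = 20
        for s in range(n_rep):
            cfg = SimulationConfig(seed=100 + s, n_panel=150, n_variants=300,
                                   n_genes=10, n_chromosomes=1,
                                   chrom_length=2_000_000, n_cis_per_gene=1,
                                   cis_eqtl_effect_size=3.0,
                                   n_hidden_confounders=0, n_tissues=1,
                                   subpop_expr_shift_sd=0.0, expr_noise_sd=1.0,
                                   dropout_rate=0.0, frac_low_expressed=0.0)
            panel, subpops = simulate_panel(cfg)
            genes = place_genes(cfg)
            tensor, cis, meta = simulate_expression(cfg, panel, genes, subpops)
            gene = next(g for g in genes if meta["cis_variants"][g.id])
            lead = meta["cis_variants"][gene.id][0][0]
            x = tensor.matrix("kernel").loc[gene.id].to_numpy()
            d = panel.imputed_dosages()
            sd = d.std(axis=0)
            ok = sd > 0
            r = np.abs((x - x.mean()) @ (d[:, ok] - d[:, ok].mean(0))) / (len(x) * x.std() * sd[ok])
            # the founder-copying process can leave a neighbour in perfect LD
            # with the lead variant; a tie at the maximum still counts
            r_lead = r[list(panel.variants["id"].to_numpy()[ok]).index(lead)]
            hits += r_lead >= r.max() - 1e-9
        assert hits >= round(0.95 * n_rep)

    def test_total_dropout_masks_everything(self):
        cfg = SimulationConfig(seed=12, n_panel=30, n_variants=100, n_genes=10,
                               dropout_rate=1.0, n_tissues=2)
        panel, subpops = simulate_panel(cfg)
        genes = place_genes(cfg)
        tensor, _, _ = simulate_expression(cfg, panel, genes, subpops)
        for t in tensor.tissue_names:
            assert tensor.matrix(t).isna().all().all()

    def test_low_expression_mode_fails_half_filter(self):
        from ensemblemap.twas import expression_filter

        cfg = SimulationConfig(seed=13, n_panel=80, n_variants=200, n_genes=40,
                               frac_low_expressed=0.25, dropout_rate=0.0, n_tissues=1)
        panel, subpops = simulate_panel(cfg)
        genes = place_genes(cfg)
        tensor, _, _ = simulate_expression(cfg, panel, genes, subpops)
        eligible = expression_filter(tensor, "kernel")
        assert len(eligible) <= cfg.n_genes - round(0.25 * cfg.n_genes) + 2


class TestTrait:
    def test_zero_heritability_trait_is_pure_noise(self, small_dataset):
        cfg = SimulationConfig(**{**small_dataset["cfg"].to_dict(), "h2_target": 0.0})
        d = small_dataset
        trait, truth = simulate_trait(cfg, d["panel"], d["genes"], d["cis"], d["meta"])
        assert truth.realized_h2 == 0.0
        assert truth.variant_weights.abs().max() == 0.0

    def test_mechanism_labels_partition_causal_set(self, small_dataset):
        truth = small_dataset["truth"]
        cfg = small_dataset["cfg"]
        assert len(truth.causal_genes) == cfg.n_causal_regulatory + cfg.n_causal_coding
        assert not truth.causal_genes["gene"].duplicated().any()
        counts = truth.causal_genes["mechanism"].value_counts()
        assert counts["regulatory"] == cfg.n_causal_regulatory
        assert counts["coding"] == cfg.n_causal_coding

    def test_truth_genes_exist_in_annotation(self, small_dataset):
        ids = {g.id for g in small_dataset["genes"]}
        assert set(small_dataset["truth"].causal_genes["gene"]) <= ids

    def test_variant_weights_reproduce_genetic_component(self, small_dataset):
        """Regressing y on the truth's genetic score gives slope 1 within 2 SE
        and R^2 equal to the recorded realized h2."""
        d = small_dataset
        w = d["truth"].variant_weights.to_numpy()
        dm = d["panel"].imputed_dosages()
        g = (dm - dm.mean(axis=0)) @ w
        y = d["trait"].values.to_numpy()
        slope, intercept = np.polyfit(g, y, 1)
        resid = y - slope * g - intercept
        se = np.sqrt(resid.var() / (len(y) * g.var()))
        assert abs(slope - 1.0) < 2 * se
        assert g.var() / y.var() == pytest.approx(d["truth"].realized_h2, abs=1e-8)

    def test_realized_h2_matches_target_in_expectation(self, small_dataset):
        d = small_dataset
        cfg = d["cfg"]
        vals = []
        for s in range(50):
            _, truth = simulate_trait(cfg, d["panel"], d["genes"], d["cis"],
                                      d["meta"], stream=300 + s)
            vals.append(truth.realized_h2)
        assert abs(np.mean(vals) - cfg.h2_target) < 0.03

    def test_h2_one_without_effects_rejected(self, small_dataset):
        d = small_dataset
        cfg = SimulationConfig(**{**d["cfg"].to_dict(), "h2_target": 1.0,
                                  "n_causal_regulatory": 0, "n_causal_coding": 0,
                                  "polygenic_fraction": 0.0, "n_polygenic": 0})
        with pytest.raises(ValueError, match="causal"):
            simulate_trait(cfg, d["panel"], d["genes"], d["cis"], d["meta"])

    def test_trait_ports_to_other_panel(self, small_dataset):
        d = small_dataset
        cfg = d["cfg"]
        nam, fams = simulate_nam_families(cfg, d["panel"])
        y = apply_trait_to_panel(d["truth"], nam, 0.5, seed=1, name="t")
        assert list(y.values.index) == nam.individuals
        # deterministic given seed
        y2 = apply_trait_to_panel(d["truth"], nam, 0.5, seed=1, name="t")
        pd.testing.assert_series_equal(y.values, y2.values)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"h2_target": 1.5},
        {"n_causal_regulatory": 400, "n_causal_coding": 200},
        {"recomb_prob": 2.0},
        {"n_panel": -1},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, **kw)
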