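import numpy as np
import pytest
from scipy import stats as sps

from pathgsea import assoc as asc
from pathgsea.errors import ConfigurationError
from pathgsea.simulate import (
    SimulationConfig,
    causal_effects,
    simulate_gene_architecture,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_study,
    write_study,
)
from pathgsea.snp2gene import map_snps_to_genes


def small(**kw):
    base = dict(n_individuals=100, n_snps=200, n_genes=40, n_sets=5,
                set_size_range=(5, 10), seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(n_snps=0),
        dict(n_genes=0),
        dict(n_individuals=-1),
        dict(maf_range=(0.0, 0.3)),
        dict(maf_range=(0.2, 0.6)),
        dict(set_size_range=(0, 5)),
        dict(set_size_range=(5, 100)),  # max > n_genes=40
        dict(missing_rate=1.0),
        dict(n_causal_genes=50),
        dict(n_causal_genes=3, causal_set_index=99),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            small(**kw).validate()


class TestGenotypes:
    def test_zero_individuals_empty_matrix_intact_map(self):
        gm = simulate_genotypes(small(n_individuals=0))
        assert gm.dosage.shape[0] == 0
        assert gm.n_snps == 200
        assert len(gm.pos) == 200

    def test_allele_frequency_matches_target(self):
        cfg = small(n_individuals=10_000, n_snps=1, n_genes=1,
                    intergenic_fraction=0.0, set_size_range=(1, 1),
                    maf_range=(0.5, 0.5), missing_rate=0.0)
        gm = simulate_genotypes(cfg)
        f = gm.dosage.mean() / 2
        assert abs(f - 0.5) < 0.015  # 3 binomial SEs

    def test_seed_determinism(self):
        g1 = simulate_genotypes(small(seed=42))
        g2 = simulate_genotypes(small(seed=42))
        np.testing.assert_array_equal(g1.dosage, g2.dosage)
        assert g1.snp_ids.tolist() == g2.snp_ids.tolist()

    def test_positions_strictly_increasing_per_chromosome(self):
        gm = simulate_genotypes(small(n_snps=500))
        for c in np.unique(gm.chrom):
            assert (np.diff(gm.pos[gm.chrom == c]) > 0).all()

    def test_missing_rate(self):
        gm = simulate_genotypes(small(n_individuals=500, missing_rate=0.05))
        frac = np.isnan(gm.dosage).mean()
        assert abs(frac - 0.05) < 0.01

    def test_hwe_holds_at_nominal_rate(self):
        cfg = SimulationConfig(n_individuals=2000, n_snps=4000, n_genes=400,
                               n_sets=2, set_size_range=(5, 10),
                               missing_rate=0.0, seed=9)
        gm = simulate_genotypes(cfg)
        p = asc.hwe_bulk(gm.dosage)
        frac = (p < 0.001).mean()
        assert frac < 0.005  # nominal 0.001 plus sampling noise


class TestArchitecture:
    def test_forced_set_size(self):
        cfg = small(n_sets=1, set_size_range=(5, 5))
        _, sets = simulate_gene_architecture(cfg)
        assert len(sets[0].members) == 5

    def test_set_sizes_within_range(self):
        genes, sets = simulate_gene_architecture(
            SimulationConfig(seed=1))
        for s in sets:
            assert 5 <= len(s.members) <= 50
            assert len(set(s.members)) == len(s.members)

    def test_set_members_exist_in_annotation(self):
        genes, sets = simulate_gene_architecture(small(seed=2))
        universe = set(genes.gene_ids)
        for s in sets:
            assert set(s.members) <= universe

    def test_intergenic_fraction_one_means_no_mapping(self):
        cfg = small(intergenic_fraction=1.0)
        gm = simulate_genotypes(cfg)
        genes, _ = simulate_gene_architecture(cfg)
        snp_map = map_snps_to_genes(gm, genes)
        assert len(snp_map) == 0

    def test_non_overlapping_gene_intervals(self):
        genes, _ = simulate_gene_architecture(small(n_genes=30, seed=3))
        df = genes.to_frame().sort_values(["chrom", "start"])
        for _, sub in df.groupby("chrom"):
            starts = sub["start"].to_numpy()[1:]
            ends = sub["end"].to_numpy()[:-1]
            assert (starts > ends).all()

    def test_causal_genes_in_causal_set_with_one_snp_each(self):
        cfg = small(n_causal_genes=4, causal_set_index=2, seed=4)
        s = simulate_study(cfg)
        causal_set = s.sets.get(s.truth["causal_set"])
        assert set(s.truth["causal_genes"]) <= set(causal_set.members)
        assert len(s.truth["causal_snps"]) == 4
        eff = causal_effects(cfg, s.genotypes)
        assert sorted(eff["gene_id"]) == sorted(s.truth["causal_genes"])


class TestPhenotypes:
    def test_noise_free_limit(self):
        cfg = small(sigma=0.0, bmi_slope=0.0, tg_location=2.0)
        gm = simulate_genotypes(cfg)
        pheno = simulate_phenotypes(gm, cfg)
        np.testing.assert_allclose(pheno["tg"], 100.0)

    def test_log_tg_in_plausible_lipid_range(self):
        cfg = SimulationConfig(n_individuals=1000, seed=6)
        s = simulate_study(cfg)
        log_tg = np.log10(s.phenotypes["tg"])
        assert 1.9 < log_tg.mean() < 2.3
        assert 0.15 < log_tg.std() < 0.40

    def test_null_association_pvalues_uniform(self):
        cfg = SimulationConfig(n_individuals=400, n_snps=600, n_genes=100,
                               n_sets=2, set_size_range=(5, 10),
                               missing_rate=0.0, seed=7)
        gm = simulate_genotypes(cfg)
        pheno = simulate_phenotypes(gm, cfg)
        y = np.log10(pheno["tg"].to_numpy())
        _, p, _ = asc.linreg_bulk(gm.dosage, y)
        assert sps.kstest(p, "uniform").statistic < 0.1

    def test_effect_recovery_within_3_se(self):
        hits = 0
        for seed in range(10):
            cfg = small(n_individuals=800, n_causal_genes=1,
                        causal_set_index=0, beta=0.05, seed=seed)
            s = simulate_study(cfg)
            j = s.genotypes.snp_ids.tolist().index(s.truth["causal_snps"][0])
            d = s.genotypes.dosage[:, j]
            y = np.log10(s.phenotypes["tg"].to_numpy())
            ok = ~np.isnan(d)
            fit = sps.linregress(d[ok], y[ok])
            hits += abs(fit.slope - 0.05) < 3 * fit.stderr
        assert hits >= 9

    def test_calibrated_effect_strength(self):
        cfg = SimulationConfig(n_individuals=1000, n_causal_genes=10,
                               causal_set_index=0, seed=8)
        s = simulate_study(cfg)
        eff = causal_effects(cfg, s.genotypes)
        assert (eff["beta"] > 0).all()
        # a calibrated SNP should give a strong (but not astronomical) signal
        y = np.log10(s.phenotypes["tg"].to_numpy())
        cols = [s.genotypes.snp_ids.tolist().index(x) for x in eff["snp_id"]]
        _, p, _ = asc.linreg_bulk(s.genotypes.dosage[:, cols], y)
        assert np.median(p) < 1e-2

    def test_missing_causal_snp_is_configuration_error(self):
        cfg = small(n_causal_genes=2, causal_set_index=0)
        gm = simulate_genotypes(cfg)
        truncated = gm.take_snps(np.arange(gm.n_snps - 150))
        with pytest.raises(ConfigurationError, match="causal"):
            simulate_phenotypes(truncated, cfg)


class TestReproducibility:
    def test_identical_seed_byte_identical_study(self, tmp_path):
        cfg = small(n_causal_genes=3, causal_set_index=0, seed=99)
        p1 = write_study(simulate_study(cfg), tmp_path / "a")
        p2 = write_study(simulate_study(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seeds_differ(self):
        g1 = simulate_genotypes(small(seed=1))
        g2 = simulate_genotypes(small(seed=2))
        assert not np.array_equal(g1.dosage, g2.dosage)


class TestLdProxies:
    def test_proxy_r2_near_expected(self):
        from pathgsea.icsn import ld_r2
        cfg = small(n_individuals=800, n_causal_genes=2, causal_set_index=0,
                    ld_proxies=2, ld_corruption=0.02, missing_rate=0.0, seed=10)
        s = simulate_study(cfg)
        ids = s.genotypes.snp_ids.tolist()
        for snp in s.truth["causal_snps"]:
            j = ids.index(snp)
            proxies = s.truth["proxy_snps"][snp]
            assert len(proxies) == 2
            for pid in proxies:
                k = ids.index(pid)
                assert abs(s.genotypes.pos[k] - s.genotypes.pos[j]) <= 1100
                r2 = ld_r2(s.genotypes.dosage[:, j], s.genotypes.dosage[:, k])
                assert r2 > 0.6  # expected (1 - 0.02)^2 ~ 0.96
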