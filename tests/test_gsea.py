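from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from pathgsea import gsea
from pathgsea.errors import DataError, PipelineError
from pathgsea.gsea import (
    GseaConfig,
    PermutationNull,
    RankedGeneList,
    compute_fdr,
    empirical_p,
    enrichment_score,
    normalize_scores,
    permute_phenotype_null,
    rank_genes,
    run_gengen,
)
from pathgsea.phenotypes import prepare_phenotypes
from pathgsea.simulate import SimulationConfig, StudyBundle, simulate_study
from conftest import make_genes, make_genotypes, make_pheno, make_sets


def brute_force_es(stats, hit_flags, p_weight):
    """Independent exact running-sum evaluation in rational arithmetic."""
    stats = [Fraction(float(s)) for s in stats]
    n = len(stats)
    nh = sum(hit_flags)
    nr = sum(abs(s) ** p_weight for s, h in zip(stats, hit_flags) if h)
    run = Fraction(0)
    best = None
    for j in range(n):
        if hit_flags[j]:
            run += (abs(stats[j]) ** p_weight) / nr if nr else Fraction(1, nh)
        else:
            run -= Fraction(1, n - nh)
        best = run if best is None or run > best else best
    return float(best)


def ranked(stats, ids=None):
    stats = np.asarray(stats, dtype=float)
    ids = np.array(ids if ids is not None
                   else [f"g{i}" for i in range(len(stats))], dtype=object)
    return RankedGeneList(gene_ids=ids, stats=stats)


class TestRankGenes:
    def test_descending_with_id_tiebreak(self):
        df = pd.DataFrame({"gene_id": ["A", "B", "C"], "r": [2.0, 5.0, 2.0]})
        rl = rank_genes(df)
        assert rl.gene_ids.tolist() == ["B", "A", "C"]

    def test_single_gene(self):
        rl = rank_genes(pd.DataFrame({"gene_id": ["X"], "r": [1.0]}))
        assert rl.n == 1

    def test_permutation_of_input(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"gene_id": [f"g{i}" for i in range(30)],
                           "r": rng.chisquare(1, 30)})
        rl = rank_genes(df)
        assert sorted(rl.gene_ids) == sorted(df["gene_id"])
        assert (np.diff(rl.stats) <= 0).all()


class TestEnrichmentScore:
    def test_worked_example(self):
        # stats [5,4,3,2,1], hits at ranks 1 and 3: N_R = 8,
        # running sum [0.625, 0.2917, 0.6667, 0.3333, 0] -> ES = 2/3
        rl = ranked([5, 4, 3, 2, 1])
        es = enrichment_score(rl, {"g0", "g2"}, p_weight=1)
        assert es == pytest.approx(2 / 3, abs=1e-12)

    def test_singleton_top_rank(self):
        rl = ranked([5, 4, 3, 2, 1])
        assert enrichment_score(rl, {"g0"}) == pytest.approx(1.0, abs=1e-12)

    def test_all_hits_at_bottom_scores_zero(self):
        # the running sum always returns to 0 at the last rank, so a set
        # concentrated at the bottom attains its maximum there: ES = 0
        rl = ranked([5, 4, 3, 2, 1])
        assert enrichment_score(rl, {"g4"}) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [set(), {"g0", "g1", "g2", "g3", "g4"}])
    def test_degenerate_set_sizes_rejected(self, bad):
        with pytest.raises(DataError):
            enrichment_score(ranked([5, 4, 3, 2, 1]), bad)

    def test_p_zero_reduces_to_unweighted_ks(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(5, 40))
            stats = np.sort(rng.chisquare(1, n))[::-1]
            nh = int(rng.integers(1, n))
            hits = np.zeros(n, dtype=bool)
            hits[rng.choice(n, nh, replace=False)] = True
            # independent unweighted KS running maximum
            best, run = -np.inf, 0.0
            for j in range(n):
                run += 1 / nh if hits[j] else -1 / (n - nh)
                best = max(best, run)
            rl = ranked(stats)
            members = set(rl.gene_ids[hits])
            assert enrichment_score(rl, members, p_weight=0) == pytest.approx(best)

    def test_brute_force_oracle_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(3, 51))
            stats = np.sort(np.round(rng.chisquare(1, n), 6))[::-1]
            nh = int(rng.integers(1, n))
            hits = np.zeros(n, dtype=bool)
            hits[rng.choice(n, nh, replace=False)] = True
            rl = ranked(stats)
            got = enrichment_score(rl, set(rl.gene_ids[hits]), p_weight=1)
            want = brute_force_es(stats, hits.tolist(), 1)
            assert got == pytest.approx(want, abs=1e-12)

    def test_bounds_and_perfect_separation(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            stats = np.sort(rng.chisquare(1, n))[::-1]
            nh = int(rng.integers(1, n))
            hits = np.zeros(n, dtype=bool)
            hits[rng.choice(n, nh, replace=False)] = True
            rl = ranked(stats)
            es = enrichment_score(rl, set(rl.gene_ids[hits]))
            assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
        # ES = 1 when the top N_H ranks are exactly the hit set
        rl = ranked([9, 8, 7, 1, 1, 1])
        assert enrichment_score(rl, {"g0", "g1", "g2"}) == pytest.approx(1.0)


class TestEmpiricalP:
    def test_worked_example(self):
        assert empirical_p(0.25, [0.1, 0.2, 0.3]) == pytest.approx(0.5)

    def test_observed_above_all(self):
        null = np.linspace(0, 0.5, 1000)
        assert empirical_p(0.9, null) == pytest.approx(1 / 1001)

    def test_observed_below_all(self):
        assert empirical_p(-0.9, np.linspace(0, 0.5, 100)) == pytest.approx(1.0)


class TestNormalize:
    def test_arithmetic(self):
        # two-point null with mean 0.3 and sample SD exactly 0.15
        x = 0.15 / np.sqrt(2)
        null = PermutationNull(["S"], np.array([[0.3 - x], [0.3 + x]]))
        assert null.mean[0] == pytest.approx(0.3)
        assert null.sd[0] == pytest.approx(0.15)
        nes, _, degen = normalize_scores(np.array([0.6]), null)
        assert nes[0] == pytest.approx(2.0)
        assert not degen[0]

    def test_observed_equal_to_mean_gives_zero(self):
        null = PermutationNull(["S"], np.array([[0.1], [0.5]]))
        nes, _, _ = normalize_scores(np.array([0.3]), null)
        assert nes[0] == pytest.approx(0.0)

    def test_standardized_null_has_unit_moments(self):
        rng = np.random.default_rng(4)
        null = PermutationNull(["a", "b"], rng.normal(0.2, 0.1, size=(500, 2)))
        _, nes_null, _ = normalize_scores(np.array([0.3, 0.1]), null)
        np.testing.assert_allclose(nes_null.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(nes_null.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_degenerate_sd_flagged(self):
        null = PermutationNull(["S"], np.full((5, 1), 0.2))
        nes, _, degen = normalize_scores(np.array([0.6]), null)
        assert nes[0] == 0.0 and degen[0]


class TestFdr:
    def test_worked_example(self):
        # pooled null: 100 values, 2 >= 2.0 and 40 >= 1.0
        pool = np.concatenate([
            np.full(2, 2.5), np.full(38, 1.5), np.full(60, 0.5)
        ])
        nes_null = pool.reshape(50, 2)
        fdr, raw = compute_fdr(np.array([2.0, 1.0]), nes_null)
        assert fdr[0] == pytest.approx(0.02 / 0.5)
        assert fdr[1] == pytest.approx(0.40 / 1.0)

    def test_smallest_nes_denominator_is_one(self):
        rng = np.random.default_rng(5)
        nes_null = rng.normal(size=(100, 3))
        obs = np.array([2.0, 1.0, -0.5])
        fdr, raw = compute_fdr(obs, nes_null)
        tail = (nes_null.ravel() >= -0.5).mean()
        assert raw[2] == pytest.approx(tail)

    def test_clipped_at_one(self):
        nes_null = np.linspace(0, 3, 100).reshape(50, 2)
        fdr, raw = compute_fdr(np.array([-1.0, -2.0]), nes_null)
        assert (fdr <= 1).all() and (raw >= 1).all()


def _toy_study(seed=0, n=120, m=150, genes=30, sets=6):
    cfg = SimulationConfig(n_individuals=n, n_snps=m, n_genes=genes,
                           n_sets=sets, set_size_range=(5, 10), seed=seed)
    return simulate_study(cfg)


class TestPermutationNull:
    def test_single_permutation_bounds(self):
        s = _toy_study()
        null = permute_phenotype_null(
            s.genotypes, s.phenotypes, s.genes, s.sets,
            GseaConfig(n_perm=1, seed=0), phenotype="binary")
        assert null.es_null.shape[0] == 1
        assert ((null.es_null >= -1) & (null.es_null <= 1)).all()

    def test_seed_determinism(self):
        s = _toy_study()
        kw = dict(phenotype="log_tg")
        n1 = permute_phenotype_null(s.genotypes, s.phenotypes, s.genes, s.sets,
                                    GseaConfig(n_perm=10, seed=5), **kw)
        n2 = permute_phenotype_null(s.genotypes, s.phenotypes, s.genes, s.sets,
                                    GseaConfig(n_perm=10, seed=5), **kw)
        np.testing.assert_array_equal(n1.es_null, n2.es_null)

    def test_constant_phenotype_rejected(self):
        s = _toy_study()
        pheno = prepare_phenotypes(s.phenotypes)
        pheno["log_tg"] = 2.0
        pheno["included"] = True
        with pytest.raises(DataError, match="distinct"):
            permute_phenotype_null(s.genotypes, pheno, s.genes, s.sets,
                                   GseaConfig(n_perm=2, seed=0), phenotype="log_tg")


class TestRunGengen:
    def test_row_order_invariance(self):
        s = _toy_study(seed=3)
        cfg = GseaConfig(n_perm=20, seed=9)
        res1 = run_gengen(s, cfg, phenotype="binary")
        rng = np.random.default_rng(0)
        perm = rng.permutation(s.genotypes.n_individuals)
        shuffled = StudyBundle(
            genotypes=s.genotypes.take_individuals(perm),
            phenotypes=s.phenotypes.iloc[perm].reset_index(drop=True),
            genes=s.genes, sets=s.sets, truth=s.truth, seed=s.seed,
        )
        res2 = run_gengen(shuffled, cfg, phenotype="binary")
        pd.testing.assert_frame_equal(res1, res2)

    def test_size_filter_excludes_small_covered_sets(self):
        s = _toy_study(seed=4)
        # add a set with only 4 genes
        from pathgsea.io import GeneSet, GeneSetCollection
        tiny = GeneSet("TINY", "too small", tuple(s.genes.gene_ids[:4]))
        sets = GeneSetCollection(list(s.sets.sets) + [tiny])
        res = run_gengen(s, GseaConfig(n_perm=5, seed=0), phenotype="binary",
                         sets=sets)
        assert "TINY" not in set(res["set_id"])
        assert ("TINY", 4) in {(sid, c) for sid, c, _ in res.attrs["skipped_sets"]}

    def test_no_surviving_set_is_pipeline_error(self):
        s = _toy_study(seed=5)
        with pytest.raises(PipelineError, match="size filter"):
            run_gengen(s, GseaConfig(n_perm=5, set_min=100, seed=0),
                       phenotype="binary")

    def test_deterministic_result_table(self):
        s = _toy_study(seed=6)
        cfg = GseaConfig(n_perm=15, seed=2)
        r1 = run_gengen(s, cfg, phenotype="log_tg")
        r2 = run_gengen(s, cfg, phenotype="log_tg")
        pd.testing.assert_frame_equal(r1, r2)
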