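"""Gene-set enrichment on GWAS results with permutation nulls.

The central statistic is a weighted Kolmogorov-Smirnov-like running sum over
the ranked gene list.  Genes are ranked by their representative association
statistic r(1) >= ... >= r(N).  For a set S with N_H members among the
ranked genes,

    ES(S) = max_{1<=j<=N} [ sum_{hits at rank <= j} |r|^p / N_R
                            - (#misses at rank <= j) / (N - N_H) ],

with N_R = sum over hits of |r|^p and weight exponent p (default 1; p = 0
reduces to the classical unweighted KS statistic).  ES is evaluated after
every position and lies in [0, 1] up to rounding: the running sum returns
to exactly 0 at the last rank, so a set concentrated at the bottom of the
ranking scores 0 rather than a negative value.

Significance comes from permutations.  In phenotype-permutation mode the
phenotype labels are shuffled across the analysis individuals, every SNP's
association statistic is recomputed, genes are re-scored and re-ranked, and
ES is recalculated for every tested set — SNP-level QC is phenotype-free and
done once.  Each set's observed ES is standardized by the mean and sample SD
of its own null column (NES); the empirical P-value is the one-sided
(1 + #{ES_null >= ES_obs}) / (B + 1); and the FDR for a set with observed
NES* is

    FDR = [fraction of all pooled null NES >= NES*]
          / [fraction of observed sets with NES >= NES*],

clipped to [0, 1] for reporting (the raw ratio is retained).

Only sets whose *covered* size (members among ranked genes) is within
[set_min, set_max] are tested, the regime in which gene-set methods are
typically applied (default 5–200).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc as asc
from .errors import DataError, PipelineError
from .io import GeneAnnotation, GeneSetCollection, GenotypeMatrix
from .phenotypes import prepare_phenotypes
from .snp2gene import DEFAULT_FLANK, map_snps_to_genes

logger = logging.getLogger(__name__)

MODE_PHENOTYPE = "phenotype_perm"
MODE_SNP_LABEL = "snp_label_perm"


@dataclass
class GseaConfig:
    """Knobs of the enrichment computation.

    p_weight: hit-increment exponent p (>= 0); n_perm: number of
    permutations B; set_min/set_max: covered-size filter; seed: RNG seed for
    the permutation stream; mode: which null is generated.
    """

    p_weight: float = 1.0
    n_perm: int = 1000
    set_min: int = 5
    set_max: int = 200
    seed: int = 0
    mode: str = MODE_PHENOTYPE

    def validate(self) -> None:
        if self.p_weight < 0:
            raise DataError("p_weight must be >= 0")
        if self.n_perm < 1:
            raise DataError("n_perm must be >= 1")
        if self.set_min > self.set_max:
            raise DataError("set_min must be <= set_max")
        if self.mode not in (MODE_PHENOTYPE, MODE_SNP_LABEL):
            raise DataError(f"unknown mode {self.mode!r}")


@dataclass
class RankedGeneList:
    """Genes in non-increasing statistic order with deterministic ties."""

    gene_ids: np.ndarray
    stats: np.ndarray

    @property
    def n(self) -> int:
        return len(self.gene_ids)


@dataclass
class PermutationNull:
    """Null ES matrix (B x n_sets) with per-set moments and standardization."""

    set_ids: list[str]
    es_null: np.ndarray  # (B, S)
    mean: np.ndarray = field(init=False)
    sd: np.ndarray = field(init=False)
    degenerate: np.ndarray = field(init=False)
    nes_null: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean = self.es_null.mean(axis=0)
        self.sd = self.es_null.std(axis=0, ddof=1) if self.es_null.shape[0] > 1 else np.zeros(
            self.es_null.shape[1]
        )
        # an SD at rounding-error scale means the null column is constant
        self.degenerate = self.sd <= np.maximum(np.abs(self.mean), 1.0) * 1e-12
        safe = np.where(self.degenerate, 1.0, self.sd)
        self.nes_null = (self.es_null - self.mean) / safe
        self.nes_null[:, self.degenerate] = 0.0

    @property
    def n_perm(self) -> int:
        return self.es_null.shape[0]


# ---------------------------------------------------------------------------
# ranking and the running-sum score
# ---------------------------------------------------------------------------


def rank_genes(gene_stats: pd.DataFrame) -> RankedGeneList:
    """Rank genes by statistic, descending; ties broken by ascending gene_id."""
    if len(gene_stats) == 0:
        raise DataError("cannot rank an empty gene table")
    df = gene_stats.sort_values("gene_id", kind="mergesort")
    order = np.argsort(-df["r"].to_numpy(dtype=float), kind="stable")
    return RankedGeneList(
        gene_ids=df["gene_id"].to_numpy(dtype=object)[order],
        stats=df["r"].to_numpy(dtype=float)[order],
    )


def _es_bulk(ranked_stats: np.ndarray, hits: np.ndarray, p_weight: float) -> np.ndarray:
    """ES for each row of the boolean hit matrix (rows = sets, cols = ranks).

    Requires 1 <= N_H < N per row.  If a set's weighted hit mass N_R is zero
    (all member statistics exactly 0 with p > 0), hit increments fall back to
    the unweighted 1/N_H.
    """
    hits = np.asarray(hits, dtype=bool)
    N = hits.shape[1]
    nh = hits.sum(axis=1)
    if np.any(nh == 0) or np.any(nh == N):
        raise DataError("ES undefined for sets with 0 or N covered genes")
    w = np.abs(np.asarray(ranked_stats, dtype=float)) ** p_weight
    hw = hits * w
    nr = hw.sum(axis=1)
    zero = nr == 0
    if zero.any():
        hw[zero] = hits[zero].astype(float)
        nr[zero] = nh[zero]
    hit_cdf = np.cumsum(hw, axis=1) / nr[:, None]
    miss_cdf = np.cumsum(~hits, axis=1) / (N - nh)[:, None]
    return (hit_cdf - miss_cdf).max(axis=1)


def enrichment_score(ranked: RankedGeneList, set_members, p_weight: float = 1.0) -> float:
    """Weighted KS-like enrichment score of one gene set on a ranked list."""
    members = set(map(str, set_members))
    hits = np.array([g in members for g in ranked.gene_ids], dtype=bool)[None, :]
    return float(_es_bulk(ranked.stats, hits, p_weight)[0])


def running_sum(ranked: RankedGeneList, set_members, p_weight: float = 1.0) -> np.ndarray:
    """The full running sum (useful for plots and leading-edge inspection)."""
    members = set(map(str, set_members))
    hits = np.array([g in members for g in ranked.gene_ids], dtype=bool)
    nh = int(hits.sum())
    if nh == 0 or nh == ranked.n:
        raise DataError("running sum undefined for sets with 0 or N covered genes")
    w = np.abs(ranked.stats) ** p_weight
    hw = np.where(hits, w, 0.0)
    nr = hw.sum()
    if nr == 0:
        hw = hits.astype(float)
        nr = float(nh)
    return np.cumsum(hw) / nr - np.cumsum(~hits) / (ranked.n - nh)


# ---------------------------------------------------------------------------
# null normalization, empirical P, FDR
# ---------------------------------------------------------------------------


def normalize_scores(es_obs: np.ndarray, null: PermutationNull):
    """NES = (ES - null mean) / null sample SD, per set.

    Sets with a degenerate (zero-SD) null get NES 0 and are flagged.
    Returns (nes, nes_null, degenerate_mask).
    """
    if null.n_perm < 2:
        raise DataError("NES needs >=2 permutations")
    es_obs = np.asarray(es_obs, dtype=float)
    degen = null.degenerate
    safe = np.where(degen, 1.0, null.sd)
    nes = (es_obs - null.mean) / safe
    nes[degen] = 0.0
    if degen.any():
        logger.warning("%d set(s) have a zero-SD permutation null", int(degen.sum()))
    return nes, null.nes_null, degen


def empirical_p(es_obs, es_null) -> np.ndarray | float:
    """One-sided permutation P: (1 + #{null >= observed}) / (B + 1)."""
    null = np.asarray(es_null, dtype=float)
    obs = np.asarray(es_obs, dtype=float)
    if null.ndim == 1:
        p = (1.0 + (null >= obs).sum()) / (null.size + 1.0)
        return float(p) if obs.ndim == 0 else np.asarray(p)
    B = null.shape[0]
    return (1.0 + (null >= obs[None, :]).sum(axis=0)) / (B + 1.0)


def compute_fdr(nes_obs: np.ndarray, nes_null: np.ndarray):
    """Ratio-of-tails FDR on standardized scores.

    numerator: fraction of the pooled null NES (all sets x all permutations)
    at or above NES*; denominator: fraction of observed sets at or above
    NES*.  Returns (clipped, raw).
    """
    nes_obs = np.asarray(nes_obs, dtype=float)
    pooled = np.sort(np.asarray(nes_null, dtype=float).ravel())
    n_pool = pooled.size
    if n_pool == 0 or nes_obs.size == 0:
        raise DataError("FDR needs a non-empty null and >=1 observed set")
    # tail counts via searchsorted on the sorted pool
    num = (n_pool - np.searchsorted(pooled, nes_obs, side="left")) / n_pool
    obs_sorted = np.sort(nes_obs)
    den = (nes_obs.size - np.searchsorted(obs_sorted, nes_obs, side="left")) / nes_obs.size
    raw = num / den  # den >= 1/n_sets by construction
    return np.clip(raw, 0.0, 1.0), raw


# ---------------------------------------------------------------------------
# phenotype-permutation engine
# ---------------------------------------------------------------------------


class _SetGeometry:
    """Gene segments and set membership over the ranked-gene universe."""

    def __init__(self, snp_map, snp_ids, sets: GeneSetCollection, set_min, set_max):
        index = {s: i for i, s in enumerate(snp_ids)}
        flat: list[int] = []
        starts: list[int] = []
        gene_ids: list[str] = []
        for gid in sorted(snp_map.gene_to_snps):
            idxs = [index[s] for s in snp_map.gene_to_snps[gid] if s in index]
            if not idxs:
                continue
            starts.append(len(flat))
            flat.extend(idxs)
            gene_ids.append(gid)
        if not gene_ids:
            raise PipelineError("no gene has a surviving associated SNP")
        self.gene_ids = np.array(gene_ids, dtype=object)
        self.flat = np.array(flat, dtype=np.intp)
        self.starts = np.array(starts, dtype=np.intp)
        self.n_genes = len(gene_ids)

        gpos = {g: i for i, g in enumerate(gene_ids)}
        n_sets = len(sets)
        membership = np.zeros((n_sets, self.n_genes), dtype=bool)
        for si, s in enumerate(sets):
            for g in s.members:
                j = gpos.get(g)
                if j is not None:
                    membership[si, j] = True
        covered = membership.sum(axis=1)
        tested, skipped = [], []
        for si, s in enumerate(sets):
            c = int(covered[si])
            if c < set_min or c > set_max:
                skipped.append((s.set_id, c, f"covered size {c} outside [{set_min}, {set_max}]"))
            elif c >= self.n_genes:
                skipped.append((s.set_id, c, "set covers every ranked gene"))
            else:
                tested.append(si)
        if not tested:
            sizes = {s.set_id: int(c) for s, c in zip(sets, covered)}
            raise PipelineError(f"no gene set passes the size filter; covered sizes: {sizes}")
        for sid, c, why in skipped:
            logger.info("set %s skipped: %s", sid, why)
        self.sets = sets
        self.tested = np.array(tested, dtype=np.intp)
        self.membership = membership[self.tested]
        self.covered = covered[self.tested]
        self.skipped = skipped

    def es_from_snp_stats(self, snp_stats: np.ndarray, p_weight: float) -> np.ndarray:
        gene_r = np.maximum.reduceat(snp_stats[self.flat], self.starts)
        order = np.argsort(-gene_r, kind="stable")  # genes pre-sorted by id
        return _es_bulk(gene_r[order], self.membership[:, order], p_weight)


class _PhenotypePermEngine:
    """Shared state for observed and permuted enrichment computations.

    Individuals are internally sorted by id, so every output is invariant to
    the row order of the input genotype/phenotype tables.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        pheno: pd.DataFrame,
        genes: GeneAnnotation,
        sets: GeneSetCollection,
        config: GseaConfig,
        phenotype: str,
        maf_min: float,
        hwe_min_p: float,
        flank: int,
    ):
        config.validate()
        rows, y = asc.select_analysis_individuals(genotypes, pheno, phenotype)
        order = np.argsort(genotypes.individual_ids[rows].astype(str), kind="stable")
        rows, y = rows[order], y[order]
        if phenotype == "binary":
            if y.all() or not y.any():
                raise DataError("fewer than 2 distinct phenotype values")
        else:
            if y.size and np.ptp(y) == 0:
                raise DataError("fewer than 2 distinct phenotype values")
        D = genotypes.dosage[rows, :]
        keep = asc.qc_mask(D, maf_min=maf_min, hwe_min_p=hwe_min_p)
        if not keep.any():
            raise PipelineError("no SNP survives MAF/HWE quality control")
        idx = np.flatnonzero(keep)
        self.snp_ids = genotypes.snp_ids[idx].astype(str)
        self.D = D[:, idx]
        self.mask = ~np.isnan(self.D)
        self.filled = np.where(self.mask, self.D, 0.0)
        self.mask_f = self.mask.astype(float)
        self.phenotype = phenotype
        self.y = y
        if phenotype != "binary":
            self.n = self.mask_f.sum(axis=0)
            self.sx = self.filled.sum(axis=0)
            self.sxx = (self.filled * self.filled).sum(axis=0)

        snp_map = map_snps_to_genes(
            pd.DataFrame(
                {"snp_id": self.snp_ids, "chrom": genotypes.chrom[idx], "pos": genotypes.pos[idx]}
            ),
            genes,
            flank=flank,
        )
        self.geom = _SetGeometry(snp_map, self.snp_ids, sets, config.set_min, config.set_max)
        self.config = config

    def snp_stats(self, y) -> np.ndarray:
        if self.phenotype == "binary":
            case = np.asarray(y, dtype=float)
            ctrl = 1.0 - case
            a, b, c, d = asc.allelic_counts_bulk(self.filled, self.mask_f, case, ctrl)
            stat, _, _ = asc.chisq_2x2(a, b, c, d)
            return stat
        yv = np.asarray(y, dtype=float)
        sy = yv @ self.mask_f
        syy = (yv * yv) @ self.mask_f
        sxy = yv @ self.filled
        stat, _, _ = asc.linreg_from_moments(self.n, self.sx, self.sxx, sy, syy, sxy)
        return stat

    def observed_es(self) -> np.ndarray:
        return self.geom.es_from_snp_stats(self.snp_stats(self.y), self.config.p_weight)

    def null(self) -> PermutationNull:
        rng = np.random.default_rng(self.config.seed)
        B = self.config.n_perm
        es = np.empty((B, len(self.geom.tested)))
        for b in range(B):
            yp = rng.permutation(self.y)
            es[b] = self.geom.es_from_snp_stats(self.snp_stats(yp), self.config.p_weight)
        return PermutationNull(
            set_ids=[self.geom.sets[int(i)].set_id for i in self.geom.tested],
            es_null=es,
        )


def _maybe_prepare(pheno: pd.DataFrame) -> pd.DataFrame:
    if "status" in pheno.columns and "log_tg" in pheno.columns:
        return pheno
    return prepare_phenotypes(pheno)


def permute_phenotype_null(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    genes: GeneAnnotation,
    sets: GeneSetCollection,
    config: GseaConfig,
    phenotype: str = "binary",
    maf_min: float = 0.01,
    hwe_min_p: float = 0.001,
    flank: int = DEFAULT_FLANK,
) -> PermutationNull:
    """Phenotype-label permutation null ES matrix for the tested sets."""
    eng = _PhenotypePermEngine(
        genotypes, _maybe_prepare(pheno), genes, sets, config, phenotype, maf_min, hwe_min_p, flank
    )
    return eng.null()


def assemble_results(
    sets: GeneSetCollection,
    tested: np.ndarray,
    covered: np.ndarray,
    es_obs: np.ndarray,
    null: PermutationNull,
    mode: str,
) -> pd.DataFrame:
    """Combine observed scores with a null into the result table."""
    nes, nes_null, degen = normalize_scores(es_obs, null)
    emp = empirical_p(es_obs, null.es_null)
    fdr, fdr_raw = compute_fdr(nes, nes_null)
    df = pd.DataFrame(
        {
            "set_id": [sets[int(i)].set_id for i in tested],
            "description": [sets[int(i)].description for i in tested],
            "size_total": [len(sets[int(i)].members) for i in tested],
            "size_covered": covered.astype(int),
            "es": es_obs,
            "nes": nes,
            "empirical_p": emp,
            "fdr": fdr,
            "fdr_raw": fdr_raw,
            "mode": mode,
            "flag": np.where(degen, "degenerate_null", ""),
        }
    )
    df = df.sort_values(
        ["empirical_p", "nes"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    df.attrs["n_perm"] = null.n_perm
    df.attrs["mode"] = mode
    return df


def run_gengen(
    study,
    config: GseaConfig,
    phenotype: str = "binary",
    sets: GeneSetCollection | None = None,
    genes: GeneAnnotation | None = None,
    maf_min: float = 0.01,
    hwe_min_p: float = 0.001,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Full phenotype-permutation enrichment analysis on a study bundle.

    ``study`` carries ``genotypes``, ``phenotypes`` (raw or prepared),
    ``genes`` and ``sets``; the latter two can be overridden.  Deterministic
    given ``config.seed``.
    """
    sets = sets if sets is not None else study.sets
    genes = genes if genes is not None else study.genes
    eng = _PhenotypePermEngine(
        study.genotypes,
        _maybe_prepare(study.phenotypes),
        genes,
        sets,
        config,
        phenotype,
        maf_min,
        hwe_min_p,
        flank,
    )
    es_obs = eng.observed_es()
    null = eng.null()
    df = assemble_results(sets, eng.geom.tested, eng.geom.covered, es_obs, null, MODE_PHENOTYPE)
    df.attrs["n_ranked_genes"] = eng.geom.n_genes
    df.attrs["skipped_sets"] = eng.geom.skipped
    return df
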