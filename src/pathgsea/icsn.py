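"""Verification arm: SNP-label-permutation enrichment and LD candidate SNPs.

This mode works from a fixed table of per-SNP GWAS P-values rather than from
genotypes.  The gene statistic is the maximum of -log10(P) over the gene's
mapped SNPs (for a fixed 1-df test family this ranks genes identically to
the raw chi-square/F statistic).  The null is generated by randomly
permuting the per-SNP statistic vector across SNP labels while keeping the
SNP-gene geometry fixed, which preserves the multiset of statistics exactly
in every replicate.  NES, empirical P and FDR reuse the same machinery as
the phenotype-permutation mode.

LD candidate-SNP selection: for each top-ranked index SNP, same-chromosome
SNPs within a search window (default 200 kb) whose dosage correlation
satisfies r^2 > r2_min (default 0.6) are collected as candidate proxies.
r^2 is the squared Pearson correlation of allele dosages (composite,
phase-free LD).  Candidate reporting is informational and does not alter
enrichment results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .gsea import (
    MODE_SNP_LABEL,
    GseaConfig,
    PermutationNull,
    _SetGeometry,
    assemble_results,
)
from .io import GeneSetCollection, GenotypeMatrix
from .snp2gene import SnpGeneMap

logger = logging.getLogger(__name__)


@dataclass
class LdConfig:
    r2_min: float = 0.6
    window: int = 200_000

    def validate(self) -> None:
        if not (0.0 <= self.r2_min <= 1.0):
            raise DataError("r2_min must lie in [0, 1]")
        if self.window <= 0:
            raise DataError("LD window must be positive")


@dataclass
class CandidateSnpSet:
    """An index SNP and its LD proxies (snp_id, r^2), index included."""

    index_snp: str
    proxies: list[tuple[str, float]] = field(default_factory=list)


def ld_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of allele dosages over complete pairs.

    Symmetric in its arguments and invariant to relabeling either SNP's
    counted allele.  Monomorphic input among the complete pairs is undefined
    and returned as 0.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        raise DataError("r^2 needs >=2 complete genotype pairs")
    a, b = a[ok], b[ok]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        logger.warning("monomorphic SNP in r^2 computation; returning 0")
        return 0.0
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def select_candidate_snps(
    assoc: pd.DataFrame,
    genotypes: GenotypeMatrix,
    top_k: int = 10,
    ld: LdConfig | None = None,
) -> list[CandidateSnpSet]:
    """LD neighborhoods of the ``top_k`` most significant SNPs.

    For each index SNP, same-chromosome SNPs within ``ld.window`` bp with
    r^2 > ``ld.r2_min`` are collected; the index SNP itself is always in its
    own set.  ``top_k`` beyond the table size is truncated with a warning.
    """
    ld = ld or LdConfig()
    ld.validate()
    ranked = assoc.sort_values(["p", "snp_id"], kind="mergesort")
    if top_k > len(ranked):
        logger.warning("top_k=%d exceeds %d SNPs; truncating", top_k, len(ranked))
        top_k = len(ranked)
    col = {s: j for j, s in enumerate(genotypes.snp_ids.astype(str))}
    out: list[CandidateSnpSet] = []
    for _, row in ranked.head(top_k).iterrows():
        sid = str(row["snp_id"])
        j = col.get(sid)
        if j is None:
            raise DataError(f"index SNP {sid!r} absent from the genotype matrix")
        same = (genotypes.chrom.astype(str) == str(genotypes.chrom[j])) & (
            np.abs(genotypes.pos - genotypes.pos[j]) <= ld.window
        )
        cand = CandidateSnpSet(index_snp=sid)
        for k in np.flatnonzero(same):
            r2 = ld_r2(genotypes.dosage[:, j], genotypes.dosage[:, k])
            if k == j or r2 > ld.r2_min:
                cand.proxies.append((str(genotypes.snp_ids[k]), r2))
        cand.proxies.sort(key=lambda t: (-t[1], t[0]))
        out.append(cand)
    return out


def snp_label_permutation_gsea(
    assoc: pd.DataFrame,
    snp_map: SnpGeneMap,
    sets: GeneSetCollection,
    config: GseaConfig,
) -> pd.DataFrame:
    """Enrichment with a SNP-label permutation null on fixed GWAS P-values.

    ``assoc`` needs columns snp_id and p (a two-column SNP/P table read by
    :func:`pathgsea.io.read_snp_pvalues` qualifies).  Deterministic given
    ``config.seed``.
    """
    config.validate()
    p = assoc["p"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise DataError("P-values must lie in (0, 1]")
    snp_ids = assoc["snp_id"].astype(str).to_numpy()
    stats = -np.log10(p)
    geom = _SetGeometry(snp_map, snp_ids, sets, config.set_min, config.set_max)
    es_obs = geom.es_from_snp_stats(stats, config.p_weight)

    rng = np.random.default_rng(config.seed)
    es = np.empty((config.n_perm, len(geom.tested)))
    for b in range(config.n_perm):
        es[b] = geom.es_from_snp_stats(rng.permutation(stats), config.p_weight)
    null = PermutationNull(
        set_ids=[geom.sets[int(i)].set_id for i in geom.tested], es_null=es
    )
    df = assemble_results(sets, geom.tested, geom.covered, es_obs, null, MODE_SNP_LABEL)
    df.attrs["n_ranked_genes"] = geom.n_genes
    df.attrs["skipped_sets"] = geom.skipped
    return df
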