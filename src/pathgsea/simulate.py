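"""Synthetic GWAS studies with the statistical structure the pipeline assumes.

One simulated study is a cohort of unrelated individuals genotyped on an
array-like SNP panel, a plasma-triglyceride phenotype, a non-overlapping
gene annotation, and a collection of gene sets with an optional designated
"causal" (enriched) set.

Genotypes: per SNP an alternate-allele frequency f is drawn uniformly from
``maf_range`` and each individual's dosage is the sum of two independent
Bernoulli(f) trials, i.e. Hardy-Weinberg equilibrium holds exactly in
expectation.  Missingness is missing-completely-at-random at
``missing_rate``.

Phenotype: an additive model on the log scale,

    log10(TG) = tg_location + sum_j beta_j * dosage_j
                + bmi_slope * (BMI - bmi_mean) + Normal(0, sigma),

with TG reported in mg/dL (10 ** log10TG) and BMI ~ Normal(bmi_mean,
bmi_sd).  Defaults put log10(TG) at mean ~2.08, SD 0.25, so roughly a fifth
of individuals exceed the 200 mg/dL case threshold and about two thirds
fall below the 150 mg/dL control threshold — the proportions typical of a
mixed obese/normal-weight cohort.

Causal architecture: ``n_causal_genes`` genes, each carrying exactly one
causal SNP, are all members of the designated causal set.  When ``beta`` is
None, each causal SNP's effect is calibrated so its expected single-marker
association strength corresponds to P ~ ``target_causal_p`` at the study's
sample size and that SNP's drawn allele frequency.

Optional linkage disequilibrium: each causal SNP can be copied into
``ld_proxies`` nearby proxy SNPs whose entries are independently redrawn
with probability ``ld_corruption`` (giving r^2 ~ (1 - ld_corruption)^2).

Identical configuration (including seed) reproduces a byte-identical study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from . import io as pio
from .io import GeneAnnotation, GeneSet, GeneSetCollection, GenotypeMatrix

_BASES = np.array(["A", "C", "G", "T"], dtype=object)
_N_CHROM = 10
_GENE_GAP = (45_000, 120_000)
_GENE_LEN = (5_000, 60_000)
_INTERGENIC_CLEARANCE = 20_000  # keep intergenic SNPs outside default flanks
_PROXY_SPACING = 500


@dataclass
class SimulationConfig:
    n_individuals: int = 1000
    n_snps: int = 2000
    n_genes: int = 400
    snps_per_gene: float | None = None  # informational; derived when None
    intergenic_fraction: float = 0.2
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_sets: int = 50
    set_size_range: tuple[int, int] = (5, 50)
    causal_set_index: int | None = None
    n_causal_genes: int = 0
    beta: float | None = None  # None -> calibrate to target_causal_p
    target_causal_p: float = 1e-4
    sigma: float = 0.25
    tg_location: float = 2.08
    bmi_mean: float = 30.0
    bmi_sd: float = 8.0
    bmi_slope: float = 0.005
    missing_rate: float = 0.002
    ld_proxies: int = 0
    ld_corruption: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 0:
            raise ConfigurationError("n_individuals must be >= 0")
        if self.n_snps <= 0 or self.n_genes <= 0:
            raise ConfigurationError("n_snps and n_genes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        smin, smax = self.set_size_range
        if not (1 <= smin <= smax):
            raise ConfigurationError("set_size_range must satisfy 1 <= min <= max")
        if smax > self.n_genes:
            raise ConfigurationError(
                f"set_size_range max {smax} exceeds n_genes {self.n_genes}"
            )
        if not (0.0 <= self.intergenic_fraction <= 1.0):
            raise ConfigurationError("intergenic_fraction must lie in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if self.n_causal_genes < 0 or self.n_causal_genes > self.n_genes:
            raise ConfigurationError("n_causal_genes must lie in [0, n_genes]")
        if self.n_causal_genes > 0:
            if self.n_sets < 1:
                raise ConfigurationError("causal genes need at least one gene set")
            ci = self.causal_set_index if self.causal_set_index is not None else 0
            if not (0 <= ci < self.n_sets):
                raise ConfigurationError("causal_set_index out of range")
            n_genic = int(round(self.n_snps * (1.0 - self.intergenic_fraction)))
            if n_genic < self.n_causal_genes:
                raise ConfigurationError(
                    "not enough genic SNPs to give each causal gene a causal SNP"
                )
        if self.ld_proxies < 0 or not (0.0 <= self.ld_corruption <= 1.0):
            raise ConfigurationError("invalid LD proxy settings")


@dataclass
class StudyBundle:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame  # columns individual_id, tg, bmi, sex
    genes: GeneAnnotation
    sets: GeneSetCollection
    truth: dict
    seed: int


# ---------------------------------------------------------------------------
# deterministic architecture shared by genotype and phenotype simulation
# ---------------------------------------------------------------------------


@dataclass
class _Architecture:
    genes: GeneAnnotation
    sets: GeneSetCollection
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    gene_of_snp: np.ndarray  # gene index or -1
    source_of_snp: np.ndarray  # proxy source SNP index or -1
    causal_snp_idx: np.ndarray
    causal_gene_idx: np.ndarray
    causal_set_id: str | None


def _seed_children(config: SimulationConfig):
    return np.random.SeedSequence(config.seed).spawn(5)


def _architecture(config: SimulationConfig) -> _Architecture:
    config.validate()
    rng = np.random.default_rng(_seed_children(config)[0])

    # --- gene intervals, non-overlapping, spread over chromosomes
    n_chrom = min(_N_CHROM, config.n_genes)
    per_chrom = np.full(n_chrom, config.n_genes // n_chrom)
    per_chrom[: config.n_genes % n_chrom] += 1
    gene_chrom, gene_start, gene_end = [], [], []
    for c in range(n_chrom):
        cursor = 0
        for _ in range(per_chrom[c]):
            gap = int(rng.integers(_GENE_GAP[0], _GENE_GAP[1] + 1))
            length = int(rng.integers(_GENE_LEN[0], _GENE_LEN[1] + 1))
            start = cursor + gap
            gene_chrom.append(str(c + 1))
            gene_start.append(start)
            gene_end.append(start + length - 1)
            cursor = start + length - 1
    gene_ids = np.array([f"G{i:04d}" for i in range(config.n_genes)], dtype=object)
    genes = GeneAnnotation(
        gene_ids=gene_ids,
        chrom=np.array(gene_chrom, dtype=object),
        start=np.array(gene_start, dtype=np.int64),
        end=np.array(gene_end, dtype=np.int64),
    )

    # --- causal genes (chosen before SNP assignment so each gets a SNP)
    if config.n_causal_genes > 0:
        causal_gene_idx = np.sort(
            rng.choice(config.n_genes, size=config.n_causal_genes, replace=False)
        )
    else:
        causal_gene_idx = np.array([], dtype=np.intp)

    # --- assign SNP counts to genes
    n_genic = int(round(config.n_snps * (1.0 - config.intergenic_fraction)))
    n_inter = config.n_snps - n_genic
    counts = np.zeros(config.n_genes, dtype=np.intp)
    counts[causal_gene_idx] += 1
    remaining = n_genic - len(causal_gene_idx)
    if remaining > 0:
        extra = rng.choice(config.n_genes, size=remaining, replace=True)
        np.add.at(counts, extra, 1)

    records = []  # (chrom_key, pos, gene_idx, source_idx placeholder)
    for gi in range(config.n_genes):
        k = int(counts[gi])
        if k == 0:
            continue
        span = np.arange(genes.start[gi], genes.end[gi] + 1)
        ppos = np.sort(rng.choice(span, size=k, replace=False))
        for p in ppos:
            records.append([int(gene_chrom[gi]), int(p), gi])

    # --- intergenic SNPs in the gaps, clear of default flanks
    if n_inter > 0:
        intervals = []  # (chrom_key, lo, hi)
        gi = 0
        for c in range(n_chrom):
            idx = [i for i in range(config.n_genes) if gene_chrom[i] == str(c + 1)]
            prev_end = 0
            for i in idx:
                lo = prev_end + _INTERGENIC_CLEARANCE + 1
                hi = gene_start[i] - _INTERGENIC_CLEARANCE - 1
                if hi >= lo:
                    intervals.append((c + 1, lo, hi))
                prev_end = gene_end[i]
            intervals.append((c + 1, prev_end + _INTERGENIC_CLEARANCE + 1,
                              prev_end + _INTERGENIC_CLEARANCE + 30_000))
        lengths = np.array([hi - lo + 1 for _, lo, hi in intervals], dtype=float)
        pick = rng.choice(len(intervals), size=n_inter, p=lengths / lengths.sum())
        for iv in range(len(intervals)):
            k = int((pick == iv).sum())
            if k == 0:
                continue
            c, lo, hi = intervals[iv]
            ppos = np.sort(rng.choice(np.arange(lo, hi + 1), size=min(k, hi - lo + 1), replace=False))
            for p in ppos:
                records.append([c, int(p), -1])

    # sort by (chrom, pos); deduplicate positions by nudging (+1)
    records.sort(key=lambda r: (r[0], r[1]))
    for i in range(1, len(records)):
        if records[i][0] == records[i - 1][0] and records[i][1] <= records[i - 1][1]:
            records[i][1] = records[i - 1][1] + 1
    m = len(records)
    chrom = np.array([str(r[0]) for r in records], dtype=object)
    pos = np.array([r[1] for r in records], dtype=np.int64)
    gene_of = np.array([r[2] for r in records], dtype=np.intp)
    source_of = np.full(m, -1, dtype=np.intp)

    # --- one causal SNP per causal gene
    causal_snp_idx = []
    for gi in causal_gene_idx:
        in_gene = np.flatnonzero(gene_of == gi)
        causal_snp_idx.append(int(rng.choice(in_gene)))
    causal_snp_idx = np.array(sorted(causal_snp_idx), dtype=np.intp)

    # --- optional LD proxies of causal SNPs
    if config.ld_proxies > 0 and len(causal_snp_idx):
        extra = []
        for ci in causal_snp_idx:
            for j in range(config.ld_proxies):
                extra.append(
                    [int(chrom[ci]), int(pos[ci]) + _PROXY_SPACING * (j + 1), int(gene_of[ci]), int(ci)]
                )
        merged = [[int(chrom[i]), int(pos[i]), int(gene_of[i]), -1, i] for i in range(m)]
        merged += [[e[0], e[1], e[2], e[3], -1] for e in extra]
        merged.sort(key=lambda r: (r[0], r[1], r[4]))
        for i in range(1, len(merged)):
            if merged[i][0] == merged[i - 1][0] and merged[i][1] <= merged[i - 1][1]:
                merged[i][1] = merged[i - 1][1] + 1
        old_to_new = {}
        for new_i, r in enumerate(merged):
            if r[4] >= 0:
                old_to_new[r[4]] = new_i
        m = len(merged)
        chrom = np.array([str(r[0]) for r in merged], dtype=object)
        pos = np.array([r[1] for r in merged], dtype=np.int64)
        gene_of = np.array([r[2] for r in merged], dtype=np.intp)
        source_of = np.array(
            [-1 if r[3] < 0 else old_to_new[r[3]] for r in merged], dtype=np.intp
        )
        causal_snp_idx = np.array(sorted(old_to_new[int(i)] for i in causal_snp_idx), dtype=np.intp)

    snp_ids = np.array([f"snp{i:06d}" for i in range(m)], dtype=object)

    # --- gene sets
    smin, smax = config.set_size_range
    sets_list: list[GeneSet] = []
    ci = (
        (config.causal_set_index if config.causal_set_index is not None else 0)
        if config.n_causal_genes > 0
        else None
    )
    all_genes = np.arange(config.n_genes)
    causal_set_id = None
    for si in range(config.n_sets):
        size = int(rng.integers(smin, smax + 1))
        if ci is not None and si == ci:
            size = max(size, len(causal_gene_idx))
            others = np.setdiff1d(all_genes, causal_gene_idx)
            fill = rng.choice(others, size=size - len(causal_gene_idx), replace=False)
            members = np.sort(np.concatenate([causal_gene_idx, fill]))
            causal_set_id = f"S{si:03d}"
        else:
            members = np.sort(rng.choice(all_genes, size=size, replace=False))
        sets_list.append(
            GeneSet(
                set_id=f"S{si:03d}",
                description="simulated pathway",
                members=tuple(gene_ids[members]),
            )
        )
    return _Architecture(
        genes=genes,
        sets=GeneSetCollection(sets_list),
        snp_ids=snp_ids,
        chrom=chrom,
        pos=pos,
        gene_of_snp=gene_of,
        source_of_snp=source_of,
        causal_snp_idx=causal_snp_idx,
        causal_gene_idx=causal_gene_idx,
        causal_set_id=causal_set_id,
    )


# ---------------------------------------------------------------------------
# public simulation operations
# ---------------------------------------------------------------------------


def simulate_gene_architecture(config: SimulationConfig):
    """Gene annotation and gene-set collection of the simulated study."""
    arch = _architecture(config)
    return arch.genes, arch.sets


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """HWE genotypes at the study's SNP positions.

    Per SNP, an alternate-allele frequency is drawn uniformly from
    ``maf_range`` and dosages are Binomial(2, f); proxies copy their source
    causal SNP with per-entry corruption; missing entries are masked at
    ``missing_rate``.
    """
    arch = _architecture(config)
    children = _seed_children(config)
    rng = np.random.default_rng(children[1])
    n, m = config.n_individuals, len(arch.snp_ids)

    lo, hi = config.maf_range
    f = rng.uniform(lo, hi, size=m)
    letters = rng.integers(0, 4, size=(m, 2))
    letters[:, 1] = (letters[:, 0] + 1 + rng.integers(0, 3, size=m)) % 4
    alleles = np.stack([_BASES[letters[:, 0]], _BASES[letters[:, 1]]], axis=1)

    dosage = rng.binomial(2, f, size=(n, m)).astype(float)

    proxies = np.flatnonzero(arch.source_of_snp >= 0)
    if proxies.size:
        rng_prox = np.random.default_rng(children[4])
        for j in proxies:
            src = arch.source_of_snp[j]
            f[j] = f[src]
            alleles[j] = alleles[src]
            col = dosage[:, src].copy()
            corrupt = rng_prox.random(n) < config.ld_corruption
            col[corrupt] = rng_prox.binomial(2, f[src], size=int(corrupt.sum()))
            dosage[:, j] = col

    if config.missing_rate > 0 and n > 0:
        rng_miss = np.random.default_rng(children[3])
        dosage[rng_miss.random((n, m)) < config.missing_rate] = np.nan

    gm = GenotypeMatrix(
        individual_ids=np.array([f"I{i:05d}" for i in range(n)], dtype=object),
        snp_ids=arch.snp_ids,
        chrom=arch.chrom,
        pos=arch.pos,
        alleles=alleles,
        dosage=dosage,
    )
    gm.validate()
    return gm


def causal_effects(config: SimulationConfig, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Causal SNP ids and their per-SNP additive effects on log10(TG).

    With ``beta=None`` each effect is calibrated so the expected regression
    noncentrality matches ``target_causal_p`` at this sample size and the
    SNP's observed allele frequency.
    """
    arch = _architecture(config)
    snp_index = {s: j for j, s in enumerate(genotypes.snp_ids)}
    rows = []
    for ci in arch.causal_snp_idx:
        sid = str(arch.snp_ids[ci])
        j = snp_index.get(sid)
        if j is None:
            raise ConfigurationError(f"causal SNP {sid!r} absent from the genotype matrix")
        col = genotypes.dosage[:, j]
        ok = ~np.isnan(col)
        fhat = col[ok].mean() / 2.0 if ok.any() else 0.0
        if config.beta is not None:
            beta = float(config.beta)
        else:
            var = 2.0 * fhat * (1.0 - fhat)
            if var <= 0 or config.n_individuals < 3:
                beta = 0.0
            else:
                target = sps.chi2.isf(config.target_causal_p, df=1)
                beta = float(config.sigma * np.sqrt(target / (var * config.n_individuals)))
        rows.append((sid, str(arch.genes.gene_ids[arch.gene_of_snp[ci]]), beta))
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "beta"])


def simulate_phenotypes(genotypes: GenotypeMatrix, config: SimulationConfig) -> pd.DataFrame:
    """TG (mg/dL), BMI and sex for each genotyped individual.

    log10(TG) is additive in the causal dosages plus a BMI term and Gaussian
    noise; the small fraction of missing causal genotypes is mean-imputed
    for phenotype generation only.
    """
    effects = causal_effects(config, genotypes)
    children = _seed_children(config)
    rng = np.random.default_rng(children[2])
    n = genotypes.n_individuals

    bmi = rng.normal(config.bmi_mean, config.bmi_sd, size=n)
    sex = np.where(rng.random(n) < 0.95, 2, 1)  # mostly-female cohort
    noise = rng.normal(0.0, config.sigma, size=n) if config.sigma > 0 else np.zeros(n)

    log_tg = np.full(n, config.tg_location, dtype=float)
    snp_index = {s: j for j, s in enumerate(genotypes.snp_ids)}
    for _, row in effects.iterrows():
        col = genotypes.dosage[:, snp_index[row["snp_id"]]].copy()
        nanmask = np.isnan(col)
        if nanmask.any():
            col[nanmask] = col[~nanmask].mean() if (~nanmask).any() else 0.0
        log_tg += row["beta"] * col
    log_tg += config.bmi_slope * (bmi - config.bmi_mean) + noise

    return pd.DataFrame(
        {
            "individual_id": genotypes.individual_ids,
            "tg": 10.0**log_tg,
            "bmi": bmi,
            "sex": sex,
        }
    )


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """One complete simulated study, byte-reproducible from the config."""
    genotypes = simulate_genotypes(config)
    phenotypes = simulate_phenotypes(genotypes, config)
    genes, sets = simulate_gene_architecture(config)
    arch = _architecture(config)
    effects = causal_effects(config, genotypes)
    proxies: dict[str, list[str]] = {}
    for j in np.flatnonzero(arch.source_of_snp >= 0):
        src = str(arch.snp_ids[arch.source_of_snp[j]])
        proxies.setdefault(src, []).append(str(arch.snp_ids[j]))
    truth = {
        "seed": config.seed,
        "causal_snps": effects["snp_id"].tolist(),
        "causal_genes": [str(g) for g in arch.genes.gene_ids[arch.causal_gene_idx]],
        "causal_set": arch.causal_set_id,
        "betas": {r["snp_id"]: r["beta"] for _, r in effects.iterrows()},
        "proxy_snps": proxies,
    }
    return StudyBundle(
        genotypes=genotypes,
        phenotypes=phenotypes,
        genes=genes,
        sets=sets,
        truth=truth,
        seed=config.seed,
    )


def write_study(bundle: StudyBundle, outdir) -> dict[str, Path]:
    """Write a study to disk: .ped/.map, phenotype TSV, BED, GMT, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": outdir / "study.ped",
        "map": outdir / "study.map",
        "phenotypes": outdir / "phenotypes.tsv",
        "genes": outdir / "genes.bed",
        "sets": outdir / "sets.gmt",
        "truth": outdir / "truth.json",
    }
    pio.write_ped_map(bundle.genotypes, paths["ped"], paths["map"])
    pio.write_phenotypes(bundle.phenotypes, paths["phenotypes"])
    pio.write_bed_genes(bundle.genes, paths["genes"])
    pio.write_gmt(bundle.sets, paths["sets"])
    pio.write_json(bundle.truth, paths["truth"])
    return paths


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["maf_range"] = list(d["maf_range"])
    d["set_size_range"] = list(d["set_size_range"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "maf_range" in d:
        d["maf_range"] = tuple(d["maf_range"])
    if "set_size_range" in d:
        d["set_size_range"] = tuple(d["set_size_range"])
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg
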