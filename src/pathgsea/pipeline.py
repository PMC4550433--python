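"""End-to-end orchestration: simulate/load -> phenotype prep -> GWAS ->
pathway analysis, with deterministic outputs and a run manifest.

The pipeline writes, into one output directory: the prepared phenotype
table, one GWAS TSV per phenotype arm, enrichment result TSVs for both the
phenotype-permutation and the SNP-label-permutation mode, optional QQ and
Manhattan-style plots (side outputs only, never inputs to any computation),
a ``manifest.json`` recording every seed and threshold, and a ``run.log``.
Log lines carry no timestamps so that two runs with the same configuration
produce byte-identical directories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from . import assoc as asc
from . import io as pio
from .errors import ConfigurationError, DataError, PipelineError
from .gsea import GseaConfig, run_gengen
from .icsn import LdConfig, snp_label_permutation_gsea
from .phenotypes import prepare_phenotypes
from .simulate import (
    SimulationConfig,
    StudyBundle,
    config_from_dict,
    config_to_dict,
    simulate_study,
    write_study,
)
from .snp2gene import map_snps_to_genes

logger = logging.getLogger("pathgsea")

_CHI2_MEDIAN_1DF = sps.chi2.ppf(0.5, df=1)  # 0.45494...


def qq_diagnostics(p_values, out_path=None, title: str = ""):
    """Genomic inflation factor and (optionally) a QQ plot.

    lambda_GC = median of the 1-df chi-square quantiles of the P-values
    divided by the null median 0.45494.  Requires >=10 P-values, all in
    (0, 1].  Returns (lambda_gc, plot_path_or_None).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 10:
        raise DataError("QQ diagnostics need at least 10 P-values")
    if np.any(np.isnan(p)) or np.any((p <= 0) | (p > 1)):
        raise DataError("P-values must lie in (0, 1]")
    chi = sps.chi2.isf(p, df=1)
    lam = float(np.median(chi) / _CHI2_MEDIAN_1DF)
    if out_path is None:
        return lam, None

    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = p.size
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    obs = -np.log10(np.sort(p))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(exp, obs, ".", ms=3, color="black")
    lim = max(exp.max(), obs.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="red", lw=1)
    ax.set_xlabel("expected $-\\log_{10} P$")
    ax.set_ylabel("observed $-\\log_{10} P$")
    ax.set_title(f"{title} (lambda = {lam:.3f})".strip())
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return lam, Path(out_path)


def manhattan_plot(assoc: pd.DataFrame, out_path, title: str = ""):
    """Simple Manhattan-style plot of -log10(P) by position (side output)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = assoc.sort_values(["chrom", "pos"], kind="mergesort")
    fig, ax = plt.subplots(figsize=(7, 3))
    offset, ticks, labels = 0, [], []
    for i, (c, sub) in enumerate(df.groupby("chrom", sort=False)):
        x = offset + np.arange(len(sub))
        ax.plot(x, -np.log10(sub["p"].to_numpy()), ".", ms=2,
                color="steelblue" if i % 2 == 0 else "darkorange")
        ticks.append(offset + len(sub) / 2)
        labels.append(str(c))
        offset += len(sub)
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("$-\\log_{10} P$")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return Path(out_path)


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either ``simulation`` is set (a study is generated) or the five input
    paths are given.  ``phenotype`` selects the arm used for the
    phenotype-permutation enrichment; the SNP-label arm consumes the same
    arm's GWAS P-values.
    """

    simulation: SimulationConfig | None = None
    ped: str | None = None
    map: str | None = None
    pheno: str | None = None
    genes: str | None = None
    sets: str | None = None
    phenotype: str = "binary"
    maf_min: float = 0.01
    hwe_min_p: float = 0.001
    flank: int = 20_000
    outlier_k: float = 3.0
    gsea: GseaConfig = field(default_factory=GseaConfig)
    ld: LdConfig = field(default_factory=LdConfig)
    outdir: str = "pathgsea_run"
    make_plots: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.simulation is None:
            paths = {"ped": self.ped, "map": self.map, "pheno": self.pheno,
                     "genes": self.genes, "sets": self.sets}
            missing = [k for k, v in paths.items() if v is None]
            if missing:
                raise ConfigurationError(
                    f"either a simulation block or input paths are required; missing {missing}"
                )
            absent = [v for v in paths.values() if not Path(v).exists()]
            if absent:
                raise ConfigurationError(f"input path(s) do not exist: {absent}")
        if self.phenotype not in asc.PHENOTYPE_CHOICES:
            raise ConfigurationError(f"phenotype must be one of {asc.PHENOTYPE_CHOICES}")
        self.gsea.validate()
        self.ld.validate()

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, **overrides)

    @classmethod
    def from_dict(cls, raw: dict, **overrides) -> "PipelineConfig":
        raw = dict(raw)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("simulation"), dict):
            raw["simulation"] = config_from_dict(raw["simulation"])
        if isinstance(raw.get("gsea"), dict):
            raw["gsea"] = GseaConfig(**raw["gsea"])
        if isinstance(raw.get("ld"), dict):
            raw["ld"] = LdConfig(**raw["ld"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys {sorted(unknown)}")
        return cls(**raw)


def _setup_logging(outdir: Path, level: str):
    logger.setLevel(level.upper())
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")  # no timestamps
    handlers = [logging.StreamHandler(), logging.FileHandler(outdir / "run.log", mode="w")]
    for h in handlers:
        h.setFormatter(fmt)
        logging.getLogger("pathgsea").addHandler(h)
    return handlers


def _teardown_logging(handlers):
    for h in handlers:
        logging.getLogger("pathgsea").removeHandler(h)
        h.close()


def load_study(cfg: PipelineConfig) -> StudyBundle:
    gm = pio.read_ped_map(cfg.ped, cfg.map)
    pheno = pio.read_phenotypes(cfg.pheno)
    genes = pio.read_bed_genes(cfg.genes)
    sets = pio.read_gmt(cfg.sets)
    return StudyBundle(
        genotypes=gm, phenotypes=pheno, genes=genes, sets=sets,
        truth={}, seed=cfg.gsea.seed,
    )


def run_full_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and return the output directory.

    Stage failures propagate as :class:`PipelineError` naming the stage;
    partial outputs are retained next to a ``FAILED`` marker file.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handlers = _setup_logging(outdir, cfg.log_level)
    manifest: dict = {
        "package": "pathgsea",
        "version": __version__,
        "phenotype_arm": cfg.phenotype,
        "qc": {"maf_min": cfg.maf_min, "hwe_min_p": cfg.hwe_min_p},
        "flank_bp": cfg.flank,
        "outlier_k": cfg.outlier_k,
        "gsea": {
            "p_weight": cfg.gsea.p_weight, "n_perm": cfg.gsea.n_perm,
            "set_min": cfg.gsea.set_min, "set_max": cfg.gsea.set_max,
            "seed": cfg.gsea.seed,
        },
        "ld": {"r2_min": cfg.ld.r2_min, "window": cfg.ld.window},
        "files": [],
        "lambda_gc": {},
    }
    stage = "setup"
    try:
        stage = "study"
        if cfg.simulation is not None:
            study = simulate_study(cfg.simulation)
            write_study(study, outdir / "study")
            manifest["simulation"] = config_to_dict(cfg.simulation)
            manifest["files"] += [f"study/{p.name}" for p in sorted((outdir / "study").iterdir())]
            logger.info("simulated study: %d individuals, %d SNPs, %d genes, %d sets",
                        study.genotypes.n_individuals, study.genotypes.n_snps,
                        len(study.genes), len(study.sets))
        else:
            study = load_study(cfg)
            manifest["inputs"] = {k: str(getattr(cfg, k)) for k in
                                  ("ped", "map", "pheno", "genes", "sets")}
            logger.info("loaded study from %s", cfg.ped)

        stage = "phenotype_prep"
        prepared = prepare_phenotypes(study.phenotypes, outlier_k=cfg.outlier_k)
        pio.write_phenotypes(prepared, outdir / "phenotypes_prepared.tsv")
        manifest["files"].append("phenotypes_prepared.tsv")
        n_excl = int((~prepared["included"]).sum())
        logger.info("phenotypes prepared: %d individuals, %d excluded as log(TG) outliers",
                    len(prepared), n_excl)

        stage = "gwas"
        gwas: dict[str, pd.DataFrame] = {}
        for arm in asc.PHENOTYPE_CHOICES:
            res = asc.run_gwas(study.genotypes, prepared, arm,
                               maf_min=cfg.maf_min, hwe_min_p=cfg.hwe_min_p)
            gwas[arm] = res
            name = f"gwas_{arm}.tsv"
            pio.write_assoc(res, outdir / name)
            manifest["files"].append(name)
            lam, _ = qq_diagnostics(res["p"].to_numpy())
            manifest["lambda_gc"][arm] = lam
            logger.info("GWAS %s: %d SNPs tested, lambda_GC = %.4f", arm, len(res), lam)
            if cfg.make_plots:
                qq_diagnostics(res["p"].to_numpy(), outdir / f"qq_{arm}.png", title=arm)
                manhattan_plot(res, outdir / f"manhattan_{arm}.png", title=arm)
                manifest["files"] += [f"qq_{arm}.png", f"manhattan_{arm}.png"]

        stage = "gengen"
        gengen = run_gengen(
            StudyBundle(study.genotypes, prepared, study.genes, study.sets,
                        study.truth, study.seed),
            cfg.gsea, phenotype=cfg.phenotype,
            maf_min=cfg.maf_min, hwe_min_p=cfg.hwe_min_p, flank=cfg.flank,
        )
        pio.write_results(gengen, outdir / "enrichment_phenotype_perm.tsv",
                          n_perm=cfg.gsea.n_perm)
        manifest["files"].append("enrichment_phenotype_perm.tsv")
        logger.info("phenotype-permutation enrichment: %d sets tested", len(gengen))

        stage = "snp_label"
        snp_map = map_snps_to_genes(study.genotypes, study.genes, flank=cfg.flank)
        snplabel = snp_label_permutation_gsea(
            gwas[cfg.phenotype], snp_map, study.sets, cfg.gsea
        )
        pio.write_results(snplabel, outdir / "enrichment_snp_label_perm.tsv",
                          n_perm=cfg.gsea.n_perm)
        manifest["files"].append("enrichment_snp_label_perm.tsv")
        logger.info("SNP-label-permutation enrichment: %d sets tested", len(snplabel))

        stage = "manifest"
        manifest["files"].append("manifest.json")
        manifest["files"].append("run.log")
        manifest["files"].sort()
        pio.write_json(manifest, outdir / "manifest.json")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        _teardown_logging(handlers)
        if isinstance(exc, (PipelineError, DataError, ConfigurationError)):
            raise PipelineError(f"stage {stage}: {exc}") from exc
        raise
    _teardown_logging(handlers)
    return outdir
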