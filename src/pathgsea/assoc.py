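"""Per-SNP quality control and association tests.

Two test families, mirroring the standard array-GWAS toolkit:

* quantitative traits: simple linear regression of the trait on allele
  dosage; the reported statistic is the squared Wald t, identical to the
  1-df F statistic, with the P-value from F(1, n-2);
* binary traits: the 1-df allelic (2x2 allele-count) Pearson chi-square
  without continuity correction, each individual contributing two alleles.
  A Cochran-Armitage trend test is available behind ``binary_test="trend"``.

QC follows the usual array conventions: SNPs are kept when the minor-allele
frequency exceeds ``maf_min`` (default 0.01) and the 1-df Hardy-Weinberg
goodness-of-fit P-value exceeds ``hwe_min_p`` (default 0.001).

Both statistics are invariant under relabeling the counted allele
(dosage -> 2 - dosage).  P-values are never reported as exactly 0: underflow
clamps to the smallest positive double and flags the result.

The ``*_bulk`` helpers evaluate a test for every SNP column of a dosage
matrix at once; permutation nulls re-enter through them.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, PipelineError
from .io import GenotypeMatrix
from . import phenotypes as ph

P_FLOOR = np.nextafter(0.0, 1.0)

FLAG_OK = ""
FLAG_DEGENERATE = "degenerate"
FLAG_EXACT_FIT = "exact_fit"


class TestResult(NamedTuple):
    stat: float
    p: float
    flag: str = FLAG_OK


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------


def compute_maf(dosages) -> float:
    """Minor-allele frequency from dosages (NaN = missing)."""
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    n = int(ok.sum())
    if n == 0:
        raise DataError("MAF undefined: all genotypes missing")
    f = d[ok].sum() / (2.0 * n)
    return float(min(f, 1.0 - f))


def maf_bulk(dosage: np.ndarray) -> np.ndarray:
    mask = ~np.isnan(dosage)
    n = mask.sum(axis=0)
    s = np.nansum(dosage, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n > 0, s / np.maximum(2.0 * n, 1), np.nan)
    return np.minimum(f, 1.0 - f)


def hwe_test(dosages) -> float:
    """1-df chi-square goodness-of-fit P-value for Hardy-Weinberg equilibrium.

    Genotype counts (n0, n1, n2) are compared with expectations from the
    sample allele frequency.  Monomorphic SNPs return P = 1 by convention.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise DataError("HWE undefined: all genotypes missing")
    counts = np.array([(d == k).sum() for k in (0.0, 1.0, 2.0)], dtype=float)
    return float(_hwe_from_counts(counts[None, :])[0])


def hwe_test_counts(n0: int, n1: int, n2: int) -> TestResult:
    """HWE chi-square and P directly from genotype counts (n0, n1, n2)."""
    counts = np.array([[n0, n1, n2]], dtype=float)
    n = counts.sum()
    if n == 0:
        raise DataError("HWE undefined: no genotypes")
    f = (2 * counts[0, 2] + counts[0, 1]) / (2 * n)
    if f <= 0 or f >= 1:
        return TestResult(0.0, 1.0, FLAG_DEGENERATE)
    exp = np.array([n * (1 - f) ** 2, 2 * n * f * (1 - f), n * f**2])
    stat = float((((counts[0] - exp) ** 2) / exp).sum())
    return TestResult(stat, float(_hwe_from_counts(counts)[0]), FLAG_OK)


def _hwe_from_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorized HWE P-values from an (m, 3) genotype-count array."""
    n = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (2.0 * counts[:, 2] + counts[:, 1]) / np.maximum(2.0 * n, 1)
        exp = np.stack(
            [n * (1 - f) ** 2, 2 * n * f * (1 - f), n * f**2], axis=1
        )
        chi = np.where(exp > 0, (counts - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0)
        stat = chi.sum(axis=1)
    mono = (f <= 0) | (f >= 1) | (n == 0)
    p = sps.chi2.sf(stat, df=1)
    p = np.where(mono, 1.0, p)
    return np.maximum(p, P_FLOOR)


def hwe_bulk(dosage: np.ndarray) -> np.ndarray:
    counts = np.stack(
        [(dosage == k).sum(axis=0) for k in (0.0, 1.0, 2.0)], axis=1
    ).astype(float)
    return _hwe_from_counts(counts)


# ---------------------------------------------------------------------------
# binary test: allelic chi-square (and trend variant)
# ---------------------------------------------------------------------------


def _case_control_masks(status) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(status)
    if s.dtype == bool:
        return s, ~s
    return s == ph.CASE, s == ph.CONTROL


def chisq_2x2(a, b, c, d) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson chi-square (1 df, no continuity correction) on [[a,b],[c,d]].

    Returns (stat, p, degenerate) arrays; any zero margin gives stat 0, p 1
    flagged degenerate.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    degen = denom <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(degen, 0.0, n * (a * d - b * c) ** 2 / np.where(degen, 1, denom))
    p = np.where(degen, 1.0, sps.chi2.sf(stat, df=1))
    return stat, np.maximum(p, P_FLOOR), degen


def allelic_counts_bulk(
    filled: np.ndarray, mask_f: np.ndarray, is_case: np.ndarray, is_control: np.ndarray
):
    """2x2 allele-count tables per SNP.

    ``filled`` is the dosage matrix with missing set to 0, ``mask_f`` the
    float non-missing indicator; ``is_case``/``is_control`` are float row
    weights (0/1).  Returns (a, b, c, d): counted/other allele counts in
    cases then controls.
    """
    a = is_case @ filled
    na = 2.0 * (is_case @ mask_f)
    c = is_control @ filled
    nc = 2.0 * (is_control @ mask_f)
    return a, na - a, c, nc - c


def allelic_chisq_bulk(dosage: np.ndarray, status) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    case, ctrl = _case_control_masks(status)
    mask = ~np.isnan(dosage)
    filled = np.where(mask, dosage, 0.0)
    a, b, c, d = allelic_counts_bulk(
        filled, mask.astype(float), case.astype(float), ctrl.astype(float)
    )
    return chisq_2x2(a, b, c, d)


def allelic_chisq(dosages, status) -> TestResult:
    """Allelic 1-df chi-square for one SNP.

    ``status`` is either a boolean array (True = case, False = control) or an
    array of {"case", "control", "unknown"} strings; unknowns are excluded.
    """
    d = np.asarray(dosages, dtype=float)
    case, ctrl = _case_control_masks(status)
    used = (case | ctrl) & ~np.isnan(d)
    if not (case & used).any() or not (ctrl & used).any():
        raise DataError("allelic test needs >=1 case and >=1 control with genotypes")
    stat, p, degen = allelic_chisq_bulk(d[used][:, None], case[used])
    flag = FLAG_DEGENERATE if degen[0] else FLAG_OK
    return TestResult(float(stat[0]), float(p[0]), flag)


def trend_chisq_bulk(dosage: np.ndarray, status) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cochran-Armitage trend chi-square (1 df) per SNP, additive scores."""
    case, ctrl = _case_control_masks(status)
    used = case | ctrl
    mask = ~np.isnan(dosage) & used[:, None]
    filled = np.where(mask, dosage, 0.0)
    mf = mask.astype(float)
    casef = case.astype(float)
    n = mf.sum(axis=0)
    r = casef @ mf  # cases with genotype, per SNP
    sd = filled.sum(axis=0)
    sd2 = (filled**2).sum(axis=0)
    scase = casef @ filled
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (n * scase - r * sd) ** 2
        den = r * (n - r) * (n * sd2 - sd**2)
        degen = den <= 0
        stat = np.where(degen, 0.0, n * num / np.where(degen, 1, den))
    p = np.where(degen, 1.0, sps.chi2.sf(stat, df=1))
    return stat, np.maximum(p, P_FLOOR), degen


# ---------------------------------------------------------------------------
# quantitative test: simple linear regression
# ---------------------------------------------------------------------------


def linreg_from_moments(n, sx, sxx, sy, syy, sxy):
    """Regression F statistic (= squared t) and P from per-SNP moment sums."""
    n, sx, sxx, sy, syy, sxy = (np.asarray(v, dtype=float) for v in (n, sx, sxx, sy, syy, sxy))
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = sxx - sx * sx / np.maximum(n, 1)
        vy = syy - sy * sy / np.maximum(n, 1)
        cov = sxy - sx * sy / np.maximum(n, 1)
        degen = (vx <= 0) | (vy <= 0) | (n < 3)
        r2 = np.where(degen, 0.0, cov**2 / np.where(degen, 1.0, vx * vy))
    r2 = np.clip(r2, 0.0, 1.0)
    exact = (~degen) & (r2 >= 1.0 - 1e-14)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(
            degen, 0.0, (n - 2) * r2 / np.where(exact, 1.0, np.maximum(1.0 - r2, 1e-300))
        )
    stat = np.where(exact, np.inf, stat)
    p = np.where(degen, 1.0, sps.f.sf(stat, 1, np.maximum(n - 2, 1)))
    p = np.where(exact, P_FLOOR, p)
    flag = np.where(exact, FLAG_EXACT_FIT, np.where(degen, FLAG_DEGENERATE, FLAG_OK))
    return stat, np.maximum(p, P_FLOOR), flag


def linreg_bulk(dosage: np.ndarray, y: np.ndarray):
    """Per-SNP simple linear regression of ``y`` on dosage, pairwise deletion."""
    mask = ~np.isnan(dosage)
    filled = np.where(mask, dosage, 0.0)
    mf = mask.astype(float)
    n = mf.sum(axis=0)
    sx = filled.sum(axis=0)
    sxx = (filled * filled).sum(axis=0)
    sy = y @ mf
    syy = (y * y) @ mf
    sxy = y @ filled
    return linreg_from_moments(n, sx, sxx, sy, syy, sxy)


def linreg_assoc(dosages, y) -> TestResult:
    """Simple linear regression test for one SNP.

    Returns the 1-df F statistic (squared Wald t) and its P-value.  A
    constant dosage gives (0, 1) flagged degenerate; an exact fit clamps the
    P-value to the smallest positive double and flags ``exact_fit``.
    """
    d = np.asarray(dosages, dtype=float)
    yv = np.asarray(y, dtype=float)
    ok = ~np.isnan(d) & ~np.isnan(yv)
    if ok.sum() < 3:
        raise DataError("linear regression needs >=3 complete pairs")
    stat, p, flag = linreg_bulk(d[ok][:, None], yv[ok])
    return TestResult(float(stat[0]), float(p[0]), str(flag[0]))


# ---------------------------------------------------------------------------
# GWAS driver
# ---------------------------------------------------------------------------

PHENOTYPE_CHOICES = ("log_tg", "log_tg_adj", "binary")


def qc_mask(
    dosage: np.ndarray, maf_min: float = 0.01, hwe_min_p: float = 0.001
) -> np.ndarray:
    """Boolean keep-mask: MAF > maf_min and HWE P > hwe_min_p."""
    maf = maf_bulk(dosage)
    hwe = hwe_bulk(dosage)
    return (maf > maf_min) & (hwe > hwe_min_p)


def select_analysis_individuals(
    genotypes: GenotypeMatrix, pheno: pd.DataFrame, phenotype: str
):
    """Align phenotypes to genotype rows and pick the analysis arm.

    Returns (row_index, y) where ``y`` is the quantitative trait vector, or
    (row_index, is_case) boolean for the binary arm.  Quantitative arms use
    outlier-included individuals; the binary arm uses everyone with a
    case/control status (the borderline band is excluded entirely).
    """
    if phenotype not in PHENOTYPE_CHOICES:
        raise DataError(f"unknown phenotype {phenotype!r}; choose from {PHENOTYPE_CHOICES}")
    tab = pheno.set_index("individual_id")
    ids = genotypes.individual_ids
    missing = [i for i in ids if i not in tab.index]
    if missing:
        raise DataError(f"phenotype table missing individuals, e.g. {missing[0]!r}")
    tab = tab.loc[list(ids)]
    if phenotype == "binary":
        keep = tab["status"].isin((ph.CASE, ph.CONTROL)).to_numpy()
        y = (tab["status"].to_numpy()[keep] == ph.CASE)
    else:
        col = tab[phenotype].to_numpy(dtype=float)
        keep = tab["included"].to_numpy(dtype=bool) & ~np.isnan(col)
        y = col[keep]
    return np.flatnonzero(keep), y


def run_gwas(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    phenotype: str,
    maf_min: float = 0.01,
    hwe_min_p: float = 0.001,
    binary_test: str = "allelic",
) -> pd.DataFrame:
    """QC-filtered single-marker GWAS.

    ``pheno`` is a prepared phenotype table (see
    :func:`pathgsea.phenotypes.prepare_phenotypes`).  SNPs failing the MAF or
    HWE threshold are excluded before testing; per-SNP missing genotypes are
    dropped pairwise.  Returns a table with columns snp_id, chrom, pos, maf,
    test, stat, p, n_used, flag.
    """
    rows, y = select_analysis_individuals(genotypes, pheno, phenotype)
    D = genotypes.dosage[rows, :]
    keep = qc_mask(D, maf_min=maf_min, hwe_min_p=hwe_min_p)
    if not keep.any():
        raise PipelineError("no SNP survives MAF/HWE quality control")
    idx = np.flatnonzero(keep)
    Dk = D[:, idx]
    maf = maf_bulk(Dk)
    n_used_geno = (~np.isnan(Dk)).sum(axis=0)

    if phenotype == "binary":
        if y.all() or not y.any():
            raise DataError("fewer than 2 distinct phenotype values in the binary arm")
        if binary_test == "allelic":
            stat, p, degen = allelic_chisq_bulk(Dk, y)
            test = "chisq_allelic"
        elif binary_test == "trend":
            stat, p, degen = trend_chisq_bulk(Dk, y)
            test = "chisq_trend"
        else:
            raise DataError(f"unknown binary test {binary_test!r}")
        flag = np.where(degen, FLAG_DEGENERATE, FLAG_OK)
    else:
        stat, p, flag = linreg_bulk(Dk, y)
        test = "linreg"

    return pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids[idx],
            "chrom": genotypes.chrom[idx],
            "pos": genotypes.pos[idx],
            "maf": maf,
            "test": test,
            "stat": stat,
            "p": p,
            "n_used": n_used_geno,
            "flag": flag,
        }
    )
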