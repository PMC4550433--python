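"""Phenotype preparation for triglyceride association analyses.

Raw plasma triglycerides (TG, mg/dL) and BMI (kg/m^2) are turned into the
three analysis phenotypes:

* ``log_tg`` — base-10 log of TG.  Base 10 is used because typical plasma
  TG values of 34–858 mg/dL land on a log scale of roughly 1.5–2.9, the
  range over which lipid traits are usually reported;
* ``log_tg_adj`` — standardized residuals of an OLS regression of log10(TG)
  on BMI (mean 0, SD 1 over the individuals entering the regression);
* ``status`` — ternary case/control/unknown from clinical thresholds:
  TG > 200 mg/dL is a case, TG < 150 mg/dL a control, and the borderline
  band 150 <= TG <= 200 is "unknown" and excluded from binary analyses.

Outlier removal is a single pass on log10(TG): individuals more than
``k`` sample SDs from the sample mean (both computed from all input values)
are flagged excluded before the BMI adjustment is fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError

CASE = "case"
CONTROL = "control"
UNKNOWN = "unknown"

TG_CASE_MGDL = 200.0
TG_CONTROL_MGDL = 150.0


def log_transform(tg_values, individual_ids=None) -> np.ndarray:
    """Elementwise log10 of TG values; non-positive values are a data error."""
    tg = np.asarray(tg_values, dtype=float)
    bad = ~(tg > 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        who = individual_ids[i] if individual_ids is not None else f"index {i}"
        raise DataError(f"non-positive TG value {tg[i]!r} for individual {who}")
    return np.log10(tg)


def remove_outliers(values, k: float = 3.0) -> np.ndarray:
    """Single-pass outlier mask: True = keep.

    Mean and SD (sample SD, ddof=1) come from *all* input values; the pass is
    not iterated after exclusions.  With zero variance nothing is removed
    (for k > 0).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DataError("outlier removal needs at least 2 values")
    mean = x.mean()
    sd = x.std(ddof=1)
    return ~(np.abs(x - mean) > k * sd)


def bmi_adjust(log_tg, bmi, return_fit: bool = False):
    """Standardized residuals of OLS log10(TG) ~ intercept + BMI.

    Residuals are divided by their sample SD, giving mean 0 and SD 1.  A
    constant BMI or an exact linear fit (zero residual variance) is a
    degenerate-covariate error.
    """
    y = np.asarray(log_tg, dtype=float)
    x = np.asarray(bmi, dtype=float)
    if y.size < 3:
        raise DataError("BMI adjustment needs at least 3 individuals")
    if np.ptp(x) == 0:
        raise DataError("BMI is constant; regression covariate is degenerate")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    resid = np.asarray(fit.resid)
    sd = resid.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(y).max())):
        raise DataError("zero residual variance: log(TG) is an exact function of BMI")
    z = resid / sd
    if return_fit:
        return z, fit
    return z


def binarize_tg(tg_values) -> np.ndarray:
    """Ternary status: TG > 200 case, TG < 150 control, 150 <= TG <= 200 unknown."""
    tg = np.asarray(tg_values, dtype=float)
    out = np.full(tg.shape, UNKNOWN, dtype=object)
    out[tg > TG_CASE_MGDL] = CASE
    out[tg < TG_CONTROL_MGDL] = CONTROL
    return out


def prepare_phenotypes(df: pd.DataFrame, outlier_k: float = 3.0) -> pd.DataFrame:
    """Full phenotype preparation.

    Input needs columns ``individual_id``, ``tg``, ``bmi`` (a raw table read
    by :func:`pathgsea.io.read_phenotypes` qualifies).  Returns a copy with
    ``log_tg``, ``included`` (outlier mask on log TG), ``log_tg_adj``
    (NaN for excluded individuals) and ``status``.

    Case/control status is assigned from raw TG for *all* individuals; the
    quantitative outlier flag does not feed the binary arm.
    """
    required = {"individual_id", "tg", "bmi"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"phenotype table missing columns {sorted(missing)}")
    out = df.copy()
    ids = out["individual_id"].to_numpy()
    out["log_tg"] = log_transform(out["tg"].to_numpy(), ids)
    included = remove_outliers(out["log_tg"].to_numpy(), k=outlier_k)
    out["included"] = included
    adj = np.full(len(out), np.nan)
    adj[included] = bmi_adjust(
        out.loc[included, "log_tg"].to_numpy(), out.loc[included, "bmi"].to_numpy()
    )
    out["log_tg_adj"] = adj
    out["status"] = binarize_tg(out["tg"].to_numpy())
    return out
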