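"""ROI summarization and group statistics.

Implements the downstream analysis stage: per-ROI map means, quadratic
age regression (metric ~ centered age + centered age^2 + sex, per ROI)
with Benjamini-Hochberg FDR across ROIs, the peak-age-of-NDI vertex
computation, and the NfL association model (z-scored log NfL regressed on
z-scored NDI with age and sex as covariates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "roi_means",
    "quadratic_age_fit",
    "fdr_adjust",
    "nfl_association",
    "RegressionReport",
]


@dataclass
class RegressionReport:
    """Per-ROI quadratic-age regression results.

    ``table`` has one row per ROI with columns: intercept, beta_age,
    beta_age2, beta_sex, their raw p-values, FDR-adjusted p-values
    (adjusted across ROIs, separately per coefficient), and peak_age —
    the age of maximum predicted metric, reported only for concave fits
    (negative age^2 coefficient) and NaN otherwise.
    """

    table: pd.DataFrame
    mean_age: float
    metric: str
    alpha: float = 0.05


def roi_means(values: np.ndarray, labels: np.ndarray) -> dict[int, float]:
    """Arithmetic mean of a map over each non-zero label, NaN-aware.

    Labels with no voxels (or only missing values) are reported as NaN
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("map and label volumes must share a grid")
    out: dict[int, float] = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = values[labels == lab]
        sel = sel[np.isfinite(sel)]
        if sel.size == 0:
            warnings.warn(f"ROI label {lab} has no valid voxels", stacklevel=2)
            out[int(lab)] = np.nan
        else:
            out[int(lab)] = float(sel.mean())
    return out


def fdr_adjust(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted, reject)``; adjusted p-values carry the standard
    cummin monotonicity enforcement and are clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, reject


def _check_full_rank(design: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify which column is linearly dependent on the preceding ones
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) <= np.linalg.matrix_rank(
                design[:, :j]
            ):
                raise ValueError(f"design matrix is rank-deficient: column "
                                 f"{names[j]!r} is collinear")
        raise ValueError("design matrix is rank-deficient")


def quadratic_age_fit(
    table: pd.DataFrame, metric: str = "ndi", alpha: float = 0.05
) -> RegressionReport:
    """Per-ROI OLS of a metric on centered age, centered age^2 and sex.

    Age is mean-centered over the subjects before squaring; sex is a 0/1
    code.  Interaction terms are omitted.  The age of peak metric is the
    parabola vertex ``mean_age - beta_age / (2 * beta_age2)``, reported
    only when the quadratic coefficient is negative (concave trajectory).
    P-values of each coefficient are FDR-adjusted across ROIs.
    """
    col = {"ndi": "mean_ndi", "odi": "mean_odi"}.get(metric, metric)
    subjects = table.drop_duplicates("subject_id")
    if len(subjects) < 10:
        raise ValueError("need >= 10 subjects")
    if table[["age", "sex"]].isna().any().any():
        raise ValueError("age and sex must not contain missing values")
    mean_age = float(subjects["age"].mean())
    rows = []
    for roi, grp in table.groupby("roi", sort=True):
        age_c = grp["age"].to_numpy() - mean_age
        design = np.column_stack(
            [np.ones(len(grp)), age_c, age_c**2, grp["sex"].to_numpy(float)]
        )
        names = ["intercept", "age", "age2", "sex"]
        _check_full_rank(design, names)
        fit = sm.OLS(grp[col].to_numpy(float), design).fit()
        b0, b_age, b_age2, b_sex = fit.params
        p0, p_age, p_age2, p_sex = fit.pvalues
        peak = mean_age - b_age / (2.0 * b_age2) if b_age2 < 0 else np.nan
        rows.append(
            dict(roi=roi, intercept=b0, beta_age=b_age, beta_age2=b_age2,
                 beta_sex=b_sex, p_age=p_age, p_age2=p_age2, p_sex=p_sex,
                 peak_age=peak, n=len(grp))
        )
    out = pd.DataFrame(rows).set_index("roi")
    for term in ("age", "age2", "sex"):
        adjusted, reject = fdr_adjust(out[f"p_{term}"].to_numpy(), alpha)
        out[f"p_{term}_fdr"] = adjusted
        out[f"sig_{term}"] = reject
    return RegressionReport(table=out, mean_age=mean_age, metric=metric,
                            alpha=alpha)


def nfl_association(table: pd.DataFrame, roi: str = "WB") -> dict:
    """Association between plasma NfL and NDI in one ROI.

    NfL is log-transformed (natural log) to remove skew; log NfL and NDI
    are then z-scored over the included sample, and z-NfL is regressed on
    z-NDI with age and sex as covariates.  Subjects with missing or
    non-positive NfL are excluded with a warning.  Returns the NDI
    coefficient (standardized beta), its p-value, the full coefficient
    vector and the sample size.
    """
    sub = table[table["roi"] == roi].copy()
    if "nfl" not in sub.columns:
        raise ValueError("table has no 'nfl' column")
    bad = sub["nfl"].isna() | (sub["nfl"] <= 0)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} subject(s) with missing or "
            "non-positive NfL", stacklevel=2,
        )
        sub = sub[~bad]
    if len(sub) < 10:
        raise ValueError("need >= 10 subjects with valid NfL")

    def zscore(x):
        return (x - x.mean()) / x.std(ddof=0)

    z_nfl = zscore(np.log(sub["nfl"].to_numpy(float)))
    z_ndi = zscore(sub["mean_ndi"].to_numpy(float))
    design = np.column_stack(
        [np.ones(len(sub)), z_ndi, sub["age"].to_numpy(float),
         sub["sex"].to_numpy(float)]
    )
    _check_full_rank(design, ["intercept", "ndi", "age", "sex"])
    fit = sm.OLS(z_nfl, design).fit()
    return {
        "beta_ndi": float(fit.params[1]),
        "p_ndi": float(fit.pvalues[1]),
        "coefficients": dict(zip(["intercept", "ndi", "age", "sex"], fit.params)),
        "n": int(len(sub)),
        "roi": roi,
    }
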