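"""Regional imaging statistics: group and hemispheric CT contrasts and
the per-(region, clinical feature) regression layer.

These produce the response variables of the two PLS models: the Welch
t-statistics of the patient/control thickness difference (single
response) and the t-statistics of the thickness-on-clinical-score
regression coefficients (multi response). All p-values are corrected
with Benjamini-Hochberg step-up FDR over the family stated per analysis.

Sign conventions: group contrasts are control minus patient, so a
positive t means thinner cortex in patients (atrophy); hemispheric
contrasts are right minus left, so a positive t means a thinner left
hemisphere.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import OLS
from statsmodels.stats.multitest import multipletests

from .synthetic import ct_column


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    flag: str | None = None


def welch_t(a: np.ndarray, b: np.ndarray) -> WelchResult:
    """Two-sample t-test assuming unequal variances (Welch).

    ``t = (mean(a) - mean(b)) / sqrt(s2_a/n_a + s2_b/n_b)`` with
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.
    Degenerate inputs (both variances zero) return a flagged result:
    ``t = +-inf, p = 0`` for distinct means, NaNs for equal means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite observations")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if diff == 0.0:
            return WelchResult(np.nan, np.nan, np.nan, "zero-variance-equal-means")
        return WelchResult(np.inf if diff > 0 else -np.inf, np.nan, 0.0, "zero-variance")
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p), None)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if not np.all(np.isfinite(pvals)) or pvals.min() < 0 or pvals.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def regional_group_contrast(
    ct: pd.DataFrame,
    regions: list[str],
    group_col: str = "group",
    patient_label: str = "patient",
    control_label: str = "control",
) -> tuple[pd.DataFrame, list[str]]:
    """Welch contrast of control minus patient CT per region column.

    ``regions`` lists CT column names (e.g. the 68 bilateral or the 34
    left-hemisphere columns); BH correction spans exactly that family.
    Columns absent from the table are excluded and returned separately.
    """
    present = [r for r in regions if r in ct.columns]
    excluded = [r for r in regions if r not in ct.columns]
    pat = ct[ct[group_col] == patient_label]
    con = ct[ct[group_col] == control_label]
    if pat.empty or con.empty:
        raise ValueError("both groups must be nonempty")
    rows = []
    for r in present:
        res = welch_t(con[r].to_numpy(), pat[r].to_numpy())
        rows.append(
            {
                "region": r,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "n_control": len(con),
                "n_patient": len(pat),
                "flag": res.flag,
            }
        )
    out = pd.DataFrame(rows)
    ok = out["flag"].isna() & np.isfinite(out["p"])
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out, excluded


def hemispheric_contrast(
    ct: pd.DataFrame,
    region_names: list[str],
    paired: bool = True,
    group: str | None = "patient",
    group_col: str = "group",
) -> pd.DataFrame:
    """Right-minus-left CT contrast per region, BH over the region set.

    Paired by default (each subject contributes both hemispheres);
    ``paired=False`` switches to the Welch unpaired test. Subjects
    missing either hemisphere are dropped per region and counted.
    """
    data = ct if group is None else ct[ct[group_col] == group]
    if data.empty:
        raise ValueError("no subjects in the requested group")
    rows = []
    for name in region_names:
        lh, rh = ct_column(name, "lh"), ct_column(name, "rh")
        if lh not in data.columns or rh not in data.columns:
            raise ValueError(f"missing hemisphere column for region {name!r}")
        pair = data[[lh, rh]].dropna()
        n_dropped = len(data) - len(pair)
        left = pair[lh].to_numpy()
        right = pair[rh].to_numpy()
        if paired:
            d = right - left
            if d.size < 2:
                raise ValueError(f"fewer than 2 complete subjects for region {name!r}")
            if d.std(ddof=1) == 0.0:
                # identical hemispheres -> no difference; constant
                # nonzero difference -> infinite statistic
                res = WelchResult(
                    0.0 if d.mean() == 0 else np.sign(d.mean()) * np.inf,
                    float(d.size - 1),
                    1.0 if d.mean() == 0 else 0.0,
                    "zero-variance",
                )
            else:
                t, p = stats.ttest_rel(right, left)
                res = WelchResult(float(t), float(d.size - 1), float(p), None)
        else:
            res = welch_t(right, left)
        rows.append(
            {
                "region": name,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "n": len(pair),
                "n_dropped": n_dropped,
                "mode": "paired" if paired else "welch",
                "flag": res.flag,
            }
        )
    out = pd.DataFrame(rows)
    ok = out["flag"].isna() & np.isfinite(out["p"])
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def ct_clinical_regression(
    ct: pd.DataFrame,
    clinical: pd.DataFrame,
    regions: list[str],
    features: list[str],
    group_col: str = "group",
    patient_label: str = "patient",
    min_complete: int = 4,
) -> pd.DataFrame:
    """Per-cell OLS of regional CT on one clinical score plus age.

    For every (region column, feature) pair fit
    ``CT_i = alpha + beta1 * K_j + beta2 * age + eps`` on patients with
    complete cases, and test ``H0: beta1 = 0`` (two-sided t). BH spans
    all non-flagged cells jointly. Cells with a singular design or fewer
    than ``min_complete`` complete cases are flagged and left out of the
    BH family.
    """
    patients = ct[ct[group_col] == patient_label]
    if patients.empty:
        raise ValueError("no patients in the CT table")
    merged = patients.merge(clinical, on="subject", how="inner", validate="one_to_one")
    rows = []
    for region in regions:
        for feature in features:
            cell = merged[[region, feature, "age"]].dropna()
            n = len(cell)
            record = {
                "region": region,
                "feature": feature,
                "beta1": np.nan,
                "t": np.nan,
                "df": np.nan,
                "p": np.nan,
                "n": n,
                "flag": None,
            }
            if n < min_complete:
                record["flag"] = "insufficient-n"
                rows.append(record)
                continue
            y = cell[region].to_numpy()
            X = np.column_stack(
                [np.ones(n), cell[feature].to_numpy(), cell["age"].to_numpy()]
            )
            if np.linalg.matrix_rank(X) < X.shape[1]:
                record["flag"] = "singular-design"
                rows.append(record)
                continue
            fit = OLS(y, X).fit()
            record.update(
                beta1=float(fit.params[1]),
                t=float(fit.tvalues[1]),
                df=float(fit.df_resid),
                p=float(fit.pvalues[1]),
            )
            rows.append(record)
    out = pd.DataFrame(rows)
    ok = out["flag"].isna() & np.isfinite(out["p"])
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def t_matrix(regression: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy regression output into a regions x features
    t-statistic matrix (the multi-response PLS target)."""
    return regression.pivot(index="region", columns="feature", values="t")
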