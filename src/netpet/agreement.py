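"""Method-agreement statistics between static and model-based binding.

Per region and static window the package reports Spearman's rank correlation
and the intraclass correlation coefficient against each kinetic model's BPND;
pooled over regions it reports ordinary least-squares regressions of static on
model BP (one line per window x model, the scatter-plot companion).  Clinical
covariate associations use Spearman's rho with Bonferroni adjustment.

The ICC variant is the two-way, single-measurement, absolute-agreement
coefficient ICC(A,1): with n subjects and k = 2 methods,

    ICC(A,1) = (MS_R - MS_E) / (MS_R + MS_E + (2/n) (MS_C - MS_E))

so a constant offset between methods (perfect consistency, imperfect
agreement) is penalized — the appropriate choice when one method is meant to
replace the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: clinical covariates tested against thalamic binding
CLINICAL_VARIABLES: tuple[str, ...] = ("age_y", "dd_y", "hy", "updrs3_off", "ledd_mg")


@dataclass(frozen=True)
class RegressionResult:
    window: str
    model: str
    slope: float
    intercept: float
    r2: float
    p: float
    n_points: int


def _check_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, have {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def spearman(x, y) -> tuple[float, float]:
    """Spearman's rho (average ranks for ties) with the large-sample p-value."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def icc(x, y, variant: str = "A1") -> float:
    """Intraclass correlation of a subjects x 2-methods table from mean squares.

    ``variant='A1'`` is absolute agreement (default); ``'C1'`` is consistency,
    (MS_R - MS_E)/(MS_R + MS_E), insensitive to a method offset.
    """
    x, y = _check_pair(x, y)
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("ICC undefined: zero total variance")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ms_r = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ms_e = np.sum(resid**2) / ((n - 1) * (k - 1))
    if variant == "A1":
        denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    elif variant == "C1":
        denom = ms_r + (k - 1) * ms_e
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    if denom == 0:
        raise ValueError("ICC undefined: zero denominator")
    return float((ms_r - ms_e) / denom)


def ols_regression(x, y, window: str = "", model: str = "") -> RegressionResult:
    """Least-squares line y = slope*x + intercept with R² and the two-sided
    slope p-value."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0:
        raise ValueError("regression undefined: zero variance in x")
    if np.ptp(y) == 0:
        # flat response: the least-squares line is y = const with no fit signal
        return RegressionResult(window, model, 0.0, float(y[0]), 0.0, 1.0, int(x.size))
    res = stats.linregress(x, y)
    return RegressionResult(
        window=window,
        model=model,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n_points=int(x.size),
    )


def significance_stars(p: float) -> str:
    """Footnote markers: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def build_agreement_tables(
    static_df: pd.DataFrame,
    model_df: pd.DataFrame,
    reference: str = "occipital",
    icc_variant: str = "A1",
    min_n: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region-wise agreement report plus pooled per-window regressions.

    ``static_df``: columns subject, region, window, bp (hemispheres pooled).
    ``model_df``: columns subject, region, method, bp (hemispheres pooled).

    Returns ``(agreement, regressions)``; the agreement table carries, per
    region x window x model: n, mean/SD of both BP variants, Spearman rho with
    p and stars, and the ICC.  Regressions pool subject x region points per
    window x model.  Missing subject-region cells abort with an explicit list.
    """
    s = static_df[static_df["region"] != reference]
    m = model_df[model_df["region"] != reference]
    merged = s.merge(m, on=["subject", "region"], suffixes=("_static", "_model"))
    expected = len(s) * m["method"].nunique()
    if len(merged) != expected:
        have = set(zip(merged["subject"], merged["region"]))
        want = set(zip(s["subject"], s["region"]))
        missing = sorted(want - have)
        raise ValueError(f"static/model join incomplete; missing cells: {missing}")

    agreement_rows = []
    for (region, window, method), grp in merged.groupby(["region", "window", "method"]):
        xs, ys = grp["bp_model"].to_numpy(), grp["bp_static"].to_numpy()
        if xs.size < min_n:
            raise ValueError(f"{region}/{window}/{method}: fewer than {min_n} subjects")
        rho, rho_p = spearman(xs, ys)
        agreement_rows.append(
            dict(
                region=region,
                window=window,
                model=method,
                n=int(xs.size),
                static_mean=float(ys.mean()),
                static_sd=float(ys.std(ddof=1)),
                model_mean=float(xs.mean()),
                model_sd=float(xs.std(ddof=1)),
                rho=rho,
                rho_p=rho_p,
                stars=significance_stars(rho_p),
                icc=icc(xs, ys, variant=icc_variant),
            )
        )
    agreement = pd.DataFrame(agreement_rows).sort_values(
        ["region", "window", "model"], ignore_index=True
    )

    regression_rows = []
    for (window, method), grp in merged.groupby(["window", "method"]):
        res = ols_regression(
            grp["bp_model"].to_numpy(), grp["bp_static"].to_numpy(), window=window, model=method
        )
        regression_rows.append(res.__dict__)
    regressions = pd.DataFrame(regression_rows).sort_values(
        ["window", "model"], ignore_index=True
    )
    return agreement, regressions


def clinical_correlations(
    bp: pd.Series,
    covariates: pd.DataFrame,
    variables: tuple[str, ...] = CLINICAL_VARIABLES,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Spearman correlation of a per-subject BP vector with clinical covariates.

    ``bp`` is indexed like ``covariates`` (one row per subject).  Missing
    covariate values are excluded pairwise with a warning.  ``p_adjusted`` is
    Bonferroni across the tested variables (never smaller than the raw p).
    """
    rows = []
    n_tests = len(variables)
    for var in variables:
        if var not in covariates.columns:
            raise KeyError(f"covariate {var!r} not in table")
        col = pd.to_numeric(covariates[var], errors="coerce")
        mask = col.notna() & bp.notna()
        if mask.sum() < len(bp):
            warnings.warn(
                f"{var}: {int((~mask).sum())} subject(s) excluded pairwise (missing values)",
                stacklevel=2,
            )
        rho, p_raw = spearman(bp[mask].to_numpy(), col[mask].to_numpy())
        if correction == "bonferroni":
            p_adj = min(1.0, p_raw * n_tests)
        elif correction == "none":
            p_adj = p_raw
        else:
            raise ValueError(f"unknown correction {correction!r}")
        rows.append(dict(variable=var, n=int(mask.sum()), rho=rho, p_raw=p_raw, p_adjusted=p_adj))
    return pd.DataFrame(rows)
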