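"""Covariate-adjusted rank statistics for the pulsatility-PVS analysis.

The central statistic is the partial Spearman rank-order correlation:
rank-transform the two variables of interest and every covariate
(average ranks for ties), residualize both ranked variables on an
intercept plus the ranked covariates by least squares, and correlate the
residuals (Pearson).  Significance uses the t approximation
t = r * sqrt((n - 2 - k) / (1 - r^2)) on n - 2 - k degrees of freedom
(k covariates), two-sided.  With k = 0 this reduces to the classical
Spearman coefficient and its t test.

Drivers reproduce the cohort analysis: a 3 x 2 matrix of correlations
between the pulsatility measures (PI_LSA, PI_MCA, DF) and the merged PVS
scores (BG, CSO) adjusted for age and sex, sensitivity re-runs adding
one cardiovascular risk factor at a time, and standardized linear
regressions of pulse pressure on each pulsatility measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "partial_spearman",
    "run_table4",
    "sensitivity_adjust",
    "standardized_regression",
    "RISK_FACTORS",
    "PULSATILITY_VARS",
    "PVS_OUTCOMES",
    "format_report",
]

PULSATILITY_VARS = ("pi_lsa", "pi_mca", "df")
PVS_OUTCOMES = ("pvs_bg_score", "pvs_cso_score")
DEFAULT_COVARIATES = ("age", "sex")
RISK_FACTORS = (
    "hypertension",
    "pulse_pressure",
    "bmi",
    "smoking_history",
    "alcohol",
    "brain_size",
)


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    covariates: tuple[str, ...]
    r_s: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    predictor: str
    covariates: tuple[str, ...]
    beta: float
    p: float
    n: int


def _rank(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, method="average")


def partial_spearman(
    x,
    y,
    covariates=None,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: tuple[str, ...] = (),
    rank_covariates: bool = True,
) -> CorrelationResult:
    """Partial Spearman correlation of x and y given covariates.

    Parameters
    ----------
    x, y : 1-D arrays of equal length (complete cases).
    covariates : optional (n, k) matrix; ranked column-wise unless
        ``rank_covariates`` is False (then used raw in the partialling).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if covariates is None:
        z = np.empty((x.size, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != x.size:
            raise ValueError("covariate rows must match x length")
    n, k = x.size, z.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least k+3={k + 3} observations, got {n}")
    if np.isnan(x).any() or np.isnan(y).any() or np.isnan(z).any():
        raise ValueError("inputs must be complete cases (no NaN)")

    rx, ry = _rank(x), _rank(y)
    design = np.column_stack([np.ones(n)] + [
        _rank(z[:, j]) if rank_covariates else z[:, j] for j in range(k)
    ])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design (collinear covariates)")
    coef_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ coef_x
    ey = ry - design @ coef_y
    sx, sy = np.sqrt(ex @ ex), np.sqrt(ey @ ey)
    tol = 1e-8 * n  # ranks are O(n); anything smaller is numerical dust
    if sx < tol or sy < tol:
        raise ValueError("zero-variance residuals: correlation undefined")
    r = float(np.clip((ex @ ey) / (sx * sy), -1.0, 1.0))

    dof = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), dof))
    return CorrelationResult(
        x_name=x_name,
        y_name=y_name,
        covariates=tuple(covariate_names),
        r_s=r,
        p=min(p, 1.0),
        n=n,
    )


def _complete_cases(table: pd.DataFrame, cols) -> pd.DataFrame:
    return table.dropna(subset=list(cols))


def run_table4(
    records: pd.DataFrame,
    pulsatility_vars=PULSATILITY_VARS,
    outcomes=PVS_OUTCOMES,
    covariates=DEFAULT_COVARIATES,
    alpha: float = 0.05,
    rank_covariates: bool = True,
) -> pd.DataFrame:
    """Matrix of partial Spearman correlations: pulsatility x PVS score.

    Returns a tidy DataFrame (one row per cell) with columns
    x, y, covariates, r_s, p, n, significant.  Complete cases are taken
    per correlation; ``significant`` flags p < alpha.
    """
    needed = set(pulsatility_vars) | set(outcomes) | set(covariates)
    missing = needed - set(records.columns)
    if missing:
        raise KeyError(f"missing required columns: {sorted(missing)}")
    rows = []
    for xv in pulsatility_vars:
        for yv in outcomes:
            sub = _complete_cases(records, [xv, yv, *covariates])
            if len(sub) < 5:
                raise ValueError(f"fewer than 5 complete cases for ({xv}, {yv})")
            res = partial_spearman(
                sub[xv].to_numpy(),
                sub[yv].to_numpy(),
                sub[list(covariates)].to_numpy() if covariates else None,
                x_name=xv,
                y_name=yv,
                covariate_names=tuple(covariates),
                rank_covariates=rank_covariates,
            )
            rows.append(
                {
                    "x": res.x_name,
                    "y": res.y_name,
                    "covariates": "+".join(res.covariates) or "none",
                    "r_s": res.r_s,
                    "p": res.p,
                    "n": res.n,
                    "significant": res.p < alpha,
                }
            )
    return pd.DataFrame(rows)


def sensitivity_adjust(
    records: pd.DataFrame,
    risk_factors=RISK_FACTORS,
    covariates=DEFAULT_COVARIATES,
    alpha: float = 0.05,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Re-run the correlation matrix adding one risk factor at a time.

    Returns {risk factor -> tidy matrix adjusted for covariates + factor}.
    """
    out = {}
    for factor in risk_factors:
        if factor not in records.columns:
            raise KeyError(f"risk factor column missing: {factor}")
        out[factor] = run_table4(
            records, covariates=(*covariates, factor), alpha=alpha, **kwargs
        )
    return out


def standardized_regression(
    records: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates=DEFAULT_COVARIATES,
    binary_covariates=("sex", "hypertension", "smoking_history"),
) -> RegressionResult:
    """OLS of z-scored outcome on z-scored predictor plus covariates.

    Continuous covariates are z-scored; binary ones (listed in
    ``binary_covariates``) enter as 0/1.  Returns the predictor's
    standardized coefficient and its two-sided p value.
    """
    cols = [outcome, predictor, *covariates]
    sub = _complete_cases(records, cols)
    n, k = len(sub), len(covariates)
    if n <= k + 2:
        raise ValueError("too few complete cases for regression")

    def z(col):
        v = sub[col].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero-variance column: {col}")
        return (v - v.mean()) / sd

    yv = z(outcome)
    cols_X = {predictor: z(predictor)}
    for cv in covariates:
        cols_X[cv] = (
            sub[cv].to_numpy(dtype=float) if cv in binary_covariates else z(cv)
        )
    X = sm.add_constant(pd.DataFrame(cols_X, index=sub.index))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm.OLS(yv, X).fit()
    return RegressionResult(
        outcome=outcome,
        predictor=predictor,
        covariates=tuple(covariates),
        beta=float(fit.params[predictor]),
        p=float(fit.pvalues[predictor]),
        n=n,
    )


def format_report(matrix: pd.DataFrame, alpha: float = 0.05) -> str:
    """Human-readable correlation matrix in the style of a cohort table:
    rows are pulsatility measures, column pairs are r_s / P per region."""
    ys = list(dict.fromkeys(matrix["y"]))
    lines = ["Partial Spearman correlations (covariates: "
             f"{matrix['covariates'].iloc[0]})", ""]
    header = f"{'measure':<10}" + "".join(f"{y:>24}" for y in ys)
    sub = f"{'':<10}" + "".join(f"{'r_s':>14}{'P':>10}" for _ in ys)
    lines += [header, sub]
    for xv in dict.fromkeys(matrix["x"]):
        row = f"{xv:<10}"
        for yv in ys:
            cell = matrix[(matrix["x"] == xv) & (matrix["y"] == yv)].iloc[0]
            star = "*" if cell["p"] < alpha else " "
            row += f"{cell['r_s']:>13.3f}{star}{cell['p']:>9.3f} "
        lines.append(row)
    lines.append("")
    lines.append(f"* P < {alpha:g} (two-sided)")
    return "\n".join(lines)
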