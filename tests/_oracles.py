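"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (normal
equations, explicit model-comparison projections, reference library calls)
so it shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def ols_line_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope/intercept by explicit normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    A = np.array([[np.sum(x * x), np.sum(x)], [np.sum(x), n]])
    b = np.array([np.sum(x * y), np.sum(y)])
    slope, intercept = np.linalg.solve(A, b)
    return float(slope), float(intercept)


def ma_slope_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """MA slope as the leading eigenvector of the sample covariance matrix."""
    S = np.cov(np.asarray(x, float), np.asarray(y, float), ddof=1)
    evals, evecs = np.linalg.eigh(S)
    v = evecs[:, np.argmax(evals)]
    return float(v[1] / v[0])


def _sum_design(frame: pd.DataFrame) -> np.ndarray:
    sp_levels = sorted(frame["species"].unique())
    sx_levels = sorted(frame["sex"].unique())
    sp = np.where(frame["species"].to_numpy() == sp_levels[0], 1.0, -1.0)
    sx = np.where(frame["sex"].to_numpy() == sx_levels[0], 1.0, -1.0)
    return np.column_stack([np.ones(len(frame)), sp, sx, sp * sx])


def type3_anova_oracle(frame: pd.DataFrame, response: str) -> dict[str, dict[str, float]]:
    """Type III SS by explicit model comparison under sum-to-zero contrasts.

    For each term, the SS is the increase in residual SS when that term's
    column is dropped from the full sum-coded design.
    """
    y = frame[response].to_numpy(float)
    X = _sum_design(frame)

    def rss(M: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        r = y - M @ beta
        return float(r @ r)

    full = rss(X)
    err_df = len(y) - X.shape[1]
    mse = full / err_df
    out = {"error": {"df": float(err_df), "sum_sq": full, "mean_sq": mse}}
    for j, term in ((1, "species"), (2, "sex"), (3, "species:sex")):
        reduced = rss(np.delete(X, j, axis=1))
        ss = reduced - full
        F = ss / mse
        from scipy.stats import f as fdist

        out[term] = {
            "df": 1.0,
            "sum_sq": ss,
            "mean_sq": ss,
            "F": F,
            "p": float(fdist.sf(F, 1, err_df)),
        }
    return out


def balanced_anova_oracle(frame: pd.DataFrame, response: str) -> dict[str, float]:
    """Classical balanced-design SS decomposition from cell means."""
    cells = frame.groupby(["species", "sex"])[response].mean().unstack()
    n_cell = frame.groupby(["species", "sex"]).size().iloc[0]
    grand = frame[response].mean()
    sp_means = cells.mean(axis=1)
    sx_means = cells.mean(axis=0)
    ss_species = 2 * n_cell * float(((sp_means - grand) ** 2).sum())
    ss_sex = 2 * n_cell * float(((sx_means - grand) ** 2).sum())
    inter = cells.sub(sp_means, axis=0).sub(sx_means, axis=1) + grand
    ss_inter = n_cell * float((inter**2).sum().sum())
    ss_err = float(
        frame.groupby(["species", "sex"])[response]
        .apply(lambda v: ((v - v.mean()) ** 2).sum())
        .sum()
    )
    return {
        "species": ss_species,
        "sex": ss_sex,
        "species:sex": ss_inter,
        "error": ss_err,
    }


def wilks_oracle(frame: pd.DataFrame, responses: list[str]) -> dict[str, tuple[float, float]]:
    """Wilks' lambda and F per term via statsmodels MANOVA (reference library)."""
    from statsmodels.multivariate.manova import MANOVA

    lhs = " + ".join(responses)
    mv = MANOVA.from_formula(
        f"{lhs} ~ C(species, Sum) * C(sex, Sum)", data=frame
    )
    res = mv.mv_test()
    mapping = {
        "C(species, Sum)": "species",
        "C(sex, Sum)": "sex",
        "C(species, Sum):C(sex, Sum)": "species:sex",
    }
    out = {}
    for key, term in mapping.items():
        stat = res.results[key]["stat"]
        row = stat.loc["Wilks' lambda"]
        out[term] = (float(row["Value"]), float(row["F Value"]))
    return out


def tukey_oracle(values: np.ndarray, groups: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD via statsmodels (reference library)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    import itertools

    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    pairs = list(itertools.combinations(res.groupsunique, 2))
    return pd.DataFrame(
        {
            "group1": [p[0] for p in pairs],
            "group2": [p[1] for p in pairs],
            "meandiff": res.meandiffs,
            "p-adj": res.pvalues,
            "reject": res.reject,
        }
    )
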