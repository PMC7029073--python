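"""Group comparisons for pattern and disruption descriptors.

A cohort is a two-factor layout — species (2 levels) x sex (2 levels) —
with one row per individual and one or more response variables (log10
granularity descriptors, mean GabRat, ...).  This module provides:

* two-way ANOVA with interaction, Type III sums of squares under
  sum-to-zero contrasts (appropriate for the unbalanced cell counts of
  field cohorts), via :mod:`statsmodels`;
* two-factor MANOVA reporting Wilks' lambda per term with its exact F
  (each term carries a single hypothesis df, for which Rao's approximation
  is exact), implemented directly on the Type III hypothesis matrices;
* Tukey-Kramer HSD pairwise comparisons of the four cells, using the
  studentized-range distribution with the error df of the cell-means model
  (identical to the two-way-with-interaction error), plus a compact-letter
  display;
* paired t tests of animal-vs-background descriptor differences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm
import statsmodels.formula.api as smf

TERMS = ("species", "sex", "species:sex")


class DesignError(ValueError):
    """Unusable factorial design (empty cells, too few groups...)."""


class MulticollinearityError(ValueError):
    """Singular residual cross-product matrix in a MANOVA."""


@dataclass(frozen=True)
class AnovaResult:
    """Type III two-way ANOVA table (terms: species, sex, species:sex, error)."""

    table: pd.DataFrame  # index: term; columns: df, sum_sq, mean_sq, F, p
    response: str

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


@dataclass(frozen=True)
class ManovaResult:
    """Wilks' lambda and its F approximation for one hypothesis term."""

    term: str
    wilks_lambda: float
    F: float
    df1: float
    df2: float
    p: float

    def __post_init__(self) -> None:
        if not 0.0 < self.wilks_lambda <= 1.0 + 1e-12:
            raise ValueError("Wilks' lambda must lie in (0, 1]")


@dataclass(frozen=True)
class TukeyResult:
    """Tukey-Kramer pairwise contrasts with a compact-letter display."""

    table: pd.DataFrame  # group1, group2, diff, se, q, p_adj, reject
    letters: dict[str, str]
    error_df: float
    error_ms: float


@dataclass(frozen=True)
class PairedTResult:
    """Paired t test of target vs background values."""

    mean_target: float
    mean_background: float
    se_target: float
    se_background: float
    t: float
    df: int
    p: float
    n: int


def validate_factor_frame(frame: pd.DataFrame, responses: list[str]) -> None:
    """Check the two-factor layout: 2x2 levels, nonempty cells, no missing data."""
    for col in ("species", "sex", *responses):
        if col not in frame.columns:
            raise DesignError(f"frame lacks column {col!r}")
    sp = sorted(frame["species"].unique())
    sx = sorted(frame["sex"].unique())
    if len(sp) != 2 or len(sx) != 2:
        raise DesignError("species and sex must each have exactly 2 levels")
    counts = frame.groupby(["species", "sex"], sort=True).size()
    if len(counts) < 4 or (counts < 1).any():
        raise DesignError("all four species x sex cells must be nonempty")
    if frame[responses].isna().any().any():
        raise DesignError("missing response values")


def two_way_anova(frame: pd.DataFrame, response: str) -> AnovaResult:
    """Type III two-way ANOVA of ``response`` on species * sex.

    Sum-to-zero contrasts are used so the Type III sums of squares test the
    usual main effects in an unbalanced design.  If the response is
    constant the table degenerates to F = 0, p = 1 for every term.
    """
    validate_factor_frame(frame, [response])
    counts = frame.groupby(["species", "sex"], sort=True).size()
    if (counts < 2).any():
        raise DesignError("each species x sex cell needs >= 2 observations")
    n = len(frame)
    if float(np.var(frame[response].to_numpy(dtype=float))) == 0.0:
        table = pd.DataFrame(
            {
                "df": [1.0, 1.0, 1.0, float(n - 4)],
                "sum_sq": [0.0, 0.0, 0.0, 0.0],
                "mean_sq": [0.0, 0.0, 0.0, 0.0],
                "F": [0.0, 0.0, 0.0, np.nan],
                "p": [1.0, 1.0, 1.0, np.nan],
            },
            index=[*TERMS, "error"],
        )
        return AnovaResult(table=table, response=response)

    model = smf.ols(
        f"Q('{response}') ~ C(species, Sum) * C(sex, Sum)", data=frame
    ).fit()
    raw = sm.stats.anova_lm(model, typ=3)
    rename = {
        "C(species, Sum)": "species",
        "C(sex, Sum)": "sex",
        "C(species, Sum):C(sex, Sum)": "species:sex",
        "Residual": "error",
    }
    raw = raw.rename(index=rename).drop(index="Intercept")
    table = pd.DataFrame(
        {
            "df": raw["df"].astype(float),
            "sum_sq": raw["sum_sq"].astype(float),
            "mean_sq": raw["sum_sq"].astype(float) / raw["df"].astype(float),
            "F": raw["F"],
            "p": raw["PR(>F)"],
        }
    ).loc[[*TERMS, "error"]]
    return AnovaResult(table=table, response=response)


def _sum_coded_design(frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + sum-to-zero species, sex, and interaction columns."""
    sp_levels = sorted(frame["species"].unique())
    sx_levels = sorted(frame["sex"].unique())
    sp = np.where(frame["species"].to_numpy() == sp_levels[0], 1.0, -1.0)
    sx = np.where(frame["sex"].to_numpy() == sx_levels[0], 1.0, -1.0)
    X = np.column_stack([np.ones(len(frame)), sp, sx, sp * sx])
    return X, ["intercept", *TERMS]


def manova_wilks(frame: pd.DataFrame, responses: list[str]) -> dict[str, ManovaResult]:
    """Two-factor MANOVA: Wilks' lambda per Type III hypothesis term.

    Each factorial term contributes one hypothesis df, so
    ``F = (1 - lambda) / lambda * (v - p + 1) / p`` with ``v`` the error df
    and ``p`` the number of responses is exact.  A singular residual
    cross-product matrix (e.g. duplicated responses) raises
    :class:`MulticollinearityError`.
    """
    validate_factor_frame(frame, responses)
    Y = frame[list(responses)].to_numpy(dtype=np.float64)
    n, p = Y.shape
    X, names = _sum_coded_design(frame)
    v = n - X.shape[1]
    if v < p + 1:
        raise DesignError(f"need at least {p + 1} error df for {p} responses, have {v}")
    XtX = X.T @ X
    B = np.linalg.solve(XtX, X.T @ Y)
    resid = Y - X @ B
    E = resid.T @ resid
    eig = np.linalg.eigvalsh(E)
    if eig[0] <= 1e-10 * max(eig[-1], 1.0):
        raise MulticollinearityError("residual cross-product matrix is singular")
    XtX_inv = np.linalg.inv(XtX)
    det_E = np.linalg.det(E)
    results: dict[str, ManovaResult] = {}
    for j, term in enumerate(names):
        if term == "intercept":
            continue
        b = B[j]
        H = np.outer(b, b) / XtX_inv[j, j]
        lam = det_E / np.linalg.det(E + H)
        df1 = float(p)
        df2 = float(v - p + 1)
        F = (1.0 - lam) / lam * df2 / df1
        results[term] = ManovaResult(
            term=term,
            wilks_lambda=float(lam),
            F=float(F),
            df1=df1,
            df2=df2,
            p=float(sps.f.sf(F, df1, df2)),
        )
    return results


def _compact_letters(groups: list[str], nonsig: set[frozenset]) -> dict[str, str]:
    """Compact-letter display from the non-significance graph.

    Maximal cliques of mutually non-different groups each receive one
    letter; a group's display is the concatenation of its cliques' letters.
    Group order (by descending mean) fixes letter order.
    """
    k = len(groups)
    idx = range(k)
    adj = {
        (i, j): (i == j) or frozenset((groups[i], groups[j])) in nonsig
        for i in idx
        for j in idx
    }
    cliques = []
    for r in range(k, 0, -1):
        for subset in itertools.combinations(idx, r):
            if all(adj[(i, j)] for i, j in itertools.combinations(subset, 2)):
                s = set(subset)
                if not any(s <= c for c in cliques):
                    cliques.append(s)
    cliques.sort(key=min)
    letters = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for i in sorted(clique):
            letters[groups[i]] += letter
    return letters


def tukey_hsd(
    values: np.ndarray,
    groups: np.ndarray,
    alpha: float = 0.05,
    error_df: float | None = None,
    error_ms: float | None = None,
) -> TukeyResult:
    """Tukey-Kramer HSD over all group pairs with a letter display.

    By default the error term is the pooled within-group variance, which
    for species x sex cells equals the two-way-with-interaction error.  An
    external error term (df, mean square) may be supplied instead.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups).tolist())
    k = len(names)
    if k < 2:
        raise DesignError("Tukey HSD needs at least 2 groups")
    data = {g: values[groups == g] for g in names}
    ns = {g: len(data[g]) for g in names}
    if min(ns.values()) < 2:
        raise DesignError("each group needs >= 2 observations")
    if error_df is None or error_ms is None:
        error_df = float(sum(ns[g] - 1 for g in names))
        sse = sum(((data[g] - data[g].mean()) ** 2).sum() for g in names)
        error_ms = float(sse / error_df)
    means = {g: float(data[g].mean()) for g in names}

    rows = []
    nonsig: set[frozenset] = set()
    for g1, g2 in itertools.combinations(names, 2):
        diff = means[g1] - means[g2]
        se = np.sqrt(error_ms / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else np.inf
        else:
            q = abs(diff) / se
        p_adj = float(sps.studentized_range.sf(q, k, error_df)) if np.isfinite(q) else 0.0
        p_adj = min(max(p_adj, 0.0), 1.0)
        reject = p_adj < alpha
        if not reject:
            nonsig.add(frozenset((g1, g2)))
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "diff": diff,
                "se": float(se),
                "q": float(q),
                "p_adj": p_adj,
                "reject": reject,
            }
        )
    order = sorted(names, key=lambda g: -means[g])
    letters = _compact_letters(order, nonsig)
    return TukeyResult(
        table=pd.DataFrame(rows),
        letters=letters,
        error_df=float(error_df),
        error_ms=float(error_ms),
    )


def paired_t(target_values: np.ndarray, background_values: np.ndarray) -> PairedTResult:
    """Paired t test of per-individual target vs background values."""
    t_vals = np.asarray(target_values, dtype=np.float64)
    b_vals = np.asarray(background_values, dtype=np.float64)
    if t_vals.shape != b_vals.shape or t_vals.ndim != 1:
        raise ValueError("target and background values must be equal-length 1-D arrays")
    n = t_vals.size
    if n < 2:
        raise ValueError("paired t test needs n >= 2")
    d = t_vals - b_vals
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DesignError("zero-variance differences: paired t undefined")
    t_stat = float(np.mean(d) / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t_stat), df))
    return PairedTResult(
        mean_target=float(t_vals.mean()),
        mean_background=float(b_vals.mean()),
        se_target=float(np.std(t_vals, ddof=1) / np.sqrt(n)),
        se_background=float(np.std(b_vals, ddof=1) / np.sqrt(n)),
        t=t_stat,
        df=df,
        p=p,
        n=n,
    )
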