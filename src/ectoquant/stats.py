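"""Two-group statistical battery: routed rank tests, categorical tests,
confounder-adjusted linear models, correlations, detectability frequencies.

The analysis design is deliberately plain, matching a discovery-style
clinical comparison: every continuous endpoint gets a two-sided Mann-Whitney
U test (with the per-group Shapiro-Wilk normality outcome logged alongside),
categorical endpoints get Fisher's exact test (2x2) or a Pearson chi-square
(2xk), and each continuous endpoint is additionally modelled by ordinary
least squares on a group indicator plus the two recorded confounders
(duration of sex work, douching) to give a covariate-adjusted group effect.
No multiplicity correction is applied anywhere — the reported p-values are
per-endpoint, by design.

Conventions: group coded 0 = control (no hormonal contraception), 1 = case
(DMPA); douching coded 0/1; all p-values two-sided.  The exact Mann-Whitney
route (small samples, no ties) uses the full permutation null; Fisher's
two-sided p is the probability-mass rule (sum over tables no more probable
than the observed one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "Endpoint",
    "ComparisonResult",
    "MannWhitneyResult",
    "RouteResult",
    "mann_whitney",
    "fisher_exact",
    "chi_square",
    "route_test",
    "adjusted_comparison",
    "detectability_comparison",
    "correlate",
]

EXACT_MW_MAX_N = 14  # exact permutation null up to this combined n (no ties)
SHAPIRO_ALPHA = 0.05


@dataclass
class Endpoint:
    """One per-subject measurement entering the comparison battery."""

    name: str
    values: pd.Series  # indexed by subject, NaN = missing
    scale: str = "raw"  # raw | log10
    family: str = "continuous"  # continuous | binary | categorical

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log10"):
            raise ValueError("scale must be 'raw' or 'log10'")
        if self.family not in ("continuous", "binary", "categorical"):
            raise ValueError("unknown endpoint family")


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    method: str  # "exact" | "asymptotic"


@dataclass
class RouteResult:
    """Routing record for a two-group continuous comparison.

    The two-sample test is always Mann-Whitney; the Shapiro-Wilk outcome per
    group is logged rather than used to switch tests, because for two groups
    the nonparametric alternatives coincide.
    """

    test_name: str
    u: float
    p: float
    shapiro_p: tuple[float, float]
    both_normal: bool
    method: str


@dataclass
class ComparisonResult:
    """Reporting row for one endpoint: univariate + adjusted comparison."""

    endpoint: str
    n_per_group: tuple[int, int]
    medians: tuple[float, float]  # (case, control)
    iqrs: tuple[tuple[float, float], tuple[float, float]]
    univariate_test: str
    univariate_p: float
    group_coef: float
    adjusted_p: float
    covariates: list[str] = field(default_factory=list)
    n_dropped_missing: int = 0
    shapiro_p: tuple[float, float] = (float("nan"), float("nan"))
    degenerate: bool = False


def _clean(x: Sequence[float]) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[~np.isnan(arr)]


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact permutation null when the combined sample is small
    (n_x + n_y <= 14) and tie-free, and the tie-corrected normal
    approximation (with continuity correction) otherwise.
    """
    xa, ya = _clean(x), _clean(y)
    if len(xa) == 0 or len(ya) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([xa, ya])
    no_ties = len(np.unique(combined)) == len(combined)
    if len(combined) <= EXACT_MW_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method=method)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (probability-mass rule)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher's exact test needs a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def chi_square(table: Sequence[Sequence[int]]) -> tuple[float, float, int]:
    """Pearson chi-square on a 2xk table, df = k-1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("need a 2xk table with k >= 2")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p), int(df)


def route_test(
    x: Sequence[float], y: Sequence[float], alpha: float = SHAPIRO_ALPHA
) -> RouteResult:
    """Normality-logged two-group comparison.

    Shapiro-Wilk is run on each group at the given alpha and its verdict
    recorded; the comparison itself is Mann-Whitney for every continuous
    endpoint (deterministic given the data).
    """
    xa, ya = _clean(x), _clean(y)
    if len(xa) < 3 or len(ya) < 3:
        raise ValueError("need n >= 3 per group")
    sp_x = float(sps.shapiro(xa).pvalue)
    sp_y = float(sps.shapiro(ya).pvalue)
    mw = mann_whitney(xa, ya)
    return RouteResult(
        test_name="mann_whitney",
        u=mw.u,
        p=mw.p,
        shapiro_p=(sp_x, sp_y),
        both_normal=(sp_x > alpha and sp_y > alpha),
        method=mw.method,
    )


def _median_iqr(v: np.ndarray) -> tuple[float, tuple[float, float]]:
    if len(v) == 0:
        return float("nan"), (float("nan"), float("nan"))
    return float(np.median(v)), (float(np.percentile(v, 25)), float(np.percentile(v, 75)))


def adjusted_comparison(
    data: pd.DataFrame,
    outcome: str,
    group_col: str = "group_code",
    covariates: Sequence[str] = ("duration_sex_work", "douching"),
) -> ComparisonResult:
    """Univariate Mann-Whitney plus covariate-adjusted OLS for one endpoint.

    ``data`` holds one row per subject with the outcome, a 0/1 group code
    (1 = case) and the covariate columns.  Rows with any missing value among
    these columns are dropped and counted.  The adjusted effect is the OLS
    coefficient of the group indicator with its two-sided t-test p-value.

    Raises on a singular design matrix, naming the collinear columns.
    """
    cols = [outcome, group_col, *covariates]
    for c in cols:
        if c not in data.columns:
            raise KeyError(f"column {c!r} missing")
    sub = data[cols].apply(pd.to_numeric, errors="coerce")
    kept = sub.dropna()
    n_dropped = len(sub) - len(kept)
    g = kept[group_col].to_numpy(dtype=float)
    if not set(np.unique(g)) <= {0.0, 1.0} or len(np.unique(g)) < 2:
        raise ValueError("group column must contain both codes 0 and 1")
    y = kept[outcome].to_numpy(dtype=float)
    x_case, x_ctrl = y[g == 1], y[g == 0]
    if len(x_case) < 2 or len(x_ctrl) < 2:
        raise ValueError("need at least 2 non-missing values per group")

    route = route_test(x_case, x_ctrl) if min(len(x_case), len(x_ctrl)) >= 3 else None
    uni_p = route.p if route else mann_whitney(x_case, x_ctrl).p

    design = sm.add_constant(kept[[group_col, *covariates]].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        offending = _collinear_columns(design)
        raise ValueError(f"singular design matrix; collinear columns: {offending}")
    fit = sm.OLS(y, design).fit()
    coef = float(fit.params[group_col])
    p_adj = float(fit.pvalues[group_col])
    degenerate = bool(np.allclose(fit.resid, 0.0))

    med_case, iqr_case = _median_iqr(x_case)
    med_ctrl, iqr_ctrl = _median_iqr(x_ctrl)
    return ComparisonResult(
        endpoint=outcome,
        n_per_group=(len(x_case), len(x_ctrl)),
        medians=(med_case, med_ctrl),
        iqrs=(iqr_case, iqr_ctrl),
        univariate_test="mann_whitney",
        univariate_p=float(uni_p),
        group_coef=coef,
        adjusted_p=p_adj,
        covariates=list(covariates),
        n_dropped_missing=n_dropped,
        shapiro_p=route.shapiro_p if route else (float("nan"), float("nan")),
        degenerate=degenerate,
    )


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    cols = list(design.columns)
    bad = []
    for c in cols:
        others = design.drop(columns=[c]).to_numpy()
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(design.to_numpy()):
            bad.append(c)
    return bad or cols


def detectability_comparison(
    flags: Sequence[bool], groups: Sequence
) -> tuple[np.ndarray, float]:
    """Over-detection-limit frequency comparison between two groups.

    Builds the detectable/undetectable x group 2x2 table (group order:
    sorted unique labels; rows: detectable, undetectable) and returns it with
    the two-sided Fisher exact p.
    """
    f = np.asarray(flags, dtype=bool)
    g = np.asarray(groups)
    if f.shape != g.shape:
        raise ValueError("flags and groups must align")
    labels = sorted(pd.unique(g).tolist())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups (got {labels})")
    table = np.array(
        [[int((f & (g == lab)).sum()) for lab in labels],
         [int((~f & (g == lab)).sum()) for lab in labels]]
    )
    if np.any(table.sum(axis=1) == 0):
        # every sample detectable (or none): frequencies identical by construction
        return table, 1.0
    return table, fisher_exact(table)


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float, str]:
    """Paired correlation: Pearson for normal data, Spearman otherwise.

    method 'auto' routes by Shapiro-Wilk on both variables (Pearson only if
    both pass at alpha 0.05); returns (coefficient, two-sided p, method used).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if len(xa) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance in one variable")
    if method == "auto":
        normal = (
            sps.shapiro(xa).pvalue > SHAPIRO_ALPHA
            and sps.shapiro(ya).pvalue > SHAPIRO_ALPHA
        )
        method = "pearson" if normal else "spearman"
    if method == "pearson":
        r, p = sps.pearsonr(xa, ya)
    elif method == "spearman":
        r, p = sps.spearmanr(xa, ya)
    else:
        raise ValueError("method must be 'auto', 'spearman' or 'pearson'")
    return float(r), float(p), method
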