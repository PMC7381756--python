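"""Statistical layer: rank-sum habitat contrasts, one-sample t tests,
Pearson correlations with significance stars, and three-predictor
variation partitioning by adjusted R²."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

EXACT_RANKSUM_MAX_N = 16


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Mann-Whitney/Wilcoxon rank-sum U statistic and two-sided p.

    Exact p by enumeration when the pooled sample has at most
    16 observations and no ties; otherwise the normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.info("all values identical in rank-sum test; p = 1")
        return (float(len(x) * len(y) / 2), 1.0)
    ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_RANKSUM_MAX_N and not ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return (float(res.statistic), float(min(res.pvalue, 1.0)))


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, float]:
    """Student's one-sample t test of the mean against ``mu0``."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("one-sample t test needs n >= 2")
    if np.std(values, ddof=1) == 0:
        raise ValueError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(values, popmean=mu0)
    return (float(res.statistic), float(res.pvalue))


def significance_stars(p: float) -> str:
    """Star coding: *p < .05, **p < .01, ***p < .001, else 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def pearson_cor(x, y) -> tuple[float, float, str]:
    """Pearson product-moment correlation with two-sided p and stars."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return (float(r), float(p), significance_stars(float(p)))


@dataclass
class VarpartResult:
    """Adjusted-R² variation partitioning over three predictors.

    ``r2`` maps each non-empty predictor subset (e.g. ``"x1,x3"``) to
    its (adjusted) R²; ``fractions`` holds the unique, pairwise-shared
    and three-way-shared components plus ``residual``. Negative
    fractions are reported as-is.
    """

    r2: dict
    fractions: dict
    adjusted: bool

    @property
    def residual(self) -> float:
        return self.fractions["residual"]

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions)


def _ols_r2(y: np.ndarray, X: np.ndarray, adjusted: bool) -> float:
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise ValueError("response has zero variance")
    r2 = 1.0 - np.sum(resid**2) / sst
    if adjusted:
        p = X.shape[1]
        r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return float(r2)


def varpart3(y, x1, x2, x3, adjusted: bool = True) -> VarpartResult:
    """Partition the variance of ``y`` explained by three predictors.

    Fits ordinary least squares for every non-empty subset of the
    predictors and decomposes the full-model (adjusted) R² into unique
    and shared fractions by inclusion-exclusion. The seven fractions sum
    to the full-model R²; residual = 1 - R²(full).
    """
    y = np.asarray(y, dtype=float)
    preds = {
        "x1": np.asarray(x1, dtype=float),
        "x2": np.asarray(x2, dtype=float),
        "x3": np.asarray(x3, dtype=float),
    }
    n = len(y)
    if n <= 5:
        raise ValueError("variation partitioning needs n > 5")
    for name, v in preds.items():
        if len(v) != n:
            raise ValueError(f"{name} length does not match response")

    full = np.column_stack([np.ones(n)] + list(preds.values()))
    if np.linalg.matrix_rank(full) < 4:
        for a, b in itertools.combinations(preds, 2):
            r = np.corrcoef(preds[a], preds[b])[0, 1]
            if abs(r) > 1 - 1e-10:
                raise ValueError(f"collinear predictors: {a} and {b}")
        raise ValueError("rank-deficient predictor matrix")

    r2: dict[str, float] = {}
    for size in (1, 2, 3):
        for combo in itertools.combinations(("x1", "x2", "x3"), size):
            X = np.column_stack([preds[c] for c in combo])
            r2[",".join(combo)] = _ols_r2(y, X, adjusted)

    R1, R2_, R3 = r2["x1"], r2["x2"], r2["x3"]
    R12, R13, R23 = r2["x1,x2"], r2["x1,x3"], r2["x2,x3"]
    R123 = r2["x1,x2,x3"]
    g = R1 + R2_ + R3 - R12 - R13 - R23 + R123
    fractions = {
        "unique_x1": R123 - R23,
        "unique_x2": R123 - R13,
        "unique_x3": R123 - R12,
        "shared_x1_x2": R1 + R2_ - R12 - g,
        "shared_x1_x3": R1 + R3 - R13 - g,
        "shared_x2_x3": R2_ + R3 - R23 - g,
        "shared_x1_x2_x3": g,
        "residual": 1.0 - R123,
    }
    return VarpartResult(r2=r2, fractions=fractions, adjusted=adjusted)


def correlation_table(
    df: pd.DataFrame,
    rows=("PD", "NRI", "NTI"),
    cols=("Anomaly2", "MAT", "MAP", "SWC", "SR", "coverage"),
) -> pd.DataFrame:
    """Pearson r (+ stars) of each metric against each covariate.

    Rows with missing values in either variable are dropped pairwise.
    Cells are formatted ``"0.35*"`` / ``"-0.18 ns"``.
    """
    out = pd.DataFrame(index=list(rows), columns=list(cols), dtype=object)
    for m in rows:
        for c in cols:
            sub = df[[m, c]].dropna()
            r, p, stars = pearson_cor(sub[m], sub[c])
            sep = " " if stars == "ns" else ""
            out.loc[m, c] = f"{r:.2f}{sep}{stars}"
    return out


def habitat_contrasts(
    df: pd.DataFrame, variables, habitat_col: str = "habitat"
) -> pd.DataFrame:
    """Rank-sum contrasts of each variable between the two habitat groups."""
    groups = sorted(df[habitat_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 habitats, got {groups}")
    g1, g2 = groups
    rows = []
    for var in variables:
        sub = df[[habitat_col, var]].dropna()
        x = sub.loc[sub[habitat_col] == g1, var].to_numpy()
        y = sub.loc[sub[habitat_col] == g2, var].to_numpy()
        u, p = wilcoxon_rank_sum(x, y)
        rows.append(
            {
                "variable": var,
                f"mean_{g1}": float(np.mean(x)),
                f"mean_{g2}": float(np.mean(y)),
                "U": u,
                "p": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def ols_slope(x, y) -> tuple[float, float]:
    """Least-squares slope and intercept of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return (float(slope), float(intercept))
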