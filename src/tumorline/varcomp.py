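"""One-way random-intercept variance decomposition and correlation matrices.

For each parameter the model ``y_ij = mu + b_i + e_ij`` is fitted with the
tumor line as random intercept; the heterogeneity ratio reported is
``sigma2_within / (sigma2_within + sigma2_between)`` (within-line variance
over total variance), so small values mark line-distinctive parameters.

Two estimators are provided: REML, computed by profiling the criterion over
the variance ratio (closed-form generalized-least-squares mean given the
ratio), and the closed-form ANOVA method-of-moments estimator.  On balanced
designs with an interior optimum the two coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "VarianceDecomposition",
    "fit_random_intercept",
    "heterogeneity_table",
    "correlation_matrix",
]


@dataclass(frozen=True)
class VarianceDecomposition:
    """Within- and between-group variance estimates for one parameter.

    ``ratio`` is within/(within+between); it is NaN (undefined) when the
    total variance is zero.
    """

    sigma2_within: float
    sigma2_between: float
    ratio: float
    method: str
    n_groups: int
    n_total: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.ratio)


def _group_summaries(values: np.ndarray, labels: np.ndarray):
    """Per-group sizes, means and the pooled within-group sum of squares."""
    groups, inverse = np.unique(labels, return_inverse=True)
    n_i = np.bincount(inverse).astype(float)
    sums = np.bincount(inverse, weights=values)
    means = sums / n_i
    ssw = float(np.sum((values - means[inverse]) ** 2))
    return n_i, means, ssw


def _anova_components(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Closed-form method-of-moments estimator, valid for unbalanced data.

    ``sigma2_w = MSW``; ``sigma2_b = (MSB - MSW) / n0`` truncated at zero,
    where ``n0 = (N - sum n_i^2 / N) / (k - 1)`` reduces to the common group
    size on balanced designs.
    """
    n_i, means, ssw = _group_summaries(values, labels)
    k, n = len(n_i), n_i.sum()
    grand = float(np.sum(n_i * means) / n)
    ssb = float(np.sum(n_i * (means - grand) ** 2))
    msw = ssw / (n - k)
    msb = ssb / (k - 1)
    n0 = (n - np.sum(n_i**2) / n) / (k - 1)
    s2b = max(0.0, (msb - msw) / n0)
    return msw, s2b


def _reml_profile(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """REML via 1-D profiling over lambda = sigma2_between / sigma2_within.

    For fixed lambda the GLS mean and the residual variance have closed
    forms; the profiled criterion
    ``(N-1) log Q(lambda) + sum log(1 + n_i lambda) + log sum w_i`` is
    minimized numerically, with the boundary lambda = 0 checked explicitly.
    """
    n_i, means, ssw = _group_summaries(values, labels)
    n = n_i.sum()

    def criterion(lam: float) -> float:
        w = n_i / (1.0 + n_i * lam)
        mu = np.sum(w * means) / np.sum(w)
        q = ssw + float(np.sum(w * (means - mu) ** 2))
        return ((n - 1) * np.log(q) + float(np.sum(np.log1p(n_i * lam)))
                + np.log(np.sum(w)))

    # optimize over r = 1/(1+lambda) in (0, 1]; r -> 0 is lambda -> infinity
    res = optimize.minimize_scalar(lambda r: criterion((1.0 - r) / r),
                                   bounds=(1e-10, 1.0), method="bounded",
                                   options={"xatol": 1e-13})
    lam = (1.0 - res.x) / res.x
    if criterion(0.0) <= res.fun:  # boundary solution: no between-group variance
        lam = 0.0
    w = n_i / (1.0 + n_i * lam)
    mu = np.sum(w * means) / np.sum(w)
    q = ssw + float(np.sum(w * (means - mu) ** 2))
    s2w = q / (n - 1)
    return s2w, lam * s2w


def fit_random_intercept(values, line_labels, method: str = "reml") -> VarianceDecomposition:
    """Decompose a parameter's variance into within- and between-line parts.

    Parameters
    ----------
    values : array-like of float
        Observations; NaNs are dropped together with their labels.
    line_labels : array-like
        Group (tumor line) label per observation.
    method : {"reml", "anova"}

    Returns
    -------
    VarianceDecomposition
        With ``ratio = sigma2_within / (sigma2_within + sigma2_between)``;
        the ratio is NaN when all retained values are identical.
    """
    values = np.asarray(values, dtype=float)
    line_labels = np.asarray(line_labels)
    if values.shape != line_labels.shape:
        raise ValueError("values and line_labels must have equal length")
    keep = np.isfinite(values)
    values, line_labels = values[keep], line_labels[keep]
    groups, counts = np.unique(line_labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if not np.any(counts >= 2):
        raise ValueError("need at least one group with two or more observations")
    n_groups, n_total = len(groups), len(values)

    if np.ptp(values) == 0:  # zero total variance: ratio undefined
        return VarianceDecomposition(0.0, 0.0, float("nan"), method, n_groups, n_total)

    if method == "anova":
        s2w, s2b = _anova_components(values, line_labels)
    elif method == "reml":
        s2w, s2b = _reml_profile(values, line_labels)
    else:
        raise ValueError(f"unknown method {method!r}")
    total = s2w + s2b
    ratio = s2w / total if total > 0 else float("nan")
    return VarianceDecomposition(s2w, s2b, ratio, method, n_groups, n_total)


def heterogeneity_table(table: pd.DataFrame, label_col: str = "line",
                        columns: list[str] | None = None,
                        method: str = "reml") -> pd.DataFrame:
    """Per-column variance decompositions of a feature table.

    Columns with fewer than two finite values, or all-missing, are skipped
    with a warning; constant columns appear with an undefined (NaN) ratio.

    Returns a DataFrame with one row per analyzed column, in input order,
    with columns ``parameter, sigma2_within, sigma2_between, ratio,
    n_groups, n_total, method``.
    """
    if label_col not in table.columns:
        raise ValueError(f"table has no {label_col!r} column")
    if columns is None:
        columns = [c for c in table.columns
                   if c not in (label_col, "sample_id")
                   and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for col in columns:
        values = pd.to_numeric(table[col], errors="coerce").to_numpy(float)
        try:
            vd = fit_random_intercept(values, table[label_col].to_numpy(), method=method)
        except ValueError as exc:
            warnings.warn(f"skipping column {col!r}: {exc}", stacklevel=2)
            continue
        rows.append({"parameter": col, "sigma2_within": vd.sigma2_within,
                     "sigma2_between": vd.sigma2_between, "ratio": vd.ratio,
                     "n_groups": vd.n_groups, "n_total": vd.n_total,
                     "method": vd.method})
    return pd.DataFrame(rows, columns=["parameter", "sigma2_within", "sigma2_between",
                                       "ratio", "n_groups", "n_total", "method"])


def correlation_matrix(table: pd.DataFrame, columns: list[str] | None = None,
                       method: str = "spearman", min_periods: int = 3) -> pd.DataFrame:
    """Pairwise-complete correlation matrix of selected columns.

    Cells with fewer than ``min_periods`` complete pairs are NaN; the
    diagonal is 1 wherever defined.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if columns is None:
        columns = [c for c in table.columns
                   if c not in ("line", "sample_id")
                   and pd.api.types.is_numeric_dtype(table[c])]
    return table[columns].corr(method=method, min_periods=min_periods)
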