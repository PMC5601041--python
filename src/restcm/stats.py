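"""Statistical kernel: repeated-measures ANOVA with the Greenhouse-Geisser
correction, Tukey HSD post-hoc tests, and Pearson correlation with a line fit.

The one-way repeated-measures ANOVA takes an (n subjects x k conditions)
table.  F = MS_condition / MS_(condition x subject); the Greenhouse-Geisser
epsilon is computed from the double-centered condition covariance,
epsilon = (tr C)^2 / ((k-1) tr C^2), and the corrected p value uses
epsilon-scaled degrees of freedom.  Both the uncorrected and corrected p are
always reported; the headline ``p`` follows the corrected value when
epsilon < 0.75 and the uncorrected one otherwise.

Studentized-range probabilities come from scipy's numerically integrated
distribution (no lookup tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "RMAnovaResult",
    "TukeyResult",
    "rm_anova_gg",
    "tukey_hsd",
    "oneway_tukey",
    "pearson_corr_fit",
]


@dataclass(frozen=True)
class RMAnovaResult:
    F: float
    df: tuple[float, float]
    epsilon: float
    p_uncorrected: float
    p_gg: float
    n_subjects: int
    k_conditions: int
    ms_error: float
    df_error: float

    @property
    def p(self) -> float:
        """Headline p: GG-corrected when epsilon < 0.75."""
        return self.p_gg if self.epsilon < 0.75 else self.p_uncorrected


@dataclass(frozen=True)
class TukeyResult:
    pairs: tuple[tuple[str, str], ...]
    mean_diff: np.ndarray
    q: np.ndarray
    p_adjusted: np.ndarray
    k: int
    df_error: float

    def p_for(self, a, b) -> float:
        for i, (x, y) in enumerate(self.pairs):
            if {x, y} == {a, b}:
                return float(self.p_adjusted[i])
        raise KeyError(f"no pair ({a}, {b})")

    def to_dict(self) -> dict:
        return {
            f"{a}-{b}": {"mean_diff": float(d), "q": float(q), "p": float(p)}
            for (a, b), d, q, p in zip(self.pairs, self.mean_diff, self.q,
                                       self.p_adjusted)
        }


def _validate_table(table) -> np.ndarray:
    X = np.asarray(table, dtype=float)
    if X.ndim != 2:
        raise ValueError("table must be subjects x conditions")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing cells are not supported")
    return X


def rm_anova_gg(table) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction."""
    X = _validate_table(table)
    n, k = X.shape
    # subject-centering first keeps identical-column tables at exactly
    # F = 0 (no catastrophic cancellation between the two sums of squares)
    D = X - X.mean(axis=1, keepdims=True)
    dcol = D.mean(axis=0)
    ss_cond = n * np.sum((dcol - dcol.mean()) ** 2)
    resid = D - dcol[None, :]
    ss_err = np.sum((resid - resid.mean()) ** 2)
    df1 = k - 1.0
    df2 = (k - 1.0) * (n - 1.0)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else (0.0 if ss_cond == 0 else np.inf)

    # Greenhouse-Geisser epsilon from the double-centered covariance
    S = np.cov(X, rowvar=False, ddof=1)
    H = np.eye(k) - np.full((k, k), 1.0 / k)
    C = H @ S @ H
    trC = np.trace(C)
    trC2 = np.trace(C @ C)
    # a vanishing double-centered covariance (e.g. compound symmetry with no
    # interaction variance) means sphericity holds exactly
    if trC2 <= 1e-12 * (np.trace(S) ** 2 + 1e-300):
        eps = 1.0
    else:
        eps = (trC**2) / ((k - 1) * trC2)
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))

    p_unc = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    p_gg = float(sps.f.sf(F, eps * df1, eps * df2)) if np.isfinite(F) else 0.0
    if F == 0.0:
        p_unc = p_gg = 1.0
    return RMAnovaResult(F=float(F), df=(df1, df2), epsilon=eps,
                         p_uncorrected=p_unc, p_gg=p_gg, n_subjects=n,
                         k_conditions=k, ms_error=float(ms_err), df_error=df2)


def tukey_hsd(table, names=None, error_ms: float | None = None,
              df_error: float | None = None) -> TukeyResult:
    """Tukey HSD pairwise comparisons for a repeated-measures design.

    The error term defaults to the condition-by-subject interaction MS from
    :func:`rm_anova_gg`.  q = |mean_i - mean_j| / sqrt(MS_err / n); adjusted p
    from the studentized-range distribution with k groups and ``df_error``.
    """
    X = _validate_table(table)
    n, k = X.shape
    if error_ms is None or df_error is None:
        res = rm_anova_gg(X)
        error_ms = res.ms_error if error_ms is None else error_ms
        df_error = res.df_error if df_error is None else df_error
    names = list(names) if names is not None else [f"c{i}" for i in range(k)]
    means = X.mean(axis=0)
    se = np.sqrt(error_ms / n)
    pairs, diffs, qs = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            pairs.append((names[i], names[j]))
            diffs.append(means[i] - means[j])
            qs.append(abs(means[i] - means[j]) / se if se > 0 else
                      (0.0 if means[i] == means[j] else np.inf))
    qs = np.array(qs)
    with np.errstate(invalid="ignore"):
        p = sps.studentized_range.sf(qs, k, df_error)
    p = np.where(np.isfinite(qs), p, 0.0)
    p = np.where(qs == 0.0, 1.0, p)
    return TukeyResult(pairs=tuple(pairs), mean_diff=np.array(diffs), q=qs,
                       p_adjusted=np.clip(p, 0.0, 1.0), k=k,
                       df_error=float(df_error))


def oneway_tukey(groups: dict[str, np.ndarray]) -> TukeyResult:
    """Tukey HSD for independent groups (one-way layout).

    Used by the simulation study with per-dipole errors as observations.
    Supports unequal group sizes via the Tukey-Kramer standard error.
    """
    names = list(groups)
    data = [np.asarray(groups[nm], dtype=float) for nm in names]
    k = len(names)
    if k < 2:
        raise ValueError("need at least two groups")
    ns = np.array([len(d) for d in data])
    if np.any(ns < 2):
        raise ValueError("each group needs at least two observations")
    means = np.array([d.mean() for d in data])
    ss_within = sum(np.sum((d - m) ** 2) for d, m in zip(data, means))
    df_err = float(ns.sum() - k)
    ms_err = ss_within / df_err
    pairs, diffs, qs = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(ms_err / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            pairs.append((names[i], names[j]))
            diffs.append(means[i] - means[j])
            qs.append(abs(means[i] - means[j]) / se if se > 0 else
                      (0.0 if means[i] == means[j] else np.inf))
    qs = np.array(qs)
    with np.errstate(invalid="ignore"):
        p = sps.studentized_range.sf(qs, k, df_err)
    p = np.where(np.isfinite(qs), p, 0.0)
    p = np.where(qs == 0.0, 1.0, p)
    return TukeyResult(pairs=tuple(pairs), mean_diff=np.array(diffs), q=qs,
                       p_adjusted=np.clip(p, 0.0, 1.0), k=k, df_error=df_err)


@dataclass(frozen=True)
class CorrFit:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def pearson_corr_fit(x, y) -> CorrFit:
    """Pearson correlation with a two-sided t-based p and least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d arrays, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return CorrFit(r=float(r), p=float(p), slope=float(slope),
                   intercept=float(intercept), n=len(x))
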