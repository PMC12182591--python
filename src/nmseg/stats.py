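"""Cohort-level statistics for nigral volume.

The analysis layer mirrors a standard clinical-neuroimaging workflow:

* one-way ANOVA / Pearson chi-square for demographics,
* ANCOVA of SNc volume on group with sex, age, total brain volume and
  imaging site as covariates — the group effect is the Type III partial F
  (equivalent, in this main-effects model, to dropping the group columns),
  estimated marginal means are model predictions at covariate means with
  categorical covariates equally weighted over levels, and post hoc pairwise
  comparisons are two-tailed t tests on the adjusted means (uncorrected by
  default; Bonferroni/Holm behind a flag),
* Pearson partial correlations via residualisation on the control set,
* Shapiro-Wilk normality checks per group.

Missing data are handled by listwise deletion with a logged count.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "AncovaResult",
    "ancova",
    "demographics_anova",
    "demographics_chisq",
    "chisq_from_counts",
    "partial_correlation",
    "normality_check",
]

logger = logging.getLogger(__name__)


@dataclass
class AncovaResult:
    F: float
    p: float
    df_effect: int
    df_residual: int
    marginal_means: dict = field(default_factory=dict)   # group -> (mean, se)
    covariate_tests: dict = field(default_factory=dict)  # covariate -> (F, p)
    posthoc: dict = field(default_factory=dict)          # (g1, g2) -> p
    n_used: int = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be >= 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def _is_categorical(series: pd.Series) -> bool:
    return (series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype)
            or series.dtype == bool)


def _design_columns(df: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str], dict]:
    """Covariate design block (treatment coding, first level reference)."""
    cols, names, groups = [], [], {}
    for cov in covariates:
        s = df[cov]
        if _is_categorical(s):
            levels = sorted(pd.unique(s.astype(str)))
            block = []
            for lev in levels[1:]:
                cols.append((s.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
                block.append(len(names) - 1)
            groups[cov] = {"columns": block, "n_levels": len(levels)}
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(cov)
            groups[cov] = {"columns": [len(names) - 1], "n_levels": None,
                           "mean": float(s.mean())}
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names, groups


def _partial_f(y, X_full, drop_idx):
    """Partial F test for dropping the given design columns."""
    fit_full = sm.OLS(y, X_full).fit()
    keep = [j for j in range(X_full.shape[1]) if j not in set(drop_idx)]
    fit_red = sm.OLS(y, X_full[:, keep]).fit()
    df_num = len(drop_idx)
    df_den = int(fit_full.df_resid)
    num = (fit_red.ssr - fit_full.ssr) / df_num
    den = fit_full.ssr / df_den
    F = max(num / den, 0.0) if den > 0 else 0.0
    return F, float(sps.f.sf(F, df_num, df_den)), fit_full


def ancova(table: pd.DataFrame, outcome: str = "snc_volume", group: str = "group",
           covariates=("sex", "age", "total_brain_volume", "site"),
           posthoc_correction: str | None = None) -> AncovaResult:
    """ANCOVA of ``outcome`` on ``group`` controlling for ``covariates``."""
    covariates = list(covariates)
    used_cols = [outcome, group, *covariates]
    df = table[used_cols].copy()
    complete = df.dropna()
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.info("ancova: dropped %d rows with missing data (listwise)", n_dropped)
    df = complete
    levels = sorted(pd.unique(df[group].astype(str)))
    if len(levels) < 2:
        raise ValueError("ancova needs at least two groups")
    counts = df[group].astype(str).value_counts()
    if (counts < 2).any():
        small = sorted(counts[counts < 2].index)
        raise ValueError(f"every group needs n >= 2; too small: {small}")

    y = df[outcome].to_numpy(dtype=float)
    n = len(df)
    g_cols = [(df[group].astype(str) == lev).to_numpy(dtype=float) for lev in levels[1:]]
    g_names = [f"{group}[{lev}]" for lev in levels[1:]]
    C, c_names, cov_groups = _design_columns(df, covariates)
    X = np.column_stack([np.ones(n), *g_cols] + ([C] if C.size else []))
    names = ["const", *g_names, *c_names]

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Name the aliased columns via pivoted QR.
        from scipy.linalg import qr as _qr
        _, _, piv = _qr(X, pivoting=True, mode="economic")
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
    if n - X.shape[1] < 1:
        raise ValueError(
            f"not enough residual degrees of freedom: {n} rows for "
            f"{X.shape[1]} design columns")

    group_idx = list(range(1, 1 + len(g_cols)))
    F, p, fit_full = _partial_f(y, X, group_idx)

    cov_tests = {}
    offset = 1 + len(g_cols)
    for cov in covariates:
        idx = [offset + j for j in cov_groups[cov]["columns"]]
        cF, cp, _ = _partial_f(y, X, idx)
        cov_tests[cov] = (cF, cp)

    # Estimated marginal means: numeric covariates at their sample means,
    # categorical covariates equally weighted over observed levels.
    base = np.zeros(X.shape[1])
    base[0] = 1.0
    for cov in covariates:
        info = cov_groups[cov]
        for j in info["columns"]:
            base[offset + j] = (info["mean"] if info["n_levels"] is None
                                else 1.0 / info["n_levels"])
    cov_params = np.asarray(fit_full.cov_params())
    beta = np.asarray(fit_full.params)
    emm_rows = {}
    for lev in levels:
        x = base.copy()
        if lev != levels[0]:
            x[1 + levels[1:].index(lev)] = 1.0
        emm_rows[lev] = x
    marginal_means = {
        lev: (float(x @ beta), float(np.sqrt(x @ cov_params @ x)))
        for lev, x in emm_rows.items()
    }

    df_resid = int(fit_full.df_resid)
    raw_pairs, raw_ps = [], []
    for g1, g2 in itertools.combinations(levels, 2):
        c = emm_rows[g1] - emm_rows[g2]
        diff = float(c @ beta)
        se = float(np.sqrt(c @ cov_params @ c))
        t = diff / se if se > 0 else 0.0
        raw_pairs.append((g1, g2))
        raw_ps.append(float(2.0 * sps.t.sf(abs(t), df_resid)))
    if posthoc_correction:
        from statsmodels.stats.multitest import multipletests
        method = {"bonferroni": "bonferroni", "holm": "holm"}[posthoc_correction]
        raw_ps = list(multipletests(raw_ps, method=method)[1])
    posthoc = dict(zip(raw_pairs, raw_ps))

    return AncovaResult(F=float(F), p=float(p), df_effect=len(g_cols),
                        df_residual=df_resid, marginal_means=marginal_means,
                        covariate_tests=cov_tests, posthoc=posthoc,
                        n_used=n, n_dropped=n_dropped)


def demographics_anova(table: pd.DataFrame, outcome: str, group: str = "group"):
    """One-way ANOVA of ``outcome`` across groups (NaNs dropped per group)."""
    samples = [g.dropna().to_numpy(dtype=float)
               for _, g in table.groupby(group, observed=True)[outcome]]
    samples = [s for s in samples if len(s) > 0]
    if len(samples) < 2:
        raise ValueError("ANOVA needs at least two groups with data")
    F, p = sps.f_oneway(*samples)
    return float(F), float(p)


def chisq_from_counts(counts) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    counts = np.asarray(counts, dtype=float)
    try:
        res = sps.chi2_contingency(counts, correction=False)
    except ValueError as exc:
        raise ValueError(f"invalid contingency table: {exc}") from exc
    return float(res.statistic), float(res.pvalue)


def demographics_chisq(table: pd.DataFrame, categorical: str, group: str = "group"):
    """Pearson chi-square of group x categorical membership."""
    counts = pd.crosstab(table[group], table[categorical])
    return chisq_from_counts(counts.to_numpy())


def partial_correlation(table: pd.DataFrame, x: str, y: str, controls=()):
    """Pearson correlation of ``x`` and ``y`` after regressing out ``controls``.

    Both variables are residualised on the controls (with intercept;
    categorical controls dummy-coded) and the residuals are correlated. The
    p-value uses t with n - 2 - k degrees of freedom, k the number of control
    regressors. With no controls this is the plain Pearson correlation.
    """
    controls = list(controls)
    df = table[[x, y, *controls]].dropna()
    n = len(df)
    Z, _, _ = _design_columns(df, controls)
    k = Z.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete rows, got {n}")
    design = np.column_stack([np.ones(n), Z]) if k else np.ones((n, 1))
    xv = df[x].to_numpy(dtype=float)
    yv = df[y].to_numpy(dtype=float)
    rx = xv - design @ np.linalg.lstsq(design, xv, rcond=None)[0]
    ry = yv - design @ np.linalg.lstsq(design, yv, rcond=None)[0]
    if np.std(rx) <= 1e-10 * max(np.std(xv), 1.0) or \
            np.std(ry) <= 1e-10 * max(np.std(yv), 1.0):
        raise ValueError("a variable is constant after residualisation")
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 2 - k
    if dof < 1:
        raise ValueError("not enough degrees of freedom")
    r_clipped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clipped * np.sqrt(dof / (1.0 - r_clipped**2))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return r, p


def normality_check(table: pd.DataFrame, outcome: str = "snc_volume",
                    group: str = "group") -> dict:
    """Shapiro-Wilk W and p per group; warns (does not abort) on p < 0.05."""
    out = {}
    for label, values in table.groupby(group, observed=True)[outcome]:
        v = values.dropna().to_numpy(dtype=float)
        if len(v) < 3:
            raise ValueError(f"group {label!r}: Shapiro-Wilk needs n >= 3")
        if np.ptp(v) == 0:
            raise ValueError(f"group {label!r}: outcome is constant")
        W, p = sps.shapiro(v)
        if p < 0.05:
            logger.warning("group %r: Shapiro-Wilk rejects normality (W=%.4f, p=%.4g)",
                           label, W, p)
        out[str(label)] = (float(W), float(p))
    return out
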