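"""Covariate-adjusted between-group comparisons.

Each endpoint (a log2 mediator concentration or a cell-count summary) is
modelled by ordinary least squares as ``endpoint ~ group + covariates`` with
treatment coding.  The overall group effect is the nested-model F test (full
vs covariates-only); pairwise group differences are estimated-marginal-means
(EMM) contrasts -- model predictions at a common reference covariate profile
(continuous covariates at their observed means, categorical covariates at
their observed level proportions) -- with t-based p-values on the residual
degrees of freedom and Benjamini-Hochberg adjustment within each endpoint's
family of contrasts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from sputumpanel.containers import DEFAULT_COVARIATES, MediatorMatrix

logger = logging.getLogger(__name__)

_CATEGORICAL_COVARIATES = {"sex", "race"}


@dataclass
class AncovaFit:
    """An OLS fit of ``endpoint ~ group + covariates`` with treatment coding."""

    params: pd.Series
    cov_params: pd.DataFrame
    df_resid: int
    group_levels: list[str]
    reference_level: str
    column_means: pd.Series  # design-matrix column means (EMM reference profile)
    f_stat: float
    df_num: int
    df_den: int
    p_overall: float
    covariate_table: pd.DataFrame  # term, coef, se, p
    n_used: int
    n_dropped: int


def _group_col(level: str) -> str:
    return f"group[{level}]"


def _build_design(
    endpoint: pd.Series, participants: pd.DataFrame, covariates: list[str]
) -> tuple[pd.Series, pd.DataFrame, list[str], str, int]:
    """Assemble y and the treatment-coded design matrix, complete-case."""
    df = participants.loc[endpoint.index].copy()
    df["_y"] = endpoint.to_numpy()
    needed = ["_y", "group"] + list(covariates)
    before = len(df)
    df = df.dropna(subset=needed)
    n_dropped = before - len(df)
    if n_dropped:
        logger.info("dropped %d row(s) with missing endpoint/covariates", n_dropped)

    levels = sorted(df["group"].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups with observations")
    counts = df["group"].value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"group(s) with < 2 observations: {list(small.index)}")
    ref = levels[0]

    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    for lev in levels[1:]:
        X[_group_col(lev)] = (df["group"].astype(str) == lev).astype(float)
    for cov in covariates:
        if cov in _CATEGORICAL_COVARIATES or df[cov].dtype == object:
            dummies = pd.get_dummies(df[cov].astype(str), prefix=cov, drop_first=True)
            for c in dummies.columns:
                X[c] = dummies[c].astype(float)
        else:
            X[cov] = df[cov].astype(float)
    return df["_y"].astype(float), X, levels, ref, n_dropped


def _check_rank(X: pd.DataFrame, covariates: list[str], levels: list[str]) -> None:
    if np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]:
        return
    base_cols = ["Intercept"] + [_group_col(l) for l in levels[1:]]
    for cov in covariates:
        cov_cols = [c for c in X.columns if c == cov or c.startswith(f"{cov}_")]
        sub = X[base_cols + cov_cols].to_numpy()
        if np.linalg.matrix_rank(sub) < sub.shape[1]:
            raise ValueError(f"covariate {cov!r} is collinear with the group design")
    raise ValueError("design matrix is rank deficient")


def fit_ancova(
    endpoint: pd.Series,
    participants: pd.DataFrame,
    covariates: list[str] | None = None,
) -> AncovaFit:
    """Fit the covariate-adjusted group model for one endpoint.

    The overall group p-value comes from the nested-model F comparison of the
    full fit against the covariates-only fit.  Rows with missing endpoint or
    covariate values are dropped (complete case, logged).
    """
    covariates = list(DEFAULT_COVARIATES) if covariates is None else list(covariates)
    missing = [c for c in covariates if c not in participants.columns]
    if missing:
        raise ValueError(f"covariate(s) not in participant table: {missing}")
    y, X, levels, ref, n_dropped = _build_design(endpoint, participants, covariates)
    _check_rank(X, covariates, levels)

    Xn = X.to_numpy()
    n, k = Xn.shape
    df_resid = n - k
    if df_resid < 1:
        raise ValueError(f"residual degrees of freedom {df_resid} < 1")

    beta, _, _, _ = np.linalg.lstsq(Xn, y.to_numpy(), rcond=None)
    resid = y.to_numpy() - Xn @ beta
    rss_full = float(resid @ resid)
    sigma2 = rss_full / df_resid
    XtX_inv = np.linalg.inv(Xn.T @ Xn)
    cov = pd.DataFrame(sigma2 * XtX_inv, index=X.columns, columns=X.columns)
    params = pd.Series(beta, index=X.columns)

    # nested comparison: drop the group dummies
    grp_cols = [_group_col(l) for l in levels[1:]]
    keep = [c for c in X.columns if c not in grp_cols]
    X0 = X[keep].to_numpy()
    beta0, _, _, _ = np.linalg.lstsq(X0, y.to_numpy(), rcond=None)
    r0 = y.to_numpy() - X0 @ beta0
    rss_red = float(r0 @ r0)
    df_num = len(grp_cols)
    f_stat = ((rss_red - rss_full) / df_num) / (rss_full / df_resid)
    p_overall = float(stats.f.sf(f_stat, df_num, df_resid))

    cov_rows = []
    for c in X.columns:
        if c == "Intercept" or c in grp_cols:
            continue
        se = float(np.sqrt(cov.loc[c, c]))
        t = params[c] / se if se > 0 else np.nan
        cov_rows.append(
            {
                "term": c,
                "coef": float(params[c]),
                "se": se,
                "p": float(2 * stats.t.sf(abs(t), df_resid)) if se > 0 else np.nan,
            }
        )

    return AncovaFit(
        params=params,
        cov_params=cov,
        df_resid=df_resid,
        group_levels=levels,
        reference_level=ref,
        column_means=X.mean(axis=0),
        f_stat=float(f_stat),
        df_num=df_num,
        df_den=df_resid,
        p_overall=p_overall,
        covariate_table=pd.DataFrame(cov_rows),
        n_used=n,
        n_dropped=n_dropped,
    )


def estimated_marginal_means(fit: AncovaFit) -> pd.Series:
    """EMM per group: the model prediction at the reference covariate profile."""
    base = fit.column_means.copy()
    grp_cols = [_group_col(l) for l in fit.group_levels[1:]]
    emms = {}
    for lev in fit.group_levels:
        x = base.copy()
        for c in grp_cols:
            x[c] = 0.0
        if lev != fit.reference_level:
            x[_group_col(lev)] = 1.0
        emms[lev] = float(x @ fit.params)
    return pd.Series(emms)


def emm_contrasts(fit: AncovaFit) -> pd.DataFrame:
    """All pairwise EMM differences with SEs and t-based p-values.

    Because every EMM shares the same covariate profile, a contrast reduces
    to a difference of group coefficients; its SE comes from the coefficient
    covariance and its p-value from a t test on the residual df.
    """
    rows = []
    for a, b in itertools.combinations(fit.group_levels, 2):
        c = pd.Series(0.0, index=fit.params.index)
        if a != fit.reference_level:
            c[_group_col(a)] = 1.0
        if b != fit.reference_level:
            c[_group_col(b)] -= 1.0
        est = float(c @ fit.params)
        se = float(np.sqrt(c @ fit.cov_params @ c))
        t = est / se if se > 0 else np.nan
        p = float(2 * stats.t.sf(abs(t), fit.df_resid)) if se > 0 else np.nan
        rows.append({"group_a": a, "group_b": b, "estimate": est, "se": se, "p": p})
    return pd.DataFrame(rows)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GroupComparisonResult:
    """Per-endpoint overall tests, pairwise contrasts, and covariate effects."""

    overall: pd.DataFrame  # endpoint, F, df_num, df_den, p, n_used, n_dropped
    contrasts: pd.DataFrame  # endpoint, group_a, group_b, estimate, se, p, p_adj, significant
    covariates: pd.DataFrame  # endpoint, term, coef, se, p
    emms: pd.DataFrame  # endpoint x group
    alpha: float = 0.05
    patterns: dict = field(default_factory=dict)  # endpoint -> tuple of significant pairs

    @property
    def n_significant_overall(self) -> int:
        return int((self.overall["p"] < self.alpha).sum())

    @property
    def n_with_significant_pairs(self) -> int:
        sig = self.contrasts[self.contrasts["significant"]]
        return sig["endpoint"].nunique()


def compare_all(
    matrix: MediatorMatrix,
    participants: pd.DataFrame,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Run the adjusted comparison for every mediator endpoint.

    BH adjustment is applied within each endpoint's family of pairwise
    contrasts.  Endpoints are partitioned into patterns by which contrasts
    pass ``alpha`` after adjustment.
    """
    if matrix.scale != "log2":
        logger.warning("compare_all typically expects log2-scale endpoints")
    overall_rows, contrast_frames, cov_frames, emm_rows = [], [], [], []
    patterns: dict[str, tuple] = {}
    for med in matrix.mediators:
        fit = fit_ancova(matrix.values[med], participants, covariates)
        overall_rows.append(
            {
                "endpoint": med,
                "F": fit.f_stat,
                "df_num": fit.df_num,
                "df_den": fit.df_den,
                "p": fit.p_overall,
                "n_used": fit.n_used,
                "n_dropped": fit.n_dropped,
            }
        )
        ct = emm_contrasts(fit)
        ct.insert(0, "endpoint", med)
        ct["p_adj"] = bh_adjust(ct["p"].to_numpy())
        ct["significant"] = ct["p_adj"] < alpha
        contrast_frames.append(ct)
        cv = fit.covariate_table.copy()
        cv.insert(0, "endpoint", med)
        cov_frames.append(cv)
        emm_rows.append(estimated_marginal_means(fit).rename(med))
        sig = ct[ct["significant"]]
        patterns[med] = tuple(sorted(zip(sig["group_a"], sig["group_b"])))
    return GroupComparisonResult(
        overall=pd.DataFrame(overall_rows),
        contrasts=pd.concat(contrast_frames, ignore_index=True),
        covariates=pd.concat(cov_frames, ignore_index=True),
        emms=pd.DataFrame(emm_rows),
        alpha=alpha,
        patterns=patterns,
    )
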