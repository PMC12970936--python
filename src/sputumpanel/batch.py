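"""Cross-study batch adjustment via the empirical-Bayes location/scale model.

The two studies' control groups are first pooled into a single "Control"
label so that batches share a biological anchor; then per-(batch, mediator)
additive (gamma) and multiplicative (delta) batch effects are estimated on
the log2 scale, shrunk across mediators with parametric empirical-Bayes
priors (normal for gamma, inverse-gamma for delta), and removed while the
protected covariates (group, age by default) are preserved -- the ComBat
model.  Applied to log2-transformed concentrations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sputumpanel.containers import MediatorMatrix

logger = logging.getLogger(__name__)


def merge_controls(participants: pd.DataFrame, control_labels: list[str]) -> pd.DataFrame:
    """Pool the listed control groups into a single ``"Control"`` label.

    All other labels and columns are untouched; the row count is preserved.
    Raises if any listed label has no rows.
    """
    groups = participants["group"].astype(str)
    for lab in control_labels:
        if not (groups == str(lab)).any():
            raise ValueError(f"control label {lab!r} not present in participant table")
    out = participants.copy()
    out["group"] = groups.where(~groups.isin([str(x) for x in control_labels]), "Control")
    return out


@dataclass
class BatchModel:
    """Estimated batch effects and standardisation parameters."""

    gamma_hat: pd.DataFrame  # batch x mediator, pre-shrinkage additive
    delta_hat: pd.DataFrame  # batch x mediator, pre-shrinkage variance ratio
    gamma_star: pd.DataFrame  # batch x mediator, EB-shrunk additive
    delta_star: pd.DataFrame  # batch x mediator, EB-shrunk variance ratio
    grand_mean: pd.Series  # per-mediator alpha-hat
    pooled_var: pd.Series  # per-mediator pooled variance
    prior_gamma: pd.DataFrame  # batch x (bar, tau2)
    prior_delta: pd.DataFrame  # batch x (a, b)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.gamma_star.index:
            for m in self.gamma_star.columns:
                rows.append(
                    {
                        "batch": b,
                        "mediator": m,
                        "gamma_star": self.gamma_star.loc[b, m],
                        "delta_star": self.delta_star.loc[b, m],
                    }
                )
        return pd.DataFrame(rows)


def _protected_design(participants: pd.DataFrame, protected: list[str]) -> np.ndarray:
    """Covariate columns (no intercept -- absorbed by the batch block)."""
    cols = []
    for cov in protected:
        s = participants[cov]
        if s.dtype == object or cov == "group" or s.dtype.name == "category":
            dummies = pd.get_dummies(s.astype(str), drop_first=True)
            cols.append(dummies.to_numpy(dtype=float))
        else:
            cols.append(s.to_numpy(dtype=float)[:, None])
    if not cols:
        return np.empty((len(participants), 0))
    return np.hstack(cols)


def _eb_iterate(
    z: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a_prior: float,
    b_prior: float,
    n_b: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard iterative solver for the parametric EB posterior modes.

    ``z`` is the standardized data for one batch (n_b x p with NaN outside);
    here we pass per-mediator sums instead for efficiency.
    """
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for it in range(max_iter):
        g_new = (n_b * tau2 * gamma_hat + d_old * gamma_bar) / (n_b * tau2 + d_old)
        sum2 = ((z - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b_prior) / (n_b / 2.0 + a_prior - 1.0)
        change = max(
            np.abs(g_new - g_old).max(initial=0.0), np.abs(d_new - d_old).max(initial=0.0)
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            return g_old, d_old
    raise RuntimeError(
        f"empirical-Bayes solver did not converge in {max_iter} iterations "
        f"(last change {change:.3g})"
    )


def combat_adjust(
    matrix: MediatorMatrix,
    participants: pd.DataFrame,
    batch_field: str = "batch",
    protected: list[str] | None = None,
    parametric: bool = True,
) -> tuple[MediatorMatrix, BatchModel | None]:
    """Remove batch effects from log2 concentrations, protecting covariates.

    Standard pipeline: (1) per-mediator OLS with batch indicators plus the
    protected design; (2) standardise by the grand mean and pooled variance;
    (3) per-batch location/scale estimates; (4) parametric EB shrinkage
    (normal prior on gamma, inverse-gamma on delta, posterior modes by the
    standard iterative update); (5) subtract gamma*, divide by sqrt(delta*),
    restore scale and protected effects.

    A single batch is returned unchanged (identity, with a warning).  Batch
    confounded with the protected design raises a rank error.
    """
    if matrix.values.isna().any().any():
        raise ValueError("combat_adjust requires a fully observed matrix (impute first)")
    protected = ["group", "age"] if protected is None else list(protected)
    batches = participants.loc[matrix.participants, batch_field].astype(str)
    levels = sorted(batches.unique())
    if len(levels) < 2:
        warnings.warn("single batch: adjustment is the identity", stacklevel=2)
        return matrix.copy(), None
    counts = batches.value_counts()
    if (counts < 2).any():
        raise ValueError(f"batch(es) with < 2 participants: {list(counts.index[counts < 2])}")

    Y = matrix.values.to_numpy(dtype=float)  # n x p
    n, p = Y.shape
    Z = np.column_stack([(batches == b).to_numpy(dtype=float) for b in levels])  # n x B
    C = _protected_design(participants.loc[matrix.participants], protected)
    X = np.hstack([Z, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"batch {batch_field!r} is confounded with the protected design {protected}"
        )

    n_batches = counts.reindex(levels).to_numpy(dtype=float)
    B_hat = np.linalg.solve(X.T @ X, X.T @ Y)  # (B + q) x p
    grand_mean = (n_batches / n) @ B_hat[: len(levels)]  # p
    resid = Y - X @ B_hat
    pooled_var = (resid**2).mean(axis=0)  # p
    if (pooled_var <= 0).any():
        raise ValueError("zero pooled variance; degenerate mediator(s)")

    stand_mean = np.outer(np.ones(n), grand_mean) + C @ B_hat[len(levels):]
    Zdata = (Y - stand_mean) / np.sqrt(pooled_var)

    gamma_hat = np.vstack(
        [Zdata[(batches == b).to_numpy()].mean(axis=0) for b in levels]
    )  # B x p
    delta_hat = np.vstack(
        [Zdata[(batches == b).to_numpy()].var(axis=0, ddof=1) for b in levels]
    )

    prior_g, prior_d = [], []
    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i, b in enumerate(levels):
        gbar = float(gamma_hat[i].mean())
        tau2 = float(gamma_hat[i].var(ddof=1))
        dmean = float(delta_hat[i].mean())
        dvar = float(delta_hat[i].var(ddof=1))
        a_prior = (2 * dvar + dmean**2) / dvar if dvar > 0 else 2.0
        b_prior = (dmean * dvar + dmean**3) / dvar if dvar > 0 else 1.0
        prior_g.append({"bar": gbar, "tau2": tau2})
        prior_d.append({"a": a_prior, "b": b_prior})
        zb = Zdata[(batches == b).to_numpy()]
        if parametric:
            gamma_star[i], delta_star[i] = _eb_iterate(
                zb, gamma_hat[i], delta_hat[i], gbar, tau2, a_prior, b_prior,
                np.full(p, float(zb.shape[0])),
            )
        else:
            gamma_star[i], delta_star[i] = gamma_hat[i], delta_hat[i]
    if (delta_star <= 0).any():
        raise ValueError("non-positive shrunk scale estimate delta*")

    bayes = Zdata.copy()
    for i, b in enumerate(levels):
        sel = (batches == b).to_numpy()
        bayes[sel] = (Zdata[sel] - gamma_star[i]) / np.sqrt(delta_star[i])
    adjusted = bayes * np.sqrt(pooled_var) + stand_mean

    med = matrix.mediators
    model = BatchModel(
        gamma_hat=pd.DataFrame(gamma_hat, index=levels, columns=med),
        delta_hat=pd.DataFrame(delta_hat, index=levels, columns=med),
        gamma_star=pd.DataFrame(gamma_star, index=levels, columns=med),
        delta_star=pd.DataFrame(delta_star, index=levels, columns=med),
        grand_mean=pd.Series(grand_mean, index=med),
        pooled_var=pd.Series(pooled_var, index=med),
        prior_gamma=pd.DataFrame(prior_g, index=levels),
        prior_delta=pd.DataFrame(prior_d, index=levels),
    )
    out = pd.DataFrame(adjusted, index=matrix.participants, columns=med)
    return MediatorMatrix(out, matrix.lod.copy(), matrix.scale), model
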