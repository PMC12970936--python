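"""Detection filtering, left-censored imputation, log2 transform, normality.

Nondetects (values below the assay limit of detection, LOD) are handled in
two steps: mediators detected in fewer than 75% of participants are dropped,
then remaining nondetects are imputed by an iterative sequential scheme that
draws each censored cell from a regression-based conditional distribution
truncated to (0, LOD).  Downstream analyses work on log2-transformed
concentrations; the Shapiro-Wilk test documents that choice per mediator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from sputumpanel.containers import MediatorMatrix

logger = logging.getLogger(__name__)


def detection_filter(matrix: MediatorMatrix, min_detection: float = 0.75) -> MediatorMatrix:
    """Drop mediators detected in fewer than ``min_detection`` of participants.

    The threshold is inclusive: a mediator detected in exactly ``min_detection``
    of participants is retained.  Raises if every mediator would be removed.
    """
    if not (0.0 < min_detection <= 1.0):
        raise ValueError(f"min_detection {min_detection} outside (0, 1]")
    frac = matrix.detection_fraction()
    keep = frac[frac >= min_detection].index
    dropped = [m for m in matrix.mediators if m not in set(keep)]
    if not len(keep):
        raise ValueError("detection filter removed every mediator")
    if dropped:
        logger.info(
            "detection_filter: removed %d mediator(s) below %.0f%% detection: %s",
            len(dropped), 100 * min_detection, ", ".join(dropped),
        )
    return MediatorMatrix(matrix.values[list(keep)].copy(), matrix.lod[list(keep)].copy(), matrix.scale)


def impute_left_censored(
    matrix: MediatorMatrix, n_iterations: int = 10, seed: int = 0, ridge: float = 1e-3
) -> MediatorMatrix:
    """Impute below-LOD nondetects with values in (0, LOD).

    Iterative sequential scheme on the log2 scale: censored cells start at
    LOD/2; then, for ``n_iterations`` sweeps, each mediator with missing
    entries is regressed on all other mediators (ridge-stabilised least
    squares) and its censored cells are redrawn from the fitted conditional
    normal truncated above at log2(LOD).  Observed cells are never touched;
    the same seed reproduces the same imputations.
    """
    mask = matrix.mask
    if not mask.to_numpy().any():
        return matrix.copy()
    if matrix.scale != "raw":
        raise ValueError("impute_left_censored expects raw concentrations")
    no_lod = mask.any(axis=0) & matrix.lod.isna()
    if no_lod.any():
        raise ValueError(
            "mediator(s) with missing entries but no LOD: " + ", ".join(no_lod.index[no_lod])
        )

    rng = np.random.default_rng(seed)
    med = matrix.mediators
    lod_log2 = np.log2(matrix.lod.to_numpy())
    Y = np.log2(matrix.values.to_numpy())  # NaN at censored cells
    M = mask.to_numpy()
    # initialise at LOD/2 (i.e. log2 LOD - 1)
    for j in range(len(med)):
        Y[M[:, j], j] = lod_log2[j] - 1.0

    target_cols = [j for j in range(len(med)) if M[:, j].any()]
    n = Y.shape[0]
    for _ in range(max(1, int(n_iterations))):
        for j in target_cols:
            X = np.delete(Y, j, axis=1)
            X = np.column_stack([np.ones(n), X])
            obs = ~M[:, j]
            Xo, yo = X[obs], Y[obs, j]
            XtX = Xo.T @ Xo + ridge * np.eye(X.shape[1])
            beta = np.linalg.solve(XtX, Xo.T @ yo)
            resid = yo - Xo @ beta
            dof = max(obs.sum() - X.shape[1], 1)
            sigma = float(np.sqrt(resid @ resid / dof))
            sigma = max(sigma, 1e-8)
            mu = X[M[:, j]] @ beta
            # draw from N(mu, sigma^2) truncated above at log2(LOD)
            b = (lod_log2[j] - mu) / sigma
            draws = stats.truncnorm.rvs(
                -np.inf, b, loc=mu, scale=sigma, random_state=rng
            )
            Y[M[:, j], j] = draws

    out = matrix.values.copy()
    vals = np.exp2(Y)
    out.loc[:, :] = np.where(M, vals, matrix.values.to_numpy())
    return MediatorMatrix(out, matrix.lod.copy(), matrix.scale)


def log2_transform(matrix: MediatorMatrix) -> MediatorMatrix:
    """Replace each concentration by its base-2 logarithm.

    Requires a fully observed, strictly positive matrix (run the detection
    filter and imputation first).
    """
    vals = matrix.values
    if vals.isna().any().any():
        rows, cols = np.where(vals.isna())
        cell = (vals.index[rows[0]], vals.columns[cols[0]])
        raise ValueError(f"missing value at participant {cell[0]!r}, mediator {cell[1]!r}")
    if (vals.to_numpy() <= 0).any():
        bad = vals.stack()[vals.stack() <= 0].index[0]
        raise ValueError(f"non-positive value at participant {bad[0]!r}, mediator {bad[1]!r}")
    out = np.log2(vals)
    lod = np.log2(matrix.lod) if matrix.lod.notna().any() else matrix.lod
    return MediatorMatrix(out, lod, scale="log2")


def assess_normality(matrix: MediatorMatrix) -> pd.DataFrame:
    """Shapiro-Wilk normality assessment on raw and log2 scales.

    Returns a tidy frame with one row per (mediator, scale): the W statistic,
    its p-value, and a ``better_scale`` flag per mediator marking the scale
    with the higher W (closer to normal).
    """
    rows = []
    for m in matrix.mediators:
        x = matrix.values[m].dropna().to_numpy()
        if len(x) < 3:
            raise ValueError(f"mediator {m!r}: need >= 3 non-missing values, got {len(x)}")
        if len(x) > 5000:
            raise ValueError(f"mediator {m!r}: Shapiro-Wilk limited to n <= 5000")
        if np.ptp(x) == 0:
            raise ValueError(f"mediator {m!r}: constant sample, W undefined")
        if matrix.scale == "raw":
            scales = {"raw": x, "log2": np.log2(x)}
        else:
            scales = {"log2": x}
        stats_by_scale = {}
        for name, data in scales.items():
            w, p = stats.shapiro(data)
            stats_by_scale[name] = (float(w), float(p))
        best = max(stats_by_scale, key=lambda k: stats_by_scale[k][0])
        for name, (w, p) in stats_by_scale.items():
            rows.append(
                {"mediator": m, "scale": name, "W": w, "p": p, "better_scale": name == best}
            )
    return pd.DataFrame(rows)
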