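"""Per-group mediator co-correlation networks and their cross-group overlap.

Pearson correlations are computed between raw (untransformed) mediator
concentrations within each group.  A mediator pair is considered
significantly co-correlated when |r| exceeds 0.6 (strictly) and the
two-sided p-value from the t transform of r is below 0.01 (strictly).
Overlap between groups' significant-pair sets is summarised with exclusive
intersection counts (UpSet semantics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sputumpanel.containers import MediatorMatrix

Pair = tuple[str, str]


@dataclass
class CorrelationNetwork:
    """One group's correlation structure and its significant pairs."""

    group: str
    r: pd.DataFrame
    p: pd.DataFrame
    pairs: frozenset[Pair]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"mediator_a": a, "mediator_b": b, "r": self.r.loc[a, b], "p": self.p.loc[a, b]}
            for a, b in sorted(self.pairs)
        ]
        return pd.DataFrame(rows, columns=["mediator_a", "mediator_b", "r", "p"])


def correlation_matrix(
    matrix: MediatorMatrix, participants: pd.DataFrame, group: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p matrices within one group.

    p-values use the t transform of r on n-2 degrees of freedom.  A mediator
    with zero variance within the group yields NaN r/p for its pairs (warned,
    treated as non-significant downstream).  If missing values remain,
    pairwise-complete observations are used with a warning.
    """
    ids = participants.index[participants["group"].astype(str) == str(group)]
    if len(ids) < 3:
        raise ValueError(f"group {group!r} has {len(ids)} participants; need >= 3")
    sub = matrix.values.loc[ids]
    if sub.isna().any().any():
        warnings.warn(
            f"group {group!r}: missing values present; using pairwise-complete observations",
            stacklevel=2,
        )
    zero_var = sub.std(ddof=1) == 0
    if zero_var.any():
        warnings.warn(
            f"group {group!r}: zero-variance mediator(s) {list(zero_var.index[zero_var])}; "
            "their correlations are undefined and treated as non-significant",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = sub.corr(method="pearson", min_periods=3)
    np.fill_diagonal(r.values, 1.0)

    counts = (~sub.isna()).astype(float).T @ (~sub.isna()).astype(float)
    n = pd.DataFrame(counts, index=r.index, columns=r.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        rv = r.to_numpy()
        df = n.to_numpy() - 2
        t = rv * np.sqrt(df / np.clip(1 - rv**2, 1e-300, None))
        p = 2 * stats.t.sf(np.abs(t), np.clip(df, 1, None))
    p = pd.DataFrame(p, index=r.index, columns=r.columns)
    np.fill_diagonal(p.values, 0.0)
    return r, p


def significant_pairs(
    r: pd.DataFrame, p: pd.DataFrame, r_threshold: float = 0.6, p_threshold: float = 0.01
) -> frozenset[Pair]:
    """Unordered mediator pairs with |r| > r_threshold and p < p_threshold.

    Both inequalities are strict; NaN entries never qualify.
    """
    if r.shape != p.shape or not r.columns.equals(p.columns):
        raise ValueError("r and p matrices must share shape and labels")
    out = set()
    cols = list(r.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            rv, pv = r.loc[a, b], p.loc[a, b]
            if np.isfinite(rv) and np.isfinite(pv) and abs(rv) > r_threshold and pv < p_threshold:
                out.add((a, b))
    return frozenset(out)


def build_network(
    matrix: MediatorMatrix,
    participants: pd.DataFrame,
    group: str,
    r_threshold: float = 0.6,
    p_threshold: float = 0.01,
) -> CorrelationNetwork:
    """Convenience wrapper: correlation matrices plus thresholded pair set."""
    r, p = correlation_matrix(matrix, participants, group)
    return CorrelationNetwork(
        group=str(group), r=r, p=p, pairs=significant_pairs(r, p, r_threshold, p_threshold)
    )


@dataclass
class OverlapTable:
    """Exclusive-intersection counts over groups' significant-pair sets."""

    exclusive: pd.DataFrame  # columns: combination (tuple of groups), count
    totals: pd.Series  # per-group total significant pairs

    @property
    def union_size(self) -> int:
        return int(self.exclusive["count"].sum())


def pair_overlap(networks: list[CorrelationNetwork]) -> OverlapTable:
    """UpSet-style exclusive intersections of the groups' pair sets.

    Each pair in the union is assigned to exactly one combination -- the set
    of groups that contain it -- so the exclusive counts sum to the union
    size.
    """
    if len(networks) < 2:
        raise ValueError("need >= 2 networks")
    universe = set(networks[0].r.columns)
    for nw in networks[1:]:
        if set(nw.r.columns) != universe:
            raise ValueError(f"network {nw.group!r} has a different mediator universe")
    membership: dict[Pair, tuple[str, ...]] = {}
    for pair in set().union(*(nw.pairs for nw in networks)):
        combo = tuple(nw.group for nw in networks if pair in nw.pairs)
        membership[pair] = combo
    counts: dict[tuple[str, ...], int] = {}
    for combo in membership.values():
        counts[combo] = counts.get(combo, 0) + 1
    rows = [
        {"combination": "+".join(combo), "n_groups": len(combo), "count": c}
        for combo, c in sorted(counts.items(), key=lambda kv: (-len(kv[0]), kv[0]))
    ]
    exclusive = pd.DataFrame(rows, columns=["combination", "n_groups", "count"])
    totals = pd.Series({nw.group: nw.n_pairs for nw in networks})
    return OverlapTable(exclusive=exclusive, totals=totals)


def membership_table(networks: list[CorrelationNetwork]) -> pd.DataFrame:
    """UpSet-ready indicator matrix: one row per pair in the union, one
    0/1 column per group."""
    union = sorted(set().union(*(nw.pairs for nw in networks)))
    data = {
        nw.group: [int(pair in nw.pairs) for pair in union] for nw in networks
    }
    out = pd.DataFrame(data, index=pd.MultiIndex.from_tuples(union, names=["mediator_a", "mediator_b"]))
    return out.reset_index()
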