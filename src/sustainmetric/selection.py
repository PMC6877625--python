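"""Three-criterion selection of the optimal countries-indicators combination.

Walking the stabilized chain from k_min up, each additional indicator costs
countries (dropout), perturbs the level of the scores (variability) and
reshuffles the ranking (rank shift).  Each criterion is min-max normalized
across candidate levels and the three are summed with equal weights; the
optimum is the level with the smallest total.

The chain's base level (k_min) has no incoming transition — all three
criteria are identically zero there by construction — so it is reported in
the criteria table but excluded from argmin candidacy; otherwise the base
level would trivially win every selection.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .frontier import Combination

CRITERIA = ("dropout", "score_sd", "rank_shift")


def dropout_criterion(chain: Sequence[Combination]) -> pd.Series:
    """Countries lost moving from level k-1 to k: n(k-1) - n(k); 0 at the base.

    Nonnegative on a nested chain (country sets only shrink as k grows).
    """
    ks = [c.k for c in chain]
    ns = [c.n for c in chain]
    out = [0.0] + [float(ns[i - 1] - ns[i]) for i in range(1, len(chain))]
    return pd.Series(out, index=pd.Index(ks, name="k"), name="dropout")


def variability_criterion(
    tables: Mapping[int, pd.DataFrame], mode: str = "cumulative"
) -> pd.Series:
    """Variability of the across-country mean suscore along the chain.

    ``mode="cumulative"`` (default): at level k, the population SD of the
    mean scores over all levels k_min..k — a stability-so-far measure.
    ``mode="adjacent"``: the population SD of the two means at k-1 and k
    (= |difference| / 2).
    """
    ks = sorted(tables)
    means = np.array([tables[k]["suscore"].mean() for k in ks])
    out = np.zeros(len(ks))
    if mode == "cumulative":
        for i in range(len(ks)):
            out[i] = float(np.std(means[: i + 1]))
    elif mode == "adjacent":
        for i in range(1, len(ks)):
            out[i] = float(np.std(means[i - 1 : i + 1]))
    else:
        raise ValueError(f"unknown variability mode {mode!r}")
    return pd.Series(out, index=pd.Index(ks, name="k"), name="score_sd")


def rank_shift_criterion(
    tables: Mapping[int, pd.DataFrame], metric: str = "displacement"
) -> pd.Series:
    """Rank instability between consecutive levels; 0 at the base level.

    ``metric="displacement"`` (default): mean absolute rank change over the
    countries shared by levels k-1 and k.  ``metric="kendall"``: normalized
    Kendall tau distance, (1 - tau) / 2, over the shared countries.
    """
    ks = sorted(tables)
    out = [0.0]
    for prev, cur in zip(ks, ks[1:]):
        shared = tables[prev].index.intersection(tables[cur].index)
        if len(shared) == 0:
            raise ValueError(f"no shared countries between k={prev} and k={cur}")
        if metric == "displacement":
            d = (tables[cur].loc[shared, "rank"] - tables[prev].loc[shared, "rank"]).abs()
            out.append(float(d.mean()))
        elif metric == "kendall":
            if len(shared) < 2:
                out.append(0.0)
            else:
                tau = stats.kendalltau(
                    tables[prev].loc[shared, "suscore"], tables[cur].loc[shared, "suscore"]
                ).statistic
                out.append(float((1.0 - tau) / 2.0))
        else:
            raise ValueError(f"unknown rank-shift metric {metric!r}")
    return pd.Series(out, index=pd.Index(ks, name="k"), name="rank_shift")


def _minmax_normalize(s: pd.Series) -> pd.Series:
    lo, hi = s.min(), s.max()
    if hi == lo:
        return pd.Series(np.zeros(len(s)), index=s.index)
    return (s - lo) / (hi - lo)


def criteria_table(
    chain: Sequence[Combination],
    tables: Mapping[int, pd.DataFrame],
    variability: str = "cumulative",
    rank_metric: str = "displacement",
) -> pd.DataFrame:
    """Raw + normalized criteria per chain level, plus the equal-weight total.

    Normalization is min-max across the candidate levels (every level above
    the base); normalized columns lie in [0,1] and ``total`` in [0,3].  The
    base level carries NaN normalized values and is never a candidate.
    """
    ks = sorted(tables)
    if [c.k for c in chain] != ks:
        raise ValueError("chain and score tables cover different k levels")
    df = pd.DataFrame(
        {
            "n": pd.Series({c.k: c.n for c in chain}),
            "dropout": dropout_criterion(chain),
            "score_sd": variability_criterion(tables, mode=variability),
            "rank_shift": rank_shift_criterion(tables, metric=rank_metric),
        }
    )
    df.index.name = "k"
    candidates = df.index[1:] if len(df) > 1 else df.index
    for crit in CRITERIA:
        norm = _minmax_normalize(df.loc[candidates, crit])
        df[f"{crit}_norm"] = norm.reindex(df.index)
    df["total"] = df[[f"{c}_norm" for c in CRITERIA]].sum(axis=1, skipna=False)
    return df


def select_optimal(
    chain: Sequence[Combination],
    tables: Mapping[int, pd.DataFrame],
    variability: str = "cumulative",
    rank_metric: str = "displacement",
) -> Combination:
    """The chain combination minimizing the aggregated normalized criteria.

    Ties go to the smaller k.  Per-criterion min-max makes the selection
    invariant to positive affine rescaling of any single raw criterion.
    """
    df = criteria_table(chain, tables, variability=variability, rank_metric=rank_metric)
    candidates = df["total"].dropna()
    if candidates.empty:  # single-level chain: nothing to trade off
        return chain[0]
    best_k = int(candidates.index[np.argmin(candidates.to_numpy())])
    by_k = {c.k: c for c in chain}
    return by_k[best_k]
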