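"""Within- and between-dimension composite scoring.

The aggregate sustainability score (SuScore) of a country is the geometric
mean of its four dimension scores; each dimension score is the arithmetic or
geometric mean of the normalized indicators it contains, per the registry's
dimension rule.  Geometric means are non-compensatory: a very low dimension
cannot be offset by high values elsewhere.

Because min-max normalization guarantees exact zeros (some country holds each
minimum), raw geometric means would annihilate every score touching a
minimum.  Values are therefore floored at ``EPS_FLOOR`` (1e-3, configurable)
before products are taken.
"""

from __future__ import annotations

import warnings
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import NormalizedPanel, preprocess_panel
from .registry import DIMENSIONS, IndicatorPanel, IndicatorRegistry

if TYPE_CHECKING:  # pragma: no cover
    from .frontier import Combination

#: Floor applied inside geometric means (min-max produces exact zeros).
EPS_FLOOR = 1e-3


def geometric_mean(values, floor: float = EPS_FLOOR) -> float:
    v = np.maximum(np.asarray(values, dtype=float), floor)
    return float(np.exp(np.mean(np.log(v))))


def dimension_score(values, rule: str, floor: float = EPS_FLOOR) -> float:
    """Aggregate one country's normalized indicator values within a dimension.

    ``rule`` is ``"arithmetic"`` (plain mean, compensatory) or ``"geometric"``
    (floored geometric mean).  A single indicator is its own score under
    either rule.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty indicator set for a dimension; a combination must "
                         "cover all four dimensions")
    if rule == "arithmetic":
        return float(np.mean(v))
    if rule == "geometric":
        if v.size == 1:
            return float(v[0])
        return geometric_mean(v, floor)
    raise ValueError(f"unknown dimension rule {rule!r}")


def aggregate_score(dim_scores, floor: float = EPS_FLOOR) -> float:
    """Geometric mean of exactly four dimension scores (with epsilon floor)."""
    v = np.asarray(dim_scores, dtype=float)
    if v.size != 4 or np.isnan(v).any():
        raise ValueError(f"need exactly four dimension scores, got {dim_scores!r}")
    return geometric_mean(v, floor)


def rank_scores(suscore: pd.Series) -> pd.Series:
    """Competition ranking ('1224'), 1 = highest score."""
    return suscore.rank(method="min", ascending=False).astype(int)


def score_normalized(
    norm: NormalizedPanel | pd.DataFrame,
    registry: IndicatorRegistry,
    floor: float = EPS_FLOOR,
) -> pd.DataFrame:
    """Score an already-normalized country x indicator table.

    Returns the ScoreTable: one row per country with the four dimension
    scores, ``suscore`` and ``rank`` (descending by suscore, competition
    ranking, countries sorted by ISO code for display).
    """
    values = norm.values if isinstance(norm, NormalizedPanel) else norm
    by_dim: dict[str, list[str]] = {d: [] for d in DIMENSIONS}
    for ind in values.columns:
        by_dim[registry.dimension_of(ind)].append(ind)
    missing = [d for d in DIMENSIONS if not by_dim[d]]
    if missing:
        raise ValueError(f"no indicators for dimension(s) {missing}; a combination "
                         "must cover all four dimensions")
    table = pd.DataFrame(index=values.index.copy())
    for dim in DIMENSIONS:
        cols = values[by_dim[dim]].to_numpy()
        rule = registry.dimension_rule[dim]
        if rule == "arithmetic":
            table[dim] = cols.mean(axis=1)
        else:
            table[dim] = np.exp(np.mean(np.log(np.maximum(cols, floor)), axis=1))
    dims = table[list(DIMENSIONS)].to_numpy()
    table["suscore"] = np.exp(np.mean(np.log(np.maximum(dims, floor)), axis=1))
    table["rank"] = rank_scores(table["suscore"])
    table.index.name = "country"
    return table.sort_index()


def score_combination(
    panel: IndicatorPanel,
    registry: IndicatorRegistry,
    combination: "Combination",
    window: tuple[int, int] | None = None,
    floor: float = EPS_FLOOR,
    year_collapse: str = "mean",
) -> pd.DataFrame:
    """End-to-end scoring of one countries-indicators combination.

    Preprocesses the panel over exactly the combination's country set (min-max
    bounds included), aggregates per the registry's dimension rules, and ranks.
    """
    norm = preprocess_panel(
        panel,
        registry,
        countries=sorted(combination.country_set),
        window=window,
        indicators=sorted(combination.indicator_set),
        year_collapse=year_collapse,
    )
    return score_normalized(norm, registry, floor)


# ---------------------------------------------------------------------------
# Correlation diagnostics
# ---------------------------------------------------------------------------

def spearman_matrix(norm: NormalizedPanel | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank-correlation matrix of the indicators.

    Computed over the complete-case country set; the diagonal is 1.  A
    constant column has undefined correlation and is reported as NaN.
    """
    values = norm.values if isinstance(norm, NormalizedPanel) else norm
    if len(values) < 3:
        raise ValueError("need >= 3 countries for a Spearman matrix")
    cols = list(values.columns)
    n = len(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if n == 1:
            mat = np.ones((1, 1))
        else:
            rho = stats.spearmanr(values.to_numpy()).statistic
            mat = np.atleast_2d(rho) if n > 2 else np.array([[1.0, float(rho)], [float(rho), 1.0]])
    mat = np.array(mat, dtype=float)
    constant = values.nunique().to_numpy() <= 1
    mat[constant, :] = np.nan
    mat[:, constant] = np.nan
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=cols, columns=cols)


def suggest_rules(norm: NormalizedPanel | pd.DataFrame, registry: IndicatorRegistry) -> pd.DataFrame:
    """Advisory per-dimension mean |rho| to revisit the arithmetic/geometric choice.

    The published mapping was a one-time judgment call made from the indicator
    correlation diagram (high internal correlation -> arithmetic, low ->
    geometric); this reports the statistic without changing the registry.
    """
    values = norm.values if isinstance(norm, NormalizedPanel) else norm
    corr = spearman_matrix(values)
    rows = []
    for dim in DIMENSIONS:
        inds = [i for i in values.columns if registry.dimension_of(i) == dim]
        if not inds:
            continue
        if len(inds) == 1:
            mean_abs = np.nan
        else:
            block = corr.loc[inds, inds].to_numpy()
            off = block[~np.eye(len(inds), dtype=bool)]
            mean_abs = float(np.nanmean(np.abs(off)))
        rows.append(
            {
                "dimension": dim,
                "n_indicators": len(inds),
                "mean_abs_spearman": mean_abs,
                "registry_rule": registry.dimension_rule[dim],
            }
        )
    return pd.DataFrame(rows).set_index("dimension")
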