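"""Availability matrix, combination enumeration, trade-off frontier, and
backward-chain stabilization.

Each indicator covers its own subset of countries, and those subsets are not
nested: the countries with complete data shrink as indicators are added,
creating a trade-off frontier n(k).  Worse, the *identity* of the complete
country set reshuffles along the frontier, so min-max bounds move and country
scores fluctuate as k changes.  Backward chaining fixes this by walking from
a chosen combination down to k_min = 4 removing one indicator at a time, so
successive country sets are nested (each step only *adds* countries).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .aggregation import score_combination
from .registry import DIMENSIONS, IndicatorPanel, IndicatorRegistry

#: One indicator per dimension is the smallest admissible combination.
K_MIN = 4


@dataclass(frozen=True)
class Combination:
    """An indicator subset plus the countries with complete data for it."""

    indicator_set: frozenset[str]
    country_set: frozenset[str]

    @property
    def k(self) -> int:
        return len(self.indicator_set)

    @property
    def n(self) -> int:
        return len(self.country_set)

    def sort_key(self) -> tuple:
        return tuple(sorted(self.indicator_set))

    def __repr__(self) -> str:  # compact: full sets can be large
        return f"Combination(k={self.k}, n={self.n})"


class FrontierPoint(NamedTuple):
    k: int
    n: int
    combination: Combination


def availability(panel: IndicatorPanel, window: tuple[int, int] | None = None) -> pd.DataFrame:
    """Boolean country x indicator coverage (>=1 observation in the window)."""
    df = panel.in_window(window)
    mat = (
        df.groupby(["country", "indicator_id"])
        .size()
        .unstack("indicator_id", fill_value=0)
        > 0
    )
    # countries/indicators observed only outside the window keep all-False rows
    all_countries = sorted(panel.records["country"].unique())
    all_inds = sorted(panel.records["indicator_id"].unique())
    mat = mat.reindex(index=all_countries, columns=all_inds, fill_value=False)
    mat.index.name = "country"
    mat.columns.name = "indicator_id"
    return mat


def complete_countries(avail: pd.DataFrame, indicator_set: Iterable[str]) -> frozenset[str]:
    """Countries with coverage for *every* indicator in the set."""
    inds = sorted(set(indicator_set))
    if not inds:
        raise ValueError("indicator_set must be non-empty")
    unknown = [i for i in inds if i not in avail.columns]
    if unknown:
        raise KeyError(f"indicators not in availability matrix: {unknown}")
    mask = avail[inds].to_numpy().all(axis=1)
    return frozenset(avail.index[mask])


def _dimension_counts(indicator_set: Iterable[str], registry: IndicatorRegistry) -> dict[str, int]:
    counts = {d: 0 for d in DIMENSIONS}
    for ind in indicator_set:
        counts[registry.dimension_of(ind)] += 1
    return counts


def _covers_all_dimensions(indicator_set: Iterable[str], registry: IndicatorRegistry) -> bool:
    return all(v > 0 for v in _dimension_counts(indicator_set, registry).values())


def enumerate_combinations(
    avail: pd.DataFrame,
    registry: IndicatorRegistry,
    k_min: int = K_MIN,
    k_max: int | None = None,
    beam_width: int = 5,
    exhaustive: bool = False,
) -> dict[frozenset[str], Combination]:
    """Map the space of admissible countries-indicators combinations.

    Admissible subsets contain >=1 indicator from each of the four dimensions.
    Exhaustive enumeration over all subsets is infeasible at 27 indicators, so
    the default is a backward best-removal beam search: start from all
    indicators, evaluate every single-indicator removal of each beam member,
    record every evaluated node, and keep the ``beam_width`` subsets with the
    most complete-data countries at each k.  ``exhaustive=True`` enumerates
    every admissible subset (use only at small scale / in tests).

    Returns a dict keyed by the indicator frozenset; values are
    :class:`Combination` records with their exact complete-data country sets.
    """
    cols = [c for c in avail.columns if c in registry]
    if k_min < len(DIMENSIONS):
        raise ValueError(f"k_min={k_min} cannot satisfy >=1 indicator per dimension")
    present = {d for d in DIMENSIONS if any(registry.dimension_of(c) == d for c in cols)}
    if present != set(DIMENSIONS):
        raise ValueError(f"availability matrix lacks dimensions: {sorted(set(DIMENSIONS) - present)}")
    if k_max is None:
        k_max = len(cols)
    k_max = min(k_max, len(cols))

    results: dict[frozenset[str], Combination] = {}

    def evaluate(subset: frozenset[str]) -> Combination:
        combo = results.get(subset)
        if combo is None:
            combo = Combination(subset, complete_countries(avail, subset))
            results[subset] = combo
        return combo

    if exhaustive:
        for k in range(k_min, k_max + 1):
            for subset in itertools.combinations(cols, k):
                fs = frozenset(subset)
                if _covers_all_dimensions(fs, registry):
                    evaluate(fs)
        return results

    full = frozenset(cols)
    beam = [evaluate(full)]
    for k in range(len(cols) - 1, k_min - 1, -1):
        candidates: dict[frozenset[str], Combination] = {}
        for combo in beam:
            counts = _dimension_counts(combo.indicator_set, registry)
            for ind in combo.indicator_set:
                if counts[registry.dimension_of(ind)] <= 1:
                    continue  # removal would empty a dimension
                child = combo.indicator_set - {ind}
                if child not in candidates:
                    candidates[child] = evaluate(child)
        if not candidates:
            break
        beam = sorted(candidates.values(), key=lambda c: (-c.n, c.sort_key()))[:beam_width]
    return {s: c for s, c in results.items() if k_min <= len(s) <= k_max}


def tradeoff_frontier(
    combinations: Mapping[frozenset[str], Combination] | Iterable[Combination],
) -> list[FrontierPoint]:
    """Per k, the combination maximizing the complete-data country count.

    Ties are broken lexicographically on the sorted indicator ids.  Returned
    in increasing k; with search that explores children of each level's best
    node, n(k) is non-increasing in k.
    """
    combos = list(combinations.values() if isinstance(combinations, Mapping) else combinations)
    if not combos:
        raise ValueError("no combinations to build a frontier from")
    best: dict[int, Combination] = {}
    for c in combos:
        cur = best.get(c.k)
        if cur is None or (-c.n, c.sort_key()) < (-cur.n, cur.sort_key()):
            best[c.k] = c
    return [FrontierPoint(k, best[k].n, best[k]) for k in sorted(best)]


def backward_chain(
    avail: pd.DataFrame,
    registry: IndicatorRegistry,
    start: Combination,
    k_min: int = K_MIN,
) -> list[Combination]:
    """Nested chain from ``start`` down to ``k_min``, one removal per step.

    Removing an indicator can only grow the complete-data country set, so
    every one-removal predecessor is nested by construction; among them the
    one adding the most countries is chosen (ties broken lexicographically on
    the removed indicator id).  Returned ordered by increasing k; consecutive
    country sets satisfy country_set(k) >= country_set(k+1).
    """
    chain = [start]
    current = start
    while current.k > k_min:
        counts = _dimension_counts(current.indicator_set, registry)
        best: tuple | None = None
        for ind in sorted(current.indicator_set):
            if counts[registry.dimension_of(ind)] <= 1:
                continue
            child = current.indicator_set - {ind}
            countries = complete_countries(avail, child)
            key = (-len(countries), ind)
            if best is None or key < best[0]:
                best = (key, Combination(child, countries))
        if best is None:  # every dimension at exactly one indicator but k > k_min
            break
        current = best[1]
        chain.append(current)
    chain.reverse()
    return chain


def chain_scores(
    panel: IndicatorPanel,
    registry: IndicatorRegistry,
    chain: Sequence[Combination],
    window: tuple[int, int] | None = None,
) -> dict[int, pd.DataFrame]:
    """Score every element of a chain; keys are indicator counts k."""
    return {
        combo.k: score_combination(panel, registry, combo, window=window)
        for combo in chain
    }


def score_trajectories(tables: Mapping[int, pd.DataFrame]) -> pd.DataFrame:
    """Per-country suscore across k (rows = countries, columns = k levels)."""
    traj = pd.DataFrame({k: t["suscore"] for k, t in sorted(tables.items())})
    traj.index.name = "country"
    traj.columns.name = "k"
    return traj


def frontier_to_json(
    frontier: Sequence[FrontierPoint],
    combinations: Mapping[frozenset[str], Combination] | None = None,
    path: str | Path | None = None,
) -> str:
    """Export the frontier (and optionally the combination map) as JSON."""
    payload: dict = {
        "frontier": [
            {
                "k": p.k,
                "n": p.n,
                "indicator_ids": sorted(p.combination.indicator_set),
                "country_codes": sorted(p.combination.country_set),
            }
            for p in frontier
        ]
    }
    if combinations is not None:
        payload["combinations"] = [
            {"k": c.k, "n": c.n, "indicator_ids": sorted(c.indicator_set)}
            for c in sorted(combinations.values(), key=lambda c: (c.k, c.sort_key()))
        ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
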