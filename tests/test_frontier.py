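"""Availability, combination enumeration, trade-off frontier and backward
chaining."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest

from sustainmetric import (
    availability,
    backward_chain,
    chain_scores,
    complete_countries,
    enumerate_combinations,
    tradeoff_frontier,
)
from sustainmetric.frontier import (
    Combination,
    K_MIN,
    frontier_to_json,
    score_trajectories,
)

from conftest import ONE_PER_DIM, TWO_PER_DIM, panel_of, registry_of


def random_availability(rng, countries=12, registry=None, p=0.7):
    reg = registry or registry_of(TWO_PER_DIM)
    idx = [f"C{i:02d}" for i in range(countries)]
    mat = pd.DataFrame(
        rng.random((countries, len(reg))) < p, index=idx, columns=reg.indicator_ids
    )
    mat.index.name = "country"
    mat.columns.name = "indicator_id"
    return mat, reg


# -- availability ------------------------------------------------------------

def test_availability_reflects_observations_in_window():
    panel = panel_of(
        {"e1": {"A": [1.0, 2.0]}, "c1": {"B": [3.0, 4.0]}}, years=(2000, 2005)
    )
    avail = availability(panel, (2000, 2005))
    assert bool(avail.loc["A", "e1"]) and not bool(avail.loc["A", "c1"])
    # observations outside the window do not count
    assert not availability(panel, (2010, 2016)).any().any()


def test_complete_countries_matches_set_intersection_brute_force():
    rng = np.random.default_rng(0)
    avail, _ = random_availability(rng, countries=15)
    inds = list(avail.columns)
    for r in range(1, len(inds) + 1):
        for subset in itertools.combinations(inds, r):
            expected = set(avail.index)
            for i in subset:
                expected &= set(avail.index[avail[i]])
            assert complete_countries(avail, subset) == frozenset(expected)


def test_complete_countries_input_validation():
    avail, _ = random_availability(np.random.default_rng(1))
    with pytest.raises(ValueError, match="non-empty"):
        complete_countries(avail, [])
    with pytest.raises(KeyError, match="zz"):
        complete_countries(avail, ["zz"])


# -- enumeration -------------------------------------------------------------

def brute_force_combinations(avail, registry, k_min=K_MIN):
    out = {}
    cols = list(avail.columns)
    for k in range(k_min, len(cols) + 1):
        for subset in itertools.combinations(cols, k):
            fs = frozenset(subset)
            dims = {registry.dimension_of(i) for i in fs}
            if len(dims) == 4:
                out[fs] = Combination(fs, complete_countries(avail, fs))
    return out


def test_exhaustive_enumeration_matches_brute_force():
    rng = np.random.default_rng(2)
    avail, reg = random_availability(rng)
    combos = enumerate_combinations(avail, reg, exhaustive=True)
    expected = brute_force_combinations(avail, reg)
    assert combos.keys() == expected.keys()
    for key, combo in combos.items():
        assert combo.country_set == expected[key].country_set


def test_beam_search_is_a_subset_of_the_exhaustive_map():
    rng = np.random.default_rng(3)
    avail, reg = random_availability(rng)
    beam = enumerate_combinations(avail, reg, beam_width=3)
    full = brute_force_combinations(avail, reg)
    for key, combo in beam.items():
        assert combo.country_set == full[key].country_set


def test_enumeration_validates_structure():
    rng = np.random.default_rng(4)
    avail, reg = random_availability(rng)
    with pytest.raises(ValueError, match="k_min"):
        enumerate_combinations(avail, reg, k_min=3)
    quartet = registry_of(ONE_PER_DIM)
    with pytest.raises(ValueError, match="lacks dimensions"):
        enumerate_combinations(avail[["e1", "c1", "s1"]], quartet, k_min=4)


# -- frontier ----------------------------------------------------------------

def test_frontier_picks_per_k_maximum_with_lexicographic_ties():
    a = Combination(frozenset(["b", "c", "d", "e"]), frozenset(["X", "Y"]))
    b = Combination(frozenset(["a", "c", "d", "e"]), frozenset(["X", "Z"]))
    front = tradeoff_frontier({a.indicator_set: a, b.indicator_set: b})
    assert len(front) == 1
    assert front[0].combination is b  # 'a...' sorts before 'b...'


def test_frontier_is_monotone_under_exhaustive_enumeration():
    rng = np.random.default_rng(5)
    for _ in range(10):
        avail, reg = random_availability(rng, p=float(rng.uniform(0.5, 0.9)))
        front = tradeoff_frontier(enumerate_combinations(avail, reg, exhaustive=True))
        ns = [p.n for p in front]
        assert ns == sorted(ns, reverse=True)


def test_frontier_requires_combinations():
    with pytest.raises(ValueError, match="no combinations"):
        tradeoff_frontier({})


# -- backward chain ----------------------------------------------------------

def test_backward_chain_prefers_the_country_maximizing_removal():
    # e2 only covers {A,B}; removing it frees the other three countries
    reg = registry_of(TWO_PER_DIM[:5])  # e1,c1,s1,f1,e2
    avail = pd.DataFrame(
        True, index=list("ABCDE"), columns=["e1", "c1", "s1", "f1", "e2"]
    )
    avail.loc[list("CDE"), "e2"] = False
    start = Combination(frozenset(avail.columns), complete_countries(avail, avail.columns))
    chain = backward_chain(avail, reg, start)
    assert [c.k for c in chain] == [4, 5]
    assert chain[0].indicator_set == frozenset(["e1", "c1", "s1", "f1"])
    assert chain[0].country_set == frozenset("ABCDE")
    assert chain[1].country_set == frozenset("AB")


def test_backward_chain_breaks_zero_gain_ties_lexicographically():
    reg = registry_of(TWO_PER_DIM)
    avail = pd.DataFrame(True, index=list("ABC"), columns=reg.indicator_ids)
    start = Combination(frozenset(reg.indicator_ids), frozenset("ABC"))
    chain = backward_chain(avail, reg, start)
    # all removals gain nothing; the smallest removable id goes first
    removed = [
        sorted(b.indicator_set - a.indicator_set)[0]
        for a, b in zip(chain, chain[1:])
    ]
    # downward removal takes the smallest id first, so walking the chain
    # upward re-adds ids in descending lexicographic order
    assert removed == sorted(removed, reverse=True)


def test_backward_chain_invariants_on_random_matrices():
    rng = np.random.default_rng(6)
    reg = registry_of(TWO_PER_DIM)
    for _ in range(30):
        avail, _ = random_availability(rng, registry=reg, p=float(rng.uniform(0.5, 0.9)))
        start = Combination(
            frozenset(avail.columns), complete_countries(avail, avail.columns)
        )
        chain = backward_chain(avail, reg, start)
        ks = [c.k for c in chain]
        assert ks == list(range(K_MIN, start.k + 1))
        for small, big in zip(chain, chain[1:]):
            assert small.country_set >= big.country_set  # nested
            assert len(big.indicator_set - small.indicator_set) == 1
            dims = {reg.dimension_of(i) for i in small.indicator_set}
            assert len(dims) == 4


# -- scoring helpers ---------------------------------------------------------

def test_chain_scores_and_trajectories_shapes():
    reg = registry_of(TWO_PER_DIM)
    rng = np.random.default_rng(7)
    panel = panel_of(
        {i: {f"C{j}": float(rng.random()) for j in range(6)} for i in reg.indicator_ids}
    )
    avail = availability(panel, None)
    start = Combination(frozenset(reg.indicator_ids), complete_countries(avail, reg.indicator_ids))
    chain = backward_chain(avail, reg, start)
    tables = chain_scores(panel, reg, chain)
    assert sorted(tables) == [c.k for c in chain]
    traj = score_trajectories(tables)
    assert traj.shape == (6, len(chain))
    assert traj.columns.name == "k"


def test_frontier_json_export_round_trips(tmp_path):
    combo = Combination(frozenset(["e1", "c1", "s1", "f1"]), frozenset(["A", "B"]))
    front = tradeoff_frontier({combo.indicator_set: combo})
    path = tmp_path / "frontier.json"
    frontier_to_json(front, {combo.indicator_set: combo}, path)
    payload = json.loads(path.read_text())
    assert payload["frontier"][0]["k"] == 4
    assert payload["frontier"][0]["country_codes"] == ["A", "B"]
    assert payload["combinations"][0]["n"] == 2
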