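"""Shared fixture helpers: tiny registries and long-format panels."""

import matplotlib

matplotlib.use("Agg")

import pandas as pd
import pytest

from sustainmetric import IndicatorMeta, IndicatorPanel, IndicatorRegistry

#: One indicator per dimension — the smallest admissible structure.
ONE_PER_DIM = [
    ("e1", "environment"),
    ("c1", "economic"),
    ("s1", "social"),
    ("f1", "food_nutrition"),
]

#: Two indicators per dimension.
TWO_PER_DIM = ONE_PER_DIM + [
    ("e2", "environment"),
    ("c2", "economic"),
    ("s2", "social"),
    ("f2", "food_nutrition"),
]


def registry_of(assignments, rule=None, special=None):
    """Build a registry from (indicator_id, dimension[, sr_sign]) tuples."""
    special = special or {}
    entries = []
    for a in assignments:
        ind, dim, *rest = a
        sr = rest[0] if rest else 1
        entries.append(
            IndicatorMeta(
                indicator_id=ind,
                name=ind,
                dimension=dim,
                sr_sign=sr,
                dp_flag="C",
                special_transform=special.get(ind),
            )
        )
    return IndicatorRegistry(entries, rule)


def panel_of(values, years=(2000,)):
    """Build a panel from {indicator_id: {country: value-or-per-year-list}}."""
    rows = []
    for ind, by_c in values.items():
        for c, v in by_c.items():
            vs = list(v) if isinstance(v, (list, tuple)) else [v] * len(years)
            for y, vv in zip(years, vs):
                rows.append((c, ind, int(y), float(vv)))
    return IndicatorPanel(
        pd.DataFrame(rows, columns=["country", "indicator_id", "year", "value"])
    )


@pytest.fixture
def quartet_registry():
    return registry_of(ONE_PER_DIM)


@pytest.fixture
def octet_registry():
    return registry_of(TWO_PER_DIM)
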