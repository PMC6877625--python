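"""Indicator registry and panel I/O.

The metric is hierarchical: indicators belong to one of four dimensions
(environment, economic, social, food_nutrition), each dimension carrying a
within-dimension mean rule (arithmetic or geometric).  The registry holds the
per-indicator metadata that drives preprocessing and aggregation: the expected
sign of the relationship with sustainability (``sr_sign``), the
degree-of-proxy flag (``dp_flag``: C = comprehensive, P = partial proxy) and
optional special transforms (currently the pH fold around 7).

Panels are long-format country x indicator x year tables; missing data is the
*absence* of a record, never a sentinel value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

DIMENSIONS: tuple[str, ...] = ("environment", "economic", "social", "food_nutrition")

#: Within-dimension mean rule of the published metric: the environment and
#: social blocks show low internal cross-correlation (geometric mean), the
#: economic and food & nutrition blocks are internally correlated (arithmetic).
DEFAULT_DIMENSION_RULE: dict[str, str] = {
    "environment": "geometric",
    "social": "geometric",
    "economic": "arithmetic",
    "food_nutrition": "arithmetic",
}

#: Short CSV column names used in score exports.
DIMENSION_SHORT = {
    "environment": "env",
    "economic": "econ",
    "social": "soc",
    "food_nutrition": "foodnutr",
}
SHORT_TO_DIMENSION = {v: k for k, v in DIMENSION_SHORT.items()}


class RegistryError(ValueError):
    """Raised for malformed registry configurations."""


class PanelError(ValueError):
    """Raised for malformed panel files."""


@dataclass(frozen=True)
class IndicatorMeta:
    """Metadata for one indicator of the metric."""

    indicator_id: str
    name: str
    dimension: str
    sr_sign: int
    dp_flag: str
    sub_dimension: str = ""
    category: str = ""
    special_transform: str | None = None
    source: str = ""
    period: str = ""
    n_countries: int | None = None

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise RegistryError(
                f"indicator {self.indicator_id!r}: unknown dimension "
                f"{self.dimension!r} (expected one of {DIMENSIONS})"
            )
        if self.sr_sign not in (1, -1):
            raise RegistryError(
                f"indicator {self.indicator_id!r}: sr_sign must be +1 or -1, "
                f"got {self.sr_sign!r}"
            )
        if self.dp_flag not in ("C", "P"):
            raise RegistryError(
                f"indicator {self.indicator_id!r}: dp_flag must be 'C' or 'P', "
                f"got {self.dp_flag!r}"
            )


class IndicatorRegistry:
    """Ordered collection of :class:`IndicatorMeta` plus the dimension rules.

    Parameters
    ----------
    entries
        Indicator metadata in registry order (order matters: e.g. the
        sensitivity analysis perturbs "the first indicator of a dimension").
    dimension_rule
        Map dimension -> ``"arithmetic"`` | ``"geometric"``.  Defaults to the
        published mapping (geometric for environment/social, arithmetic for
        economic/food_nutrition).
    """

    def __init__(
        self,
        entries: Iterable[IndicatorMeta],
        dimension_rule: Mapping[str, str] | None = None,
    ) -> None:
        self._entries: dict[str, IndicatorMeta] = {}
        for meta in entries:
            if meta.indicator_id in self._entries:
                raise RegistryError(f"duplicate indicator_id {meta.indicator_id!r}")
            self._entries[meta.indicator_id] = meta
        if not self._entries:
            raise RegistryError("registry has no indicators")
        rule = dict(DEFAULT_DIMENSION_RULE if dimension_rule is None else dimension_rule)
        for dim, r in rule.items():
            if dim not in DIMENSIONS:
                raise RegistryError(f"dimension_rule: unknown dimension {dim!r}")
            if r not in ("arithmetic", "geometric"):
                raise RegistryError(
                    f"dimension_rule[{dim!r}] must be 'arithmetic' or 'geometric', got {r!r}"
                )
        for dim in self.dimensions_present():
            if dim not in rule:
                raise RegistryError(f"dimension {dim!r} has indicators but no dimension_rule")
        self.dimension_rule: dict[str, str] = rule

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[IndicatorMeta]:
        return iter(self._entries.values())

    def __contains__(self, indicator_id: object) -> bool:
        return indicator_id in self._entries

    def __getitem__(self, indicator_id: str) -> IndicatorMeta:
        try:
            return self._entries[indicator_id]
        except KeyError:
            raise KeyError(f"unknown indicator_id {indicator_id!r}") from None

    @property
    def indicator_ids(self) -> list[str]:
        return list(self._entries)

    def dimensions_present(self) -> list[str]:
        seen = {m.dimension for m in self}
        return [d for d in DIMENSIONS if d in seen]

    def indicators_in(self, dimension: str) -> list[str]:
        """Indicator ids of one dimension, in registry order."""
        return [m.indicator_id for m in self if m.dimension == dimension]

    def dimension_of(self, indicator_id: str) -> str:
        return self[indicator_id].dimension

    def counts_by_dimension(self) -> dict[str, int]:
        out = {d: 0 for d in DIMENSIONS}
        for m in self:
            out[m.dimension] += 1
        return out

    def subset(self, indicator_ids: Iterable[str]) -> "IndicatorRegistry":
        ids = set(indicator_ids)
        return IndicatorRegistry(
            [m for m in self if m.indicator_id in ids], self.dimension_rule
        )

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        entries = []
        for m in self:
            d = {
                "indicator_id": m.indicator_id,
                "name": m.name,
                "dimension": m.dimension,
                "sub_dimension": m.sub_dimension,
                "category": m.category,
                "sr_sign": m.sr_sign,
                "dp_flag": m.dp_flag,
            }
            if m.special_transform:
                d["special_transform"] = m.special_transform
            if m.source:
                d["source"] = m.source
            if m.period:
                d["period"] = m.period
            if m.n_countries is not None:
                d["n_countries"] = m.n_countries
            entries.append(d)
        return {"dimension_rule": dict(self.dimension_rule), "indicators": entries}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _meta_from_mapping(raw: Mapping, index: int) -> IndicatorMeta:
    where = f"indicator #{index + 1}"
    if "indicator_id" not in raw:
        raise RegistryError(f"{where}: missing required field 'indicator_id'")
    where = f"indicator {raw['indicator_id']!r}"
    for fld in ("dimension", "sr_sign", "dp_flag"):
        if fld not in raw or raw[fld] is None:
            raise RegistryError(f"{where}: missing required field {fld!r}")
    sr = raw["sr_sign"]
    if isinstance(sr, str):
        sr = {"+": 1, "-": -1, "+1": 1, "-1": -1}.get(sr.strip(), sr)
    if sr not in (1, -1):
        raise RegistryError(f"{where}: sr_sign must be +1 or -1, got {raw['sr_sign']!r}")
    nc = raw.get("n_countries")
    return IndicatorMeta(
        indicator_id=str(raw["indicator_id"]),
        name=str(raw.get("name", raw["indicator_id"])),
        dimension=str(raw["dimension"]),
        sr_sign=int(sr),
        dp_flag=str(raw["dp_flag"]),
        sub_dimension=str(raw.get("sub_dimension", "")),
        category=str(raw.get("category", "")),
        special_transform=raw.get("special_transform"),
        source=str(raw.get("source", "")),
        period=str(raw.get("period", "")),
        n_countries=None if nc is None else int(nc),
    )


def load_registry(path: str | Path) -> IndicatorRegistry:
    """Read a registry from a YAML (or JSON, a YAML subset) config file.

    The format is one block per indicator under ``indicators:`` plus an
    optional ``dimension_rule:`` mapping; see the packaged
    ``table2_registry.yaml`` for the canonical example.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping) or "indicators" not in raw:
        raise RegistryError(f"{path}: registry config must contain an 'indicators' list")
    items = raw["indicators"]
    if not items:
        raise RegistryError(f"{path}: 'indicators' list is empty")
    entries = [_meta_from_mapping(r, i) for i, r in enumerate(items)]
    return IndicatorRegistry(entries, raw.get("dimension_rule"))


def default_registry() -> IndicatorRegistry:
    """The packaged 27-indicator registry of the published metric."""
    ref = resources.files("sustainmetric.data") / "table2_registry.yaml"
    with resources.as_file(ref) as p:
        return load_registry(p)


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

PANEL_COLUMNS = ["country", "indicator_id", "year", "value"]


@dataclass
class IndicatorPanel:
    """Long-format country x indicator x year observations.

    ``records`` has columns ``country`` (ISO-3166 alpha-3), ``indicator_id``,
    ``year`` (int) and ``value`` (float).  (country, indicator_id, year)
    triples are unique; a missing observation is simply an absent row.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise PanelError(f"panel missing columns: {missing}")
        df = df[PANEL_COLUMNS].copy()
        df["year"] = df["year"].astype(int)
        df["value"] = df["value"].astype(float)
        dup = df.duplicated(subset=["country", "indicator_id", "year"])
        if dup.any():
            first = df[dup].iloc[0]
            raise PanelError(
                "duplicate (country, indicator_id, year) triple: "
                f"({first['country']}, {first['indicator_id']}, {first['year']})"
            )
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def countries(self) -> list[str]:
        return sorted(self.records["country"].unique())

    @property
    def indicator_ids(self) -> list[str]:
        return sorted(self.records["indicator_id"].unique())

    def in_window(self, window: tuple[int, int] | None) -> pd.DataFrame:
        if window is None:
            return self.records
        lo, hi = window
        y = self.records["year"]
        return self.records[(y >= lo) & (y <= hi)]

    def collapse(
        self,
        window: tuple[int, int] | None = None,
        countries: Sequence[str] | None = None,
        indicators: Sequence[str] | None = None,
        how: str = "mean",
    ) -> pd.DataFrame:
        """Collapse years to one value per (country, indicator).

        ``how="mean"`` averages the available years inside the window (the
        default used throughout); ``how="latest"`` keeps the most recent
        available year.  Returns a wide country x indicator DataFrame with
        NaN where a country has no observation.
        """
        df = self.in_window(window)
        if countries is not None:
            df = df[df["country"].isin(set(countries))]
        if indicators is not None:
            df = df[df["indicator_id"].isin(set(indicators))]
        if how == "mean":
            agg = df.groupby(["country", "indicator_id"])["value"].mean()
        elif how == "latest":
            agg = (
                df.sort_values("year")
                .groupby(["country", "indicator_id"])["value"]
                .last()
            )
        else:
            raise ValueError(f"unknown year-collapse rule {how!r}")
        wide = agg.unstack("indicator_id")
        if countries is not None:
            wide = wide.reindex(sorted(set(countries)))
        if indicators is not None:
            wide = wide.reindex(columns=sorted(set(indicators)))
        wide.index.name = "country"
        return wide


def load_panel(path: str | Path, registry: IndicatorRegistry) -> IndicatorPanel:
    """Read a long-format panel CSV and validate it against the registry.

    Malformed rows (non-numeric year/value) and unknown indicator ids are
    reported with their 1-based file line numbers (header = line 1).
    """
    df = pd.read_csv(path, dtype={"country": str, "indicator_id": str})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"{path}: missing columns {missing} (header required)")

    lines = df.index + 2  # 1-based, after header
    bad = []
    year = pd.to_numeric(df["year"], errors="coerce")
    value = pd.to_numeric(df["value"], errors="coerce")
    for idx in df.index[year.isna() | value.isna()]:
        bad.append(f"line {lines[idx]}: non-numeric year or value")
    unknown = ~df["indicator_id"].isin(set(registry.indicator_ids))
    for idx in df.index[unknown]:
        bad.append(f"line {lines[idx]}: unknown indicator_id {df.loc[idx, 'indicator_id']!r}")
    dup = df.duplicated(subset=["country", "indicator_id", "year"], keep=False)
    dup_second = dup & df.duplicated(subset=["country", "indicator_id", "year"])
    for idx in df.index[dup_second]:
        bad.append(
            f"line {lines[idx]}: duplicate triple "
            f"({df.loc[idx, 'country']}, {df.loc[idx, 'indicator_id']}, {df.loc[idx, 'year']})"
        )
    if bad:
        head = "; ".join(bad[:10])
        more = f" (+{len(bad) - 10} more)" if len(bad) > 10 else ""
        raise PanelError(f"{path}: {head}{more}")

    df = df.assign(year=year.astype(int), value=value.astype(float))
    return IndicatorPanel(df)


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

SCORE_CSV_COLUMNS = ["country", "env", "econ", "soc", "foodnutr", "suscore", "rank"]


def write_scores(table: pd.DataFrame, path: str | Path, precision: int = 12) -> None:
    """Write a score table to CSV (columns country,env,econ,soc,foodnutr,suscore,rank).

    NaN dimension scores (dimension absent from a combination is an error
    upstream, but temporal tables may carry missing periods) are written as
    empty fields.  Round-trips through :func:`read_scores` to <=1e-9.
    """
    if table.empty:
        raise ValueError("refusing to write an empty score table")
    out = table.copy()
    out.insert(0, "country", out.index)
    rename = {d: s for d, s in DIMENSION_SHORT.items() if d in out.columns}
    out = out.rename(columns=rename)
    cols = [c for c in SCORE_CSV_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False, float_format=f"%.{precision}g")


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a score table written by :func:`write_scores`."""
    df = pd.read_csv(path)
    if "country" not in df.columns:
        raise PanelError(f"{path}: score CSV must have a 'country' column")
    df = df.set_index("country")
    df = df.rename(columns=SHORT_TO_DIMENSION)
    if "rank" in df.columns and df["rank"].notna().all():
        df["rank"] = df["rank"].astype(int)
    return df
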