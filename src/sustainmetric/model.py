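"""statsmodels-style facade: a model built from data whose ``fit()`` returns
a results object carrying estimates, diagnostics and a summary table.

``SustainabilityIndex`` bundles a long-format indicator panel, the indicator
registry and the analysis window.  ``fit()`` runs the whole pipeline —
availability matrix, combination beam search, trade-off frontier, backward
chaining from the chosen starting combination, per-level scoring, the
three-criterion table and the optimal-combination selection — and returns a
``SustainabilityIndexResults`` with the country score table for the optimal
combination, rank/score stability diagnostics, and hooks for the sensitivity
and temporal analyses.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import frontier as frontier_mod
from .aggregation import EPS_FLOOR, score_combination, spearman_matrix, suggest_rules
from .frontier import (
    Combination,
    FrontierPoint,
    availability,
    backward_chain,
    chain_scores,
    enumerate_combinations,
    score_trajectories,
    tradeoff_frontier,
)
from .preprocessing import preprocess_panel
from .registry import (
    IndicatorPanel,
    IndicatorRegistry,
    default_registry,
    load_panel,
    load_registry,
    write_scores,
)
from .selection import criteria_table, select_optimal
from .sensitivity import DEFAULT_PERIODS, period_scores, sensitivity_table


class SustainabilityIndex:
    """Composite food-system sustainability index model.

    Parameters
    ----------
    panel
        Long-format country x indicator x year observations.
    registry
        Indicator metadata and dimension rules; defaults to the packaged
        27-indicator registry.
    window
        Analysis year window (inclusive); years outside it are ignored.
    k_min
        Smallest admissible indicator count (one per dimension).
    beam_width
        Beam width of the combination search; ``exhaustive=True`` in
        :meth:`fit` enumerates every admissible subset instead (small scale
        only).
    """

    def __init__(
        self,
        panel: IndicatorPanel,
        registry: IndicatorRegistry | None = None,
        window: tuple[int, int] = (2000, 2016),
        k_min: int = frontier_mod.K_MIN,
        beam_width: int = 5,
    ) -> None:
        self.panel = panel
        self.registry = default_registry() if registry is None else registry
        self.window = window
        self.k_min = k_min
        self.beam_width = beam_width

    @classmethod
    def from_csv(
        cls,
        panel_path: str | Path,
        registry_path: str | Path | None = None,
        **kwargs,
    ) -> "SustainabilityIndex":
        registry = default_registry() if registry_path is None else load_registry(registry_path)
        return cls(load_panel(panel_path, registry), registry, **kwargs)

    def fit(
        self,
        start_k: int | None = None,
        exhaustive: bool = False,
        variability: str = "cumulative",
        rank_metric: str = "displacement",
        floor: float = EPS_FLOOR,
    ) -> "SustainabilityIndexResults":
        """Run the full pipeline and return the results object.

        ``start_k`` chooses the frontier combination from which the backward
        chain starts (default: the largest k on the frontier, i.e. all
        indicators with any complete-data country).
        """
        avail = availability(self.panel, self.window)
        combos = enumerate_combinations(
            avail,
            self.registry,
            k_min=self.k_min,
            beam_width=self.beam_width,
            exhaustive=exhaustive,
        )
        front = tradeoff_frontier(combos)
        usable = [p for p in front if p.n >= 2]
        if not usable:
            raise ValueError("no frontier combination covers >= 2 countries")
        if start_k is None:
            start = usable[-1].combination
        else:
            by_k = {p.k: p.combination for p in front}
            if start_k not in by_k:
                raise ValueError(f"no frontier combination at k={start_k}")
            start = by_k[start_k]
        chain = backward_chain(avail, self.registry, start, k_min=self.k_min)
        tables = chain_scores(self.panel, self.registry, chain, window=self.window)
        crit = criteria_table(chain, tables, variability=variability, rank_metric=rank_metric)
        optimal = select_optimal(chain, tables, variability=variability, rank_metric=rank_metric)
        return SustainabilityIndexResults(
            model=self,
            availability=avail,
            combinations=combos,
            frontier=front,
            chain=chain,
            chain_score_tables=tables,
            criteria=crit,
            optimal=optimal,
            floor=floor,
        )


class SustainabilityIndexResults:
    """Fitted pipeline outputs: scores, frontier, chain, criteria, diagnostics."""

    def __init__(
        self,
        model: SustainabilityIndex,
        availability: pd.DataFrame,
        combinations: Mapping[frozenset, Combination],
        frontier: Sequence[FrontierPoint],
        chain: Sequence[Combination],
        chain_score_tables: Mapping[int, pd.DataFrame],
        criteria: pd.DataFrame,
        optimal: Combination,
        floor: float = EPS_FLOOR,
    ) -> None:
        self.model = model
        self.availability = availability
        self.combinations = dict(combinations)
        self.frontier = list(frontier)
        self.chain = list(chain)
        self.chain_score_tables = dict(chain_score_tables)
        self.criteria = criteria
        self.optimal = optimal
        self.floor = floor
        #: ScoreTable of the optimal combination (countries x dimension
        #: scores, suscore, rank).
        self.scores: pd.DataFrame = chain_score_tables[optimal.k]

    # -- convenience accessors ---------------------------------------------
    @property
    def suscore(self) -> pd.Series:
        return self.scores["suscore"]

    @property
    def ranks(self) -> pd.Series:
        return self.scores["rank"]

    def normalized_panel(self):
        """Re-derive the normalized inputs of the optimal combination."""
        return preprocess_panel(
            self.model.panel,
            self.model.registry,
            countries=sorted(self.optimal.country_set),
            window=self.model.window,
            indicators=sorted(self.optimal.indicator_set),
        )

    def correlation_matrix(self) -> pd.DataFrame:
        """Indicator Spearman matrix over the optimal combination's countries."""
        return spearman_matrix(self.normalized_panel())

    def rule_advisory(self) -> pd.DataFrame:
        return suggest_rules(self.normalized_panel(), self.model.registry)

    def score_trajectories(self) -> pd.DataFrame:
        """Per-country suscore across the chain's k levels."""
        return score_trajectories(self.chain_score_tables)

    # -- simulation-based analyses ------------------------------------------
    def sensitivity(self, seed: int = 0, replicates: int = 100, **kwargs) -> pd.DataFrame:
        """Perturbation sensitivity grid on the optimal combination."""
        return sensitivity_table(
            self.model.panel,
            self.model.registry,
            self.optimal,
            seed=seed,
            replicates=replicates,
            window=self.model.window,
            **kwargs,
        )

    def period_scores(
        self, periods: Sequence[tuple[int, int]] = DEFAULT_PERIODS, **kwargs
    ) -> pd.DataFrame:
        """Sub-period score trajectories on the optimal combination."""
        return period_scores(
            self.model.panel, self.model.registry, self.optimal, periods=periods, **kwargs
        )

    # -- output --------------------------------------------------------------
    def save_scores(self, path: str | Path) -> None:
        write_scores(self.scores, path)

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary (frontier, selection criteria, top countries)."""
        lines = []
        lines.append("Sustainability index fit")
        lines.append("=" * 64)
        lines.append(f"Window:            {self.model.window[0]}-{self.model.window[1]}")
        lines.append(f"Indicators (pool): {self.availability.shape[1]}")
        lines.append(f"Countries (pool):  {self.availability.shape[0]}")
        lines.append(f"Combinations:      {len(self.combinations)}")
        fk, lk = self.frontier[0], self.frontier[-1]
        lines.append(
            f"Frontier:          k={fk.k} -> {fk.n} countries ... k={lk.k} -> {lk.n} countries"
        )
        lines.append(
            f"Optimal:           {self.optimal.k} indicators, {self.optimal.n} countries"
        )
        lines.append("")
        lines.append("Selection criteria (min-max normalized, equal weights):")
        crit = self.criteria[["n", "dropout", "score_sd", "rank_shift", "total"]].copy()
        lines.append(crit.to_string(float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        lines.append(f"Top {top} countries (aggregate score):")
        best = self.scores.sort_values("rank").head(top)
        lines.append(best.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    # -- plots ---------------------------------------------------------------
    def plot_frontier(self, ax=None):
        """Trade-off frontier: complete-data countries vs indicator count."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ks = [p.k for p in self.frontier]
        ns = [p.n for p in self.frontier]
        cs = [c.n for c in self.combinations.values()]
        cks = [c.k for c in self.combinations.values()]
        ax.scatter(cks, cs, s=8, alpha=0.3, label="combinations")
        ax.plot(ks, ns, "o-", color="C3", label="frontier")
        ax.axvline(self.optimal.k, ls="--", color="C2", label=f"optimal k={self.optimal.k}")
        ax.set_xlabel("number of indicators (k)")
        ax.set_ylabel("countries with complete data (n)")
        ax.legend()
        return ax

    def plot_stability(self, countries: Sequence[str] | None = None, ax=None):
        """Per-country score trajectories along the stabilized chain."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        traj = self.score_trajectories()
        if countries is None:
            countries = list(traj.dropna().index[:6])
        for c in countries:
            ax.plot(traj.columns, traj.loc[c], marker="o", label=c)
        ax.set_xlabel("number of indicators (k)")
        ax.set_ylabel("aggregate sustainability score")
        ax.legend()
        return ax
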