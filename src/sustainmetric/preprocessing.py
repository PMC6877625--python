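"""Raw indicator values -> [0,1] sustainability-increasing scores.

Per indicator, over the country set being normalized:

1. years inside the analysis window are collapsed to one value per country
   (arithmetic mean by default);
2. a special transform is applied if tagged (water pH is folded to the
   absolute deviation from the neutral reference 7, after which larger means
   worse, i.e. the series behaves as sr_sign = -1);
3. a Box-Cox transform (lambda by maximum likelihood) is applied iff the
   bias-corrected sample skewness exceeds 2 in absolute value, shifting by
   ``1 - min`` first when any value is <= 0;
4. the series is oriented so that larger always means more sustainable
   (negation for sr_sign = -1);
5. min-max rescaling to [0, 1] over exactly the normalization country set.

Every step is logged in a per-indicator provenance record.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registry import IndicatorMeta, IndicatorPanel, IndicatorRegistry

#: |skewness| above which Box-Cox is applied.
SKEW_THRESHOLD = 2.0


class PreprocessingError(ValueError):
    pass


def fold_ph(values) -> pd.Series | np.ndarray:
    """Fold pH readings to the absolute deviation from neutral (|pH - 7|).

    The folded series is monotone-negative in sustainability: a larger
    deviation from 7 means worse water quality regardless of direction.
    Out-of-range readings (outside 0-14) pass through with a warning.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and ((finite < 0) | (finite > 14)).any():
        warnings.warn("pH values outside the plausible 0-14 range", stacklevel=2)
    out = np.abs(arr - 7.0)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def sample_skewness(values) -> float:
    """Bias-corrected (adjusted Fisher-Pearson) sample skewness.

    A constant series is defined to have skewness 0 (degenerate but usable in
    toy fixtures); fewer than 3 finite values is an error.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise PreprocessingError(f"skewness undefined for n={x.size} (< 3) values")
    if np.ptp(x) == 0:
        return 0.0
    return float(stats.skew(x, bias=False))


def boxcox_if_skewed(
    values, threshold: float = SKEW_THRESHOLD
) -> tuple[pd.Series | np.ndarray, float | None]:
    """Apply Box-Cox iff |skewness| > ``threshold``; return (series, lambda).

    lambda is chosen by profile maximum likelihood (scipy).  When any value is
    <= 0 the series is shifted by ``1 - min`` first, the conventional
    order-preserving remedy.  All-equal series cannot be transformed and pass
    through with a warning.
    """
    x = np.asarray(values, dtype=float)
    if abs(sample_skewness(x)) <= threshold:
        return values, None
    if np.ptp(x[np.isfinite(x)]) == 0:
        warnings.warn("constant series cannot be Box-Cox transformed", stacklevel=2)
        return values, None
    shift = 1.0 - np.nanmin(x) if np.nanmin(x) <= 0 else 0.0
    transformed, lam = stats.boxcox(x + shift)
    if isinstance(values, pd.Series):
        transformed = pd.Series(transformed, index=values.index, name=values.name)
    return transformed, float(lam)


def orient(values, sr_sign: int):
    """Orient a series so larger always means more sustainable.

    sr_sign=+1 is the identity; sr_sign=-1 negates (followed by min-max this
    is equivalent to ``1 - minmax(x)``).
    """
    if sr_sign not in (1, -1):
        raise ValueError(f"sr_sign must be +1 or -1, got {sr_sign!r}")
    return values if sr_sign == 1 else -values


def minmax(values) -> pd.Series | np.ndarray:
    """Min-max rescaling to [0, 1]: (x - min) / (max - min).

    A constant series maps to all 0.5 with a warning so that degenerate toy
    inputs remain usable rather than erroring.
    """
    x = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        warnings.warn("constant series in min-max; mapping to 0.5", stacklevel=2)
        out = np.full_like(x, 0.5)
    else:
        out = (x - lo) / (hi - lo)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


@dataclass
class NormalizedPanel:
    """Normalized country x indicator values plus the transform provenance.

    ``values`` is a wide DataFrame (rows = countries of the normalization set,
    columns = indicator ids), every entry in [0, 1].  ``provenance`` records,
    per indicator, the applied chain (ph_fold / boxcox lambda / orientation /
    min-max bounds) and the analysis window.
    """

    values: pd.DataFrame
    provenance: dict[str, dict] = field(default_factory=dict)

    @property
    def countries(self) -> list[str]:
        return list(self.values.index)

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.values.columns)

    def provenance_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.provenance, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def preprocess_series(x: pd.Series, meta: IndicatorMeta, skew_threshold: float = SKEW_THRESHOLD) -> tuple[pd.Series, dict]:
    """Run the per-indicator transform chain on an already-collapsed series."""
    steps: list[str] = []
    sign = meta.sr_sign
    if meta.special_transform == "ph_fold_7":
        x = fold_ph(x)
        sign = -1  # folded deviation: larger is worse by construction
        steps.append("ph_fold_7")
    raw_skew = sample_skewness(x) if len(x) >= 3 else 0.0
    lam = None
    if len(x) >= 3:
        x, lam = boxcox_if_skewed(x, threshold=skew_threshold)
        if lam is not None:
            steps.append(f"boxcox(lambda={lam:.6g})")
    x = orient(x, sign)
    steps.append("orient(+1)" if sign == 1 else "orient(-1)")
    lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-series warning handled by caller
        x = minmax(x)
    steps.append("minmax")
    prov = {
        "steps": steps,
        "sr_sign": int(meta.sr_sign),
        "effective_sign": int(sign),
        "skewness": float(raw_skew),
        "boxcox_lambda": lam,
        "bounds": [lo, hi],
    }
    return x, prov


def preprocess_panel(
    panel: IndicatorPanel,
    registry: IndicatorRegistry,
    countries: Sequence[str],
    window: tuple[int, int] | None = None,
    indicators: Sequence[str] | None = None,
    year_collapse: str = "mean",
    skew_threshold: float = SKEW_THRESHOLD,
) -> NormalizedPanel:
    """Preprocess a panel into a :class:`NormalizedPanel` over ``countries``.

    Min-max bounds are computed over exactly the ``countries`` set — scoring
    a different country set rescales the indicators, which is precisely the
    instability the frontier/stabilization machinery manages.  Every
    (country, indicator) pair in scope must have at least one observation in
    the window; callers are expected to pass a complete-data country set.
    """
    if indicators is None:
        indicators = [i for i in panel.indicator_ids if i in registry]
    unknown = [i for i in indicators if i not in registry]
    if unknown:
        raise KeyError(f"indicators not in registry: {unknown}")
    collapsed = panel.collapse(
        window=window, countries=countries, indicators=indicators, how=year_collapse
    )
    if collapsed.isna().any().any():
        holes = collapsed.isna()
        pairs = [
            (c, i) for c in collapsed.index for i in collapsed.columns if holes.loc[c, i]
        ][:5]
        raise PreprocessingError(
            f"countries lack observations for in-scope indicators (first few: {pairs}); "
            "pass a complete-data country set"
        )
    out = {}
    prov = {}
    for ind in collapsed.columns:
        series, p = preprocess_series(collapsed[ind], registry[ind], skew_threshold)
        p["window"] = list(window) if window is not None else None
        p["year_collapse"] = year_collapse
        p["n_countries"] = int(len(series))
        out[ind] = series
        prov[ind] = p
    values = pd.DataFrame(out, index=collapsed.index)
    values.index.name = "country"
    return NormalizedPanel(values=values, provenance=prov)
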