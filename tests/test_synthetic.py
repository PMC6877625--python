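"""Seeded synthetic-panel generator: coverage, skew, correlation, ground truth."""

import numpy as np
import pandas as pd
import pytest

import sustainmetric as sm
from sustainmetric import (
    GeneratorConfig,
    SyntheticIndicator,
    availability,
    complete_countries,
    generate_panel,
    sample_skewness,
    spearman_matrix,
    sweet_spot_panel,
    table2_profile,
)
from sustainmetric.synthetic import _country_codes, frontier_hopping_panel


def quartet_specs(**kw):
    return [
        SyntheticIndicator("e1", "environment", 1, **kw),
        SyntheticIndicator("c1", "economic", 1, **kw),
        SyntheticIndicator("s1", "social", 1, **kw),
        SyntheticIndicator("f1", "food_nutrition", 1, **kw),
    ]


# -- config validation -------------------------------------------------------

def test_config_rejects_infeasible_correlations_and_models():
    with pytest.raises(ValueError, match="magnitude"):
        GeneratorConfig(indicators=quartet_specs(), within_dim_correlation={"economic": 1.0})
    three = [SyntheticIndicator(f"f{i}", "food_nutrition", 1) for i in range(3)]
    with pytest.raises(ValueError, match="positive semi-definite"):
        GeneratorConfig(indicators=three, within_dim_correlation={"food_nutrition": -0.9})
    with pytest.raises(ValueError, match="coverage_model"):
        GeneratorConfig(indicators=quartet_specs(), coverage_model="patchy")


def test_indicator_spec_validation():
    with pytest.raises(ValueError, match="coverage_fraction"):
        SyntheticIndicator("x", "economic", 1, coverage_fraction=0.0)
    with pytest.raises(ValueError, match="skew_target"):
        SyntheticIndicator("x", "economic", 1, skew_target="extreme")


def test_generate_panel_requires_indicators():
    with pytest.raises(ValueError, match="empty"):
        generate_panel(GeneratorConfig(indicators=[]))


# -- determinism and coverage ------------------------------------------------

def test_generation_is_deterministic_under_a_fixed_seed():
    cfg = table2_profile(n_countries=30, seed=5)
    p1, _, t1 = generate_panel(cfg)
    p2, _, t2 = generate_panel(table2_profile(n_countries=30, seed=5))
    pd.testing.assert_frame_equal(p1.records, p2.records)
    pd.testing.assert_frame_equal(t1, t2)


def test_full_coverage_gives_an_all_true_availability_matrix():
    cfg = GeneratorConfig(n_countries=12, indicators=quartet_specs(), seed=0)
    panel, _, _ = generate_panel(cfg)
    avail = availability(panel, cfg.years)
    assert avail.all().all()
    assert complete_countries(avail, avail.columns) == frozenset(panel.countries)


def test_blocky_coverage_counts_are_exact_and_sets_non_nested():
    specs = quartet_specs() + [
        SyntheticIndicator("x1", "economic", 1, coverage_fraction=0.6),
        SyntheticIndicator("x2", "economic", 1, coverage_fraction=0.6),
    ]
    cfg = GeneratorConfig(n_countries=50, indicators=specs, coverage_model="blocky", seed=3)
    panel, _, _ = generate_panel(cfg)
    avail = availability(panel, cfg.years)
    assert avail["x1"].sum() == 30 and avail["x2"].sum() == 30
    a = set(avail.index[avail["x1"]])
    b = set(avail.index[avail["x2"]])
    assert not (a <= b or b <= a)  # similar marginals, far smaller overlap


def test_random_coverage_matches_fraction_within_binomial_error():
    specs = quartet_specs() + [
        SyntheticIndicator("x1", "social", 1, coverage_fraction=0.5)
    ]
    cfg = GeneratorConfig(n_countries=400, indicators=specs, coverage_model="random", seed=4)
    panel, _, _ = generate_panel(cfg)
    avail = availability(panel, cfg.years)
    phat = avail["x1"].mean()
    assert abs(phat - 0.5) < 4 * np.sqrt(0.25 / 400)


def test_country_codes_are_unique_iso_style_triples():
    codes = _country_codes(800)
    assert codes[:3] == ["AAA", "AAB", "AAC"]
    assert len(set(codes)) == 800
    assert all(len(c) == 3 and c.isupper() for c in codes)


# -- marginals and correlation -----------------------------------------------

def test_high_skew_marginals_reliably_trigger_the_boxcox_regime():
    specs = [SyntheticIndicator("g1", "environment", 1, skew_target="high")]
    hits = 0
    draws = 100
    for seed in range(draws):
        cfg = GeneratorConfig(
            n_countries=5_000, indicators=specs, years=(2000, 2000), seed=seed
        )
        panel, _, _ = generate_panel(cfg)
        x = panel.collapse(indicators=["g1"])["g1"]
        hits += abs(sample_skewness(x)) > 2.0
    assert hits >= 0.95 * draws


def test_copula_correlation_appears_in_the_generated_block():
    specs = [SyntheticIndicator(f"f{i}", "food_nutrition", 1) for i in range(3)]
    specs += [
        SyntheticIndicator("e1", "environment", 1),
        SyntheticIndicator("c1", "economic", 1),
        SyntheticIndicator("s1", "social", 1),
    ]
    cfg = GeneratorConfig(
        n_countries=500,
        indicators=specs,
        years=(2000, 2000),
        within_dim_correlation={"food_nutrition": 0.9},
        propensity_effect=0.0,
        seed=6,
    )
    panel, _, _ = generate_panel(cfg)
    wide = panel.collapse(indicators=["f0", "f1", "f2"])
    corr = spearman_matrix(wide)
    off = corr.to_numpy()[~np.eye(3, dtype=bool)]
    assert off.mean() > 0.7


def test_propensity_shifts_values_in_the_oriented_direction():
    specs = [
        SyntheticIndicator("up", "economic", 1),
        SyntheticIndicator("down", "social", -1),
    ] + quartet_specs()[::3]  # add env and f&n coverage
    cfg = GeneratorConfig(n_countries=300, indicators=specs, propensity_effect=1.5, seed=7)
    panel, _, truth = generate_panel(cfg)
    wide = panel.collapse()
    rho_up = wide["up"].corr(truth["propensity"], method="spearman")
    rho_down = wide["down"].corr(truth["propensity"], method="spearman")
    assert rho_up > 0.5 and rho_down < -0.5


def test_ph_deviation_shrinks_as_propensity_grows():
    cfg = table2_profile(n_countries=300, seed=8)
    panel, _, truth = generate_panel(cfg)
    wide = panel.collapse(indicators=["water_ph"])
    dev = (wide["water_ph"] - 7.0).abs().dropna()
    rho = dev.corr(truth.loc[dev.index, "propensity"], method="spearman")
    assert rho < -0.3


def test_generated_dominance_is_preserved_in_scores():
    cfg = GeneratorConfig(
        n_countries=20, indicators=quartet_specs(), propensity_effect=3.0, seed=9
    )
    panel, reg, _ = generate_panel(cfg)
    wide = panel.collapse()
    from sustainmetric.aggregation import score_combination
    from sustainmetric.frontier import Combination

    combo = Combination(frozenset(wide.columns), frozenset(wide.index))
    table = score_combination(panel, reg, combo, window=cfg.years)
    oriented = wide * [reg[c].sr_sign for c in wide.columns]
    pairs = 0
    for a in wide.index:
        for b in wide.index:
            if a != b and (oriented.loc[a] >= oriented.loc[b]).all():
                pairs += 1
                assert table.loc[a, "suscore"] >= table.loc[b, "suscore"] - 1e-12
    assert pairs > 0  # the strong propensity effect guarantees dominated pairs


# -- packaged profiles -------------------------------------------------------

def test_table2_profile_mirrors_the_registry_structure():
    cfg = table2_profile()
    assert len(cfg.indicators) == 27
    by_dim = {}
    for s in cfg.indicators:
        by_dim[s.dimension] = by_dim.get(s.dimension, 0) + 1
    assert by_dim == {
        "environment": 8,
        "economic": 3,
        "social": 3,
        "food_nutrition": 13,
    }
    fracs = {s.indicator_id: s.coverage_fraction for s in cfg.indicators}
    assert min(fracs.values()) == pytest.approx(72 / 249)
    assert max(fracs.values()) == pytest.approx(245 / 249)
    skewed = {s.indicator_id for s in cfg.indicators if s.skew_target == "high"}
    assert skewed == {"ghg_agriculture", "foodborne_illness"}
    ph = [s for s in cfg.indicators if s.special_transform == "ph_fold_7"]
    assert [s.indicator_id for s in ph] == ["water_ph"]


def test_sweet_spot_panel_structure():
    panel, registry, k_star = sweet_spot_panel(seed=0)
    assert k_star == 8
    avail = availability(panel, (2000, 2004))
    informative = [i for i in registry.indicator_ids if i.startswith("ind")]
    dups = [i for i in registry.indicator_ids if i.startswith("dup")]
    assert len(informative) == 8 and len(dups) == 4
    assert avail[informative].all().all()  # informative: full coverage
    assert (avail[dups].sum() == 22).all()  # duplicates: partial coverage


def test_frontier_hopping_panel_families():
    panel, registry = frontier_hopping_panel(seed=0)
    avail = availability(panel, (2000, 2002))
    a_fam = [i for i in registry.indicator_ids if i.startswith("a")]
    b_fam = [i for i in registry.indicator_ids if i.startswith("b")]
    assert len(a_fam) == len(b_fam) == 6
    assert (avail[a_fam].sum() == 20).all()
    assert (avail[b_fam].sum() == 11).all()
    # each family alone is admissible (covers all four dimensions)
    for fam in (a_fam, b_fam):
        assert {registry.dimension_of(i) for i in fam} == set(sm.DIMENSIONS)
    # family b shares one country set; family a rotates
    b_sets = [frozenset(avail.index[avail[i]]) for i in b_fam]
    assert len(set(b_sets)) == 1
    a_sets = [frozenset(avail.index[avail[i]]) for i in a_fam]
    assert len(set(a_sets)) == 6
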