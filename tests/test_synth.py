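"""Generator: determinism, distributional calibration, conservation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from admin_prev import (
    SOURCES,
    SynthConfig,
    assign_capture,
    capture_cell_probabilities,
    emit_records,
    generate_population,
    generate_study,
    inject_missingness,
    sample_registry,
)


def test_config_validation_names_offending_field():
    with pytest.raises(ValueError, match="missing_birth_year_rate"):
        SynthConfig(population_size=10, missing_birth_year_rate=1.5)
    with pytest.raises(ValueError, match="population_size"):
        SynthConfig(population_size=0)
    with pytest.raises(ValueError, match="capture_prob"):
        SynthConfig(population_size=10,
                    capture_prob={"hospital": 1.0, "drug": 0.5,
                                  "outpatient": 0.5})


def test_case_count_near_binomial_expectation():
    cfg = SynthConfig(population_size=100_000, prevalence_per_100k=90, seed=1)
    persons = generate_population(cfg)
    n_cases = int(persons["is_case"].sum())
    # Binomial(1e5, 9e-4): mean 90, sd ~9.5; allow 4 sd
    assert abs(n_cases - 90) < 4 * np.sqrt(90)


def test_zero_prevalence_means_zero_cases():
    cfg = SynthConfig(population_size=20_000, prevalence_per_100k=0, seed=2)
    persons = generate_population(cfg)
    assert persons["is_case"].sum() == 0


def test_generator_is_deterministic(small_config):
    a = generate_study(small_config)
    b = generate_study(small_config)
    pd.testing.assert_frame_equal(a["persons"], b["persons"])
    pd.testing.assert_frame_equal(a["records"], b["records"])
    np.testing.assert_array_equal(a["registry_ids"], b["registry_ids"])


def test_symmetric_independent_capture_is_uniform():
    _, probs = capture_cell_probabilities(
        {s: 0.5 for s in SOURCES}, {}
    )
    np.testing.assert_allclose(probs, np.full(8, 1 / 8), atol=1e-12)


def test_near_degenerate_capture_concentrates_on_one_pattern():
    patterns, probs = capture_cell_probabilities(
        {"hospital": 0.9999, "drug": 0.0001, "outpatient": 0.0001}
    )
    assert probs[patterns.index((1, 0, 0))] > 0.999


def test_capture_marginal_matches_configured_probability():
    # Monte-Carlo vs Binomial-SE oracle: marginal of source A within 0.6+/-0.01
    n = 50_000
    cfg = SynthConfig(
        population_size=n, prevalence_per_100k=100_000 - 1, seed=7,
        capture_prob={"hospital": 0.6, "drug": 0.5, "outpatient": 0.4},
        nonresident_fraction=0.0,
    )
    persons = generate_population(cfg, np.random.default_rng(7))
    persons = assign_capture(persons, cfg, np.random.default_rng(8))
    cases = persons.loc[persons["is_case"]]
    assert abs(cases["cap_hospital"].mean() - 0.6) < 0.01


def test_independent_capture_table_matches_product_form():
    # chi-square GOF of the empirical 8-cell table vs product expectation:
    # at n=50k the fit should be comfortable in >=18 of 20 seeds
    probs_true = None
    n_pass = 0
    for seed in range(20):
        cfg = SynthConfig(
            population_size=50_000, prevalence_per_100k=99_000, seed=seed,
            nonresident_fraction=0.0,
        )
        persons = generate_population(cfg, np.random.default_rng(seed))
        persons = assign_capture(persons, cfg, np.random.default_rng(seed + 100))
        cases = persons.loc[persons["is_case"]]
        pats, probs_true = capture_cell_probabilities(cfg.capture_prob)
        key = (
            cases["cap_hospital"] * 4 + cases["cap_drug"] * 2
            + cases["cap_outpatient"]
        )
        observed = np.bincount(key, minlength=8)
        expected = len(cases) * np.array(
            [probs_true[pats.index((k // 4, (k // 2) % 2, k % 2))]
             for k in range(8)]
        )
        stat, p = chisquare(observed, expected)
        n_pass += p > 0.01
    assert n_pass >= 18


def test_emit_records_respects_patterns_and_counts(rng):
    cfg = SynthConfig(population_size=100, prevalence_per_100k=100_000 - 1,
                      extra_record_rate=0.0, seed=3,
                      nonresident_fraction=0.0)
    persons = generate_population(cfg, rng)
    persons["cap_hospital"] = 1
    persons["cap_drug"] = 0
    persons["cap_outpatient"] = 0
    records = emit_records(persons, cfg, np.random.default_rng(0))
    # extra rate 0: exactly one hospital row per person, nothing else
    assert (records["source"] == "hospital").all()
    assert len(records) == 100
    assert set(records["person_id"]) <= set(persons["person_id"])


def test_empty_pattern_emits_no_records(rng):
    cfg = SynthConfig(population_size=50, seed=4)
    persons = generate_population(cfg, rng)
    for s in SOURCES:
        persons[f"cap_{s}"] = 0
    assert emit_records(persons, cfg).empty


def test_mixed_pattern_routes_to_matching_sources(rng):
    cfg = SynthConfig(population_size=10, prevalence_per_100k=100_000 - 1,
                      seed=5, extra_record_rate=0.0)
    persons = generate_population(cfg, rng)
    persons["cap_hospital"] = 1
    persons["cap_drug"] = 1
    persons["cap_outpatient"] = 0
    records = emit_records(persons, cfg, np.random.default_rng(1))
    assert set(records["source"]) == {"hospital", "drug"}


@pytest.mark.parametrize("rate,expect_all", [(0.0, False), (1.0, True)])
def test_missingness_extremes(rng, rate, expect_all):
    cfg = SynthConfig(population_size=500, seed=6,
                      missing_birth_year_rate=rate, missing_area_rate=rate)
    persons = generate_population(cfg, rng)
    masked = inject_missingness(persons, cfg, np.random.default_rng(2))
    if expect_all:
        assert masked["birth_year"].isna().all()
        assert masked["area"].isna().all()
    else:
        pd.testing.assert_frame_equal(masked, persons)


def test_missingness_rate_matches_binomial_oracle():
    n = 10_000
    cfg = SynthConfig(population_size=n, seed=3,
                      missing_birth_year_rate=0.025)
    persons = generate_population(cfg, np.random.default_rng(3))
    masked = inject_missingness(persons, cfg, np.random.default_rng(3))
    n_masked = int(masked["birth_year"].isna().sum())
    tol = 3 * np.sqrt(n * 0.025 * 0.975)
    assert abs(n_masked - 250) <= tol
    # ground truth (the input frame) is untouched
    assert persons["birth_year"].notna().all()


@pytest.mark.parametrize("fraction,expected", [(1.0, "all"), (0.0, "none")])
def test_registry_fraction_extremes(small_study, small_config, fraction,
                                    expected):
    truth = small_study["persons_truth"]
    ids = sample_registry(truth, fraction, np.random.default_rng(9))
    resident_cases = truth.loc[truth["is_case"] & truth["resident"],
                               "person_id"]
    if expected == "all":
        assert set(ids) == set(resident_cases)
    else:
        assert len(ids) == 0


def test_registry_size_follows_rounding_rule(small_study):
    truth = small_study["persons_truth"]
    n_cases = int((truth["is_case"] & truth["resident"]).sum())
    ids = sample_registry(truth, 1460 / 5362, np.random.default_rng(10))
    assert len(ids) == round(1460 / 5362 * n_cases)


def test_registry_members_are_cases(small_study):
    truth = small_study["persons_truth"]
    reg = set(small_study["registry_ids"])
    case_ids = set(truth.loc[truth["is_case"], "person_id"])
    assert reg <= case_ids


def test_mar_mode_masks_females_more_often():
    cfg = SynthConfig(population_size=40_000, seed=8, mar_on_sex=True,
                      missing_birth_year_rate=0.2, missing_area_rate=0.2)
    persons = generate_population(cfg, np.random.default_rng(8))
    masked = inject_missingness(persons, cfg, np.random.default_rng(9))
    miss = masked["birth_year"].isna()
    rate_f = miss[persons["sex"] == "F"].mean()
    rate_m = miss[persons["sex"] == "M"].mean()
    assert rate_f > rate_m
    # marginal rate preserved
    assert abs(miss.mean() - 0.2) < 0.01


def test_false_positive_knob_captures_noncases():
    cfg = SynthConfig(population_size=20_000, prevalence_per_100k=90,
                      seed=12, false_positive_rate=0.01)
    persons = generate_population(cfg, np.random.default_rng(12))
    persons = assign_capture(persons, cfg, np.random.default_rng(13))
    noncases = persons.loc[~persons["is_case"]]
    captured = noncases[[f"cap_{s}" for s in SOURCES]].sum(axis=1)
    # ~1% of non-cases acquire exactly one source
    assert 0.005 < (captured > 0).mean() < 0.02
    assert captured.max() == 1


def test_every_record_id_exists_in_person_table(small_study):
    persons = small_study["persons"]
    records = small_study["records"]
    assert records["person_id"].isin(persons["person_id"]).all()
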