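"""Frequency tables, gamete-pool ML fitting (with grid-search oracle), arm test."""

import numpy as np
import pandas as pd
import pytest

from quadrivalent.inference import (
    GametePoolParams,
    InsufficientDataError,
    arm_conservation_test,
    fit_gamete_pool,
    frequency_table,
    zygote_probabilities,
)
from quadrivalent.segregation import ParameterError, ViabilityMap
from quadrivalent.synthetic_data import SimScenario, generate_counts


# --- frequency tables -----------------------------------------------------

class TestFrequencyTable:
    def test_pooled_survey_frequencies(self, survey_counts):
        ft = frequency_table(survey_counts)
        pooled = ft.loc["pooled"]
        assert pooled["I"] == 82.0 and pooled["IV"] == 16.1
        assert pooled["II"] == 0.6 and pooled["III"] == 0.4 and pooled["V"] == 0.8

    def test_population_rows_sum_to_100(self, survey_counts):
        ft = frequency_table(survey_counts)
        label_cols = [c for c in ft.columns if c not in ("total", "flagged")]
        sums = ft[label_cols].sum(axis=1)
        assert ((sums - 100.0).abs() <= 0.1 + 1e-9).all()

    def test_single_individual(self):
        df = pd.DataFrame(
            [{"population_id": "p", "sex": "female", "karyomorph": "I", "count": 1}]
        )
        ft = frequency_table(df)
        assert ft.loc["p", "I"] == 100.0

    def test_half_up_rounding(self):
        # 1/16 = 6.25% rounds up to 6.3, 15/16 = 93.75% to 93.8
        df = pd.DataFrame(
            [
                {"population_id": "p", "sex": "male", "karyomorph": "I", "count": 15},
                {"population_id": "p", "sex": "male", "karyomorph": "IV", "count": 1},
            ]
        )
        ft = frequency_table(df)
        assert ft.loc["p", "I"] == 93.8 and ft.loc["p", "IV"] == 6.3

    def test_zero_total_population_flagged(self):
        df = pd.DataFrame(
            [
                {"population_id": "a", "sex": "male", "karyomorph": "I", "count": 3},
                {"population_id": "b", "sex": "male", "karyomorph": "I", "count": 0},
            ]
        )
        ft = frequency_table(df)
        assert bool(ft.loc["b", "flagged"]) and not bool(ft.loc["a", "flagged"])

    def test_all_zero_counts_rejected(self):
        df = pd.DataFrame(
            [{"population_id": "p", "sex": "male", "karyomorph": "I", "count": 0}]
        )
        with pytest.raises(InsufficientDataError):
            frequency_table(df)


# --- gamete-pool ML -------------------------------------------------------

_VIABLE = ("I", "II", "III", "IV", "V")


def _grid_log_likelihood(counts_by_label, step=0.005):
    """Dense grid search over the 3-simplex (independent oracle)."""
    counts = np.array([counts_by_label.get(lab, 0) for lab in _VIABLE], dtype=float)
    n_steps = int(round(1.0 / step))
    grid = np.arange(n_steps + 1) * step
    best_ll, best_f = -np.inf, None
    f2g, f3g = np.meshgrid(grid, grid, indexing="ij")
    for f1 in grid:
        f4 = 1.0 - f1 - f2g - f3g
        ok = f4 >= -1e-12
        if not ok.any():
            continue
        f2, f3, f4v = f2g[ok], f3g[ok], np.clip(f4[ok], 0.0, 1.0)
        p = np.stack(
            [
                f1 * f1 * np.ones_like(f2),
                2 * f1 * f3,
                2 * f1 * f4v,
                2 * f1 * f2 + 2 * f3 * f4v,
                2 * f2 * f3,
            ],
            axis=1,
        )
        mass = p.sum(axis=1)
        valid = mass > 0
        if not valid.any():
            continue
        p = p[valid] / mass[valid, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(
                (p > 0) | (counts == 0), counts * np.log(np.clip(p, 1e-300, None)), -np.inf
            ).sum(axis=1)
        i = int(np.argmax(ll))
        if ll[i] > best_ll:
            f2b, f3b, f4b = f2[valid][i], f3[valid][i], f4v[valid][i]
            best_ll, best_f = float(ll[i]), (f1, f2b, f3b, f4b)
    return best_ll, best_f


def test_zygote_probabilities_sum_to_one_and_match_the_nine_type_grid():
    f = (0.6, 0.2, 0.15, 0.05)
    p = zygote_probabilities(f)
    assert sum(p.values()) == pytest.approx(1.0)
    assert p["I"] == pytest.approx(0.36)
    assert p["IV"] == pytest.approx(2 * 0.6 * 0.2 + 2 * 0.15 * 0.05)
    assert p["IX"] == pytest.approx(0.04)


def test_zygote_model_agrees_with_gamete_union_machinery():
    # dual route: closed-form probabilities vs explicit gamete convolution
    from quadrivalent.synthetic_data import zygote_distribution_from_pool

    pool = GametePoolParams(0.6, 0.2, 0.15, 0.05)
    dist = zygote_distribution_from_pool(pool, ViabilityMap.all_viable())
    closed = zygote_probabilities(pool.as_tuple())
    for k, p in dist.items():
        assert p == pytest.approx(closed[k.label], abs=1e-12)


def test_fit_all_type_I_gives_pure_normal_gametes():
    res = fit_gamete_pool({"I": 500})
    assert res.estimates.f1 == pytest.approx(1.0, abs=1e-6)
    assert res.boundary


def test_fit_beats_dense_grid_oracle():
    datasets = [
        {"I": 386, "II": 3, "III": 2, "IV": 76, "V": 4},
        {"I": 50, "II": 10, "III": 10, "IV": 25, "V": 5},
        {"I": 10, "IV": 90},
    ]
    for obs in datasets:
        res = fit_gamete_pool(obs)
        grid_ll, _ = _grid_log_likelihood(obs)
        assert res.log_likelihood >= grid_ll - 1e-3


def test_parameter_recovery_from_synthetic_counts():
    truth = (0.8, 0.15, 0.03, 0.02)
    scenario = SimScenario(GametePoolParams(*truth), (5000,), seed=7)
    pooled = generate_counts(scenario).groupby("karyomorph")["count"].sum()
    res = fit_gamete_pool(pooled)
    for est, tru in zip(res.estimates.as_tuple(), truth):
        assert abs(est - tru) <= 0.02


def test_estimator_consistency_with_sample_size():
    truth = GametePoolParams(0.8, 0.15, 0.03, 0.02)
    errs = {}
    for n in (200, 2000, 20000):
        errors = []
        for seed in (11, 12, 13, 14, 15):
            pooled = generate_counts(
                SimScenario(truth, (n,), seed=seed)
            ).groupby("karyomorph")["count"].sum()
            res = fit_gamete_pool(pooled)
            errors.append(abs(res.estimates.f1 - truth.f1))
        errs[n] = float(np.mean(errors))
    assert errs[20000] < errs[200]
    assert errs[20000] < 0.01


def test_expected_counts_sum_to_observed_total():
    obs = {"I": 386, "II": 3, "III": 2, "IV": 76, "V": 4}
    res = fit_gamete_pool(obs)
    assert sum(res.expected_counts.values()) == pytest.approx(sum(obs.values()))
    assert res.log_likelihood <= 0.0
    # the expected ordering reproduces the observed one: I > IV > the rest
    exp = res.expected_counts
    assert exp["I"] > exp["IV"] > max(exp["II"], exp["III"], exp["V"])


def test_fit_rejects_counts_for_lethal_types():
    with pytest.raises(ParameterError):
        fit_gamete_pool({"I": 10, "IX": 1})


def test_gamete_pool_params_validation():
    with pytest.raises(ParameterError):
        GametePoolParams(0.5, 0.5, 0.5, 0.5)
    with pytest.raises(ParameterError):
        GametePoolParams(-0.1, 0.6, 0.3, 0.2)


# --- arm-length conservation ----------------------------------------------

class TestArmConservation:
    def test_measured_cells_support_length_conservation(self, length_table):
        res = arm_conservation_test(length_table)
        assert round(res.mean_het_sum, 2) == 17.72
        assert round(res.mean_norm_sum, 2) == 18.07
        assert res.p_value > 0.05 and res.conserved

    def test_identical_sums_give_t_zero(self):
        df = pd.DataFrame(
            {"1-1": [5.0, 6.0], "1-2": [3.0, 4.0], "6-1": [2.0, 2.5], "6-2": [4.0, 4.5]}
        )
        # built so 1-2 + 6-2 == 1-1 + 6-1 in every cell
        res = arm_conservation_test(df)
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_fewer_than_two_cells_rejected(self):
        df = pd.DataFrame({"1-1": [5.0], "1-2": [3.0], "6-1": [2.0], "6-2": [4.0]})
        with pytest.raises(InsufficientDataError):
            arm_conservation_test(df)

    def test_missing_column_rejected(self):
        df = pd.DataFrame({"1-1": [5.0, 5.0], "1-2": [3.0, 3.0], "6-1": [2.0, 2.0]})
        with pytest.raises(ParameterError):
            arm_conservation_test(df)
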