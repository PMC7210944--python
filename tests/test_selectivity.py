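"""Multinomial vs Dirichlet-multinomial posterior-odds machinery."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import dirichlet_multinomial

from lissoir.selectivity import (
    FaunalAssemblage,
    ObservationCounts,
    RibFrequencyProfile,
    SelectivityModel,
    dirichlet_multinomial_likelihood,
    multinomial_likelihood,
    posterior_odds,
    rib_profile,
    run_selection_test,
    summarize,
)

import pandas as pd


def _assemblage(categories, ribs, grouping=None, layer="test"):
    return FaunalAssemblage(
        layer=layer,
        records=pd.DataFrame(
            {"category": categories, "nisp": [r + 1 for r in ribs], "ribs": ribs}
        ),
        grouping=grouping or {},
    )


def _model(alphas: dict[str, float], c: float = 1.0) -> SelectivityModel:
    # masses exp(alpha) give selectivities ln(mass) = alpha exactly
    return SelectivityModel(masses_kg={k: math.exp(a) for k, a in alphas.items()}, c=c)


# --- rib profiles -----------------------------------------------------------


def test_layer_l3a_large_bovid_frequency(fx):
    profile = rib_profile(fx["assemblages"]["L-3A"])
    assert profile["large bovid"] == pytest.approx(0.6)
    assert profile["medium ungulate"] == pytest.approx(0.4)


def test_single_category_profile_is_one():
    profile = rib_profile(_assemblage(["a"], [4]))
    assert profile["a"] == 1.0


def test_identity_grouping_profile():
    profile = rib_profile(_assemblage(["a", "b", "c"], [1, 1, 2]))
    assert [profile["a"], profile["b"], profile["c"]] == [0.25, 0.25, 0.5]


def test_zero_ribs_rejected():
    with pytest.raises(ValueError, match="no ribs"):
        rib_profile(_assemblage(["a"], [0]))


def test_rib_count_cannot_exceed_nisp():
    with pytest.raises(ValueError):
        FaunalAssemblage(
            layer="x",
            records=pd.DataFrame({"category": ["a"], "nisp": [1], "ribs": [2]}),
        )


# --- likelihoods ------------------------------------------------------------


def test_single_observation_multinomial(fx):
    profile = rib_profile(fx["assemblages"]["L-3A"])
    obs = ObservationCounts({"large bovid": 1})
    assert multinomial_likelihood(obs, profile) == pytest.approx(0.6)


def test_empty_observation_has_likelihood_one():
    profile = RibFrequencyProfile({"a": 0.3, "b": 0.7})
    assert multinomial_likelihood(ObservationCounts({}), profile) == 1.0
    assert dirichlet_multinomial_likelihood(ObservationCounts({}), _model({"a": 1, "b": 2})) == 1.0


def test_multinomial_brute_force_example():
    profile = RibFrequencyProfile({"a": 0.25, "b": 0.75})
    obs = ObservationCounts({"a": 1, "b": 2})
    # brute force: enumerate the 2^3 ordered outcomes with one a, two b
    assert multinomial_likelihood(obs, profile) == pytest.approx(3 * 0.25 * 0.75**2)


def test_multinomial_zero_frequency_category():
    profile = RibFrequencyProfile({"a": 1.0, "b": 0.0})
    assert multinomial_likelihood(ObservationCounts({"b": 1}), profile) == 0.0


def test_dm_single_observation_is_alpha_ratio():
    model = _model({"a": 2.0, "b": 3.0, "c": 5.0})
    lik = dirichlet_multinomial_likelihood(ObservationCounts({"a": 1}), model)
    assert lik == pytest.approx(0.2)


def test_dm_symmetric_alphas_give_uniform_single_draw():
    model = _model({k: 1.7 for k in "abcd"})
    for k in "abcd":
        assert dirichlet_multinomial_likelihood(
            ObservationCounts({k: 1}), model
        ) == pytest.approx(0.25)


def test_dm_closed_form_example():
    model = _model({"a": 2.0, "b": 3.0})
    lik = dirichlet_multinomial_likelihood(ObservationCounts({"a": 1, "b": 2}), model)
    assert lik == pytest.approx(12 / 35, abs=1e-12)  # 0.342857...


def test_dm_agrees_with_scipy():
    model = _model({"a": 2.0, "b": 3.0, "c": 1.5})
    for counts in [(1, 2, 0), (0, 0, 4), (2, 2, 2)]:
        obs = ObservationCounts(dict(zip("abc", counts)))
        ours = dirichlet_multinomial_likelihood(obs, model)
        ref = dirichlet_multinomial.pmf(list(counts), [2.0, 3.0, 1.5], sum(counts))
        assert ours == pytest.approx(float(ref), rel=1e-10)


def test_dm_matches_monte_carlo_dirichlet_oracle():
    """DM pmf equals the Dirichlet-integrated multinomial, by simulation."""
    rng = np.random.default_rng(2024)
    draws = rng.dirichlet([2.0, 3.0], size=1_000_000)
    vals = 3.0 * draws[:, 0] * draws[:, 1] ** 2  # multinomial pmf of (1,2) given p
    mc, se = vals.mean(), vals.std(ddof=1) / math.sqrt(len(vals))
    exact = dirichlet_multinomial_likelihood(
        ObservationCounts({"a": 1, "b": 2}), _model({"a": 2.0, "b": 3.0})
    )
    assert abs(mc - exact) < 3 * se


@pytest.mark.parametrize("k, n", [(2, 5), (3, 4), (4, 3)])
def test_likelihoods_normalise_over_outcomes(k, n):
    cats = [f"c{i}" for i in range(k)]
    raw = np.linspace(1.0, 2.0, k)
    profile = RibFrequencyProfile(dict(zip(cats, raw / raw.sum())))
    model = _model(dict(zip(cats, raw)))
    total_mn = total_dm = 0.0
    for counts in itertools.product(range(n + 1), repeat=k):
        if sum(counts) != n:
            continue
        obs = ObservationCounts(dict(zip(cats, counts)))
        total_mn += multinomial_likelihood(obs, profile)
        total_dm += dirichlet_multinomial_likelihood(obs, model)
    assert total_mn == pytest.approx(1.0, abs=1e-10)
    assert total_dm == pytest.approx(1.0, abs=1e-10)


def test_dm_single_observation_invariant_to_concentration_scaling():
    alphas = {"a": 1.3, "b": 2.6, "c": 0.4}
    obs = ObservationCounts({"b": 1})
    ref = dirichlet_multinomial_likelihood(obs, _model(alphas, c=1.0))
    for c in (1e-3, 0.5, 7.0, 1e4):
        lik = dirichlet_multinomial_likelihood(obs, _model(alphas, c=c))
        assert lik == pytest.approx(ref, rel=1e-8)


def test_dm_converges_to_multinomial_at_large_concentration():
    cats = ["a", "b", "c"]
    p = np.array([0.2, 0.3, 0.5])
    profile = RibFrequencyProfile(dict(zip(cats, p)))
    model = _model(dict(zip(cats, p)), c=1e6)
    for counts in itertools.product(range(4), repeat=3):
        if sum(counts) == 0:
            continue
        obs = ObservationCounts(dict(zip(cats, counts)))
        mn = multinomial_likelihood(obs, profile)
        dm = dirichlet_multinomial_likelihood(obs, model)
        assert abs(dm - mn) / mn < 1e-3


def test_concentration_recovered_from_simulated_draws():
    """MLE over c on 500 Dirichlet-multinomial samples finds the truth
    within a factor of two."""
    rng = np.random.default_rng(7)
    alphas = {"a": 1.6, "b": 4.9, "c": 6.5}
    c_true, n = 5.0, 10
    base = np.array(list(alphas.values()))
    samples = []
    for _ in range(500):
        theta = rng.dirichlet(c_true * base)
        samples.append(rng.multinomial(n, theta))

    def neg_log_lik(log_c):
        model = _model(alphas, c=math.exp(log_c))
        total = 0.0
        for counts in samples:
            obs = ObservationCounts(dict(zip(alphas, (int(x) for x in counts))))
            total += math.log(dirichlet_multinomial_likelihood(obs, model))
        return -total

    res = minimize_scalar(neg_log_lik, bounds=(-4, 8), method="bounded")
    c_hat = math.exp(res.x)
    assert c_true / 2 <= c_hat <= c_true * 2


# --- odds -------------------------------------------------------------------


def test_posterior_odds_reported_value():
    odds = posterior_odds(0.6, 0.125, 1.0)
    assert odds == pytest.approx(0.125 / 0.6)
    assert round(odds, 1) == 0.2


def test_equal_likelihoods_give_unit_odds():
    assert posterior_odds(0.3, 0.3, 1.0) == 1.0


def test_odds_on_rounded_inputs():
    assert posterior_odds(0.0009, 0.0037, 1.0) == pytest.approx(4.11, abs=0.005)


def test_odds_reciprocal_property():
    for a, b in [(0.6, 0.125), (0.0009, 0.0037), (0.5, 0.5)]:
        assert posterior_odds(a, b) * posterior_odds(b, a) == pytest.approx(1.0)


def test_zero_null_likelihood_warns_and_returns_inf():
    with pytest.warns(UserWarning):
        assert posterior_odds(0.0, 0.5) == math.inf


# --- full test --------------------------------------------------------------


def test_l3a_single_tool_favours_null(fx):
    result = run_selection_test(
        fx["assemblages"]["L-3A"],
        ObservationCounts({"large bovid": 1}),
        fx["masses"],
        c_strong=10.0,
        c_weak=1.0,
    )
    assert result.likelihood_h0 == pytest.approx(0.6)
    for variant in ("strong", "weak"):
        assert result.posterior_odds[variant] < 1
        assert result.better_supported(variant) == "H0"
    # single observation: strong and weak variants coincide
    assert result.likelihood_ha["strong"] == pytest.approx(result.likelihood_ha["weak"])


def test_l3b_three_tools_favour_alternative(fx):
    result = run_selection_test(
        fx["assemblages"]["L-3B"],
        ObservationCounts({"large bovid": 3}),
        fx["masses"],
        c_strong=10.0,
        c_weak=1.0,
    )
    assert round(result.likelihood_h0, 4) == 0.0009
    for variant in ("strong", "weak"):
        assert result.posterior_odds[variant] > 1
    assert "alternative" in summarize(result)


def test_no_observations_give_prior_odds(fx):
    result = run_selection_test(
        fx["assemblages"]["L-3A"],
        ObservationCounts({}),
        fx["masses"],
        c_strong=10.0,
        c_weak=1.0,
        prior_odds_value=2.5,
    )
    assert result.likelihood_h0 == 1.0
    assert all(v == 1.0 for v in result.likelihood_ha.values())
    assert all(v == 2.5 for v in result.posterior_odds.values())


def test_missing_mass_rejected(fx):
    with pytest.raises(ValueError, match="no body mass"):
        run_selection_test(
            fx["assemblages"]["L-3A"],
            ObservationCounts({"large bovid": 1}),
            {"large bovid": 700.0},  # medium ungulate missing
            c_strong=10.0,
            c_weak=1.0,
        )


def test_selectivity_requires_masses_above_one_kg():
    with pytest.raises(ValueError, match="1 kg"):
        SelectivityModel(masses_kg={"a": 0.5}, c=1.0)
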