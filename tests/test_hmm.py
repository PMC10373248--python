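"""Two-state HMM: densities, likelihood, decoding, fitting, diagnostics.

Exhaustive path enumeration over all 2^T state sequences serves as the
independent oracle for the forward likelihood, the Viterbi path, and the
forward-backward marginals on short series.
"""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

from carpmove.errors import ValidationError
from carpmove.hmm import (
    AngleParams,
    FitOptions,
    HmmDesign,
    LinearCoefficients,
    TransitionCoefficients,
    angle_density,
    decode,
    fit_hmm,
    loglik_forward,
    pseudo_residuals,
    state_probabilities,
    state_time_budget,
    step_density,
    transition_matrix,
    viterbi,
)
from carpmove.regularize import StepAngleSeries
from carpmove.simulate import make_treatment_profile, simulate_step_series
from conftest import intercept_only_params


def make_series(steps, angles=None, co2=None, fish_id="f1"):
    steps = np.asarray(steps, dtype=float)
    T = len(steps)
    if angles is None:
        angles = np.full(T, np.nan)
        if T > 1:
            angles[1:] = 0.3
    co2 = np.zeros(T) if co2 is None else np.asarray(co2, dtype=float)
    return StepAngleSeries(
        fish_id=fish_id,
        trial_id=1,
        t_s=6.0 * np.arange(T),
        step_m=steps,
        angle_rad=np.asarray(angles, dtype=float),
        pump_on=np.ones(T, dtype=int),
        co2_mgL=co2,
        temp_C=np.full(T, 0.0),
    )


def enumerate_paths(params, series):
    """Brute-force likelihood, posterior marginals, and best path."""
    T = len(series)
    covs = [
        {
            "trial_id": series.trial_id,
            "pump_on": series.pump_on[t],
            "co2_mgL": series.co2_mgL[t],
            "temp_C": series.temp_C[t],
        }
        for t in range(T)
    ]
    b = np.array(
        [
            [
                step_density(series.step_m[t], k, params.step, covs[t])
                * angle_density(series.angle_rad[t], k, params.angle)
                for k in (1, 2)
            ]
            for t in range(T)
        ]
    )
    G = [transition_matrix(params.transition, covs[t]) for t in range(T)]
    delta = params.delta
    total = 0.0
    marg = np.zeros((T, 2))
    best_p, best_path = -1.0, None
    for path in itertools.product((0, 1), repeat=T):
        p = delta[path[0]] * b[0, path[0]]
        for t in range(1, T):
            p *= G[t - 1][path[t - 1], path[t]] * b[t, path[t]]
        total += p
        for t in range(T):
            marg[t, path[t]] += p
        if p > best_p:
            best_p, best_path = p, path
    return np.log(total), marg / total, np.asarray(best_path) + 1


# ---------------------------------------------------------------------------
# transition matrix
# ---------------------------------------------------------------------------

def test_zero_coefficients_give_half(reference_covariates):
    coef = TransitionCoefficients(LinearCoefficients(), LinearCoefficients())
    m = transition_matrix(coef, reference_covariates)
    assert np.allclose(m, 0.5)


def test_intercept_logistic_value(reference_covariates, baseline_params):
    m = transition_matrix(baseline_params.transition, reference_covariates)
    # logistic(logit(0.0989)) round-trips the baseline switching probability
    assert m[0, 1] == pytest.approx(0.0989, abs=1e-4)
    assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
    assert np.all((m >= 0) & (m <= 1))


def test_unknown_trial_level_rejected():
    lc = LinearCoefficients(intercept=0.0, trial={2: 0.5})
    lc.reference_trial = 1
    coef = TransitionCoefficients(lc, LinearCoefficients())
    with pytest.raises(ValidationError):
        transition_matrix(
            coef, {"trial_id": 99, "pump_on": 1, "co2_mgL": 0, "temp_C": 0}
        )


# ---------------------------------------------------------------------------
# emission densities
# ---------------------------------------------------------------------------

def test_step_density_zero_returns_point_mass(baseline_params, reference_covariates):
    p0 = baseline_params.step.zero_mass(1)
    assert step_density(0.0, 1, baseline_params.step, reference_covariates) == p0


def test_step_density_moment_matched_gamma(baseline_params, reference_covariates):
    # mean 0.988 m, SD 0.928 m -> shape 1.1335, scale 0.8716
    x = 0.7
    d = step_density(x, 1, baseline_params.step, reference_covariates)
    p0 = baseline_params.step.zero_mass(1)
    expected = (1 - p0) * gamma_dist.pdf(x, a=1.1335, scale=0.8716)
    assert d == pytest.approx(expected, rel=1e-3)


def test_log_sd_link_consistency(baseline_params):
    # working value -0.0745... exponentiates to the reported 0.928 m SD
    assert baseline_params.step.sd(1) == pytest.approx(0.928, abs=5e-4)


def test_negative_step_rejected(baseline_params, reference_covariates):
    with pytest.raises(ValidationError):
        step_density(-0.1, 1, baseline_params.step, reference_covariates)


def test_angle_density_uniform_limit():
    ap = AngleParams(mu=[0.0, 0.0], kappa=[0.0, 0.0])
    for phi in (-3.0, 0.0, 2.5):
        assert angle_density(phi, 1, ap) == pytest.approx(1 / (2 * np.pi))


def test_angle_density_bessel_value():
    ap = AngleParams(mu=[0.0, 0.0], kappa=[1.0, 0.0])
    assert angle_density(0.0, 1, ap) == pytest.approx(0.3417, abs=1e-4)


def test_angle_density_symmetry_and_missing():
    ap = AngleParams(mu=[0.7, 0.0], kappa=[2.3, 0.0])
    for x in (0.1, 1.0, 2.9):
        assert angle_density(0.7 + x, 1, ap) == pytest.approx(
            angle_density(0.7 - x, 1, ap)
        )
    assert angle_density(float("nan"), 1, ap) == 1.0


@pytest.mark.parametrize("kappa", [0.0, 0.001, 1.0, 10.0])
def test_angle_density_integrates_to_one(kappa):
    ap = AngleParams(mu=[0.4, 0.0], kappa=[kappa, 0.0])
    val, err = quad(lambda x: angle_density(x, 1, ap), -np.pi, np.pi,
                    limit=200)
    assert abs(val - 1.0) < 1e-8


def test_negative_kappa_rejected():
    with pytest.raises(ValidationError):
        AngleParams(mu=[0.0, 0.0], kappa=[-1.0, 0.0])


# ---------------------------------------------------------------------------
# forward likelihood vs enumeration
# ---------------------------------------------------------------------------

def test_single_step_closed_form(reference_covariates):
    params = intercept_only_params(delta=[0.3, 0.7])
    s = make_series([0.5])
    b = [
        step_density(0.5, k, params.step, reference_covariates)
        for k in (1, 2)
    ]
    expected = np.log(0.3 * b[0] + 0.7 * b[1])
    assert loglik_forward(params, [s]) == pytest.approx(expected, rel=1e-12)


def test_forward_matches_enumeration_t8():
    params = intercept_only_params(delta=[0.4, 0.6])
    rng = np.random.default_rng(2)
    s = make_series(
        rng.gamma(1.1, 0.8, 8),
        angles=np.concatenate([[np.nan], rng.uniform(-np.pi, np.pi, 7)]),
        co2=np.linspace(0, 120, 8),  # time-varying transition matrices
    )
    # make CO2 matter for the transitions
    params.transition.to_encamped.co2 = 0.0096
    ll_enum, _, _ = enumerate_paths(params, s)
    assert loglik_forward(params, [s]) == pytest.approx(ll_enum, rel=1e-10)


def test_label_swap_symmetry():
    params = intercept_only_params(delta=[0.4, 0.6])
    swapped = intercept_only_params(
        mean1=0.026, mean2=0.988, sd1=0.019, sd2=0.928,
        psi12=0.1824, psi21=0.0989, zm=(-15.27, -8.45),
        kappa=(0.0009, 0.00002), mu=(-0.00008, -3.1414), delta=[0.6, 0.4],
    )
    rng = np.random.default_rng(4)
    s = make_series(rng.gamma(1.1, 0.8, 30))
    assert loglik_forward(params, [s]) == pytest.approx(
        loglik_forward(swapped, [s]), rel=1e-12
    )


def test_nan_covariate_identified():
    params = intercept_only_params(delta=[0.5, 0.5])
    s = make_series([0.5, 0.7, 0.2])
    s.co2_mgL[1] = np.nan
    with pytest.raises(ValidationError, match="step 1"):
        loglik_forward(params, [s])


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def test_viterbi_matches_enumeration_t10():
    params = intercept_only_params(delta=[0.4, 0.6])
    rng = np.random.default_rng(6)
    s = make_series(rng.gamma(0.8, 0.5, 10))
    _, _, best = enumerate_paths(params, s)
    assert np.array_equal(viterbi(params, [s])[0], best)


def test_identical_emissions_follow_transition_prior():
    # both states emit identically; chain started encamped and absorbed there
    params = intercept_only_params(
        mean1=0.5, mean2=0.5, sd1=0.4, sd2=0.4, zm=(-8.0, -8.0),
        kappa=(0.0, 0.0), mu=(0.0, 0.0), psi12=0.9, psi21=1e-9,
        delta=[0.0, 1.0],
    )
    s = make_series(np.full(12, 0.4))
    assert np.all(viterbi(params, [s])[0] == 2)


def test_viterbi_recovers_well_separated_states(sticky_params):
    profile = make_treatment_profile("null", horizon_s=12600.0)
    series, states = simulate_step_series(
        sticky_params, profile, n_steps=2000, n_tracks=1, seed=9
    )
    acc = np.mean(viterbi(sticky_params, series)[0] == states[0])
    assert acc >= 0.99


def test_posterior_single_step_closed_form(reference_covariates):
    params = intercept_only_params(delta=[0.3, 0.7])
    s = make_series([0.5])
    b = np.array(
        [step_density(0.5, k, params.step, reference_covariates) for k in (1, 2)]
    )
    expected = np.array([0.3, 0.7]) * b
    expected /= expected.sum()
    post = state_probabilities(params, [s])[0]
    assert np.allclose(post[0], expected, atol=1e-12)


def test_posteriors_normalized_and_match_enumeration_t6():
    params = intercept_only_params(delta=[0.45, 0.55])
    rng = np.random.default_rng(8)
    s = make_series(rng.gamma(1.0, 0.6, 6))
    _, marg, _ = enumerate_paths(params, s)
    post = state_probabilities(params, [s])[0]
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)
    assert np.allclose(post, marg, atol=1e-10)


def test_empty_series_rejected(baseline_params):
    s = make_series([])
    with pytest.raises(ValidationError):
        viterbi(baseline_params, [s])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_opts(**kw):
    kw.setdefault("n_restarts", 2)
    kw.setdefault("seed", 0)
    kw.setdefault("compute_se", False)
    return FitOptions(**kw)


def test_fit_recovers_intercepts_small(sticky_params):
    profile = make_treatment_profile("null", horizon_s=2400.0)
    series, _ = simulate_step_series(
        sticky_params, profile, n_steps=400, n_tracks=10, seed=12
    )
    fit = fit_hmm(series, HmmDesign(), _fit_opts())
    m1 = np.exp(fit.params_hat.step.mean[0].intercept)
    m2 = np.exp(fit.params_hat.step.mean[1].intercept)
    assert m1 == pytest.approx(0.988, rel=0.10)
    assert m2 == pytest.approx(0.026, rel=0.10)
    assert fit.convergence


def test_fit_is_deterministic(sticky_params):
    profile = make_treatment_profile("null", horizon_s=1500.0)
    series, _ = simulate_step_series(
        sticky_params, profile, n_steps=250, n_tracks=4, seed=13
    )
    f1 = fit_hmm(series, HmmDesign(), _fit_opts())
    f2 = fit_hmm(series, HmmDesign(), _fit_opts())
    assert f1.loglik == f2.loglik
    assert f1.params_hat.step.mean[0].intercept == f2.params_hat.step.mean[0].intercept


def test_fit_orders_states_by_mean_step(sticky_params):
    profile = make_treatment_profile("null", horizon_s=1500.0)
    series, _ = simulate_step_series(
        sticky_params, profile, n_steps=250, n_tracks=4, seed=14
    )
    fit = fit_hmm(series, HmmDesign(), _fit_opts())
    assert (
        fit.params_hat.step.mean[0].intercept
        > fit.params_hat.step.mean[1].intercept
    )


def test_wald_intervals_cover_truth():
    """95% CIs from the observed information cover the generating values
    for >= 85% of reported coefficients (transition + step-mean + log-SD),
    aggregated over seeded replicates."""
    from scipy.special import logit

    truth = intercept_only_params(psi12=0.08, psi21=0.10)
    truth.transition.to_encamped.co2 = 0.0096
    profile = make_treatment_profile("pump_co2", horizon_s=2400.0)
    truth_by_name = {
        "psi[1->2].intercept": float(logit(0.08)),
        "psi[1->2].co2": 0.0096,
        "psi[2->1].intercept": float(logit(0.10)),
        "psi[2->1].co2": 0.0,
        "step_mean[exploratory].intercept": np.log(0.988),
        "step_mean[encamped].intercept": np.log(0.026),
        "log_sd[exploratory]": np.log(0.928),
        "log_sd[encamped]": np.log(0.019),
    }
    covered = []
    for rep in range(5):
        series, _ = simulate_step_series(truth, profile, 400, 10, seed=rep)
        fit = fit_hmm(
            series,
            HmmDesign(transition_terms=("co2",), step_terms=()),
            _fit_opts(compute_se=True),
        )
        ci = fit.wald_ci(0.95).set_index("name")
        covered += [
            bool(ci.loc[n, "lo"] <= v <= ci.loc[n, "hi"])
            for n, v in truth_by_name.items()
        ]
    assert np.mean(covered) >= 0.85


# ---------------------------------------------------------------------------
# budgets and residuals
# ---------------------------------------------------------------------------

class _FakeDecoding:
    def __init__(self, states):
        self.viterbi_states = np.asarray(states)
        self.budget = float(np.mean(self.viterbi_states == 1))


def test_pooled_budget_fraction():
    # 4,508 exploratory of 10,125 pooled steps -> 44.5%
    decs = {
        "a": _FakeDecoding([1] * 4508 + [2] * 5000),
        "b": _FakeDecoding([2] * 617),
    }
    exits = {"a": (12.0, 1), "b": (90.0, 0)}
    df, overall = state_time_budget(decs, exits)
    assert 100 * overall == pytest.approx(44.5, abs=0.05)
    assert df.set_index("fish_id").loc["b", "exit_time_min"] == 90.0


def test_budget_all_exploratory():
    decs = {"a": _FakeDecoding([1, 1, 1])}
    df, overall = state_time_budget(decs, {"a": (5.0, 1)})
    assert overall == 1.0
    assert df["fraction_exploratory"].iloc[0] == 1.0


def test_budget_missing_exit_or_empty_decoding():
    with pytest.raises(ValidationError):
        state_time_budget({"a": _FakeDecoding([1])}, {})
    with pytest.raises(ValidationError):
        state_time_budget({"a": _FakeDecoding([])}, {"a": (5.0, 1)})


def test_residual_zero_at_mixture_median(reference_covariates):
    params = intercept_only_params(delta=[0.5, 0.5])

    def mix_cdf(x):
        tot = 0.0
        for w, k in zip(params.delta, (1, 2)):
            m = np.exp(params.step.mean[k - 1].intercept)
            sd = params.step.sd(k)
            p0 = params.step.zero_mass(k)
            tot += w * (
                p0 + (1 - p0) * gamma_dist.cdf(x, a=m * m / sd**2, scale=sd**2 / m)
            )
        return tot

    med = brentq(lambda x: mix_cdf(x) - 0.5, 1e-9, 10.0)
    s = make_series([med])
    res = pseudo_residuals(params, [s])
    assert res["step_resid"].iloc[0] == pytest.approx(0.0, abs=1e-7)


def test_residuals_deterministic(baseline_params):
    profile = make_treatment_profile("null", horizon_s=1200.0)
    series, _ = simulate_step_series(baseline_params, profile, 150, 1, seed=21)
    r1 = pseudo_residuals(baseline_params, series)
    r2 = pseudo_residuals(baseline_params, series)
    assert r1.equals(r2)


def test_residuals_calibrated_under_true_model(baseline_params):
    profile = make_treatment_profile("null", horizon_s=36000.0)
    series, _ = simulate_step_series(baseline_params, profile, 2500, 2, seed=22)
    res = pseudo_residuals(baseline_params, series)
    z = res["step_resid"].to_numpy()
    assert abs(z.mean()) < 0.05
    assert abs(z.std() - 1.0) < 0.05
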