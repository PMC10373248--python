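"""Synthetic-trial generator: treatment profiles, movement mechanics, I/O."""

import numpy as np
import pytest
from scipy.stats import kstest

from carpmove.errors import ValidationError
from carpmove.simulate import (
    LockArena,
    SimulatedTrial,
    make_treatment_profile,
    read_covariate_table,
    read_fix_table,
    simulate_step_series,
    simulate_trial,
    study_default_params,
    study_roster,
    write_fixtures,
)
from conftest import intercept_only_params


# ---------------------------------------------------------------------------
# treatment profiles
# ---------------------------------------------------------------------------

def test_null_profile_is_all_zero():
    p = make_treatment_profile("null")
    t = np.linspace(0, p.horizon_s, 50)
    assert np.all(p.co2_mgL(t) == 0)
    assert np.all(p.pump_on(t) == 0)


def test_pump_only_profile_zero_co2_pump_on():
    p = make_treatment_profile("pump_only")
    t = np.linspace(0, p.horizon_s, 50)
    assert np.all(p.co2_mgL(t) == 0)
    assert np.all(p.pump_on(t) == 1)


def test_co2_ramp_reaches_target():
    p = make_treatment_profile("pump_co2", target_co2=150.0, ramp_minutes=10.0)
    assert p.co2_mgL(600.0) == pytest.approx(150.0)
    assert p.co2_mgL(5000.0) == pytest.approx(150.0)  # held after ramp


def test_co2_ramp_linear_interpolation():
    p = make_treatment_profile("pump_co2", target_co2=100.0, ramp_minutes=5.0)
    assert p.co2_mgL(150.0) == pytest.approx(50.0)


def test_co2_ramp_nondecreasing():
    p = make_treatment_profile("pump_co2")
    t = np.linspace(0, p.horizon_s, 500)
    assert np.all(np.diff(p.co2_mgL(t)) >= 0)


def test_unknown_label_rejected():
    with pytest.raises(ValidationError):
        make_treatment_profile("co2_only")


def test_arena_invariants():
    with pytest.raises(ValidationError):
        LockArena(length=-1.0)
    with pytest.raises(ValidationError):
        LockArena(gate_x=100.0)


# ---------------------------------------------------------------------------
# emission-level distributional checks (no walls)
# ---------------------------------------------------------------------------

def _single_state_params(**kw):
    # absorbing exploratory state: zero mass off, uniform angles by default
    kw.setdefault("psi12", 1e-12)
    kw.setdefault("psi21", 1.0 - 1e-12)
    kw.setdefault("zm", (-30.0, -30.0))
    kw.setdefault("kappa", (0.0, 0.0))
    return intercept_only_params(**kw)


def test_simulated_angles_uniform_when_kappa_zero():
    params = _single_state_params()
    profile = make_treatment_profile("null", horizon_s=61000.0)
    series, _ = simulate_step_series(params, profile, 10001, 1, seed=31)
    ang = series[0].angle_rad
    ang = ang[np.isfinite(ang)]
    assert len(ang) >= 9900
    stat, pval = kstest(ang, "uniform", args=(-np.pi, 2 * np.pi))
    assert pval > 0.01


def test_simulated_step_moments_match_emission():
    params = _single_state_params()
    profile = make_treatment_profile("null", horizon_s=61000.0)
    series, states = simulate_step_series(params, profile, 10000, 1, seed=32)
    assert np.all(states[0] == 1)
    steps = series[0].step_m
    n = len(steps)
    mean, sd = 0.988, 0.928
    shape = mean**2 / sd**2
    assert abs(steps.mean() - mean) < 3 * sd / np.sqrt(n)
    # delta-method Monte-Carlo SE of the sample SD for a gamma
    se_sd = sd * np.sqrt((2 + 6 / shape) / n) / 2
    assert abs(steps.std() - sd) < 3 * se_sd


def test_simulated_transition_frequencies_match_matrix():
    params = intercept_only_params(psi12=0.12, psi21=0.25)
    profile = make_treatment_profile("null", horizon_s=61000.0)
    series, states = simulate_step_series(params, profile, 10000, 1, seed=33)
    s = states[0]
    for a, b, psi in ((1, 2, 0.12), (2, 1, 0.25)):
        from_a = s[:-1] == a
        n_a = from_a.sum()
        freq = np.mean(s[1:][from_a] == b)
        assert abs(freq - psi) < 3 * np.sqrt(psi * (1 - psi) / n_a)


# ---------------------------------------------------------------------------
# spatial mechanics
# ---------------------------------------------------------------------------

def test_positions_inside_arena_and_truth_shapes():
    arena = LockArena()
    profile = make_treatment_profile("pump_co2")
    fish = simulate_trial(arena, profile, study_default_params(), 3, seed=7)
    for fixes, truth in fish:
        assert np.all(truth.x >= arena.gate_x - 1e-9)
        assert np.all(truth.x <= arena.length + 1e-9)
        assert np.all((truth.y >= -1e-9) & (truth.y <= arena.width + 1e-9))
        # one more path node than steps (plus the exit node when exiting)
        assert len(truth.t) == len(truth.state_sequence) + 1
        assert fixes.t[0] == 0.0


def test_simulation_deterministic_under_seed():
    arena = LockArena()
    profile = make_treatment_profile("pump_only")
    a = simulate_trial(arena, profile, study_default_params(), 2, seed=5)
    b = simulate_trial(arena, profile, study_default_params(), 2, seed=5)
    for (fa, ta), (fb, tb) in zip(a, b):
        assert np.array_equal(fa.x, fb.x) and np.array_equal(fa.t, fb.t)
        assert np.array_equal(ta.state_sequence, tb.state_sequence)


def test_position_noise_median_error():
    arena = LockArena(length=5000.0, width=5000.0)  # avoid wall contact
    profile = make_treatment_profile("null")
    fish = simulate_trial(arena, profile, intercept_only_params(), 5, seed=8)
    errs = []
    for fixes, truth in fish:
        tx = np.interp(fixes.t, truth.t, truth.x)
        ty = np.interp(fixes.t, truth.t, truth.y)
        errs.append(np.hypot(fixes.x - tx, fixes.y - ty))
    med = np.median(np.concatenate(errs))
    assert med == pytest.approx(0.878, abs=0.05)


def test_ballistic_exploratory_fish_all_exit():
    # long, persistent steps: quasi-ballistic motion finds the gate quickly
    params = intercept_only_params(
        mean1=4.0, mean2=0.02, sd1=1.0, sd2=0.01,
        psi12=1e-9, psi21=1.0 - 1e-9, kappa=(50.0, 0.0), mu=(0.0, 0.0),
    )
    fish = simulate_trial(
        LockArena(), make_treatment_profile("null"), params, 5, seed=9
    )
    assert all(not truth.censored for _, truth in fish)
    assert all(truth.exit_time_s < 5400.0 for _, truth in fish)


def test_bad_fish_count_rejected():
    with pytest.raises(ValidationError):
        simulate_trial(
            LockArena(), make_treatment_profile("null"),
            study_default_params(), 0, seed=1,
        )


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def test_write_fixtures_counts_and_roundtrip(tmp_path):
    arena = LockArena()
    profile = make_treatment_profile("pump_co2", horizon_s=600.0)
    fish = simulate_trial(arena, profile, study_default_params(), 3, seed=2)
    trial = SimulatedTrial(trial_id=1, arena=arena, profile=profile, fish=fish)
    manifest = write_fixtures([trial], tmp_path)

    entry = manifest["trials"][0]
    assert len(entry["fix_files"]) == 3
    assert (tmp_path / "manifest.json").exists()
    assert (tmp_path / entry["covariate_file"]).exists()

    back = read_fix_table(tmp_path / entry["fix_files"][0])
    orig = fish[0][0]
    assert np.allclose(back.t, orig.t) and np.allclose(back.x, orig.x)
    cov = read_covariate_table(tmp_path / entry["covariate_file"])
    assert list(cov.columns) == ["trial_id", "t_s", "pump_on", "co2_mgL", "temp_C"]


def test_write_fixtures_empty_rejected(tmp_path):
    with pytest.raises(ValidationError):
        write_fixtures([], tmp_path)


def test_write_fixtures_unwritable_directory(tmp_path):
    blocker = tmp_path / "blocker"
    blocker.write_text("not a directory")
    arena = LockArena()
    profile = make_treatment_profile("null", horizon_s=120.0)
    fish = simulate_trial(arena, profile, study_default_params(), 1, seed=2)
    trial = SimulatedTrial(trial_id=1, arena=arena, profile=profile, fish=fish)
    with pytest.raises(ValidationError):
        write_fixtures([trial], blocker / "sub")


def test_study_roster_structure():
    roster = study_roster()
    assert len(roster) == 20
    counts = roster.groupby("treatment")["trial_id"].count()
    assert counts["pump_co2"] == 12
    assert counts["pump_only"] == 6
    assert counts["null"] == 2
    assert roster["n_fish"].sum() == 57
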