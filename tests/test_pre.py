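"""PRE forward model: rates, ratios, ensemble averaging, population fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapmech.peaks import RatioProfile
from gapmech.pre import (
    ConformerEnsemble,
    RelaxationParameters,
    ensemble_gamma2,
    fit_populations,
    gamma2_point,
    gamma2_to_ratio,
    mix_populations,
    place_label_sites,
    r2_from_linewidth,
    tau_c,
)


def oracle_gamma2(r_angstrom, kappa_cm6, tau_r_ns, tau_s_ns, freq_mhz):
    """Independent re-derivation of the Solomon-Bloembergen transverse rate."""
    tc = 1.0 / (1.0 / (tau_r_ns * 1e-9) + 1.0 / (tau_s_ns * 1e-9))
    omega = 2.0 * np.pi * freq_mhz * 1e6
    r_cm = r_angstrom * 1e-8
    return kappa_cm6 * (4.0 * tc + 3.0 * tc / (1.0 + omega**2 * tc**2)) / r_cm**6


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def test_correlation_time_harmonic_composition():
    assert tau_c(70, 100) == pytest.approx(700 / 17)
    assert tau_c(70, 1e12) == pytest.approx(70, rel=1e-9)
    assert tau_c(100, 100) == pytest.approx(50)
    with pytest.raises(ValueError):
        tau_c(-1, 100)


def test_gamma2_point_hand_value(default_params):
    # 16 A, tau_r 70 ns, tau_s 100 ns, 850 MHz -> ~1.21e2 /s
    assert gamma2_point(16.0, default_params) == pytest.approx(120.8, rel=1e-3)


def test_gamma2_matches_independent_oracle_on_log_grid(default_params):
    r = np.logspace(np.log10(2), np.log10(60), 40)
    ours = gamma2_point(r, default_params)
    ref = oracle_gamma2(r, 1.23e-32, 70, 100, 850)
    assert np.allclose(ours, ref, rtol=1e-10)


def test_r6_distance_law(default_params):
    assert gamma2_point(20.0, default_params) * 64 == pytest.approx(
        gamma2_point(10.0, default_params), rel=1e-12
    )


def test_kappa_linearity(default_params):
    doubled = RelaxationParameters(kappa_cm6=2 * default_params.kappa_cm6)
    assert gamma2_point(12.0, doubled) == pytest.approx(
        2 * gamma2_point(12.0, default_params), rel=1e-12
    )


def test_zero_distance_is_singular(default_params):
    with pytest.raises(ValueError):
        gamma2_point(0.0, default_params)


def test_ratio_limits():
    assert gamma2_to_ratio(0.0, 20.0, 6.89e-3) == pytest.approx(1.0)
    assert gamma2_to_ratio(1e9, 20.0, 6.89e-3) == pytest.approx(0.0, abs=1e-12)


def test_ratio_hand_chain():
    # continues the 16 A example: R2 = 20/s, t = 6.89 ms
    assert gamma2_to_ratio(120.8, 20.0, 6.89e-3) == pytest.approx(0.0618, rel=1e-2)


@given(g=st.floats(0, 1e4), r2=st.floats(1.0, 200.0))
@settings(max_examples=60, deadline=None)
def test_ratio_bounds_and_monotonicity(g, r2):
    t = 6.89e-3
    val = gamma2_to_ratio(g, r2, t)
    assert 0 < val <= 1
    assert gamma2_to_ratio(g + 10, r2, t) < val
    if g > 1e-3:
        assert gamma2_to_ratio(g, r2 * 2, t) > val  # increasing in R2


def test_r2_from_linewidth():
    assert r2_from_linewidth(10.0) == pytest.approx(np.pi * 10)
    assert r2_from_linewidth(1 / np.pi) == pytest.approx(1.0)
    assert r2_from_linewidth(20.0) == pytest.approx(2 * r2_from_linewidth(10.0))
    with pytest.raises(ValueError):
        r2_from_linewidth(0.0)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def single_probe_ensemble(distances, n_protons=1):
    """One probe at given distance(s) from a label at the origin, 1 frame each."""
    frames = np.full((len(distances), 1, n_protons, 3), np.nan)
    for f, d in enumerate(distances):
        for p in range(n_protons):
            frames[f, 0, p, :] = (d, 0.0, 0.0)
    labels = np.zeros((len(distances), 1, 3))
    return ConformerEnsemble([(1, "CD1")], frames, labels)


def test_single_frame_equals_point_rate(default_params):
    ens = single_probe_ensemble([14.0])
    val = ensemble_gamma2(ens, default_params).iloc[0]
    assert val == pytest.approx(gamma2_point(14.0, default_params), rel=1e-12)


def test_two_frames_average_rates(default_params):
    ens = single_probe_ensemble([10.0, 20.0])
    expected = 0.5 * (gamma2_point(10.0, default_params) + gamma2_point(20.0, default_params))
    assert ensemble_gamma2(ens, default_params).iloc[0] == pytest.approx(expected, rel=1e-12)


def test_duplicate_label_samples_change_nothing(default_params):
    frames = np.full((1, 1, 1, 3), np.nan)
    frames[0, 0, 0] = (15.0, 0, 0)
    one = ConformerEnsemble([(1, "CD1")], frames, np.zeros((1, 1, 3)))
    two = ConformerEnsemble([(1, "CD1")], frames, np.zeros((1, 2, 3)))
    assert ensemble_gamma2(one, default_params).iloc[0] == pytest.approx(
        ensemble_gamma2(two, default_params).iloc[0], rel=1e-12
    )


def test_frame_permutation_invariance(default_params, rng):
    n_frames, n_probes = 8, 5
    coords = rng.uniform(8, 30, (n_frames, n_probes, 1, 1)) * np.array([1.0, 0, 0])
    labels = rng.normal(0, 1, (n_frames, 2, 3))
    keys = [(i, "CD1") for i in range(n_probes)]
    ens = ConformerEnsemble(keys, coords, labels)
    perm = rng.permutation(n_frames)
    assert np.allclose(
        ensemble_gamma2(ens, default_params).to_numpy(),
        ensemble_gamma2(ens.permuted(perm), default_params).to_numpy(),
    )


def test_missing_probe_coordinates_rejected():
    frames = np.full((2, 1, 1, 3), np.nan)
    frames[0, 0, 0] = (10.0, 0, 0)  # frame 1 has no coordinates
    with pytest.raises(ValueError, match="no coordinates"):
        ConformerEnsemble([(1, "CD1")], frames, np.zeros((2, 1, 3)))


def test_label_site_placement_geometry(rng):
    ca, cb = np.array([0.0, 0, 0]), np.array([1.53, 0, 0])
    sites = place_label_sites(ca, cb, n_samples=500, offset=3.5, jitter=0.0, rng=rng)
    assert np.allclose(sites, [1.53 + 3.5, 0, 0])
    jittered = place_label_sites(ca, cb, n_samples=2000, offset=3.5, jitter=1.5, rng=rng)
    assert np.linalg.norm(jittered.mean(0) - [5.03, 0, 0]) < 0.15


# ---------------------------------------------------------------------------
# population mixing and fitting
# ---------------------------------------------------------------------------

def test_mix_populations_cases():
    profiles = np.array([[100.0, 300.0], [300.0, 100.0]])
    assert np.allclose(mix_populations(profiles, [1, 0]), profiles[0])
    assert np.allclose(mix_populations(np.array([[100.0, 300.0]] * 2), [0.3, 0.7]), [100, 300])
    assert mix_populations(np.array([[100.0], [300.0]]), [0.9, 0.1])[0] == pytest.approx(120.0)
    with pytest.raises(ValueError, match="sum to 1"):
        mix_populations(profiles, [0.6, 0.6])


def profile_from_ratios(keys, ratios, error=0.0, flags=None):
    residues = [k[0] for k in keys]
    atoms = [k[1] for k in keys]
    return RatioProfile.from_arrays(
        residues, atoms, ratios, errors=np.full(len(keys), error), flags=flags
    )


def two_state_profiles(default_params, rng, n=12):
    keys = [(i + 1, "CD1") for i in range(n)]
    g_a = pd.Series(gamma2_point(rng.uniform(14, 25, n), default_params),
                    index=pd.MultiIndex.from_tuples(keys))
    g_b = pd.Series(gamma2_point(rng.uniform(20, 40, n), default_params),
                    index=pd.MultiIndex.from_tuples(keys))
    return keys, {"A": g_a, "B": g_b}


def test_fit_recovers_pure_state(default_params, rng):
    keys, states = two_state_profiles(default_params, rng)
    obs = gamma2_to_ratio(states["A"].to_numpy(), 20.0, default_params.t_evolution_s)
    flags = ["observed"] * len(keys)
    fit = fit_populations(profile_from_ratios(keys, obs, flags=flags), states, default_params)
    assert np.allclose(fit.weights, [1.0, 0.0])
    assert fit.slope == pytest.approx(1.0, abs=1e-6)
    assert fit.pearson_r == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("w", [0.0, 0.2, 0.5, 0.7, 1.0])
def test_fit_recovers_noiseless_mixtures_on_grid(default_params, rng, w):
    keys, states = two_state_profiles(default_params, rng)
    g_mix = mix_populations(np.vstack([s.to_numpy() for s in states.values()]), [w, 1 - w])
    obs = gamma2_to_ratio(g_mix, 20.0, default_params.t_evolution_s)
    fit = fit_populations(profile_from_ratios(keys, obs, flags=["observed"] * len(keys)),
                          states, default_params)
    assert abs(fit.weights[0] - w) <= 0.05 + 1e-9


def test_identical_states_tie_to_uniform(default_params, rng):
    keys, states = two_state_profiles(default_params, rng)
    states = {"A": states["A"], "B": states["A"].copy()}
    obs = gamma2_to_ratio(states["A"].to_numpy(), 20.0, default_params.t_evolution_s)
    fit = fit_populations(profile_from_ratios(keys, obs, flags=["observed"] * len(keys)),
                          states, default_params)
    assert np.allclose(fit.weights, [0.5, 0.5])


def test_fit_mixes_rates_not_ratios(default_params, rng):
    """Back-calculation mixes Gamma2 before the nonlinear ratio map."""
    keys, states = two_state_profiles(default_params, rng)
    w = np.array([0.6, 0.4])
    arr = np.vstack([s.to_numpy() for s in states.values()])
    rate_mixed = gamma2_to_ratio(mix_populations(arr, w), 20.0, default_params.t_evolution_s)
    ratio_mixed = w @ gamma2_to_ratio(arr, 20.0, default_params.t_evolution_s)
    assert not np.allclose(rate_mixed, ratio_mixed)  # genuinely different conventions
    obs = profile_from_ratios(keys, rate_mixed, flags=["observed"] * len(keys))
    fit = fit_populations(obs, states, default_params, grid_step=0.2, refine_step=0.2)
    at_w = fit.trace[(fit.trace["A"] == 0.6) & (fit.trace["B"] == 0.4)]["chi2"]
    assert at_w.min() == pytest.approx(0.0, abs=1e-12)


def test_underdetermined_fit_rejected(default_params, rng):
    keys, states = two_state_profiles(default_params, rng, n=2)
    obs = profile_from_ratios(keys, [0.5, 0.6], flags=["observed", "observed"])
    with pytest.raises(ValueError, match="underdetermined"):
        fit_populations(obs, states, default_params)


def test_synthetic_two_state_recovery(two_state, default_params):
    """Dominant-state weight recovered within one coarse grid step at 2% noise."""
    states = {
        "A": ensemble_gamma2(two_state["ensemble_a"], default_params),
        "B": ensemble_gamma2(two_state["ensemble_b"], default_params),
    }
    fit = fit_populations(two_state["observed"], states, default_params)
    assert abs(fit.weights[0] - two_state["weights"][0]) <= 0.05 + 1e-9
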