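"""Membrane GAP kinetics: network structure, integration, C50, fitting."""

import numpy as np
import pytest

from gapmech import kinetics as kin
from gapmech.kinetics import (
    AssayCondition,
    CompartmentGeometry,
    DoseResponse,
    KineticModel,
    Reaction,
    build_in_tandem_model,
    build_in_trans_model,
    build_scenario_model,
    c50,
    decompose_enhancement,
    dose_response,
    fit_global,
    fit_kd_from_saturation,
    simulate_assay,
)


@pytest.fixture(scope="module")
def ladder():
    return decompose_enhancement()


def pseudo_first_order_model(k=1e4):
    """One irreversible bimolecular step E + S -> E + P (closed-form oracle)."""
    return KineticModel(
        name="pfo",
        species=["E", "S", "P"],
        reactions=[Reaction(("E", "S"), ("E", "P"), "k")],
        parameters={"k": k},
        geometry=CompartmentGeometry(),
        moieties={"S": {"S": 1, "P": 1}, "E": {"E": 1}},
        hydrolyzed_species=["P"],
        substrate_moiety="S",
    )


# ---------------------------------------------------------------------------
# network structure
# ---------------------------------------------------------------------------

def test_both_networks_have_eleven_state_variables():
    assert build_in_trans_model().n_species == 11
    assert build_in_tandem_model().n_species == 11


def test_reactions_conserve_all_moieties():
    # __post_init__ validates conservation; a broken reaction must be rejected
    with pytest.raises(ValueError, match="conserve"):
        KineticModel(
            name="bad",
            species=["S", "P"],
            reactions=[Reaction(("S",), ("P", "P"), "k")],
            parameters={"k": 1.0},
            geometry=CompartmentGeometry(),
            moieties={"S": {"S": 1, "P": 1}},
            hydrolyzed_species=["P"],
        )


def test_negative_rate_constant_rejected():
    with pytest.raises(ValueError, match=">= 0"):
        build_in_trans_model(parameters={"k_cat": -1.0})


def test_without_pip2_no_membrane_species_form():
    model = build_in_tandem_model()
    cond = AssayCondition(initial={"ArfT": 1e-6, "E_s": 1e-6}, pip2_present=False, time_s=60.0)
    rhs, jac, args = model.compile(False)
    from scipy.integrate import odeint

    y0 = np.zeros(11)
    y0[model.index("ArfT")] = 1e-6
    y0[model.index("E_s")] = 1e-6
    out = odeint(rhs, y0, [0, 60.0], Dfun=jac, args=args, tfirst=True, rtol=1e-8, atol=1e-18)
    for s in ("E_m", "E_m.ArfT_P", "E_m.ArfT_PZ", "E_m.ArfD"):
        assert out[-1][model.index(s)] == 0.0


def test_alpha_one_matches_localization_only_scenario():
    full, preset = build_scenario_model("pza_pip2", parameters={"alpha": 1.0})
    loc, _ = build_scenario_model("localization_only")
    cond = AssayCondition(initial={"ArfT": 1e-6, "E_s": 1e-8}, pip2_present=True)
    assert simulate_assay(full, cond) == pytest.approx(simulate_assay(loc, cond), rel=1e-12)


def test_membrane_enhancement_factor_from_geometry():
    geom = CompartmentGeometry(lipid_concentration_m=5e-4, area_per_lipid_nm2=0.7,
                               shell_thickness_nm=10.0)
    lipids = 5e-4 * 6.02214076e23
    v_shell_l = lipids * 0.7e-18 * 10e-9 * 1e3
    assert geom.enhancement == pytest.approx(1 / v_shell_l, rel=1e-12)
    thicker = CompartmentGeometry(shell_thickness_nm=20.0)
    assert thicker.enhancement == pytest.approx(geom.enhancement / 2, rel=1e-12)


# ---------------------------------------------------------------------------
# integration correctness
# ---------------------------------------------------------------------------

def test_zero_enzyme_zero_hydrolysis():
    model = build_in_tandem_model()
    cond = AssayCondition(initial={"ArfT": 1e-6}, pip2_present=True)
    assert simulate_assay(model, cond) == 0.0


def test_pseudo_first_order_matches_closed_form():
    model = pseudo_first_order_model(k=1e4)
    for e0 in (1e-6, 5e-6, 2e-5):
        cond = AssayCondition(initial={"E": e0, "S": 1e-6}, time_s=180.0)
        frac = simulate_assay(model, cond)
        assert frac == pytest.approx(1 - np.exp(-1e4 * e0 * 180.0), abs=1e-6)


def test_saturating_catalysis_hydrolyzes_everything():
    model = build_in_tandem_model(parameters={"alpha": 1e6, "k_cat": 1.0})
    cond = AssayCondition(initial={"ArfT": 1e-6, "E_s": 1e-5}, pip2_present=True)
    assert simulate_assay(model, cond) > 0.999


def test_mass_conservation_through_integration():
    """Moiety totals drift by less than 1e-8 (relative) along the trajectory."""
    from scipy.integrate import odeint

    model = build_in_tandem_model()
    rhs, jac, args = model.compile(True)
    y0 = np.zeros(11)
    y0[model.index("ArfT")] = 1e-6
    y0[model.index("E_s")] = 1e-9
    ts = np.linspace(0, 180, 50)
    out = odeint(rhs, y0, ts, Dfun=jac, args=args, tfirst=True, rtol=1e-8, atol=1e-20,
                 mxstep=200_000)
    for counts in model.moieties.values():
        tot = sum(counts.get(s, 0) * out[:, model.index(s)] for s in model.species)
        assert np.max(np.abs(tot - tot[0])) / tot[0] < 1e-8


def test_in_tandem_reduces_to_in_trans_without_ph_coupling():
    """With PH:substrate binding and intramolecular engagement off (and no
    membrane), the fusion behaves exactly like the free catalytic module."""
    tandem = build_in_tandem_model(parameters={"k_on_ph_arf": 0.0, "c_eff": 0.0})
    trans = build_in_trans_model()
    cond_t = AssayCondition(initial={"ArfT": 1e-6, "E_s": 1e-4}, pip2_present=False)
    cond_z = AssayCondition(initial={"ArfT": 1e-6, "ZA": 1e-4}, pip2_present=False)
    assert simulate_assay(tandem, cond_t) == pytest.approx(
        simulate_assay(trans, cond_z), rel=1e-8
    )


# ---------------------------------------------------------------------------
# dose-response and C50
# ---------------------------------------------------------------------------

def test_dose_response_monotone_in_concentration():
    model, preset = build_scenario_model("pza_pip2")
    base = AssayCondition(initial={"ArfT": 1e-6}, pip2_present=True)
    curve = dose_response(model, "E_s", np.logspace(-13, -8, 12), base)
    assert np.all(np.diff(curve.fractions) >= -1e-10)


def test_fraction_monotone_in_time_kcat_alpha():
    for param, values in (("k_cat", [0.01, 0.05, 0.2]), ("alpha", [1.0, 100.0, 1e4])):
        fracs = []
        for v in values:
            model = build_in_tandem_model(parameters={param: v})
            cond = AssayCondition(initial={"ArfT": 1e-6, "E_s": 1e-10}, pip2_present=True)
            fracs.append(simulate_assay(model, cond))
        assert fracs == sorted(fracs)
    model = build_in_tandem_model()
    fracs = [
        simulate_assay(model, AssayCondition(initial={"ArfT": 1e-6, "E_s": 1e-10},
                                             pip2_present=True, time_s=t))
        for t in (60.0, 180.0, 600.0)
    ]
    assert fracs == sorted(fracs)


def test_c50_closed_form_oracle():
    k, t = 1e4, 180.0
    model = pseudo_first_order_model(k=k)
    base = AssayCondition(initial={"S": 1e-6}, time_s=t)
    conc = np.logspace(-8, -5, 30)
    curve = dose_response(model, "E", conc, base)
    expected = np.log(2) / (k * t)
    assert c50(curve) == pytest.approx(expected, rel=0.02)
    curve2 = dose_response(pseudo_first_order_model(k=2 * k), "E", conc, base)
    assert c50(curve2) == pytest.approx(expected / 2, rel=0.02)


def test_c50_undefined_for_flat_curve():
    flat = DoseResponse(np.logspace(-9, -6, 5), np.zeros(5), scenario="flat")
    with pytest.warns(UserWarning, match="does not cross"):
        assert np.isnan(c50(flat))


def test_scenario_ladder_ordering(ladder):
    """Activity order matches the mechanistic expectation: catalytic module
    alone < recruitment only < binding only < recruitment+binding < full."""
    c50s = ladder.set_index("scenario")["c50_m"]
    order = ["za_alone", "phdza_pip2", "pza_nopip2", "localization_only", "pza_pip2"]
    vals = [c50s[s] for s in order]
    assert all(np.isfinite(vals))
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_localization_only_never_exceeds_full_model(ladder):
    curves = ladder.attrs["curves"]
    loc, full = curves["localization_only"], curves["pza_pip2"]
    assert np.all(loc.fractions <= full.fractions + 1e-9)


def test_halved_affinity_changes_c50_less_than_twofold(ladder):
    fold = ladder.attrs["halved_affinity_c50_fold_change"]
    assert 0.5 < fold < 2.0


def test_allosteric_factor_dominates_c50_gap(ladder):
    c50s = ladder.set_index("scenario")["c50_m"]
    gap = c50s["localization_only"] / c50s["pza_pip2"]
    assert 100 < gap < 1e4  # reflects alpha = 1e3


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_noiseless_self_consistency_with_truth_start():
    """The objective's optimum sits at the generating parameters."""
    from gapmech.synthetic import gen_doseresponse

    data = gen_doseresponse(seed=3, noise=0.0, scenarios=("za_alone", "pza_nopip2", "pza_pip2"))
    truth = {k: kin.REFERENCE_PARAMETERS[k] for k in kin.DEFAULT_FREE_PARAMETERS}
    res = fit_global(
        data["datasets"], n_starts=2, seed=3, start_nfev=5, polish_nfev=60,
        n_polish=3, extra_starts=[truth],
    )
    for name, true_val in truth.items():
        assert res.parameters[name] == pytest.approx(true_val, rel=0.01)


def test_alpha_unidentifiable_without_pip2_data():
    from gapmech.synthetic import gen_doseresponse

    data = gen_doseresponse(seed=2, noise=0.02, scenarios=("pza_nopip2",))
    res = fit_global(data["datasets"], n_starts=2, seed=2, start_nfev=4,
                     polish_nfev=6, n_polish=1)
    assert "alpha" in res.unidentifiable


def test_fit_kd_noiseless_recovery():
    kd = 2e-6
    c = np.logspace(-7, -4.5, 8)
    rates = 0.05 - 0.04 * c / (c + kd)
    out = fit_kd_from_saturation(c, rates)
    assert out["kd"] == pytest.approx(kd, rel=1e-4)
    # half-maximal reduction at c = Kd is the model identity behind the assay
    assert 0.05 - (out["r_free"] - out["delta_r"] * kd / (kd + kd)) == pytest.approx(
        0.02, rel=1e-3
    )


def test_fit_kd_noisy_recovery_within_25_percent(rng):
    kd = 2e-6
    c = np.logspace(-7, -4.5, 8)
    rates = (0.05 - 0.04 * c / (c + kd)) * (1 + 0.05 * rng.standard_normal(8))
    out = fit_kd_from_saturation(c, rates, mode="competitive-inhibition")
    assert out["kd"] == pytest.approx(kd, rel=0.25)


def test_fit_kd_warns_without_saturation():
    kd = 1e-4
    c = np.logspace(-8, -6, 6)  # two decades below Kd
    rates = 0.05 - 0.04 * c / (c + kd)
    with pytest.warns(UserWarning, match="saturate"):
        out = fit_kd_from_saturation(c, rates)
    assert out["warning"] is not None


def test_dn14_preset_halves_affinity_and_removes_allostery():
    model, _ = build_scenario_model("dn14_pza_pip2")
    ref = build_in_tandem_model()
    assert model.parameters["k_off_ph_arf"] == pytest.approx(
        2 * ref.parameters["k_off_ph_arf"]
    )
    assert model.parameters["alpha"] == 1.0
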