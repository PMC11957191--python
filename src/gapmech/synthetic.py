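"""Synthetic inputs with known ground truth for every pipeline stage.

The study's raw inputs (peak lists, conformer ensembles, dose-response
assays) are not deposited, so each generator here emulates one input class
from a known ground truth and returns that truth alongside, enabling
closed-loop recovery tests: shifted/broadened peak lists, two-pose conformer
ensembles with controlled label-probe geometry, endpoint assay titrations
from the reference kinetic model, and small PDB fixtures with analytically
known properties.

All generators are deterministic given a seed: identical arguments produce
byte-identical serialized output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import kinetics as kin
from .peaks import FLAG_BROADENED, FLAG_OBSERVED, PeakTable, RatioProfile
from .pre import ConformerEnsemble, RelaxationParameters, ensemble_gamma2, gamma2_to_ratio, mix_populations

__all__ = [
    "gen_peaklists",
    "gen_two_state_ensemble",
    "gen_doseresponse",
    "gen_toy_structures",
    "write_pdb",
]


# ---------------------------------------------------------------------------
# peak lists
# ---------------------------------------------------------------------------

def gen_peaklists(
    n_probes: int = 60,
    strong_fraction: float = 0.10,
    shift_sigma_ppm: float = 0.01,
    noise_sigma_ppm: float = 0.0,
    intensity_noise: float = 0.0,
    detection_floor: float = 0.1,
    params: RelaxationParameters | None = None,
    seed: int = 0,
) -> dict:
    """Reference/perturbed and diamagnetic/paramagnetic peak-table pairs.

    A ``strong_fraction`` subset of probes receives true shifts large enough
    to exceed 2 sigma of the background scatter (``shift_sigma_ppm``); all
    probes get Gaussian read noise ``noise_sigma_ppm``. The paramagnetic
    table attenuates intensities by I/I0 ratios computed through the PRE
    forward model from a generated label-probe geometry; probes whose true
    ratio falls below ``detection_floor`` are dropped from the paramagnetic
    table (broadened beyond detection). Returns the four tables plus truth.
    """
    rng = np.random.default_rng(seed)
    params = params or RelaxationParameters()
    residues = np.arange(1, n_probes + 1)
    atoms = np.where(residues % 2 == 0, "CD1", "CG1")

    dh = rng.uniform(0.2, 1.4, n_probes)
    dx = rng.uniform(10.0, 25.0, n_probes)
    intensity = rng.lognormal(mean=np.log(100.0), sigma=0.3, size=n_probes)
    snr = rng.uniform(20.0, 60.0, n_probes)

    def table(dh_, dx_, inten, snr_, keep=None):
        df = pd.DataFrame(
            {
                "residue": residues,
                "atom": atoms,
                "dH_ppm": dh_,
                "dX_ppm": dx_,
                "nucleus": "13C",
                "intensity": inten,
                "snr": snr_,
            }
        )
        if keep is not None:
            df = df[keep].reset_index(drop=True)
        return PeakTable(df)

    # true shifts: background scatter for all, large shifts for the chosen subset
    n_strong = int(round(strong_fraction * n_probes))
    strong_idx = rng.choice(n_probes, size=n_strong, replace=False)
    true_dh = np.zeros(n_probes)
    true_dx = np.zeros(n_probes)
    true_dh[strong_idx] = rng.uniform(3.0, 6.0, n_strong) * shift_sigma_ppm * 2
    true_dx[strong_idx] = rng.uniform(3.0, 6.0, n_strong) * shift_sigma_ppm * 2 / np.sqrt(0.185)
    noise_h = noise_sigma_ppm * rng.standard_normal(n_probes)
    noise_x = noise_sigma_ppm * rng.standard_normal(n_probes)

    reference = table(dh, dx, intensity, snr)
    perturbed = table(dh + true_dh + noise_h, dx + true_dx + noise_x, intensity, snr)

    # PRE pair: label at origin, probes at drawn distances
    dist = rng.uniform(12.0, 35.0, n_probes)
    u = rng.standard_normal((n_probes, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    coords = (dist[:, None] * u)[None, :, None, :]  # 1 frame, 1 proton each
    ens = ConformerEnsemble(
        probe_keys=list(zip(residues.tolist(), atoms.tolist())),
        probe_coords=coords,
        label_coords=np.zeros((1, 1, 3)),
    )
    gamma2 = ensemble_gamma2(ens, params).to_numpy()
    r2 = 20.0 if isinstance(params.r2, dict) else float(params.r2)
    true_ratio = gamma2_to_ratio(gamma2, r2, params.t_evolution_s)
    mult = np.exp(intensity_noise * rng.standard_normal(n_probes)) if intensity_noise else 1.0
    para_int = intensity * true_ratio * mult
    keep = true_ratio >= detection_floor
    diamagnetic = table(dh, dx, intensity, snr)
    paramagnetic = table(dh, dx, para_int, np.maximum(snr * true_ratio, 1.0), keep=keep)

    truth = pd.DataFrame(
        {
            "residue": residues,
            "atom": atoms,
            "true_dH": true_dh,
            "true_dX": true_dx,
            "is_strong": np.isin(np.arange(n_probes), strong_idx),
            "distance_A": dist,
            "true_gamma2": gamma2,
            "true_ratio": true_ratio,
            "detectable": keep,
        }
    )
    return {
        "reference": reference,
        "perturbed": perturbed,
        "diamagnetic": diamagnetic,
        "paramagnetic": paramagnetic,
        "truth": truth,
        "shift_sigma_ppm": shift_sigma_ppm,
    }


# ---------------------------------------------------------------------------
# two-state ensembles
# ---------------------------------------------------------------------------

def gen_two_state_ensemble(
    n_probes: int = 30,
    n_frames: int = 20,
    weights: tuple[float, float] = (0.9, 0.1),
    noise_sigma: float = 0.02,
    n_label_samples: int = 3,
    frame_jitter: float = 0.4,
    detection_floor: float = 0.0,
    params: RelaxationParameters | None = None,
    seed: int = 7,
) -> dict:
    """Two conformer ensembles with distinct label-probe distances + mixed profile.

    Pose A places probes 8-18 A from the label site, pose B the same probes
    at 18-35 A, with per-frame coordinate jitter. The observed intensity
    ratio profile is the rate-space population mixture at ``weights`` with
    Gaussian noise ``noise_sigma`` for every probe. Setting a positive
    ``detection_floor`` additionally flags probes whose noiseless mixed
    ratio falls below it as broadened-beyond-detection (ratio 0), emulating
    peak lists in which strongly suppressed resonances are lost; the default
    keeps all probes quantitative.
    """
    if abs(sum(weights) - 1) > 1e-9:
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    params = params or RelaxationParameters()
    residues = np.arange(1, n_probes + 1)
    atoms = ["CD1"] * n_probes
    keys = list(zip(residues.tolist(), atoms))

    u = rng.standard_normal((n_probes, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)

    def make_ensemble(dmin, dmax):
        base = rng.uniform(dmin, dmax, n_probes)
        frames = np.empty((n_frames, n_probes, 1, 3))
        for f in range(n_frames):
            d = np.clip(base + frame_jitter * rng.standard_normal(n_probes), 2.0, None)
            frames[f, :, 0, :] = d[:, None] * u
        labels = 0.3 * rng.standard_normal((n_frames, n_label_samples, 3))
        return ConformerEnsemble(keys, frames, labels), base

    ens_a, base_a = make_ensemble(8.0, 18.0)
    ens_b, base_b = make_ensemble(18.0, 35.0)

    g_a = ensemble_gamma2(ens_a, params)
    g_b = ensemble_gamma2(ens_b, params)
    g_mix = mix_populations(np.vstack([g_a.to_numpy(), g_b.to_numpy()]), weights)
    r2 = 20.0 if isinstance(params.r2, dict) else float(params.r2)
    true_ratio = gamma2_to_ratio(g_mix, r2, params.t_evolution_s)

    noisy = true_ratio + noise_sigma * rng.standard_normal(n_probes)
    flags = np.where(true_ratio < detection_floor, FLAG_BROADENED, FLAG_OBSERVED)
    ratio = np.where(flags == FLAG_BROADENED, 0.0, np.clip(noisy, 1e-4, None))
    err = np.full(n_probes, noise_sigma)
    observed = RatioProfile(
        pd.DataFrame(
            {
                "residue": residues,
                "atom": atoms,
                "ratio": ratio,
                "error": err,
                "flag": flags,
            }
        )
    )
    truth = pd.DataFrame(
        {
            "residue": residues,
            "atom": atoms,
            "base_distance_a": base_a,
            "base_distance_b": base_b,
            "gamma2_a": g_a.to_numpy(),
            "gamma2_b": g_b.to_numpy(),
            "true_ratio": true_ratio,
        }
    )
    return {
        "ensemble_a": ens_a,
        "ensemble_b": ens_b,
        "observed": observed,
        "weights": tuple(weights),
        "truth": truth,
        "params": params,
    }


# ---------------------------------------------------------------------------
# dose-response datasets
# ---------------------------------------------------------------------------

#: titration windows (M) bracketing each scenario's reference-model transition
SCENARIO_RANGES: dict[str, tuple[float, float]] = {
    "za_alone": (1e-6, 1e-2),
    "phdza_pip2": (1e-9, 1e-4),
    "pza_nopip2": (1e-9, 1e-4),
    "localization_only": (1e-10, 1e-5),
    "dn14_pza_pip2": (1e-10, 1e-5),
    "pza_pip2": (1e-13, 1e-8),
}


def gen_doseresponse(
    scenarios: tuple[str, ...] = ("za_alone", "phdza_pip2", "pza_nopip2", "pza_pip2"),
    parameters: dict | None = None,
    geometry: kin.CompartmentGeometry | None = None,
    n_points: int = 10,
    noise: float = 0.05,
    arf0: float = 1.0e-6,
    time_s: float = 180.0,
    seed: int = 1,
) -> dict:
    """Endpoint titration curves for the scenario ladder, with known truth.

    Curves come from the reference kinetic model (or ``parameters``), sampled
    at ``n_points`` log-spaced enzyme concentrations per scenario and
    corrupted with multiplicative log-normal noise (sd ``noise``), the
    precision class of the underlying radioactivity assay.
    """
    rng = np.random.default_rng(seed)
    geometry = geometry or kin.CompartmentGeometry()
    params = {**kin.REFERENCE_PARAMETERS, **(parameters or {})}
    datasets, clean = [], []
    for scen in scenarios:
        lo, hi = SCENARIO_RANGES[scen]
        conc = np.logspace(np.log10(lo), np.log10(hi), n_points)
        model, preset = kin.build_scenario_model(scen, geometry, params)
        base = kin.AssayCondition(initial={"ArfT": arf0}, pip2_present=preset["pip2"], time_s=time_s)
        curve = kin.dose_response(model, preset["enzyme"], conc, base, scenario=scen)
        noisy = np.clip(curve.fractions * np.exp(noise * rng.standard_normal(n_points)), 0.0, 1.0)
        errors = noise * np.maximum(curve.fractions, 0.05)
        datasets.append(kin.DoseResponse(conc, noisy, scenario=scen, errors=errors))
        clean.append(curve)
    return {
        "datasets": datasets,
        "clean": clean,
        "parameters": params,
        "geometry": geometry,
        "arf0": arf0,
        "time_s": time_s,
    }


# ---------------------------------------------------------------------------
# toy PDB structures
# ---------------------------------------------------------------------------

def _pdb_atom(serial, name, resname, chain, resid, xyz, element):
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field:<4s}{'':1s}{resname:>3s} {chain}{resid:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def write_pdb(models: list[list[tuple]], path=None) -> str:
    """Serialize models of (name, resname, chain, resid, xyz, element) atoms."""
    lines = []
    multi = len(models) > 1
    for i, atoms in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        for serial, atom in enumerate(atoms, start=1):
            lines.append(_pdb_atom(serial, *atom))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        from .io import atomic_write

        atomic_write(path, text)
    return text


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def gen_toy_structures(seed: int = 0) -> dict:
    """PDB text fixtures with analytically known geometry.

    * ``globule``: single-atom glycine "residues" — one at the origin,
      tightly caged by two concentric shells, plus one isolated far-away
      residue; the central residue is almost fully buried, the remote one
      fully exposed.
    * ``hbond_ensemble``: 10-frame two-residue system whose donor-H...acceptor
      geometry satisfies standard hydrogen-bond criteria in exactly 7 frames.
    * ``com_fixture``: one frame with two equal-mass atoms placed symmetrically
      about a phosphorus target atom, so the COM-target distance equals the
      perpendicular offset exactly.
    """
    # --- globule ------------------------------------------------------------
    atoms = [("CA", "GLY", "A", 1, (0.0, 0.0, 0.0), "C")]
    resid = 2
    for r, n in ((3.6, 30), (6.8, 60)):
        for p in _fibonacci_sphere(n) * r:
            atoms.append(("CA", "GLY", "A", resid, tuple(p), "C"))
            resid += 1
    isolated_resid = resid
    atoms.append(("CA", "GLY", "A", resid, (60.0, 0.0, 0.0), "C"))
    globule = write_pdb([atoms])

    # --- hydrogen-bond ensemble ----------------------------------------------
    frames = []
    bonded = [True] * 7 + [False] * 3
    for is_bonded in bonded:
        ax = 2.8 if is_bonded else 5.0
        frames.append(
            [
                ("OG", "SER", "A", 1, (0.0, 0.0, 0.0), "O"),
                ("HG", "SER", "A", 1, (0.96, 0.0, 0.0), "H"),
                ("CB", "SER", "A", 1, (-0.8, 1.2, 0.0), "C"),
                ("OG", "SER", "A", 2, (ax, 0.0, 0.0), "O"),
                ("CB", "SER", "A", 2, (ax + 0.8, 1.2, 0.0), "C"),
            ]
        )
    hbond = write_pdb(frames)

    # --- COM fixture ----------------------------------------------------------
    # two carbons at (+/-3, 4, 0): COM = (0, 4, 0); target P at origin -> d = 4
    com_fixture = write_pdb(
        [
            [
                ("C1", "LIG", "A", 1, (3.0, 4.0, 0.0), "C"),
                ("C2", "LIG", "A", 1, (-3.0, 4.0, 0.0), "C"),
                ("PG", "GTP", "A", 2, (0.0, 0.0, 0.0), "P"),
            ]
        ]
    )
    return {
        "globule": globule,
        "globule_core_resid": 1,
        "globule_isolated_resid": isolated_resid,
        "hbond_ensemble": hbond,
        "hbond_occupancy": 0.7,
        "com_fixture": com_fixture,
        "com_distance": 4.0,
    }
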