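"""Forward calculation of paramagnetic relaxation enhancements from ensembles.

A nitroxide spin label attached to one partner broadens the methyl resonances
of the other with an r^-6 distance dependence. For a conformer ensemble the
transverse PRE rate of each methyl proton is computed with the
Solomon-Bloembergen expression

    Gamma2 = kappa * [4*tau_c + 3*tau_c / (1 + (wH*tau_c)^2)] / r^6

averaged in *rate space* over label-site samples within each frame, over the
(up to three) methyl protons, and over frames. Candidate binding poses are
mixed as a population-weighted average of rates, then converted to intensity
ratios

    I/I0 = R2 * exp(-Gamma2 * t) / (R2 + Gamma2)

for comparison with experiment; the population weights are fitted on a
simplex grid by chi-square.

Distances are in Angstrom internally; kappa (1.23e-32 cm^6 s^-2 for a proton)
is converted once to Angstrom^6 s^-2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import FLAG_BROADENED, FLAG_OBSERVED, RatioProfile

__all__ = [
    "RelaxationParameters",
    "ConformerEnsemble",
    "PopulationFit",
    "tau_c",
    "gamma2_point",
    "ensemble_gamma2",
    "gamma2_to_ratio",
    "r2_from_linewidth",
    "mix_populations",
    "fit_populations",
    "place_label_sites",
]

CM6_TO_A6 = 1e48  # (1 cm = 1e8 A)^6


@dataclass
class RelaxationParameters:
    """Physical constants of the PRE forward model.

    kappa_cm6: electron-proton dipolar constant, cm^6 s^-2.
    tau_r_ns / tau_s_ns: rotational and electronic relaxation times (ns);
    the effective correlation time is their harmonic composition.
    frequency_mhz: 1H spectrometer frequency.
    t_evolution_s: total transverse evolution time of the pulse sequence.
    r2: intrinsic transverse relaxation rate(s), s^-1 (global float or
    per-probe mapping keyed by (residue, atom)).
    """

    kappa_cm6: float = 1.23e-32
    tau_r_ns: float = 70.0
    tau_s_ns: float = 100.0
    frequency_mhz: float = 850.0
    t_evolution_s: float = 6.89e-3
    r2: float | dict = 20.0

    def __post_init__(self):
        for name in ("kappa_cm6", "tau_r_ns", "tau_s_ns", "frequency_mhz", "t_evolution_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def kappa_a6(self) -> float:
        return self.kappa_cm6 * CM6_TO_A6

    @property
    def tau_c_s(self) -> float:
        return tau_c(self.tau_r_ns, self.tau_s_ns) * 1e-9

    @property
    def omega_h(self) -> float:
        return 2 * np.pi * self.frequency_mhz * 1e6

    def r2_for(self, key) -> float:
        if isinstance(self.r2, dict):
            return float(self.r2[key])
        return float(self.r2)


def tau_c(tau_r_ns: float, tau_s_ns: float) -> float:
    """Effective correlation time (ns): 1/tau_c = 1/tau_R + 1/tau_S."""
    if tau_r_ns <= 0 or tau_s_ns <= 0:
        raise ValueError("correlation times must be positive")
    return 1.0 / (1.0 / tau_r_ns + 1.0 / tau_s_ns)


def gamma2_point(r_angstrom, params: RelaxationParameters):
    """Solomon-Bloembergen transverse PRE rate (s^-1) at distance r (A).

    Vectorized over r. r = 0 is singular and rejected.
    """
    r = np.asarray(r_angstrom, dtype=float)
    if np.any(r <= 0):
        raise ValueError("electron-proton distance must be > 0")
    tc = params.tau_c_s
    spectral = 4.0 * tc + 3.0 * tc / (1.0 + (params.omega_h * tc) ** 2)
    out = params.kappa_a6 * spectral * r**-6
    return out if out.ndim else float(out)


def gamma2_to_ratio(gamma2, r2, t_s):
    """Paramagnetic/diamagnetic intensity ratio from a PRE rate.

    I/I0 = R2 * exp(-Gamma2*t) / (R2 + Gamma2); lies in (0, 1] for
    Gamma2 >= 0 and decreases monotonically with Gamma2.
    """
    gamma2 = np.asarray(gamma2, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 <= 0):
        raise ValueError("R2 must be positive")
    if t_s < 0:
        raise ValueError("evolution time must be >= 0")
    out = r2 * np.exp(-gamma2 * t_s) / (r2 + gamma2)
    return out if out.ndim else float(out)


def r2_from_linewidth(fwhm_hz: float) -> float:
    """Intrinsic R2 (s^-1) from the half-height linewidth: R2 = pi * FWHM."""
    if fwhm_hz <= 0:
        raise ValueError("linewidth must be positive")
    return float(np.pi * fwhm_hz)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class ConformerEnsemble:
    """Frames of probe-proton and spin-label-site coordinates.

    probe_keys: list of (residue, atom) identifying each probe.
    probe_coords: (n_frames, n_probes, n_protons, 3) A; unused proton slots
    are NaN (a methyl carries up to three equivalent protons).
    label_coords: (n_frames, n_samples, 3) A, >= 1 label-site sample per
    frame (sampling stands in for explicit label rotamers).
    """

    probe_keys: list[tuple[int, str]]
    probe_coords: np.ndarray
    label_coords: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.probe_coords = np.asarray(self.probe_coords, dtype=float)
        self.label_coords = np.asarray(self.label_coords, dtype=float)
        if self.probe_coords.ndim != 4 or self.probe_coords.shape[-1] != 3:
            raise ValueError("probe_coords must have shape (frames, probes, protons, 3)")
        if self.label_coords.ndim != 3 or self.label_coords.shape[-1] != 3:
            raise ValueError("label_coords must have shape (frames, samples, 3)")
        if self.label_coords.shape[0] != self.probe_coords.shape[0]:
            raise ValueError("frame count mismatch between probes and label sites")
        if self.label_coords.shape[1] < 1:
            raise ValueError("every frame needs at least one label-site sample")
        if len(self.probe_keys) != self.probe_coords.shape[1]:
            raise ValueError("probe_keys length does not match probe_coords")
        # every probe needs >= 1 finite proton in every frame
        ok = np.isfinite(self.probe_coords).all(-1).any(-1)
        if not ok.all():
            f, p = np.argwhere(~ok)[0]
            raise ValueError(f"probe {self.probe_keys[p]} has no coordinates in frame {f}")

    @property
    def n_frames(self) -> int:
        return self.probe_coords.shape[0]

    def permuted(self, order) -> "ConformerEnsemble":
        return ConformerEnsemble(
            self.probe_keys, self.probe_coords[order], self.label_coords[order], dict(self.meta)
        )


def ensemble_gamma2(ensemble: ConformerEnsemble, params: RelaxationParameters) -> pd.Series:
    """Per-probe Gamma2 averaged over label samples, methyl protons and frames.

    All averaging is done on rates (<r^-6> weighting), matching the physical
    fast-exchange limit for label motion and methyl rotation.
    """
    # distances: (frames, probes, protons, samples)
    diff = ensemble.probe_coords[:, :, :, None, :] - ensemble.label_coords[:, None, None, :, :]
    r = np.sqrt((diff**2).sum(-1))
    finite = np.isfinite(r)
    r_safe = np.where(finite, r, 1.0)
    if np.any(r_safe[finite] <= 0):
        raise ValueError("zero electron-proton distance in ensemble")
    g = gamma2_point(r_safe, params)
    g = np.where(finite, g, np.nan)
    per_proton = np.nanmean(g, axis=3)        # label-sample rate average
    per_probe_frame = np.nanmean(per_proton, axis=2)  # methyl-proton average
    values = per_probe_frame.mean(axis=0)     # frame average
    return pd.Series(values, index=pd.MultiIndex.from_tuples(ensemble.probe_keys))


def place_label_sites(
    ca: np.ndarray,
    cb: np.ndarray,
    n_samples: int = 10,
    offset: float = 3.5,
    jitter: float = 1.5,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Pseudo spin-label site samples for one frame.

    The nitroxide midpoint is approximated as CB + ``offset`` A along the
    CA->CB direction, with ``n_samples`` draws of isotropic Gaussian jitter
    (sd ``jitter`` A) standing in for label rotamer spread.
    """
    rng = np.random.default_rng(rng)
    ca = np.asarray(ca, float)
    cb = np.asarray(cb, float)
    u = cb - ca
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("CA and CB coincide; cannot orient label site")
    center = cb + offset * u / norm
    return center[None, :] + jitter * rng.standard_normal((n_samples, 3))


# ---------------------------------------------------------------------------
# population mixing and fitting
# ---------------------------------------------------------------------------

def mix_populations(state_profiles: np.ndarray, weights) -> np.ndarray:
    """Convex combination of per-state Gamma2 profiles (rate-space mixing)."""
    profiles = np.asarray(state_profiles, dtype=float)
    w = np.asarray(weights, dtype=float)
    if profiles.shape[0] != w.shape[0]:
        raise ValueError("one weight per state required")
    if np.any(w < -1e-12):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
    return w @ profiles


@dataclass
class PopulationFit:
    weights: np.ndarray
    slope: float
    pearson_r: float
    objective: float
    probe_keys: list
    calc_ratio: np.ndarray
    trace: pd.DataFrame

    @property
    def dominant_ratio(self) -> float:
        """Largest:rest population ratio (e.g. 0.9/0.1 -> 9)."""
        w = np.sort(self.weights)[::-1]
        rest = 1.0 - w[0]
        return float(w[0] / rest) if rest > 0 else np.inf


def _simplex_grid(n_states: int, step: float):
    k = int(round(1.0 / step))
    for combo in itertools.product(range(k + 1), repeat=n_states - 1):
        if sum(combo) <= k:
            rest = k - sum(combo)
            yield np.array(list(combo) + [rest], dtype=float) / k


def _objective(weights, profiles, obs_ratio, obs_err, obs_flags, params, r2_vec, floor):
    gamma_mix = mix_populations(profiles, weights)
    calc = gamma2_to_ratio(gamma_mix, r2_vec, params.t_evolution_s)
    err = np.where(obs_err > 0, obs_err, 1.0)
    resid = np.where(
        obs_flags == FLAG_OBSERVED,
        (calc - obs_ratio) / err,
        # broadened probes only bound the ratio from above: penalize a
        # calculated ratio that would have been detectable
        np.maximum(0.0, calc - floor) / err,
    )
    return float((resid**2).sum()), calc


def fit_populations(
    observed: RatioProfile,
    state_profiles: dict,
    params: RelaxationParameters,
    grid_step: float = 0.05,
    refine_step: float = 0.01,
    detection_floor: float = 0.1,
) -> PopulationFit:
    """Fit state populations by chi-square on a simplex grid.

    ``state_profiles`` maps state name -> per-probe Gamma2 Series (as from
    :func:`ensemble_gamma2`). The coarse grid (default step 0.05) is refined
    once (step 0.01) around the optimum; ties resolve toward the most uniform
    weight vector. Also reports the slope of the calculated-vs-observed
    regression through the origin and the Pearson correlation at the optimum.
    """
    if len(state_profiles) < 2:
        raise ValueError("need at least two states to fit populations")
    names = list(state_profiles)
    obs = observed.data.set_index(["residue", "atom"])
    shared = obs.index
    for s in names:
        shared = shared.intersection(state_profiles[s].index)
    shared = shared[np.isin(obs.loc[shared, "flag"], [FLAG_OBSERVED, FLAG_BROADENED])]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared probes; population fit is underdetermined")

    profiles = np.vstack([state_profiles[s].loc[shared].to_numpy() for s in names])
    obs_ratio = obs.loc[shared, "ratio"].to_numpy(dtype=float)
    obs_err = obs.loc[shared, "error"].to_numpy(dtype=float)
    obs_flags = obs.loc[shared, "flag"].to_numpy()
    r2_vec = np.array([params.r2_for(k) for k in shared])

    uniform = np.full(len(names), 1.0 / len(names))

    def _search(candidates):
        best = None
        rows = []
        for w in candidates:
            chi2, _ = _objective(w, profiles, obs_ratio, obs_err, obs_flags, params, r2_vec, detection_floor)
            rows.append((*w, chi2))
            key = (chi2, np.linalg.norm(w - uniform))
            if best is None or key < best[0]:
                best = (key, w)
        return best[1], rows

    w_best, rows = _search(list(_simplex_grid(len(names), grid_step)))
    fine = [
        w
        for w in _simplex_grid(len(names), refine_step)
        if np.all(np.abs(w - w_best) <= grid_step + 1e-9)
    ]
    w_best, rows_fine = _search(fine)
    chi2, calc = _objective(
        w_best, profiles, obs_ratio, obs_err, obs_flags, params, r2_vec, detection_floor
    )

    mask = obs_flags == FLAG_OBSERVED
    x, y = obs_ratio[mask], calc[mask]
    slope = float((x @ y) / (x @ x)) if x.size and (x @ x) > 0 else np.nan
    pearson = float(np.corrcoef(x, y)[0, 1]) if x.size > 1 else np.nan

    trace = pd.DataFrame(rows + rows_fine, columns=[*names, "chi2"])
    return PopulationFit(
        weights=w_best,
        slope=slope,
        pearson_r=pearson,
        objective=chi2,
        probe_keys=list(shared),
        calc_ratio=calc,
        trace=trace,
    )
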