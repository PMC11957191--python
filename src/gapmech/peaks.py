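"""Chemical-shift-perturbation and intensity-ratio analysis of NMR peak tables.

The experimental primitives here are per-probe quantities extracted from pairs
of 2D spectra (methyl HMQC or amide TROSY-HSQC): a *probe* is one resonance,
keyed by ``(residue, atom)`` where the atom label distinguishes prochiral
methyl pairs (``CD1``/``CD2``, ``CG1``/``CG2``) and backbone amides (``NH``).

Two derived profiles are produced:

* combined chemical shift perturbations
  ``CSP = sqrt(ddH^2 + A * ddX^2)`` with the heteronucleus change scaled by
  ``A = 0.17`` for 15N and ``A = 0.185`` for 13C;
* intensity ratios ``I/I0`` between two states (paramagnetic/diamagnetic, or
  protonated/deuterated partner) with errors propagated from spectral
  signal-to-noise, ``err = (I/I0) * sqrt(SNR^-2 + SNR0^-2)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "CSPProfile",
    "RatioProfile",
    "CSP_SCALE",
    "compute_csp",
    "classify_perturbations",
    "estimate_sigma",
    "intensity_ratio",
    "delta_ratio",
]

#: default heteronucleus scale factors for the combined CSP
CSP_SCALE = {"15N": 0.17, "13C": 0.185}

PEAK_COLUMNS = ["residue", "atom", "dH_ppm", "dX_ppm", "nucleus", "intensity", "snr"]

FLAG_OBSERVED = "observed"
FLAG_MISSING_REF = "missing-in-reference"
FLAG_MISSING_PERT = "missing-in-perturbed"
FLAG_BROADENED = "broadened-beyond-detection"


@dataclass
class PeakTable:
    """One spectrum's peak list.

    ``data`` columns: residue (int), atom (str), dH_ppm, dX_ppm (float, ppm),
    nucleus ('13C' or '15N'), intensity (float, a.u.), snr (float).
    """

    data: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in PEAK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"peak table missing columns: {missing}")
        df["residue"] = df["residue"].astype(int)
        df["atom"] = df["atom"].astype(str)
        dup = df.duplicated(subset=["residue", "atom"])
        if dup.any():
            bad = df.loc[dup, ["residue", "atom"]].to_records(index=False).tolist()
            raise ValueError(f"duplicate probes in peak table: {bad}")
        bad_nuc = set(df["nucleus"]) - set(CSP_SCALE)
        if bad_nuc:
            raise ValueError(f"unknown nucleus labels: {sorted(bad_nuc)}")
        has_i = df["intensity"].notna()
        if (df.loc[has_i, "snr"] <= 0).any():
            raise ValueError("snr must be > 0 wherever an intensity is present")
        self.data = df.reset_index(drop=True)

    def keyed(self) -> pd.DataFrame:
        return self.data.set_index(["residue", "atom"])

    @property
    def probes(self) -> set[tuple[int, str]]:
        return set(map(tuple, self.data[["residue", "atom"]].itertuples(index=False)))

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_tsv(cls, path_or_buf, name: str = "") -> "PeakTable":
        df = pd.read_csv(path_or_buf, sep="\t", comment="#", float_precision="round_trip")
        return cls(df, name=name)

    def to_tsv(self, path_or_buf) -> None:
        self.data.to_csv(path_or_buf, sep="\t", index=False)

    def to_string(self) -> str:
        buf = io.StringIO()
        self.to_tsv(buf)
        return buf.getvalue()


@dataclass
class CSPProfile:
    """Per-probe combined chemical shift perturbations (ppm, >= 0)."""

    data: pd.DataFrame  # residue, atom, nucleus, csp, flag

    def observed(self) -> pd.DataFrame:
        return self.data[self.data["flag"] == FLAG_OBSERVED]

    def to_tsv(self, path_or_buf) -> None:
        self.data.to_csv(path_or_buf, sep="\t", index=False)


@dataclass
class RatioProfile:
    """Per-probe intensity ratios with propagated errors.

    Probes flagged ``broadened-beyond-detection`` carry ratio 0: the resonance
    was visible in the reference (denominator) state but lost in the other.
    """

    data: pd.DataFrame  # residue, atom, ratio, error, flag
    warnings: list[str] = field(default_factory=list)

    def observed(self) -> pd.DataFrame:
        return self.data[self.data["flag"] == FLAG_OBSERVED]

    def to_tsv(self, path_or_buf) -> None:
        self.data.to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_arrays(cls, residues, atoms, ratios, errors=None, flags=None) -> "RatioProfile":
        ratios = np.asarray(ratios, dtype=float)
        if errors is None:
            errors = np.zeros_like(ratios)
        if flags is None:
            flags = [FLAG_BROADENED if r == 0 else FLAG_OBSERVED for r in ratios]
        return cls(
            pd.DataFrame(
                {
                    "residue": np.asarray(residues, dtype=int),
                    "atom": list(atoms),
                    "ratio": ratios,
                    "error": np.asarray(errors, dtype=float),
                    "flag": list(flags),
                }
            )
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_csp(
    reference: PeakTable,
    perturbed: PeakTable,
    scale_override: dict[str, float] | None = None,
) -> CSPProfile:
    """Combined 1H/X chemical shift perturbation per probe.

    CSP = sqrt(ddH^2 + A * ddX^2), A = 0.17 (15N) or 0.185 (13C) unless
    overridden per nucleus. Probes present in only one table are kept with a
    ``missing-in-*`` flag and NaN csp rather than dropped.
    """
    scale = dict(CSP_SCALE)
    if scale_override:
        scale.update(scale_override)

    ref = reference.keyed()
    per = perturbed.keyed()
    shared = ref.index.intersection(per.index)
    if len(shared) == 0:
        raise ValueError("peak tables share no probes")
    mism = shared[(ref.loc[shared, "nucleus"] != per.loc[shared, "nucleus"]).to_numpy()]
    if len(mism):
        raise ValueError(f"nucleus mismatch for probes {list(mism)}")

    rows = []
    for key in shared:
        res, atom = key
        nuc = ref.at[key, "nucleus"]
        ddh = per.at[key, "dH_ppm"] - ref.at[key, "dH_ppm"]
        ddx = per.at[key, "dX_ppm"] - ref.at[key, "dX_ppm"]
        csp = float(np.sqrt(ddh**2 + scale[nuc] * ddx**2))
        rows.append((res, atom, nuc, csp, FLAG_OBSERVED))
    for key in ref.index.difference(per.index):
        rows.append((key[0], key[1], ref.at[key, "nucleus"], np.nan, FLAG_MISSING_PERT))
    for key in per.index.difference(ref.index):
        rows.append((key[0], key[1], per.at[key, "nucleus"], np.nan, FLAG_MISSING_REF))

    df = pd.DataFrame(rows, columns=["residue", "atom", "nucleus", "csp", "flag"])
    df = df.sort_values(["residue", "atom"]).reset_index(drop=True)
    return CSPProfile(df)


def estimate_sigma(profile: CSPProfile) -> float:
    """Robust sigma of the CSP distribution: MAD scaled to a Gaussian sigma.

    Large true perturbations behave as outliers, so the median absolute
    deviation is used instead of the sample standard deviation.
    """
    csp = profile.observed()["csp"].to_numpy()
    if csp.size == 0:
        raise ValueError("no observed probes to estimate sigma from")
    mad = np.median(np.abs(csp - np.median(csp)))
    sigma = 1.4826 * float(mad)
    if sigma <= 0:
        # degenerate (e.g. all-zero) profile; fall back to std
        sigma = float(np.std(csp))
    if sigma <= 0:
        raise ValueError("sigma estimate is non-positive; supply sigma explicitly")
    return sigma


def classify_perturbations(
    profile: CSPProfile,
    sigma: float | dict[str, float] | str = "estimate",
) -> pd.DataFrame:
    """Classify probes as strong (csp >= 2*sigma), moderate ([sigma, 2*sigma)) or weak.

    Boundary values resolve upward: a csp exactly at a threshold takes the
    higher class. ``sigma`` may be one value, a per-atom-group mapping keyed
    by atom label, or ``"estimate"`` (robust MAD estimate from the profile).
    """
    obs = profile.observed().copy()
    if isinstance(sigma, str):
        if sigma != "estimate":
            raise ValueError("sigma must be a number, mapping or 'estimate'")
        sigma_val = {a: estimate_sigma(profile) for a in obs["atom"].unique()}
    elif isinstance(sigma, dict):
        sigma_val = dict(sigma)
    else:
        sigma_val = {a: float(sigma) for a in obs["atom"].unique()}
    for a, s in sigma_val.items():
        if s <= 0:
            raise ValueError(f"non-positive sigma for atom group {a!r}")

    def _cls(row):
        s = sigma_val[row["atom"]]
        if row["csp"] >= 2 * s:
            return "strong"
        if row["csp"] >= s:
            return "moderate"
        return "weak"

    obs["class"] = obs.apply(_cls, axis=1)
    obs["sigma"] = obs["atom"].map(sigma_val)
    return obs.reset_index(drop=True)


def intensity_ratio(numerator: PeakTable, denominator: PeakTable) -> RatioProfile:
    """I/I0 per probe with SNR-propagated error.

    Probes detected in the denominator (e.g. diamagnetic) state but absent in
    the numerator (paramagnetic) are flagged broadened-beyond-detection with
    ratio 0 and error 0. Probes whose denominator intensity is <= 0 are
    excluded with a warning record.
    """
    num = numerator.keyed()
    den = denominator.keyed()
    shared = den.index.intersection(num.index)
    rows, warns = [], []
    for key in den.index:
        res, atom = key
        i0 = den.at[key, "intensity"]
        if not np.isfinite(i0) or i0 <= 0:
            warns.append(f"probe {key}: non-positive denominator intensity {i0!r}; excluded")
            continue
        if key not in shared or not np.isfinite(num.at[key, "intensity"]):
            rows.append((res, atom, 0.0, 0.0, FLAG_BROADENED))
            continue
        i = num.at[key, "intensity"]
        ratio = float(i / i0)
        snr, snr0 = num.at[key, "snr"], den.at[key, "snr"]
        err = abs(ratio) * float(np.sqrt((1.0 / snr) ** 2 + (1.0 / snr0) ** 2))
        rows.append((res, atom, ratio, err, FLAG_OBSERVED))
    df = pd.DataFrame(rows, columns=["residue", "atom", "ratio", "error", "flag"])
    df = df.sort_values(["residue", "atom"]).reset_index(drop=True)
    return RatioProfile(df, warnings=warns)


def delta_ratio(profile_a: RatioProfile, profile_b: RatioProfile) -> pd.DataFrame:
    """Ratio-of-ratios comparing two intensity-ratio profiles probe by probe.

    delta = ratio_a / ratio_b; probes where ratio_b is 0 (or either probe is
    flagged) are kept with NaN delta and flag 'undefined'.
    """
    a = profile_a.data.set_index(["residue", "atom"])
    b = profile_b.data.set_index(["residue", "atom"])
    shared = a.index.intersection(b.index)
    rows = []
    for key in shared:
        ra, rb = a.at[key, "ratio"], b.at[key, "ratio"]
        ok = (
            a.at[key, "flag"] == FLAG_OBSERVED
            and b.at[key, "flag"] == FLAG_OBSERVED
            and rb > 0
        )
        rows.append((key[0], key[1], ra / rb if ok else np.nan, "observed" if ok else "undefined"))
    df = pd.DataFrame(rows, columns=["residue", "atom", "delta", "flag"])
    return df.sort_values(["residue", "atom"]).reset_index(drop=True)
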