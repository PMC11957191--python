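"""Docking restraints from interface-mapping NMR data.

Two restraint classes feed a data-driven docking run:

* **Ambiguous interaction restraints (AIRs)** from chemical-shift
  perturbations: *active* residues are strongly perturbed (> 2 sigma) and
  solvent exposed (relative SASA >= 20%); *passive* residues are exposed
  residues that are moderately perturbed (1-2 sigma) and/or lie within a
  neighbor cutoff (default 6.5 A) of an active residue.
* **Unambiguous distance restraints** from paramagnetic broadening: every
  probe whose paramagnetic/diamagnetic intensity ratio falls below a
  suppression threshold (default I/I0 < 0.2, including resonances broadened
  beyond detection) is restrained to lie 1.8-16 A from the spin-label site.

Restraints are serialized as CNS-style ``assign`` statements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.Structure import Structure

from .io import atomic_write, read_structure
from .peaks import FLAG_BROADENED, FLAG_OBSERVED, RatioProfile

__all__ = [
    "MAX_SASA",
    "ResidueAccessibility",
    "DistanceRestraint",
    "AmbiguousRestraint",
    "RestraintSet",
    "relative_sasa",
    "define_airs",
    "pre_to_restraints",
    "write_restraints",
    "parse_restraints",
]

# Theoretical maximum solvent accessibility per residue type (A^2), from the
# Gly-X-Gly tripeptide normalization of Tien et al. (2013). Only the relative
# 20% exposure cutoff depends on this choice.
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass
class ResidueAccessibility:
    """Per-residue absolute and relative solvent accessibility."""

    data: pd.DataFrame  # chain_id, residue, resname, sasa, relative_sasa

    def exposed(self, cutoff: float = 0.20) -> set[int]:
        df = self.data
        return set(df.loc[df["relative_sasa"] >= cutoff, "residue"].astype(int))


@dataclass(frozen=True)
class DistanceRestraint:
    label_site: str          # e.g. "A:38:CB" (segid:resid:atom of the label site)
    target_residue: int
    target_atom: str
    target_segid: str
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"restraint bounds must satisfy lower < upper, got {self.lower}, {self.upper}")


@dataclass
class AmbiguousRestraint:
    """Active/passive residue lists for one docking partner."""

    segid: str
    active: list[int]
    passive: list[int]

    def __post_init__(self):
        overlap = set(self.active) & set(self.passive)
        if overlap:
            raise ValueError(f"residues in both active and passive sets: {sorted(overlap)}")


@dataclass
class RestraintSet:
    ambiguous: dict[str, AmbiguousRestraint] = field(default_factory=dict)
    unambiguous: list[DistanceRestraint] = field(default_factory=list)


# ---------------------------------------------------------------------------
# solvent accessibility
# ---------------------------------------------------------------------------

def relative_sasa(structure, probe_radius: float = 1.4, n_points: int = 960) -> ResidueAccessibility:
    """Shrake-Rupley SASA per residue, normalized by tabulated maxima.

    ``structure`` is a Biopython Structure (first model used) or a PDB path.
    Residue types without a reference area get relative_sasa = NaN and are
    reported in the table rather than dropped.
    """
    if not isinstance(structure, Structure):
        structure = read_structure(structure)
    model = next(iter(structure))
    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_points)
    sr.compute(model, level="R")
    rows = []
    for chain in model:
        for res in chain:
            if res.id[0].strip():
                continue  # skip waters / hetero records
            resname = res.get_resname()
            sasa = float(res.sasa)
            ref = MAX_SASA.get(resname)
            rel = sasa / ref if ref else np.nan
            rows.append((chain.id, int(res.id[1]), resname, sasa, rel))
    return ResidueAccessibility(
        pd.DataFrame(rows, columns=["chain_id", "residue", "resname", "sasa", "relative_sasa"])
    )


# ---------------------------------------------------------------------------
# ambiguous restraints
# ---------------------------------------------------------------------------

def _residue_coords(structure, mode: str) -> dict[int, np.ndarray]:
    """Heavy-atom (or CB) coordinates per residue of the first model."""
    if not isinstance(structure, Structure):
        structure = read_structure(structure)
    model = next(iter(structure))
    coords = {}
    for chain in model:
        for res in chain:
            if res.id[0].strip():
                continue
            if mode == "cb":
                names = ["CB"] if "CB" in res else ["CA"]
            else:
                names = [a.get_name() for a in res if a.element != "H"]
            xyz = np.array([res[n].coord for n in names if n in res], dtype=float)
            if len(xyz):
                coords[int(res.id[1])] = xyz
    return coords


def define_airs(
    csp_classes: pd.DataFrame,
    accessibility: ResidueAccessibility,
    structure,
    neighbor_cutoff: float = 6.5,
    sasa_cutoff: float = 0.20,
    segid: str = "A",
    contact_mode: str = "heavy",
) -> AmbiguousRestraint:
    """Active/passive residue sets for one partner.

    ``csp_classes`` is the output of :func:`gapmech.peaks.classify_perturbations`
    (per-probe rows); a residue's class is the strongest among its probes.
    Active = strong and exposed. Passive = exposed and (moderate or within
    ``neighbor_cutoff`` A — any heavy atom pair by default — of an active
    residue), minus the active set.
    """
    order = {"weak": 0, "moderate": 1, "strong": 2}
    per_res = (
        csp_classes.assign(rank=csp_classes["class"].map(order))
        .groupby("residue")["rank"]
        .max()
    )
    exposed = accessibility.exposed(sasa_cutoff)
    strong = {int(r) for r, k in per_res.items() if k == 2}
    moderate = {int(r) for r, k in per_res.items() if k == 1}

    active = sorted(strong & exposed)
    if not active:
        raise ValueError("no active residues (strong CSP and exposed); docking would be unconstrained")

    coords = _residue_coords(structure, contact_mode)
    neighbors: set[int] = set()
    if neighbor_cutoff > 0:
        for a in active:
            if a not in coords:
                continue
            xa = coords[a]
            for r, xr in coords.items():
                if r in neighbors or r == a:
                    continue
                d2 = ((xa[:, None, :] - xr[None, :, :]) ** 2).sum(-1)
                if d2.min() <= neighbor_cutoff**2:
                    neighbors.add(r)
    passive = sorted(((moderate | neighbors) & exposed) - set(active))
    return AmbiguousRestraint(segid=segid, active=list(active), passive=list(passive))


# ---------------------------------------------------------------------------
# unambiguous PRE restraints
# ---------------------------------------------------------------------------

def pre_to_restraints(
    profile: RatioProfile,
    label_site: str,
    threshold: float = 0.2,
    bounds: tuple[float, float] = (1.8, 16.0),
    target_segid: str = "B",
) -> list[DistanceRestraint]:
    """One distance restraint per suppressed probe.

    Exactly the probes with ratio < ``threshold`` — including those broadened
    beyond detection (ratio 0) — yield a record with the configured bounds.
    """
    lower, upper = bounds
    out = []
    for row in profile.data.itertuples(index=False):
        if row.flag not in (FLAG_OBSERVED, FLAG_BROADENED):
            continue
        if row.ratio < threshold:
            out.append(
                DistanceRestraint(
                    label_site=label_site,
                    target_residue=int(row.residue),
                    target_atom=str(row.atom),
                    target_segid=target_segid,
                    lower=float(lower),
                    upper=float(upper),
                )
            )
    return out


# ---------------------------------------------------------------------------
# CNS-style serialization
# ---------------------------------------------------------------------------

def _parse_site(site: str) -> tuple[str, int, str]:
    seg, resid, atom = site.split(":")
    return seg, int(resid), atom


def write_restraints(restraint_set: RestraintSet, destination) -> str:
    """Serialize a RestraintSet as CNS/HADDOCK ``assign`` statements.

    Unambiguous records are written as ``d dminus dplus`` with d = upper,
    dminus = upper - lower, dplus = 0 (upper-bound convention for PRE
    restraints). Ambiguous records restrain each active residue to the
    (active + passive) selection of the other partner at 2.0 -2.0 +0.0.
    Output is byte-stable for identical input.
    """
    lines = ["! gapmech restraint file", "! ambiguous interaction restraints"]
    partners = sorted(restraint_set.ambiguous)
    for seg in partners:
        others = [p for p in partners if p != seg]
        air = restraint_set.ambiguous[seg]
        for a in air.active:
            for other in others:
                oair = restraint_set.ambiguous[other]
                sel = sorted(set(oair.active) | set(oair.passive))
                if not sel:
                    continue
                terms = " or ".join(
                    f"(segid {other} and resid {r})" for r in sel
                )
                lines.append(
                    f"assign (segid {seg} and resid {a}) ({terms}) 2.00 2.00 0.00"
                )
    lines.append("! unambiguous distance restraints")
    for r in restraint_set.unambiguous:
        seg, resid, atom = _parse_site(r.label_site)
        lines.append(
            "assign "
            f"(segid {seg} and resid {resid} and name {atom}) "
            f"(segid {r.target_segid} and resid {r.target_residue} and name {r.target_atom}) "
            f"{r.upper:.2f} {r.upper - r.lower:.2f} 0.00"
        )
    text = "\n".join(lines) + "\n"
    try:
        atomic_write(destination, text)
    except (OSError, TypeError) as exc:
        raise OSError(f"could not write restraints to {destination}: {exc}") from exc
    return text


_UNAMBIG_RE = re.compile(
    r"assign \(segid (\w+) and resid (\d+) and name (\S+)\) "
    r"\(segid (\w+) and resid (\d+) and name (\S+)\) "
    r"([\d.]+) ([\d.]+) ([\d.]+)"
)


def parse_restraints(path) -> list[DistanceRestraint]:
    """Read back the unambiguous records of a restraint file."""
    out = []
    for line in Path(path).read_text().splitlines():
        m = _UNAMBIG_RE.match(line.strip())
        if not m:
            continue
        seg1, res1, atom1, seg2, res2, atom2, d, dminus, dplus = m.groups()
        upper = float(d) + float(dplus)
        lower = float(d) - float(dminus)
        out.append(
            DistanceRestraint(
                label_site=f"{seg1}:{res1}:{atom1}",
                target_residue=int(res2),
                target_atom=atom2,
                target_segid=seg2,
                lower=lower,
                upper=upper,
            )
        )
    return out
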