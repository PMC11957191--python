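"""Geometric observables over conformer ensembles.

These report how the nucleotide pocket and switch regions of a GTPase
rearrange between ensembles (e.g. substrate alone versus substrate bound to
an activating domain): distance from the switch-1 center of mass to the GTP
gamma-phosphate, per-residue Calpha distance shifts relative to the
gamma-phosphate, and donor-acceptor hydrogen-bond occupancies.

Ensembles are MDAnalysis Universes (multi-model PDB or any supported
trajectory); selections use the MDAnalysis selection language.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ObservableSeries",
    "com_distance",
    "per_residue_distance_shift",
    "hbond_occupancy",
]


@dataclass
class ObservableSeries:
    """A per-frame scalar observable with summary statistics."""

    values: np.ndarray
    unit: str = "A"
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=0))

    def histogram(self, bin_width: float = 0.1):
        """Normalized histogram (mass sums to 1) with fixed bin width."""
        lo = np.floor(self.values.min() / bin_width) * bin_width
        hi = np.ceil(self.values.max() / bin_width) * bin_width + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(self.values, bins=edges)
        return counts / counts.sum(), edges

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.values)), "value": self.values})


def _single_atom(universe, selection: str, what: str):
    group = universe.select_atoms(selection)
    if len(group) != 1:
        raise ValueError(f"{what} selection {selection!r} matched {len(group)} atoms, need exactly 1")
    return group


def com_distance(universe, residue_selection: str, target_atom: str, backbone_only: bool = False) -> ObservableSeries:
    """Distance between a residue range's mass-weighted COM and one atom, per frame.

    ``residue_selection`` picks the residue set (e.g. ``"resid 39:45"``); all
    atoms of those residues enter the COM unless ``backbone_only``.
    """
    sel = residue_selection + (" and backbone" if backbone_only else "")
    group = universe.select_atoms(sel)
    if len(group) == 0:
        raise ValueError(f"empty selection {sel!r}")
    target = _single_atom(universe, target_atom, "target atom")
    values = []
    for ts in universe.trajectory:
        com = group.center_of_mass()
        values.append(np.linalg.norm(com - target.positions[0]))
    return ObservableSeries(np.array(values), unit="A", label=f"COM({residue_selection}) -> {target_atom}")


def per_residue_distance_shift(
    universe_a,
    universe_b,
    target_atom: str,
    residue_selection: str = "protein",
    error: str = "sum",
) -> pd.DataFrame:
    """Mean per-residue Calpha distance change to a reference atom, A minus B.

    For each residue i shared by the two ensembles, computes
    mean_a d(target -> CA_i) - mean_b d(target -> CA_i). The error bar is the
    sum of the two per-ensemble SDs (convention used for this observable;
    ``error="quadrature"`` gives sqrt(SD_a^2 + SD_b^2) instead). Residues
    present in only one ensemble are excluded and listed in the
    ``excluded`` attribute of the returned frame.
    """
    if error not in ("sum", "quadrature"):
        raise ValueError("error must be 'sum' or 'quadrature'")

    def _stats(universe):
        ca = universe.select_atoms(f"({residue_selection}) and name CA")
        target = _single_atom(universe, target_atom, "target atom")
        dists = []
        for ts in universe.trajectory:
            dists.append(np.linalg.norm(ca.positions - target.positions[0], axis=1))
        dists = np.array(dists)
        return {
            int(r): (dists[:, i].mean(), dists[:, i].std(ddof=0))
            for i, r in enumerate(ca.resids)
        }

    stats_a, stats_b = _stats(universe_a), _stats(universe_b)
    shared = sorted(set(stats_a) & set(stats_b))
    excluded = sorted(set(stats_a) ^ set(stats_b))
    rows = []
    for r in shared:
        ma, sa = stats_a[r]
        mb, sb = stats_b[r]
        err = sa + sb if error == "sum" else float(np.hypot(sa, sb))
        rows.append((r, ma - mb, err))
    out = pd.DataFrame(rows, columns=["residue", "delta_distance", "error"])
    out.attrs["excluded"] = excluded
    return out


def hbond_occupancy(
    universe,
    donor_selection: str,
    acceptor_selection: str,
    distance_cutoff: float = 3.5,
    angle_cutoff_deg: float = 120.0,
    hydrogen_bond_length: float = 1.25,
    allow_heavy_only: bool = False,
):
    """Per-frame hydrogen-bond counts between donor and acceptor selections.

    A bond is counted when the donor-acceptor heavy-atom distance is at most
    ``distance_cutoff`` A and some donor hydrogen makes a D-H...A angle of at
    least ``angle_cutoff_deg``. Hydrogens are located by covalent proximity
    to the donor (< ``hydrogen_bond_length`` A). If the structure carries no
    hydrogens the call fails unless ``allow_heavy_only`` is set, in which
    case the distance criterion alone is applied.

    Returns ``(series, occupancy)`` where occupancy is the fraction of
    frames with at least one bond.
    """
    donors = universe.select_atoms(donor_selection)
    acceptors = universe.select_atoms(acceptor_selection)
    if len(donors) == 0 or len(acceptors) == 0:
        raise ValueError("empty donor or acceptor selection")
    hydrogens = universe.select_atoms("name H* or type H")

    counts = []
    for ts in universe.trajectory:
        n = 0
        for d in donors:
            # hydrogens covalently attached to this donor, this frame
            if len(hydrogens):
                dh = np.linalg.norm(hydrogens.positions - d.position, axis=1)
                attached = hydrogens.positions[dh < hydrogen_bond_length]
            else:
                attached = np.empty((0, 3))
            if attached.shape[0] == 0 and not allow_heavy_only:
                raise ValueError(
                    f"donor {d.name} (resid {d.resid}) has no attached hydrogen; "
                    "add hydrogens or set allow_heavy_only=True"
                )
            for a in acceptors:
                if a.index == d.index:
                    continue
                da = np.linalg.norm(a.position - d.position)
                if da > distance_cutoff:
                    continue
                if attached.shape[0] == 0:
                    n += 1
                    continue
                v1 = d.position - attached
                v2 = a.position - attached
                cosang = (v1 * v2).sum(1) / (
                    np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
                )
                angles = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if np.any(angles >= angle_cutoff_deg):
                    n += 1
        counts.append(n)
    series = ObservableSeries(
        np.array(counts, dtype=float),
        unit="count",
        label=f"H-bonds {donor_selection} -> {acceptor_selection}",
    )
    occupancy = float(np.mean(np.array(counts) >= 1))
    return series, occupancy
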