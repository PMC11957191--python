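"""Structure and table I/O shared across the pipeline.

All text outputs go through :func:`atomic_write` (temp file + rename) so a
failed run never leaves a truncated artifact behind. Structures are read with
Biopython (single models, SASA) and MDAnalysis (multi-model ensembles).
"""

from __future__ import annotations

import hashlib
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio.PDB import PDBParser
from Bio.PDB.Structure import Structure

__all__ = [
    "atomic_write",
    "read_structure",
    "read_ensemble_universe",
    "validate_multimodel",
    "read_table",
    "RunConfig",
]


def atomic_write(path, text: str) -> None:
    """Write ``text`` to ``path`` atomically (temp file in same dir + rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_structure(path, name: str | None = None) -> Structure:
    """Parse a PDB file into a Biopython Structure (all models kept)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    parser = PDBParser(QUIET=True)
    return parser.get_structure(name or path.stem, str(path))


def validate_multimodel(path) -> int:
    """Check every model of a multi-model PDB has the same atoms.

    Returns the model count; raises ValueError naming the first offending
    model if atom counts differ.
    """
    structure = read_structure(path)
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")
    n0 = len(list(models[0].get_atoms()))
    for m in models[1:]:
        n = len(list(m.get_atoms()))
        if n != n0:
            raise ValueError(
                f"{path}: model {m.id + 1} has {n} atoms, expected {n0} (model 1)"
            )
    return len(models)


def read_ensemble_universe(path):
    """Load a multi-model PDB as an MDAnalysis Universe (models = frames)."""
    import MDAnalysis as mda

    validate_multimodel(path)
    return mda.Universe(str(path))


def read_table(path, schema: list[str], sep: str = "\t") -> pd.DataFrame:
    """Read a delimited table and verify required columns are present."""
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; schema is {schema}")
    return df


@dataclass
class RunConfig:
    """Resolved run configuration; unknown keys are rejected at load time."""

    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "gapmech_out"
    verbose: bool = False

    KNOWN = ("inputs", "params", "seed", "outdir", "verbose")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.KNOWN)
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def snapshot(self, outdir=None) -> Path:
        """Write the resolved config (plus its own hash) next to the outputs."""
        out = Path(outdir or self.outdir)
        payload = {
            "inputs": self.inputs,
            "params": self.params,
            "seed": self.seed,
            "outdir": str(self.outdir),
            "verbose": self.verbose,
        }
        text = yaml.safe_dump(payload, sort_keys=True)
        digest = hashlib.sha256(text.encode()).hexdigest()[:16]
        atomic_write(out / "run_config.yaml", text + f"# config_sha256: {digest}\n")
        return out / "run_config.yaml"
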