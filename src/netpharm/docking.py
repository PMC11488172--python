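"""Docking-score triage.

Docking itself is performed by external services; this module only ranks a
supplied binding-energy table and flags candidate ligands. The convention
is kcal/mol with more negative meaning stronger predicted binding; the
candidate threshold defaults to −8 kcal/mol, inclusive (an energy of
exactly −8 counts as a candidate; set ``strict`` for exclusive reading).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["DockingTriageConfig", "triage_docking", "read_docking_table"]


@dataclass(frozen=True)
class DockingTriageConfig:
    energy_threshold: float = -8.0
    strict: bool = False
    #: interpret positive energies as magnitudes of negative binding
    #: energies (sign slips are common in transcribed score tables)
    assume_magnitude: bool = False

    def __post_init__(self):
        import math
        if not math.isfinite(self.energy_threshold):
            raise ValueError("energy_threshold must be finite")


def read_docking_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns (compound, binding_energy)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("compound", "binding_energy"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    nonnum = pd.to_numeric(df["binding_energy"], errors="coerce").isna()
    if nonnum.any():
        raise ValueError(f"{path}: non-numeric binding_energy at line "
                         f"{int(nonnum.idxmax()) + 2}")
    df["binding_energy"] = df["binding_energy"].astype(float)
    return df


def triage_docking(scores: pd.DataFrame,
                   cfg: DockingTriageConfig = DockingTriageConfig()) -> pd.DataFrame:
    """Flag candidate compounds and sort ascending by energy."""
    df = scores.copy()
    energies = pd.to_numeric(df["binding_energy"], errors="coerce")
    if energies.isna().any():
        bad = int(energies.isna().idxmax())
        raise ValueError(f"non-numeric binding energy in row {bad}")
    if cfg.assume_magnitude:
        energies = -energies.abs()
    df["binding_energy"] = energies
    if cfg.strict:
        df["candidate"] = energies < cfg.energy_threshold
    else:
        df["candidate"] = energies <= cfg.energy_threshold
    return df.sort_values(["binding_energy", "compound"]).reset_index(drop=True)
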