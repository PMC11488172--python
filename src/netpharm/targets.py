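"""Compound→target mapping by fingerprint similarity, and disease-target sets.

Putative protein targets of absorbed compounds are inferred by structural
similarity to annotated reference ligands: when a query compound's
fingerprint exceeds the similarity threshold against a reference ligand,
every target annotated to that ligand is transferred to the compound.
The default score is the Tanimoto coefficient on bit-vector fingerprints;
the similarity function is pluggable for users with their own score table.

Disease-target lists from two sources are unioned with duplicates removed,
retaining per-identifier provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "Fingerprint",
    "MappingConfig",
    "TargetAssociation",
    "DiseaseTargetSet",
    "tanimoto",
    "map_targets",
    "union_disease_targets",
    "read_fingerprints",
    "write_fingerprints",
    "read_annotation",
    "read_id_list",
    "normalize_id",
]


@dataclass(frozen=True)
class Fingerprint:
    compound_id: str
    bits: tuple[int, ...]  # 0/1 vector

    def __post_init__(self):
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("fingerprint bits must be 0/1")

    @classmethod
    def from_hex(cls, compound_id: str, hexstr: str, n_bits: int) -> "Fingerprint":
        val = int(hexstr, 16)
        bits = tuple((val >> (n_bits - 1 - i)) & 1 for i in range(n_bits))
        return cls(compound_id, bits)

    def to_hex(self) -> str:
        val = 0
        for b in self.bits:
            val = (val << 1) | b
        width = (len(self.bits) + 3) // 4
        return format(val, f"0{width}x")


@dataclass(frozen=True)
class MappingConfig:
    """Threshold is strict: associations require similarity > threshold."""

    similarity_threshold: float = 0.60

    def __post_init__(self):
        if not (0 <= self.similarity_threshold < 1):
            raise ValueError("similarity_threshold must lie in [0, 1)")


@dataclass(frozen=True)
class TargetAssociation:
    compound_id: str
    target_id: str
    similarity: float
    via_compound_id: str


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a∧b| / |a∨b|; 0 for two all-zero vectors."""
    if len(a.bits) != len(b.bits):
        raise ValueError(f"fingerprint length mismatch: {len(a.bits)} vs {len(b.bits)}")
    av, bv = np.asarray(a.bits, bool), np.asarray(b.bits, bool)
    union = int(np.sum(av | bv))
    if union == 0:
        return 0.0
    return int(np.sum(av & bv)) / union


def map_targets(
    compounds: Iterable[Fingerprint],
    reference_library: Iterable[Fingerprint],
    annotation: Mapping[str, Iterable[str]],
    cfg: MappingConfig = MappingConfig(),
    similarity: Callable[[Fingerprint, Fingerprint], float] = tanimoto,
) -> list[TargetAssociation]:
    """Transfer targets from reference ligands scoring above threshold.

    One association is emitted per (compound, annotated target) pair with
    similarity strictly above ``cfg.similarity_threshold``; duplicate
    (compound, target) pairs keep the maximal similarity. Reference ligands
    without annotation are skipped with a warning. Output ordering is
    independent of library ordering (sorted by compound, target).
    """
    best: dict[tuple[str, str], TargetAssociation] = {}
    refs = list(reference_library)
    unannotated = [r.compound_id for r in refs if r.compound_id not in annotation]
    if unannotated:
        warnings.warn(f"reference ligands without annotation skipped: "
                      f"{sorted(set(unannotated))}")
    for c in compounds:
        for r in refs:
            if r.compound_id not in annotation:
                continue
            s = similarity(c, r)
            if s <= cfg.similarity_threshold:
                continue
            for t in annotation[r.compound_id]:
                key = (c.compound_id, t)
                prev = best.get(key)
                if prev is None or s > prev.similarity:
                    best[key] = TargetAssociation(c.compound_id, t, s, r.compound_id)
    return [best[k] for k in sorted(best)]


def normalize_id(s: str) -> str:
    """Upper-cased, whitespace-trimmed gene/protein identifier."""
    return s.strip().upper()


@dataclass(frozen=True)
class DiseaseTargetSet:
    source_a_ids: tuple[str, ...]
    source_b_ids: tuple[str, ...]

    @property
    def unioned_ids(self) -> frozenset[str]:
        return frozenset(self.source_a_ids) | frozenset(self.source_b_ids)

    def provenance(self) -> dict[str, str]:
        a, b = set(self.source_a_ids), set(self.source_b_ids)
        return {i: ("both" if i in a and i in b else "a" if i in a else "b")
                for i in self.unioned_ids}


def union_disease_targets(a: Iterable[str], b: Iterable[str]) -> DiseaseTargetSet:
    """Combine two disease-target lists, deduplicating after normalization."""
    return DiseaseTargetSet(
        tuple(normalize_id(x) for x in a),
        tuple(normalize_id(x) for x in b),
    )


# ---------------------------------------------------------------- file I/O

def read_fingerprints(path: str | Path, n_bits: int) -> list[Fingerprint]:
    """TSV with columns (id, hex bitstring)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [Fingerprint.from_hex(r["id"], r["fingerprint_hex"], n_bits)
            for _, r in df.iterrows()]


def write_fingerprints(fps: Iterable[Fingerprint], path: str | Path) -> None:
    pd.DataFrame([{"id": f.compound_id, "fingerprint_hex": f.to_hex()}
                  for f in fps]).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> dict[str, list[str]]:
    """TSV with columns (ligand_id, target_id), one pair per row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    ann: dict[str, list[str]] = {}
    for _, r in df.iterrows():
        ann.setdefault(r["ligand_id"], []).append(normalize_id(r["target_id"]))
    return ann


def read_id_list(path: str | Path) -> list[str]:
    """Plain text, one identifier per line; blanks and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(normalize_id(line))
    return out
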