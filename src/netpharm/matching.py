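"""Plasma-to-decoction prototype matching.

An absorbed prototype is a decoction component detected unchanged in
post-dose plasma. Matching follows the serum-pharmacochemistry convention:
a plasma feature is assigned to a decoction component when their molecular
formulas agree and retention times are close; the recomputed mass error of
the plasma observation against the matched formula is recorded. Features
whose formula assignment disagrees with every component can still be
matched by exact normalized compound name (isomer re-assignments between
the two tables); such matches are flagged.

Tables are TSV with columns
``rt, name, observed_mz, formula, error_ppm, adduct, fragments, source``
(fragments semicolon-separated, m/z in Da, RT in minutes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .formula import Adduct, MolecularFormula, adduct_mz, parse_formula, ppm_error

__all__ = [
    "MzFeature",
    "MatchConfig",
    "PlasmaMatch",
    "read_feature_table",
    "write_feature_table",
    "match_plasma",
    "recompute_ppm_report",
    "normalize_name",
]

TABLE_COLUMNS = ["rt", "name", "observed_mz", "formula", "error_ppm",
                 "adduct", "fragments", "source"]


@dataclass(frozen=True)
class MzFeature:
    """One row of a component or plasma feature table."""

    rt: float
    name: str
    observed_mz: float
    formula: MolecularFormula
    adduct: Adduct
    reported_ppm: float | None = None
    fragments: tuple[float, ...] = ()
    source: str = ""

    def __post_init__(self):
        if self.observed_mz <= 0:
            raise ValueError("observed_mz must be positive")
        if self.rt < 0:
            raise ValueError("rt must be non-negative")

    @property
    def theoretical_mz(self) -> float:
        return adduct_mz(self.formula, self.adduct)


@dataclass(frozen=True)
class MatchConfig:
    """Tolerances of the prototype matcher.

    ppm_tolerance applies to m/z comparison when matching without formula
    equality; rt_tolerance applies always. Defaults reproduce the bundled
    decoction/plasma tables' 30 absorbed prototypes.
    """

    ppm_tolerance: float = 10.0
    rt_tolerance: float = 0.5
    require_formula_equal: bool = True
    allow_name_fallback: bool = True
    fragment_tolerance: float = 0.01

    def __post_init__(self):
        if self.ppm_tolerance <= 0 or self.rt_tolerance <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class PlasmaMatch:
    """A plasma feature assigned to its decoction prototype."""

    plasma_feature: MzFeature
    decoction_component: MzFeature
    ppm_error: float
    rt_delta: float
    by_name_fallback: bool = False
    shared_fragments: int = 0


_SUB = re.compile(r"[\s\-_′'’]+")


def normalize_name(name: str) -> str:
    """Case-folded, whitespace/hyphen/prime-stripped compound name."""
    return _SUB.sub("", name).casefold()


def _parse_fragments(s) -> tuple[float, ...]:
    if s is None or (isinstance(s, float)) or not str(s).strip():
        return ()
    return tuple(float(x) for x in str(s).split(";") if x.strip())


def read_feature_table(path: str | Path) -> list[MzFeature]:
    """Read a TSV feature table (decoction components or plasma features)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    feats = []
    for i, row in df.iterrows():
        try:
            feats.append(MzFeature(
                rt=float(row["rt"]),
                name=row["name"],
                observed_mz=float(row["observed_mz"]),
                formula=parse_formula(row["formula"]),
                adduct=Adduct.from_label(row["adduct"]),
                reported_ppm=float(row["error_ppm"]) if row["error_ppm"] else None,
                fragments=_parse_fragments(row.get("fragments", "")),
                source=row.get("source", ""),
            ))
        except (ValueError, KeyError) as e:
            raise ValueError(f"{path}: bad row {i + 2}: {e}") from e
    return feats


def write_feature_table(feats: list[MzFeature], path: str | Path) -> None:
    rows = [{
        "rt": f"{ft.rt:.2f}",
        "name": ft.name,
        "observed_mz": f"{ft.observed_mz:.4f}",
        "formula": str(ft.formula),
        "error_ppm": "" if ft.reported_ppm is None else f"{ft.reported_ppm:g}",
        "adduct": ft.adduct.value,
        "fragments": ";".join(f"{x:g}" for x in ft.fragments),
        "source": ft.source,
    } for ft in feats]
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def _shared_fragments(a: MzFeature, b: MzFeature, tol: float) -> int:
    return sum(1 for x in a.fragments if any(abs(x - y) <= tol for y in b.fragments))


def match_plasma(plasma: list[MzFeature], decoction: list[MzFeature],
                 cfg: MatchConfig = MatchConfig()) -> list[PlasmaMatch]:
    """Assign each plasma feature to at most one decoction component.

    With ``require_formula_equal`` (default) a candidate component must have
    the identical molecular formula and RT within ``rt_tolerance``; the
    plasma feature's mass error against the candidate formula (at the
    plasma feature's own adduct) is recorded. Without it, candidates are
    components of the same adduct whose theoretical m/z lies within
    ``ppm_tolerance`` of the observed plasma m/z, RT within tolerance.

    Among candidates the best is the one with minimal |ppm error|, then
    minimal |RT delta|, then lexicographic name. Features with no candidate
    may fall back to exact normalized-name identity (flagged).
    Output is ordered by plasma RT, then name; it does not depend on the
    input ordering of either list.
    """
    out: list[PlasmaMatch] = []
    for pf in sorted(plasma, key=lambda f: (f.rt, f.name)):
        candidates: list[PlasmaMatch] = []
        for dc in decoction:
            rt_delta = pf.rt - dc.rt
            if abs(rt_delta) > cfg.rt_tolerance:
                continue
            err = ppm_error(pf.observed_mz, adduct_mz(dc.formula, pf.adduct))
            if cfg.require_formula_equal:
                if dc.formula != pf.formula:
                    continue
            else:
                if dc.adduct is not pf.adduct or abs(err) > cfg.ppm_tolerance:
                    continue
            candidates.append(PlasmaMatch(
                pf, dc, err, rt_delta,
                shared_fragments=_shared_fragments(pf, dc, cfg.fragment_tolerance)))
        if not candidates and cfg.allow_name_fallback:
            key = normalize_name(pf.name)
            for dc in decoction:
                if normalize_name(dc.name) == key:
                    candidates.append(PlasmaMatch(
                        pf, dc,
                        ppm_error(pf.observed_mz, pf.theoretical_mz),
                        pf.rt - dc.rt, by_name_fallback=True,
                        shared_fragments=_shared_fragments(pf, dc,
                                                           cfg.fragment_tolerance)))
        if candidates:
            out.append(min(candidates, key=lambda m: (abs(m.ppm_error),
                                                      abs(m.rt_delta),
                                                      m.decoction_component.name)))
    return out


#: Hydrogen-atom and neutral-CHO₂ masses, used only to audit printed errors
#: produced by software that neglects the electron mass of the anion.
_H_ATOM = 1.0078250319
_CHO2_NEUTRAL = 44.9976543


def recompute_ppm_report(feats: list[MzFeature], band: float = 0.5) -> pd.DataFrame:
    """Audit printed mass errors by recomputing them from formula and adduct.

    Vendor software is inconsistent about whether the theoretical m/z of a
    negative ion includes the electron mass (an offset of 0.00055 Da, i.e.
    0.5–6 ppm depending on m/z). Each printed value is therefore checked
    against both conventions: the package's own ion-mass arithmetic
    (``recomputed_ppm``, electron included) and the neutral-species variant
    (``recomputed_ppm_neutral``). ``within_band`` is true when either agrees
    with the printed value to *band* ppm; ``convention`` records which one.
    Rows outside the band are surfaced for inspection, not corrected:
    printed tables carry rounding and occasional transcription slips.
    """
    rows = []
    for ft in feats:
        rec = ppm_error(ft.observed_mz, ft.theoretical_mz)
        from .formula import Adduct as _A, monoisotopic_mass
        m = monoisotopic_mass(ft.formula)
        th_neutral = (m - _H_ATOM if ft.adduct is _A.M_MINUS_H
                      else m + _CHO2_NEUTRAL)
        rec_n = ppm_error(ft.observed_mz, th_neutral)
        printed = ft.reported_ppm
        if printed is None:
            dev = dev_n = None
            conv = "unreported"
        else:
            dev, dev_n = abs(rec - printed), abs(rec_n - printed)
            if min(dev, dev_n) > band:
                conv = "outlier"
            else:
                conv = "ion" if dev <= dev_n else "neutral"
        rows.append({
            "name": ft.name,
            "formula": str(ft.formula),
            "adduct": ft.adduct.value,
            "observed_mz": ft.observed_mz,
            "theoretical_mz": ft.theoretical_mz,
            "printed_ppm": printed,
            "recomputed_ppm": rec,
            "recomputed_ppm_neutral": rec_n,
            "abs_deviation_ppm": None if dev is None else min(dev, dev_n),
            "convention": conv,
            "within_band": conv in ("ion", "neutral"),
        })
    return pd.DataFrame(rows)
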