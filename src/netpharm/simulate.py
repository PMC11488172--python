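"""Synthetic inputs with planted ground truth for every pipeline stage.

Real runs of this pipeline depend on proprietary or versioned external
resources (similarity search engines, disease databases, STRING, DAVID,
docking services). The generators here emulate each input class at desk
scale with a known planted signal, so downstream stages can be tested for
recovery rather than against unreproducible database snapshots:

* a scale-free confidence-weighted interactome (Barabási–Albert
  preferential attachment, Beta-distributed edge confidences) with a
  planted high-centrality module of drug/disease targets;
* plasma feature tables built from a known subset of decoction components
  plus ppm-scale mass noise and decoy features;
* fingerprint libraries in which planted active compounds share bits with
  annotated reference ligands;
* GMT annotation libraries with exactly one term enriched for major hubs;
* docking score tables with a known sub-threshold candidate set.

Every generator is a pure function of its config: one integer seed drives
one dedicated RNG stream per generator, so adding a generator never
perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import AnnotationTerm
from .formula import MolecularFormula, adduct_mz, ppm_error, Adduct
from .matching import MzFeature
from .targets import Fingerprint

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigError",
    "component_id",
    "simulate_interactome",
    "simulate_disease_lists",
    "simulate_plasma_tables",
    "simulate_fingerprint_library",
    "simulate_annotation_library",
    "simulate_docking_scores",
]

# Fixed stream indices: one per generator.
_STREAM = {"interactome": 1, "plasma": 2, "gmt": 3, "fingerprints": 4,
           "docking": 5, "disease": 6}


class ConfigError(ValueError):
    """Invalid simulation configuration; names the offending field."""

    def __init__(self, fld: str, message: str):
        super().__init__(f"{fld}: {message}")
        self.field = fld


@dataclass(frozen=True)
class SimConfig:
    """Shapes and noise levels of all synthetic inputs.

    Defaults are desk-scale: a 300-node scale-free interactome with a
    10-node planted hub module, Beta(4, 2) confidences (≈9% of edges fall
    at or below the 0.4 STRING-style filter), a 50-term annotation library
    with one planted term, and plasma tables with 3 ppm mass noise.
    """

    seed: int = 0
    # interactome
    n_targets: int = 300
    attach_m: int = 3
    conf_alpha: float = 4.0
    conf_beta: float = 2.0
    n_drug_targets: int = 60
    n_disease_targets: int = 40
    n_shared: int = 8
    n_planted_hubs: int = 10
    # annotation library
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    planted_term_overlap: int = 10
    # fingerprints
    n_compounds: int = 40
    fp_bits: int = 256
    fp_density: float = 0.15
    active_fraction: float = 0.6
    # plasma
    n_absorbed_true: int = 10
    n_decoy_features: int = 5
    mz_noise_ppm: float = 3.0
    rt_jitter_min: float = 0.05

    def validate(self) -> None:
        counts = ["n_targets", "attach_m", "n_drug_targets", "n_disease_targets",
                  "n_shared", "n_planted_hubs", "n_terms", "planted_term_overlap",
                  "n_compounds", "fp_bits", "n_absorbed_true", "n_decoy_features"]
        for fld in counts:
            if getattr(self, fld) < 0:
                raise ConfigError(fld, "must be non-negative")
        if self.n_shared > min(self.n_drug_targets, self.n_disease_targets):
            raise ConfigError("n_shared",
                              "must not exceed min(n_drug_targets, n_disease_targets)")
        if self.n_drug_targets + self.n_disease_targets - self.n_shared > self.n_targets:
            raise ConfigError("n_targets", "fewer nodes than labelled targets")
        if self.attach_m >= self.n_targets and self.n_targets > 0:
            raise ConfigError("attach_m", "must be below n_targets")
        if not (0 < self.fp_density < 1):
            raise ConfigError("fp_density", "must lie in (0, 1)")
        if self.conf_alpha <= 0 or self.conf_beta <= 0:
            raise ConfigError("conf_alpha", "Beta shape parameters must be positive")
        if self.mz_noise_ppm < 0:
            raise ConfigError("mz_noise_ppm", "must be non-negative")
        lo, hi = self.term_size_range
        if not (0 < lo <= hi):
            raise ConfigError("term_size_range", "must be a positive (lo, hi) pair")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream]])


@dataclass
class GroundTruth:
    """Planted signal: what a correct pipeline must recover."""

    planted_hub_ids: tuple[str, ...] = ()
    true_absorbed_ids: tuple[str, ...] = ()
    decoy_feature_names: tuple[str, ...] = ()
    planted_term_id: str = ""
    planted_associations: tuple[tuple[str, str], ...] = ()
    docking_candidate_ids: tuple[str, ...] = ()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=list) + "\n")


# ------------------------------------------------------------- interactome

def simulate_interactome(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Scale-free interactome with planted hubs and origin labels.

    Returns (edge table, origin table, truth). The planted hubs receive
    extra uniform-random edges until their degree reaches at least three
    times the expected attachment degree 2·attach_m, so they are wired for
    high degree, betweenness and closeness by construction.
    """
    cfg.validate()
    rng = cfg.rng("interactome")
    n = cfg.n_targets
    g = nx.barabasi_albert_graph(n, cfg.attach_m, seed=int(rng.integers(2**31)))
    ids = [f"T{i:04d}" for i in range(n)]
    g = nx.relabel_nodes(g, dict(enumerate(ids)))

    perm = [ids[i] for i in rng.permutation(n)]
    n_shared = cfg.n_shared
    n_drug_only = cfg.n_drug_targets - n_shared
    n_dis_only = cfg.n_disease_targets - n_shared
    shared = perm[:n_shared]
    drug_only = perm[n_shared:n_shared + n_drug_only]
    dis_only = perm[n_shared + n_drug_only:n_shared + n_drug_only + n_dis_only]
    origin = {v: "none" for v in ids}
    origin.update({v: "both" for v in shared})
    origin.update({v: "drug" for v in drug_only})
    origin.update({v: "disease" for v in dis_only})

    labelled = shared + drug_only + dis_only
    k = min(cfg.n_planted_hubs, len(labelled))
    planted = sorted(rng.choice(labelled, size=k, replace=False).tolist()) if k else []
    target_degree = 3 * 2 * cfg.attach_m
    for hub in planted:
        while g.degree(hub) < target_degree:
            other = ids[int(rng.integers(n))]
            if other != hub and not g.has_edge(hub, other):
                g.add_edge(hub, other)

    rows = []
    for a, b in sorted(map(sorted, g.edges())):
        conf = float(rng.beta(cfg.conf_alpha, cfg.conf_beta))
        conf = min(max(conf, 1e-6), 1.0 - 1e-6)
        rows.append({"node_a": a, "node_b": b, "confidence": conf})
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
    origins = pd.DataFrame({"node": ids, "origin": [origin[v] for v in ids]})
    return edges, origins, GroundTruth(planted_hub_ids=tuple(planted))


def simulate_disease_lists(cfg: SimConfig, origins: pd.DataFrame,
                           ) -> tuple[list[str], list[str]]:
    """Two overlapping source lists whose union is the disease target set,
    emulating the smaller and larger of two disease databases."""
    rng = cfg.rng("disease")
    disease = sorted(origins.loc[origins["origin"].isin(["disease", "both"]), "node"])
    if not disease:
        return [], []
    n_a = max(1, round(0.15 * len(disease)))
    a = sorted(rng.choice(disease, size=n_a, replace=False).tolist())
    # source B holds the rest plus a few duplicates of A
    rest = [d for d in disease if d not in set(a)]
    n_dup = min(len(a), max(1, len(a) // 3))
    dups = sorted(rng.choice(a, size=n_dup, replace=False).tolist()) if a else []
    return a, sorted(rest + dups)


# ------------------------------------------------------------------ plasma

def component_id(f: MzFeature) -> str:
    """Stable identifier for a component table row (names recur across rows)."""
    return f"{f.name}@{f.rt:.2f}"


def _identifiable(components: list[MzFeature], rt_window: float = 1.0) -> list[MzFeature]:
    """Components with no same-formula neighbour within *rt_window* minutes;
    co-eluting isobars cannot be told apart by any m/z+RT matcher."""
    out = []
    for i, c in enumerate(components):
        ambiguous = any(j != i and d.formula == c.formula
                        and abs(d.rt - c.rt) <= rt_window
                        for j, d in enumerate(components))
        if not ambiguous:
            out.append(c)
    return out


def simulate_plasma_tables(cfg: SimConfig, components: list[MzFeature],
                           ) -> tuple[list[MzFeature], GroundTruth]:
    """Plasma feature table: true absorbed prototypes plus decoys.

    True features reproduce a sampled component's theoretical adduct m/z
    times (1 + ε), ε ~ Normal(0, mz_noise_ppm·1e−6) truncated at 3σ, with a
    small RT jitter. Decoy features are rejection-sampled to lie more than
    3·mz_noise_ppm from every theoretical adduct m/z of the component
    library, making false matches a pure tolerance property.
    """
    cfg.validate()
    if not components:
        raise ConfigError("n_absorbed_true", "component list is empty")
    eligible = _identifiable(components)
    if cfg.n_absorbed_true > len(eligible):
        raise ConfigError("n_absorbed_true",
                          f"exceeds the {len(eligible)} unambiguous components")
    rng = cfg.rng("plasma")
    picks = rng.choice(len(eligible), size=cfg.n_absorbed_true, replace=False)
    noise = cfg.mz_noise_ppm * 1e-6

    feats: list[MzFeature] = []
    true_ids = []
    for i in sorted(picks.tolist()):
        c = eligible[i]
        eps = 0.0
        if noise > 0:
            while True:
                eps = float(rng.normal(0.0, noise))
                if abs(eps) <= 3 * noise:
                    break
        th = c.theoretical_mz
        obs = th * (1 + eps)
        rt = max(0.0, c.rt + float(rng.uniform(-cfg.rt_jitter_min, cfg.rt_jitter_min)))
        feats.append(MzFeature(rt=rt, name=c.name, observed_mz=obs,
                               formula=c.formula, adduct=c.adduct,
                               reported_ppm=ppm_error(obs, th),
                               fragments=c.fragments, source=c.source))
        true_ids.append(component_id(c))

    all_theoretical = np.array([adduct_mz(c.formula, ad)
                                for c in components for ad in Adduct])
    known_formulas = {c.formula for c in components}
    decoys = []
    for j in range(cfg.n_decoy_features):
        while True:
            mz = float(rng.uniform(100.0, 1300.0))
            if np.min(np.abs(all_theoretical - mz) / all_theoretical) * 1e6 > 3 * cfg.mz_noise_ppm:
                break
        while True:
            nc = int(rng.integers(8, 50))
            nh = int(rng.integers(nc, 2 * nc + 3))
            no = int(rng.integers(1, 15))
            fdec = MolecularFormula.from_dict({"C": nc, "H": nh, "O": no})
            if fdec not in known_formulas:
                break
        name = f"DECOY{j:02d}"
        decoys.append(MzFeature(
            rt=float(rng.uniform(0.0, 20.0)), name=name, observed_mz=mz,
            formula=fdec, adduct=list(Adduct)[int(rng.integers(2))],
        ))
    feats = sorted(feats + decoys, key=lambda f: (f.rt, f.name))
    return feats, GroundTruth(true_absorbed_ids=tuple(true_ids),
                              decoy_feature_names=tuple(d.name for d in decoys))


# ------------------------------------------------------------ fingerprints

def simulate_fingerprint_library(
    cfg: SimConfig, query_ids: list[str], target_pool: list[str],
) -> tuple[list[Fingerprint], list[Fingerprint], dict[str, list[str]], GroundTruth]:
    """Query fingerprints, annotated reference ligands, and planted actives.

    A fraction ``active_fraction`` of queries are near-copies (2% bit
    flips) of a dedicated annotated reference ligand, so their similarity
    far exceeds the 0.60 mapping threshold; the rest are random at
    ``fp_density`` (expected random-pair Tanimoto ≈ d/(2−d) ≈ 0.08).
    Returns (queries, references, ligand→target annotation, truth).
    """
    cfg.validate()
    if not target_pool:
        raise ConfigError("n_drug_targets", "empty target pool")
    rng = cfg.rng("fingerprints")
    nb = cfg.fp_bits

    def random_bits():
        return tuple(int(b) for b in (rng.random(nb) < cfg.fp_density))

    queries, refs, ann = [], [], {}
    planted: list[tuple[str, str]] = []
    n_active = round(cfg.active_fraction * len(query_ids))
    active_idx = set(rng.choice(len(query_ids), size=n_active,
                                replace=False).tolist()) if query_ids else set()
    for i, qid in enumerate(query_ids):
        bits = random_bits()
        if i in active_idx:
            ref_id = f"REF_{i:03d}"
            flips = rng.random(nb) < 0.02
            ref_bits = tuple(int(b ^ f) for b, f in zip(bits, flips))
            refs.append(Fingerprint(ref_id, ref_bits))
            n_t = int(rng.integers(1, 4))
            tgts = sorted(rng.choice(target_pool, size=min(n_t, len(target_pool)),
                                     replace=False).tolist())
            ann[ref_id] = tgts
            planted.extend((qid, t) for t in tgts)
        queries.append(Fingerprint(qid, bits))
    # extra random annotated references (inactive background)
    for j in range(max(5, len(query_ids) // 4)):
        rid = f"REF_BG{j:03d}"
        refs.append(Fingerprint(rid, random_bits()))
        ann[rid] = sorted(rng.choice(target_pool,
                                     size=min(2, len(target_pool)),
                                     replace=False).tolist())
    return queries, refs, ann, GroundTruth(planted_associations=tuple(sorted(set(planted))))


# -------------------------------------------------------------- annotation

def simulate_annotation_library(cfg: SimConfig, major_hubs: list[str],
                                universe: list[str],
                                ) -> tuple[list[AnnotationTerm], GroundTruth]:
    """GMT library with exactly one term enriched for the major hubs.

    The planted term contains ``planted_term_overlap`` major-hub members
    (plus random filler up to a size drawn from ``term_size_range``); the
    remaining terms are uniform samples from the universe.
    """
    cfg.validate()
    if cfg.n_terms == 0:
        return [], GroundTruth()
    if cfg.planted_term_overlap > len(major_hubs):
        raise ConfigError("planted_term_overlap", "exceeds the major-hub count")
    rng = cfg.rng("gmt")
    uni = sorted(set(universe))
    lo, hi = cfg.term_size_range

    hubs_in = sorted(rng.choice(sorted(major_hubs), size=cfg.planted_term_overlap,
                                replace=False).tolist())
    size = int(rng.integers(lo, hi + 1))
    non_hubs = [u for u in uni if u not in set(hubs_in)]
    n_fill = max(0, min(size - len(hubs_in), len(non_hubs)))
    fill = rng.choice(non_hubs, size=n_fill, replace=False).tolist()
    planted = AnnotationTerm("GS0000", "planted_term",
                             frozenset(hubs_in) | frozenset(fill))
    terms = [planted]
    for t in range(1, cfg.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(uni, size=min(size, len(uni)), replace=False).tolist()
        terms.append(AnnotationTerm(f"GS{t:04d}", f"random_term_{t}",
                                    frozenset(members)))
    return terms, GroundTruth(planted_term_id="GS0000")


# ----------------------------------------------------------------- docking

def simulate_docking_scores(cfg: SimConfig, compound_ids: list[str],
                            ) -> tuple[pd.DataFrame, GroundTruth]:
    """Binding-energy table (kcal/mol) with a known sub-threshold subset.

    Energies are Normal(−7, 1.5): roughly a quarter of compounds fall at or
    below the −8 kcal/mol candidate threshold.
    """
    rng = cfg.rng("docking")
    energies = rng.normal(-7.0, 1.5, size=len(compound_ids)).round(1)
    df = pd.DataFrame({"compound": compound_ids, "binding_energy": energies})
    cands = tuple(df.loc[df["binding_energy"] <= -8.0, "compound"])
    return df, GroundTruth(docking_candidate_ids=cands)
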