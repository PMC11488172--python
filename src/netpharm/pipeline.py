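"""End-to-end orchestration of the serum-pharmacochemistry →
network-pharmacology chain.

The default run mirrors the study design: the bundled decoction and plasma
compound tables are matched to identify absorbed prototypes; every
database-backed stage downstream (target mapping, disease lists,
interactome, annotation, docking scores) is emulated by the synthetic
generators with planted ground truth, seeded from one integer so the whole
bundle is byte-reproducible. Each stage writes its table under the output
directory and the run ends with a JSON summary of all counts and cutoffs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import docking as docking_mod
from .docking import DockingTriageConfig, triage_docking
from .enrichment import enrich, results_frame, write_gmt
from .matching import (MatchConfig, match_plasma, read_feature_table,
                       recompute_ppm_report, write_feature_table)
from .network import (NetworkConfig, ScreeningConfig, build_network,
                      centralities, export_network, screen_hubs)
from .simulate import (SimConfig, component_id, simulate_annotation_library,
                       simulate_disease_lists, simulate_docking_scores,
                       simulate_fingerprint_library, simulate_interactome,
                       simulate_plasma_tables)
from .targets import (MappingConfig, map_targets, union_disease_targets,
                      write_fingerprints)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "bundled_table", "load_bundled_tables"]


def bundled_table(name: str) -> Path:
    """Path of a bundled fixture table (``decoction`` or ``plasma``)."""
    fname = {"decoction": "decoction_components.tsv",
             "plasma": "absorbed_plasma.tsv"}[name]
    return Path(resources.files("netpharm").joinpath("data", fname))


def load_bundled_tables():
    return (read_feature_table(bundled_table("decoction")),
            read_feature_table(bundled_table("plasma")))


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results/pipeline"
    decoction_path: str | None = None   # None → bundled fixture
    plasma_path: str | None = None      # None → bundled fixture
    match: MatchConfig = field(default_factory=MatchConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    docking: DockingTriageConfig = field(default_factory=DockingTriageConfig)
    sim: SimConfig | None = None        # None → SimConfig(seed=seed)
    top_terms: int = 10

    def resolved_sim(self) -> SimConfig:
        return self.sim if self.sim is not None else SimConfig(seed=self.seed)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(name, e) from e
        return wrapped
    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run match → map → union → build → screen → enrich → triage.

    Returns the summary dict; all stage outputs and ``summary.json`` are
    written under ``cfg.out_dir``. Identical configs produce byte-identical
    summaries.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.resolved_sim()

    # -- stage: ingest ----------------------------------------------------
    @_stage("ingest")
    def ingest():
        dec = read_feature_table(cfg.decoction_path or bundled_table("decoction"))
        pla = read_feature_table(cfg.plasma_path or bundled_table("plasma"))
        return dec, pla
    decoction, plasma = ingest()

    # -- stage: match -----------------------------------------------------
    @_stage("match")
    def match():
        ms = match_plasma(plasma, decoction, cfg.match)
        rows = [{
            "plasma_name": m.plasma_feature.name,
            "plasma_rt": round(m.plasma_feature.rt, 2),
            "component_id": component_id(m.decoction_component),
            "ppm_error": round(m.ppm_error, 2),
            "rt_delta": round(m.rt_delta, 2),
            "by_name_fallback": m.by_name_fallback,
            "shared_fragments": m.shared_fragments,
        } for m in ms]
        pd.DataFrame(rows).to_csv(out / "matches.tsv", sep="\t", index=False)
        recompute_ppm_report(decoction).to_csv(out / "ppm_audit.tsv",
                                               sep="\t", index=False)
        return ms
    matches = match()
    absorbed_ids = sorted({component_id(m.decoction_component) for m in matches})

    # -- stage: interactome simulation -----------------------------------
    @_stage("simulate_interactome")
    def sim_net():
        edges, origins, truth = simulate_interactome(sim)
        edges.to_csv(out / "interactome_edges.tsv", sep="\t", index=False)
        origins.to_csv(out / "node_origins.tsv", sep="\t", index=False)
        return edges, origins, truth
    edges, origins, net_truth = sim_net()

    # -- stage: target mapping -------------------------------------------
    @_stage("map_targets")
    def mapping():
        drug_pool = sorted(origins.loc[origins["origin"].isin(["drug", "both"]),
                                       "node"])
        queries, refs, ann, fp_truth = simulate_fingerprint_library(
            sim, absorbed_ids, drug_pool)
        write_fingerprints(queries, out / "compound_fingerprints.tsv")
        write_fingerprints(refs, out / "reference_fingerprints.tsv")
        assoc = map_targets(queries, refs, ann, cfg.mapping)
        pd.DataFrame([{
            "compound": a.compound_id, "target": a.target_id,
            "similarity": round(a.similarity, 4), "via": a.via_compound_id,
        } for a in assoc]).to_csv(out / "target_associations.tsv",
                                  sep="\t", index=False)
        return assoc, fp_truth
    associations, fp_truth = mapping()
    drug_targets = sorted({a.target_id for a in associations})

    # -- stage: disease targets ------------------------------------------
    @_stage("disease_targets")
    def disease():
        a, b = simulate_disease_lists(sim, origins)
        (out / "disease_source_a.txt").write_text("\n".join(a) + "\n" if a else "")
        (out / "disease_source_b.txt").write_text("\n".join(b) + "\n" if b else "")
        return union_disease_targets(a, b)
    disease_set = disease()

    # -- stage: network build + screen -----------------------------------
    @_stage("network")
    def network():
        g = build_network(edges, drug_targets, sorted(disease_set.unioned_ids),
                          cfg.network)
        cents = centralities(g)
        report = screen_hubs(g, cents, cfg.screening)
        export_network(g, report, cents, out / "network")
        pd.DataFrame([dataclasses.asdict(c) for c in cents]).to_csv(
            out / "centralities.tsv", sep="\t", index=False)
        (out / "hubs.txt").write_text("\n".join(report.hubs) + "\n")
        (out / "major_hubs.txt").write_text("\n".join(report.major_hubs) + "\n")
        return g, cents, report
    net, cents, hub_report = network()

    # -- stage: enrichment ------------------------------------------------
    @_stage("enrichment")
    def enrichment():
        universe = sorted(str(v) for v in net.nodes)
        terms, gmt_truth = simulate_annotation_library(
            sim, list(hub_report.major_hubs), universe)
        write_gmt(terms, out / "annotation.gmt")
        res = enrich(hub_report.major_hubs, terms, universe)
        results_frame(res).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        return res, gmt_truth
    enrichment_results, gmt_truth = enrichment()

    # -- stage: docking triage -------------------------------------------
    @_stage("docking")
    def dock():
        scores, dock_truth = simulate_docking_scores(sim, absorbed_ids)
        scores.to_csv(out / "docking_scores.tsv", sep="\t", index=False)
        triaged = triage_docking(scores, cfg.docking)
        triaged.to_csv(out / "docking_triage.tsv", sep="\t", index=False)
        return triaged, dock_truth
    triaged, dock_truth = dock()

    summary = {
        "seed": cfg.seed,
        "decoction_components": len(decoction),
        "plasma_features": len(plasma),
        "match_count": len(matches),
        "absorbed_compounds": len(absorbed_ids),
        "target_associations": len(associations),
        "drug_targets": len(drug_targets),
        "disease_targets": len(disease_set.unioned_ids),
        "network": {"nodes": net.number_of_nodes(),
                    "edges": net.number_of_edges()},
        "hub_screen": hub_report.summary(),
        "top_terms": [{"term_id": r.term_id, "p_value": r.p_value,
                       "p_adjusted": r.p_adjusted, "k": r.k, "K": r.K}
                      for r in enrichment_results[:cfg.top_terms]],
        "docking_candidates": sorted(
            triaged.loc[triaged["candidate"], "compound"].tolist()),
        "ground_truth": {
            "planted_hub_ids": list(net_truth.planted_hub_ids),
            "planted_term_id": gmt_truth.planted_term_id,
            "docking_candidate_ids": list(dock_truth.docking_candidate_ids),
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True) + "\n")
    return summary
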