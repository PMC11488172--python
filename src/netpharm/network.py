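"""Component–target–disease PPI network assembly and hub screening.

The network is an undirected simple graph over target identifiers with a
per-edge confidence score (STRING convention, (0, 1]) and a per-node origin
label: ``drug`` (target of an absorbed compound), ``disease``, ``both`` or
``none`` (interactor added by network expansion). Edges at or below the
confidence threshold are dropped, as are nodes isolated afterwards.

Hub screening is a two-stage median filter on three topological statistics:

* stage 1 keeps nodes whose degree centrality (DC) exceeds the median
  degree over the whole network — with all-distinct degrees this keeps
  exactly ⌊n/2⌋ nodes;
* stage 2 keeps, among stage-1 hubs, nodes whose DC, normalized betweenness
  (BC) and Wasserman–Faust closeness (CC) each exceed the respective median
  recomputed over the stage-1 hub subset (centralities still taken from the
  full network).

All cutoffs are strict (>). Major hubs are partitioned by origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping
import warnings

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkConfig",
    "ScreeningConfig",
    "CentralityTriple",
    "HubReport",
    "build_network",
    "read_edge_table",
    "centralities",
    "screen_hubs",
    "export_network",
    "read_graphml",
]

ORIGINS = ("drug", "disease", "both", "none")


@dataclass(frozen=True)
class NetworkConfig:
    """Edges are retained only with confidence strictly above the threshold."""

    confidence_threshold: float = 0.4

    def __post_init__(self):
        if not (0 <= self.confidence_threshold < 1):
            raise ValueError("confidence_threshold must lie in [0, 1)")


@dataclass(frozen=True)
class ScreeningConfig:
    """Median cutoffs are computed from the data, never user-supplied,
    unless explicit overrides are given (``cutoff_overrides``)."""

    stage2_scope: str = "hubs"  # medians over stage-1 hubs ("hubs") or all nodes ("all")
    cutoff_overrides: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.stage2_scope not in ("hubs", "all"):
            raise ValueError("stage2_scope must be 'hubs' or 'all'")


@dataclass(frozen=True)
class CentralityTriple:
    node_id: str
    dc: int
    bc: float
    cc: float


@dataclass(frozen=True)
class HubReport:
    hubs: tuple[str, ...]
    major_hubs: tuple[str, ...]
    partition: dict[str, int]
    stage1_cutoff: float
    stage2_cutoffs: tuple[float, float, float]  # DC, BC, CC medians

    def summary(self) -> dict:
        return {
            "n_hubs": len(self.hubs),
            "n_major_hubs": len(self.major_hubs),
            "partition": dict(self.partition),
            "stage1_dc_cutoff": self.stage1_cutoff,
            "stage2_cutoffs": {"dc": self.stage2_cutoffs[0],
                               "bc": self.stage2_cutoffs[1],
                               "cc": self.stage2_cutoffs[2]},
        }


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns (node_a, node_b, confidence)."""
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    for col in ("node_a", "node_b", "confidence"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad = df[~df["confidence"].apply(lambda x: isinstance(x, (int, float))
                                     and 0 < float(x) <= 1)]
    if len(bad):
        raise ValueError(f"{path}: malformed confidence at line "
                         f"{int(bad.index[0]) + 2}")
    return df


def build_network(
    edges: pd.DataFrame,
    drug_targets: Iterable[str],
    disease_targets: Iterable[str],
    cfg: NetworkConfig = NetworkConfig(),
) -> nx.Graph:
    """Confidence-filter the edge table and label node origins.

    Self-loops are discarded; parallel edges keep the maximal confidence.
    Nodes isolated after filtering are dropped.
    """
    drug, disease = set(drug_targets), set(disease_targets)
    g = nx.Graph()
    for a, b, c in edges[["node_a", "node_b", "confidence"]].itertuples(index=False):
        c = float(c)
        if a == b or c <= cfg.confidence_threshold:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], c)
        else:
            g.add_edge(a, b, confidence=c)
    for n in g.nodes:
        g.nodes[n]["origin"] = ("both" if n in drug and n in disease
                                else "drug" if n in drug
                                else "disease" if n in disease
                                else "none")
    return g


def centralities(net: nx.Graph) -> list[CentralityTriple]:
    """DC (raw degree), BC (Brandes, normalized by 2/((n−1)(n−2))), CC
    (Wasserman–Faust component-scaled closeness). Singletons score zero."""
    if net.number_of_nodes() == 0:
        return []
    n = net.number_of_nodes()
    bc = (nx.betweenness_centrality(net, normalized=True) if n >= 3
          else {v: 0.0 for v in net})
    cc = nx.closeness_centrality(net, wf_improved=True) if n >= 2 else {v: 0.0 for v in net}
    return [CentralityTriple(str(v), net.degree(v), bc[v], cc[v])
            for v in sorted(net.nodes, key=str)]


def _median(values) -> float:
    return float(np.median(np.asarray(list(values), dtype=float)))


def screen_hubs(
    net: nx.Graph,
    cents: list[CentralityTriple],
    cfg: ScreeningConfig = ScreeningConfig(),
) -> HubReport:
    """Two-stage strict-median hub screen with origin partition."""
    if net.number_of_nodes() == 0 or not cents:
        warnings.warn("empty network: empty hub report")
        return HubReport((), (), {o: 0 for o in ORIGINS}, 0.0, (0.0, 0.0, 0.0))
    by_id = {c.node_id: c for c in cents}
    missing = [str(v) for v in net.nodes if str(v) not in by_id]
    if missing:
        raise ValueError(f"centralities missing for nodes: {missing[:5]}")

    dc_median = _median(c.dc for c in cents)
    hubs = sorted(c.node_id for c in cents if c.dc > dc_median)

    if cfg.cutoff_overrides is not None:
        dc_cut, bc_cut, cc_cut = cfg.cutoff_overrides
    else:
        scope = [by_id[h] for h in hubs] if cfg.stage2_scope == "hubs" else cents
        if not scope:
            scope = cents
        dc_cut = _median(c.dc for c in scope)
        bc_cut = _median(c.bc for c in scope)
        cc_cut = _median(c.cc for c in scope)

    major = sorted(h for h in hubs
                   if by_id[h].dc > dc_cut and by_id[h].bc > bc_cut
                   and by_id[h].cc > cc_cut)

    partition = {o: 0 for o in ORIGINS}
    origin = {str(v): d.get("origin", "none") for v, d in net.nodes(data=True)}
    for h in major:
        partition[origin.get(h, "none")] += 1
    return HubReport(tuple(hubs), tuple(major), partition,
                     dc_median, (dc_cut, bc_cut, cc_cut))


def export_network(
    net: nx.Graph,
    report: HubReport | None,
    cents: list[CentralityTriple] | None,
    out_prefix: str | Path,
) -> dict[str, Path]:
    """Write GraphML (with origin/centrality/hub-flag node attributes) and
    SIF (interaction type ``pp``) files for Cytoscape-style tools."""
    out_prefix = Path(out_prefix)
    g = net.copy()
    if cents:
        for c in cents:
            if c.node_id in g:
                g.nodes[c.node_id].update(dc=int(c.dc), bc=float(c.bc),
                                          cc=float(c.cc))
    if report:
        hubs, major = set(report.hubs), set(report.major_hubs)
        for v in g.nodes:
            g.nodes[v]["hub"] = str(v) in hubs
            g.nodes[v]["major_hub"] = str(v) in major
    graphml = out_prefix.with_suffix(".graphml")
    sif = out_prefix.with_suffix(".sif")
    nx.write_graphml(g, graphml)
    with open(sif, "w") as fh:
        for a, b in sorted(map(sorted, g.edges())):
            fh.write(f"{a}\tpp\t{b}\n")
        for v in sorted(nx.isolates(g)):
            fh.write(f"{v}\n")
    return {"graphml": graphml, "sif": sif}


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
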