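"""Synthetic-data generators: determinism, shape contracts, config errors."""

import numpy as np
import pandas as pd
import pytest

from netpharm.formula import Adduct, adduct_mz
from netpharm.simulate import (ConfigError, SimConfig, simulate_annotation_library,
                               simulate_disease_lists, simulate_docking_scores,
                               simulate_fingerprint_library, simulate_interactome,
                               simulate_plasma_tables)


def test_ba_edge_count_without_planting():
    """Pure preferential attachment: m·(n−m) edges."""
    cfg = SimConfig(seed=1, n_targets=50, attach_m=2, n_drug_targets=5,
                    n_disease_targets=5, n_shared=0, n_planted_hubs=0)
    edges, origins, truth = simulate_interactome(cfg)
    assert len(origins) == 50
    assert len(edges) == 2 * (50 - 2)
    assert truth.planted_hub_ids == ()


def test_interactome_contracts():
    cfg = SimConfig(seed=2)
    edges, origins, truth = simulate_interactome(cfg)
    assert (edges.node_a != edges.node_b).all()          # no self-loops
    pairs = list(map(tuple, edges[["node_a", "node_b"]].values))
    assert len(set(pairs)) == len(pairs)                 # simple graph
    assert ((edges.confidence > 0) & (edges.confidence < 1)).all()
    counts = origins.origin.value_counts()
    assert counts.get("both", 0) == cfg.n_shared
    assert counts.get("drug", 0) == cfg.n_drug_targets - cfg.n_shared
    assert counts.get("disease", 0) == cfg.n_disease_targets - cfg.n_shared
    # planted hubs wired to at least 3x the expected attachment degree
    deg = pd.concat([edges.node_a, edges.node_b]).value_counts()
    for hub in truth.planted_hub_ids:
        assert deg[hub] >= 3 * 2 * cfg.attach_m


def test_interactome_determinism():
    a = simulate_interactome(SimConfig(seed=12))
    b = simulate_interactome(SimConfig(seed=12))
    pd.testing.assert_frame_equal(a[0], b[0])
    pd.testing.assert_frame_equal(a[1], b[1])
    assert a[2].planted_hub_ids == b[2].planted_hub_ids
    c = simulate_interactome(SimConfig(seed=13))
    assert not a[0].equals(c[0])


@pytest.mark.parametrize("kw,fld", [
    (dict(n_shared=5, n_drug_targets=3), "n_shared"),
    (dict(n_targets=-1), "n_targets"),
    (dict(fp_density=1.5), "fp_density"),
    (dict(attach_m=400), "attach_m"),
    (dict(conf_alpha=0.0), "conf_alpha"),
    (dict(term_size_range=(0, 5)), "term_size_range"),
])
def test_config_errors_name_offending_field(kw, fld):
    with pytest.raises(ConfigError) as e:
        simulate_interactome(SimConfig(seed=1, **kw))
    assert e.value.field == fld


def test_plasma_table_composition(decoction):
    cfg = SimConfig(seed=3, n_absorbed_true=10, n_decoy_features=5)
    plasma, truth = simulate_plasma_tables(cfg, decoction)
    assert len(plasma) == 15
    assert len(truth.true_absorbed_ids) == 10
    assert len(truth.decoy_feature_names) == 5


def test_plasma_determinism(decoction):
    a, _ = simulate_plasma_tables(SimConfig(seed=8), decoction)
    b, _ = simulate_plasma_tables(SimConfig(seed=8), decoction)
    assert [(f.name, f.observed_mz, f.rt) for f in a] == \
           [(f.name, f.observed_mz, f.rt) for f in b]


def test_plasma_noise_bounded_and_decoys_separated(decoction):
    cfg = SimConfig(seed=4, n_absorbed_true=15, n_decoy_features=10)
    plasma, truth = simulate_plasma_tables(cfg, decoction)
    theo = np.array([adduct_mz(c.formula, ad) for c in decoction for ad in Adduct])
    for f in plasma:
        if f.name in truth.decoy_feature_names:
            dist_ppm = np.min(np.abs(theo - f.observed_mz) / theo) * 1e6
            assert dist_ppm > 3 * cfg.mz_noise_ppm
        else:
            assert abs(f.observed_mz / f.theoretical_mz - 1) * 1e6 <= 3 * cfg.mz_noise_ppm


def test_plasma_too_many_true_raises(decoction):
    with pytest.raises(ConfigError):
        simulate_plasma_tables(SimConfig(seed=1, n_absorbed_true=10_000), decoction)
    with pytest.raises(ConfigError):
        simulate_plasma_tables(SimConfig(seed=1), [])


def test_annotation_library_contract():
    cfg = SimConfig(seed=5, n_terms=20)
    uni = [f"T{i:04d}" for i in range(200)]
    hubs = uni[:30]
    terms, truth = simulate_annotation_library(cfg, hubs, uni)
    assert len(terms) == 20
    planted = next(t for t in terms if t.term_id == truth.planted_term_id)
    assert len(planted.members & set(hubs)) >= cfg.planted_term_overlap
    lo, hi = cfg.term_size_range
    assert all(lo <= len(t.members) <= hi for t in terms)
    # determinism
    terms2, _ = simulate_annotation_library(cfg, hubs, uni)
    assert [(t.term_id, t.members) for t in terms] == \
           [(t.term_id, t.members) for t in terms2]


def test_annotation_overlap_too_large():
    with pytest.raises(ConfigError):
        simulate_annotation_library(SimConfig(seed=1, planted_term_overlap=5),
                                    ["h1", "h2"], ["h1", "h2", "x"])


def test_disease_lists_union_covers_disease_nodes():
    cfg = SimConfig(seed=6)
    _, origins, _ = simulate_interactome(cfg)
    a, b = simulate_disease_lists(cfg, origins)
    disease = set(origins.loc[origins.origin.isin(["disease", "both"]), "node"])
    assert set(a) | set(b) == disease
    assert set(a) & set(b)      # sources overlap, union must deduplicate


def test_fingerprint_shapes_and_determinism():
    cfg = SimConfig(seed=7, n_compounds=12, fp_bits=128)
    qids = [f"C{i}" for i in range(12)]
    pool = [f"T{i}" for i in range(20)]
    q1, r1, a1, t1 = simulate_fingerprint_library(cfg, qids, pool)
    q2, r2, a2, t2 = simulate_fingerprint_library(cfg, qids, pool)
    assert [f.bits for f in q1] == [f.bits for f in q2]
    assert a1 == a2 and t1.planted_associations == t2.planted_associations
    assert all(len(f.bits) == 128 for f in q1 + r1)


def test_docking_scores_truth_consistent():
    cfg = SimConfig(seed=9)
    ids = [f"C{i}" for i in range(30)]
    df, truth = simulate_docking_scores(cfg, ids)
    assert set(truth.docking_candidate_ids) == \
           set(df.loc[df.binding_energy <= -8.0, "compound"])
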