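# Methods

## Scope and data model

The pipeline chains seven stages: absorbed-prototype identification from
paired LC/MS compound tables; compound→target mapping by fingerprint
similarity; disease-target union; PPI-network assembly under a confidence
filter; two-stage median-centrality hub screening; hypergeometric gene-set
enrichment of the major hubs; and docking-score triage. The unit records are
a molecular formula (element→count map), an m/z feature (RT, name, observed
m/z, formula, adduct, fragments), a confidence-weighted undirected graph
with per-node origin labels, and a hypergeometric test record (k, K, n, N,
p, adjusted p).

## Mass arithmetic

Monoisotopic element masses are taken from the NIST table shipped with
pyteomics (most-abundant isotope per element). Ion masses are
electron-inclusive and fixed by convention:

* [M−H]⁻ = M − 1.00727646 Da (a proton is removed; the electron stays),
* [M+HCOO]⁻ = M + 44.99820 Da (CHO₂ monoisotopic plus one electron).

Formula parsing is Hill-style with no charges or isotopes; parse errors
carry the character offset. RTs are minutes, printed to two decimals.

**Auditing printed mass errors.** Vendor software is inconsistent about the
electron term: omitting it shifts the theoretical m/z by 0.00055 Da, i.e.
0.5–6 ppm depending on m/z — far from negligible at instrument accuracy.
The bundled component table demonstrably mixes both conventions across rows
(107 rows agree with the electron-inclusive recomputation within 0.5 ppm,
23 with the electron-free one, 3 with neither). The audit report
(`recompute_ppm_report`) therefore checks each printed error against both
conventions, records which one matched, and flags the rest as outliers —
among them a chemically impossible formula (odd hydrogen count) that is
preserved verbatim and surfaced rather than corrected. The package's own
arithmetic always uses the electron-inclusive constants above.

## Prototype matching

A plasma feature is matched to a decoction component by **formula equality**
plus RT agreement (default tolerance 0.5 min). The recorded ppm error is the
plasma observation against the matched formula at the plasma feature's own
adduct; it is *not* a gate in this route, because observed m/z values in
printed tables are sometimes truncated (one bundled plasma row is printed to
two decimals, a 21 ppm apparent error, yet is unambiguous by formula + RT).
An alternative route (`require_formula_equal=False`) matches by m/z within a
ppm tolerance (default 10 ppm) at the same adduct — this is the route whose
false-match behaviour is a pure tolerance property and it is exercised
against synthetic ground truth. When no candidate is found, exact
normalized-name identity (case-folded, hyphen/subscript-stripped) is
accepted and flagged: paired tables occasionally re-assign an isomer between
acquisition runs, so the same compound appears with an updated formula.
Among candidates, the best match minimizes (|ppm error|, |ΔRT|, name);
matching tolerances were chosen once so the bundled tables reproduce their
printed 30-prototype result, and the defaults are not adjusted thereafter.
Fragment-ion overlap (shared fragments within 0.01 Da) is recorded but not
used as a filter; no rule for it is established.

## Target mapping and disease sets

Similarity is the Tanimoto coefficient on equal-length bit vectors, defined
as 0 for two empty vectors; the mapping threshold is strict (> 0.60), and
the similarity function is pluggable because proprietary similarity engines
do not document their score. Associations transfer every annotated target of
a reference ligand scoring above threshold; duplicate (compound, target)
pairs keep the maximal similarity. Identifiers are normalized by upper-case
trimming only — no ortholog or synonym mapping. Disease lists from two
sources are unioned after normalization with per-identifier provenance.

## Network and hub screen

Edges at confidence ≤ 0.4 are dropped (strict >, following the STRING-style
rule), then isolated nodes are removed. Centralities: DC is the raw degree;
BC is Brandes betweenness normalized by 2/((n−1)(n−2)) for n ≥ 3 (0
otherwise); CC is Wasserman–Faust component-scaled closeness
(fraction-reachable × inverse mean within-component distance), so
small-component nodes cannot outrank giant-component ones — the choice
matters only for disconnected networks and is configurable by using any
other closeness in a custom `CentralityTriple` list.

Medians use the mean-of-middle-two rule for even counts (hence half-integer
cutoffs such as 20.5 on an even node count), and every cutoff is strict.
Stage-2 medians are computed over the stage-1 hub subset but from
centralities of the full network, not of an induced subgraph: re-screening
the surviving half against its own medians is what makes the second-stage
DC cutoff exceed the global median. With all-distinct degrees stage 1 keeps
exactly ⌊n/2⌋ nodes. Nodes labelled `none` (expansion interactors) remain
hub-eligible and are reported as a fourth partition bucket.

## Enrichment

The upper tail P(X ≥ k) of Hypergeometric(N, K, n) is summed in log-space
from lgamma-based binomial coefficients — exact, no normal or saddlepoint
approximation. Terms with zero hits are excluded from output and, by
default, from the BH denominator (DAVID-style "tested = hit terms");
`test_all_terms` includes them. The universe defaults to the analyzed
network's node set and is overridable. Results carry both the raw p < 0.05
flag and the BH-adjusted one. The EASE-style deflated score (k − 1) is a
documented possible extension, not implemented.

## Docking triage and assay metric

"Below −8 kcal/mol" is read inclusively (energy ≤ −8.0 counts), with a
`strict` flag for the exclusive reading. Score tables transcribed from
reports sometimes drop the sign; `assume_magnitude` (off by default)
interprets positive energies as magnitudes of negative ones. The
discrimination index is (t_novel − t_old)/(t_novel + t_old), undefined when
both times are zero.

## Synthetic data: what it emulates, and what it does not

The generators stand in for database-backed inputs that are proprietary,
versioned, or service-generated. Each consumes one dedicated RNG stream
derived from a single seed, so outputs are byte-reproducible and adding a
generator never perturbs another.

* **Interactome**: Barabási–Albert preferential attachment (scale-free,
  hub-dominated like real PPI data), default 300 nodes, m = 3. Edge
  confidences are Beta(4, 2), putting ≈9% of edges at or below the 0.4
  filter so the threshold is exercised non-trivially. A planted module of
  10 labelled nodes receives extra uniform-random edges until each reaches
  at least 3 × 2m = 18 neighbours — wired for high degree, betweenness and
  closeness. Origin labels: 60 drug targets, 40 disease targets, 8 shared.
* **Plasma tables**: 10 true features sampled from the component table
  (observed m/z = theoretical × (1 + ε), ε ~ N(0, 3 ppm) truncated at 3σ;
  RT jitter ≤ 0.05 min) plus 5 decoys rejection-sampled to lie > 3 × noise
  ppm from every theoretical adduct m/z, with formulas absent from the
  library. True features are sampled only among components with no
  same-formula neighbour within 1.0 min RT: co-eluting isobars (which the
  printed table contains) are not identifiable by any m/z + RT matcher, so
  id-level recovery is only meaningful for unambiguous picks. The 3σ
  truncation makes true/decoy separability exact at tolerances ≥ 3 × noise.
* **Fingerprints**: 256 bits at density 0.15; 60% of query compounds are
  2%-bit-flip copies of a dedicated annotated reference (similarity ≈ 0.9),
  the rest random (expected random-pair Tanimoto ≈ d/(2−d) ≈ 0.08, so
  spurious associations above 0.60 are effectively impossible).
* **Annotation library**: 50 terms of size 10–40 sampled uniformly from the
  universe; one planted term contains 10 major-hub members plus filler.
* **Docking scores**: Normal(−7, 1.5) kcal/mol, ≈ a quarter below −8.

The mass-noise default (3 ppm) reflects the magnitude of errors printed in
the bundled component table; it is a modelling choice, not a reported
instrument figure.

What passing on synthetic data does **not** show: the generators have no
fragmentation chemistry, no correlated RT/mass errors, no database
identifier semantics, no edge-confidence structure beyond an i.i.d. Beta,
and the planted hub module is wired more cleanly than any real drug–disease
module. Recovery results certify the screening arithmetic, not biological
validity of any particular database snapshot.

## Problem sizes and determinism

Default analyses run a 300-node interactome; planted-signal recovery is
evaluated over 20 seeds (hub recovery ≥ 90% aggregate, planted-term rank-1
in ≥ 95% of seeds, exact matching recovery). The centrality implementation
is verified against an exhaustive path-enumeration oracle on 200 random
graphs of ≤ 8 nodes, and the hypergeometric tail against complete draw
enumeration for all parameter combinations with N ≤ 12; null calibration
uses a 1200-gene universe, 41 terms of sizes 60–260 and 1000 random
120-gene queries, a design whose exact expected fraction of sub-0.05 terms
is 0.038 (the discrete tail is conservative, never anti-conservative).
Pipeline runs with one config are byte-identical, including the summary
JSON.

## Known limitations

* The similarity metric behind the 0.60 mapping threshold is unknowable for
  proprietary engines; Tanimoto is the field-standard stand-in and the
  function is pluggable.
* Name-fallback matching trusts compound nomenclature; homonyms in
  carelessly curated tables would produce flagged false matches.
* Closeness and betweenness use unweighted shortest paths; confidences act
  only as a filter, never as edge weights.
* Enrichment ignores annotation-graph structure (no GO is-a propagation).
* The printed compound tables are preserved verbatim, including a
  chemically impossible formula; the audit surfaces, never repairs.
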