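"""Hypergeometric over-representation analysis of gene sets.

For a query of n genes drawn from a universe of N genes, a term with K
members in the universe, and k query hits in the term, the enrichment
p-value is the upper tail P(X ≥ k) of Hypergeometric(N, K, n). The tail is
summed in log-space from lgamma-based binomial coefficients; no asymptotic
approximation is used. Benjamini–Hochberg adjusted p-values are reported
alongside the raw p < 0.05 rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable
import warnings

import pandas as pd

__all__ = [
    "AnnotationTerm",
    "EnrichmentResult",
    "hypergeom_test",
    "enrich",
    "bh_adjust",
    "read_gmt",
    "write_gmt",
    "results_frame",
]


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"term {self.term_id}: empty member set")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    description: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    p_adjusted: float
    fold_enrichment: float

    @property
    def significant_raw(self) -> bool:
        return self.p_value < 0.05

    @property
    def significant_adjusted(self) -> bool:
        return self.p_adjusted < 0.05


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X ≥ k) for X ~ Hypergeometric(N, K, n), exact."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid population: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"invalid hit count k={k} for K={K}, n={n}")
    if k == 0:
        return 1.0
    denom = _log_binom(N, n)
    logs = [_log_binom(K, j) + _log_binom(N - K, n - j) - denom
            for j in range(k, min(K, n) + 1)
            if n - j <= N - K]
    if not logs:
        return 0.0
    m = max(logs)
    return min(1.0, math.exp(m) * sum(math.exp(x - m) for x in logs))


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    for p in pvalues:
        if not (0 < p <= 1):
            raise ValueError(f"p-value out of (0, 1]: {p}")
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        running = min(running, pvalues[i] * m / rank_from_end)
        adj[i] = running
    return adj


def enrich(
    query: Iterable[str],
    library: Iterable[AnnotationTerm],
    universe: Iterable[str],
    test_all_terms: bool = False,
) -> list[EnrichmentResult]:
    """Test each term for over-representation of the query.

    Query identifiers outside the universe are dropped with a warning, as
    are term members outside the universe. Terms with zero hits are omitted
    from the output; they enter the BH denominator only when
    ``test_all_terms`` is set (the default mirrors DAVID, which tests only
    terms hit by the query). Results are sorted by ascending p-value, ties
    by term id.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    outside = q - uni
    if outside:
        warnings.warn(f"{len(outside)} query ids outside universe dropped")
        q &= uni
    n, N = len(q), len(uni)

    tested: list[tuple[AnnotationTerm, int, int]] = []
    for term in library:
        members = term.members & uni
        if len(members) < len(term.members):
            warnings.warn(f"term {term.term_id}: "
                          f"{len(term.members) - len(members)} members outside "
                          f"universe dropped")
        if not members:
            continue
        tested.append((term, len(q & members), len(members)))

    scored = [(t, k, K) for t, k, K in tested if k >= 1 or test_all_terms]
    pvals = [hypergeom_test(k, K, n, N) for _, k, K in scored]
    padj = bh_adjust(pvals) if pvals else []

    out = []
    for (term, k, K), p, pa in zip(scored, pvals, padj):
        if k < 1:
            continue
        fold = (k / n) / (K / N) if n else 0.0
        out.append(EnrichmentResult(term.term_id, term.description,
                                    k, K, n, N, p, pa, fold))
    return sorted(out, key=lambda r: (r.p_value, r.term_id))


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "term_id": r.term_id, "description": r.description,
        "k": r.k, "K": r.K, "n": r.n, "N": r.N,
        "fold_enrichment": r.fold_enrichment,
        "p_value": r.p_value, "p_adjusted": r.p_adjusted,
        "significant_raw": r.significant_raw,
        "significant_adjusted": r.significant_adjusted,
    } for r in results])


def read_gmt(path: str | Path) -> list[AnnotationTerm]:
    """Tab-delimited gene sets: term, description, member identifiers."""
    terms = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line needs >= 3 fields: {line[:60]!r}")
        terms.append(AnnotationTerm(parts[0], parts[1],
                                    frozenset(p for p in parts[2:] if p)))
    return terms


def write_gmt(terms: Iterable[AnnotationTerm], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.description, *sorted(t.members)]) + "\n")
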