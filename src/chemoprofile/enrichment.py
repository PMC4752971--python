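"""PPI-neighborhood annotation enrichment.

A protein's "complex" is approximated by its interaction neighborhood
(itself plus everything within ``depth`` hops, default 1). Each annotation
term (disease, pathway, GO) is tested for over-representation in that
neighborhood with the upper-tail hypergeometric test against a universe of
proteins (by default all nodes of the PPI network), and p-values are
corrected per annotation category with Benjamini-Hochberg (Bonferroni
available via ``method="bonferroni"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import AnnotationCategory, AnnotationSet, PpiNetwork


def to_graph(network: PpiNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from(network.to_pairs())
    return g


def neighborhood(protein: str, network: PpiNetwork, depth: int = 1) -> Set[str]:
    """The protein plus all nodes within ``depth`` hops.

    A protein absent from the network yields the singleton of itself.
    """
    g = to_graph(network)
    if protein not in g:
        return {protein}
    return set(nx.single_source_shortest_path_length(g, protein, cutoff=depth))


def hypergeom_p(overlap: int, set_size: int, neighborhood_size: int, universe_size: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    X counts annotation-set members in a draw of ``neighborhood_size``
    proteins from a universe containing ``set_size`` members.
    """
    if not (
        0 <= overlap <= min(set_size, neighborhood_size)
        and set_size <= universe_size
        and neighborhood_size <= universe_size
    ):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, set={set_size}, "
            f"neighborhood={neighborhood_size}, universe={universe_size}"
        )
    return float(hypergeom.sf(overlap - 1, universe_size, set_size, neighborhood_size))


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    category: AnnotationCategory
    overlap: int
    set_size: int
    neighborhood_size: int
    universe_size: int
    p_value: float
    p_adjusted: float


def enrich(
    neighborhood: Set[str],
    annotations: Sequence[AnnotationSet],
    universe: Set[str],
    method: str = "fdr_bh",
) -> List[EnrichmentResult]:
    """Test every annotation term against a neighborhood.

    Terms are restricted to the universe; one result per term with overlap
    >= 1; correction applied across all tested terms within each category;
    results sorted by (p_adjusted, p_value, term_id).
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not neighborhood <= universe:
        raise ValueError("neighborhood must be a subset of the universe")
    by_category: Dict[AnnotationCategory, List[AnnotationSet]] = {}
    for ann in annotations:
        by_category.setdefault(ann.category, []).append(ann)

    results: List[EnrichmentResult] = []
    for category, terms in by_category.items():
        tested = []
        pvals = []
        for term in terms:
            members = term.members & universe
            overlap = len(members & neighborhood)
            if not members or overlap < 1:
                continue
            p = hypergeom_p(overlap, len(members), len(neighborhood), len(universe))
            tested.append((term, overlap, len(members), p))
            pvals.append(p)
        if not tested:
            continue
        _, p_adj, _, _ = multipletests(pvals, method=method)
        for (term, overlap, set_size, p), adj in zip(tested, p_adj):
            results.append(
                EnrichmentResult(
                    term_id=term.term_id,
                    category=category,
                    overlap=overlap,
                    set_size=set_size,
                    neighborhood_size=len(neighborhood),
                    universe_size=len(universe),
                    p_value=p,
                    p_adjusted=float(adj),
                )
            )
    results.sort(key=lambda r: (r.p_adjusted, r.p_value, r.term_id))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "category": [r.category.value for r in results],
            "overlap": [r.overlap for r in results],
            "set_size": [r.set_size for r in results],
            "neighborhood_size": [r.neighborhood_size for r in results],
            "universe_size": [r.universe_size for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
        }
    )
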