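"""Building, propagating and filtering term-membership matrices.

Gene Ontology style annotations arrive as a direct gene-to-term table plus an
``is_a`` child-to-parent edge list. Propagation annotates every gene to all
ancestors of its direct terms (transitive closure over is_a), after which the
collection is restricted to terms of a useful size — small enough to be
functionally specific, large enough to aggregate signal. The screen-scale
default keeps terms with 4-200 annotated genes.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AnnotationMatrix
from .errors import AnnotationError

log = logging.getLogger(__name__)

#: Default term-size bounds applied after restriction to the gene universe.
DEFAULT_MIN_TERM_SIZE = 4
DEFAULT_MAX_TERM_SIZE = 200


def build_annotation_matrix(
    direct: pd.DataFrame,
    universe: Iterable[str],
    term_names: pd.Series | None = None,
) -> AnnotationMatrix:
    """Turn a two-column (gene_id, term_id) table into a binary matrix.

    Genes outside ``universe`` are dropped with a logged count; terms are kept
    even if all their members fall outside (size filtering is separate).
    """
    universe = pd.Index(dict.fromkeys(universe))
    gene_col, term_col = direct.columns[:2]
    inside = direct[gene_col].isin(set(universe))
    if (~inside).any():
        log.info("dropped %d direct annotations outside the gene universe",
                 int((~inside).sum()))
    terms = pd.Index(dict.fromkeys(direct[term_col]))
    membership = pd.DataFrame(0, index=universe, columns=terms, dtype=np.int8)
    kept = direct[inside]
    membership.values[
        universe.get_indexer(kept[gene_col]), terms.get_indexer(kept[term_col])
    ] = 1
    return AnnotationMatrix(membership, term_names)


def propagate_annotations(
    direct: pd.DataFrame, is_a_edges: pd.DataFrame
) -> pd.DataFrame:
    """Annotate each gene to every is_a ancestor of its direct terms.

    Parameters
    ----------
    direct
        Two columns, gene_id and term_id (one row per direct annotation).
    is_a_edges
        Two columns, child term id and parent term id; must form a DAG.

    Returns
    -------
    A two-column (gene_id, term_id) table containing the direct annotations
    plus one row per (gene, ancestor term). Deterministic order.
    """
    gene_col, term_col = direct.columns[:2]
    graph = nx.DiGraph()
    graph.add_nodes_from(direct[term_col].unique())
    graph.add_edges_from(is_a_edges.itertuples(index=False, name=None))
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise AnnotationError(f"is_a edges contain a cycle through {cycle[0][0]!r}")
    ancestors = {t: nx.descendants(graph, t) for t in graph.nodes}
    rows: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for gene, term in direct[[gene_col, term_col]].itertuples(index=False, name=None):
        for t in (term, *sorted(ancestors.get(term, ()))):
            if (gene, t) not in seen:
                seen.add((gene, t))
                rows.append((gene, t))
    return pd.DataFrame(rows, columns=[gene_col, term_col])


def filter_term_sizes(
    ann: AnnotationMatrix,
    min_size: int = DEFAULT_MIN_TERM_SIZE,
    max_size: int = DEFAULT_MAX_TERM_SIZE,
) -> AnnotationMatrix:
    """Keep terms whose size (within the current gene universe) is in bounds."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    sizes = ann.term_sizes
    keep = sizes.index[(sizes >= min_size) & (sizes <= max_size)]
    if len(keep) == 0:
        log.warning("term-size filter [%d, %d] removed every term", min_size, max_size)
    return AnnotationMatrix(ann.membership[keep], ann.term_names.reindex(keep))


def overlap_index(set_a: Iterable, set_b: Iterable) -> float:
    """Intersection size divided by the size of the smaller set."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("overlap_index is undefined for empty sets")
    return len(a & b) / min(len(a), len(b))
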