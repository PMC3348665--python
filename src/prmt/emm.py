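"""Environmental Metabolome Matrix (EMM) construction.

From a direction-expanded reaction catalog this module builds

1. the metabolite network (nodes = metabolites, edges = enzyme-catalyzed
   transformations, both directions kept for reversible reactions),
2. the raw connectivity matrix C (metabolites x enzyme functions,
   entry = #directed reactions of the enzyme producing the metabolite
   minus #consuming it), and
3. the EMM: C row-normalized so that inputs to a compound sum to 1 and
   outputs sum to -1.

Forward and reverse directions of a reversible reaction are summed into
the same column of C, so an enzyme all of whose reactions are reversible
has an identically-zero column. That cancellation happens in the RAW
counts, before normalization: it is what makes turnover scores exactly
invariant to the abundance of purely-reversible enzymes. The network
representation keeps both directed edges for topology and export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .reactions import DirectedReaction

logger = logging.getLogger(__name__)

#: absolute tolerance for the EMM row-sum invariant
EMM_ATOL = 1e-9


@dataclass
class MetabolicNetwork:
    """Metabolite graph; one edge per (directed reaction, substrate, product)."""

    nodes: set[str] = field(default_factory=set)
    #: (metabolite_a, metabolite_b, enzyme_id, direction) quadruples
    edges: list[tuple[str, str, str, str]] = field(default_factory=list)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for a, b, enzyme, direction in self.edges:
            g.add_edge(a, b, enzyme=enzyme, direction=direction)
        return g


@dataclass
class ComponentSummary:
    """Connected-component statistics of the undirected metabolite network."""

    #: (n_nodes, n_edges) per component, sorted descending
    sizes: list[tuple[int, int]] = field(default_factory=list)
    two_node_components: int = 0
    total_components: int = 0


def build_network(directed: list[DirectedReaction]) -> MetabolicNetwork:
    """Construct the metabolite network from directed reactions.

    Each (directed reaction, consumed metabolite, produced metabolite)
    pair contributes one edge; the node set is every metabolite
    mentioned on either side.
    """
    net = MetabolicNetwork()
    for dr in directed:
        net.nodes |= dr.consumed | dr.produced
        for a in sorted(dr.consumed):
            for b in sorted(dr.produced):
                net.edges.append((a, b, dr.enzyme_id, dr.direction))
    return net


def build_connectivity(
    directed: list[DirectedReaction],
    enzyme_universe: set[str] | None = None,
) -> pd.DataFrame:
    """Signed connectivity matrix: rows = metabolites, columns = enzymes.

    Entry (i, j) counts directed reactions of enzyme j producing
    metabolite i minus those consuming it, so the two directions of a
    reversible reaction cancel exactly. Enzymes in ``enzyme_universe``
    with no catalog reaction (annotation-only enzymes) get all-zero
    columns so downstream count vectors conform dimensionally.
    Row/column order is lexicographic for reproducible output.
    """
    enzymes = set(enzyme_universe or set())
    metabolites: set[str] = set()
    for dr in directed:
        enzymes.add(dr.enzyme_id)
        metabolites |= dr.consumed | dr.produced
    rows = sorted(metabolites)
    cols = sorted(enzymes)
    values = np.zeros((len(rows), len(cols)), dtype=np.int64)
    row_ix = {m: i for i, m in enumerate(rows)}
    col_ix = {e: j for j, e in enumerate(cols)}
    for dr in directed:
        j = col_ix[dr.enzyme_id]
        for m in dr.produced:
            values[row_ix[m], j] += 1
        for m in dr.consumed:
            values[row_ix[m], j] -= 1
    return pd.DataFrame(values, index=rows, columns=cols)


def normalize_emm(connectivity: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize connectivity into the EMM.

    Per metabolite row: positive entries are divided by the row's
    positive sum (inputs sum to 1) and negative entries by the absolute
    value of the row's negative sum (outputs sum to -1). Zeros are
    untouched and rows lacking one side normalize only the side present.
    Idempotent.
    """
    values = connectivity.to_numpy(dtype=float)
    pos = np.where(values > 0, values, 0.0)
    neg = np.where(values < 0, values, 0.0)
    pos_sum = pos.sum(axis=1, keepdims=True)
    neg_sum = -neg.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pos_n = np.divide(pos, pos_sum, out=np.zeros_like(pos), where=pos_sum > 0)
        neg_n = np.divide(neg, neg_sum, out=np.zeros_like(neg), where=neg_sum > 0)
    return pd.DataFrame(
        pos_n + neg_n, index=connectivity.index, columns=connectivity.columns
    )


def check_emm_invariant(emm: pd.DataFrame, atol: float = EMM_ATOL) -> float:
    """Max deviation of any non-zero-sided row sum from +1 / -1."""
    values = emm.to_numpy(dtype=float)
    pos_sum = np.where(values > 0, values, 0.0).sum(axis=1)
    neg_sum = np.where(values < 0, values, 0.0).sum(axis=1)
    err = 0.0
    for p, n in zip(pos_sum, neg_sum):
        if p > 0:
            err = max(err, abs(p - 1.0))
        if n < 0:
            err = max(err, abs(n + 1.0))
    if err > atol:
        logger.warning("EMM row-sum invariant violated: max error %.3g", err)
    return err


def connected_components(
    net: MetabolicNetwork, collapse_reversible: bool = True
) -> ComponentSummary:
    """Summarize connected components of the undirected projection.

    Edge counts are per component; with ``collapse_reversible`` the
    forward/reverse pair of a reversible transformation counts as one
    enzyme reaction (one unique (unordered pair, enzyme) combination),
    otherwise directed edges are counted as-is.
    """
    if not net.nodes:
        return ComponentSummary()
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((a, b) for a, b, _, _ in net.edges)
    sizes: list[tuple[int, int]] = []
    for comp in nx.connected_components(g):
        if collapse_reversible:
            uniq = {
                (frozenset((a, b)), enzyme)
                for a, b, enzyme, _ in net.edges
                if a in comp
            }
            n_edges = len(uniq)
        else:
            n_edges = sum(1 for a, _, _, _ in net.edges if a in comp)
        sizes.append((len(comp), n_edges))
    sizes.sort(reverse=True)
    return ComponentSummary(
        sizes=sizes,
        two_node_components=sum(1 for n, _ in sizes if n == 2),
        total_components=len(sizes),
    )


def metabolite_degree(emm: pd.DataFrame) -> pd.Series:
    """Number of enzymes with a non-zero EMM entry per metabolite.

    A turnover score is best read in the context of how connected the
    metabolite is; this degree column accompanies score exports.
    """
    return (emm != 0).sum(axis=1).astype(int)
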