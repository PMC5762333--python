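"""Subpathway mining: k-clique decomposition and lncRNA embedding.

A subpathway is a maximal set of pathway genes in which every pair lies
within unweighted shortest-path distance ``k`` (default 3) of each other
in the pathway graph. These sets are exactly the maximal cliques of the
auxiliary graph obtained by thresholding the all-pairs distance matrix
at ``k``. lncRNAs that competitively regulate at least one member gene
are then embedded as additional subpathway components, and small graphs
(fewer than 3 genes or fewer than 2 lncRNAs by default) are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from subspa.errors import InputError
from subspa.pathway_io import PathwayGraph, RegulationTable

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class SubpathwayGraph:
    """A gene subgraph plus its embedded lncRNA regulators.

    ``gene_edges`` are the parent-pathway edges induced on ``genes``;
    ``reg_edges`` are (lncrna, gene) regulation pairs with the gene
    inside the subpathway.
    """

    subpathway_id: str
    parent_id: str
    parent_name: str
    genes: frozenset
    lncrnas: frozenset
    gene_edges: frozenset = field(default_factory=frozenset)
    reg_edges: frozenset = field(default_factory=frozenset)

    @property
    def components(self) -> frozenset:
        """All measured-expression components: genes plus lncRNAs."""
        return self.genes | self.lncrnas

    def validate(self) -> None:
        for e in self.gene_edges:
            if len(e) != 2 or not e <= self.genes:
                raise InputError(
                    f"{self.subpathway_id}: gene edge {sorted(e)} not within gene set"
                )
        covered = set()
        for l, g in self.reg_edges:
            if g not in self.genes:
                raise InputError(
                    f"{self.subpathway_id}: regulation edge ({l},{g}) targets a non-member gene"
                )
            if l not in self.lncrnas:
                raise InputError(
                    f"{self.subpathway_id}: regulation edge ({l},{g}) from unknown lncRNA"
                )
            covered.add(l)
        if covered != set(self.lncrnas):
            orphan = sorted(set(self.lncrnas) - covered)
            raise InputError(
                f"{self.subpathway_id}: lncRNA(s) {orphan} have no regulation edge"
            )
        if self.genes & self.lncrnas:
            raise InputError(f"{self.subpathway_id}: gene/lncRNA namespaces overlap")


@dataclass(frozen=True)
class MiningConfig:
    """Mining thresholds: distance bound ``k`` and minimum component counts."""

    k: int = 3
    min_genes: int = 3
    min_lncrnas: int = 2

    def __post_init__(self):
        if self.k < 1:
            raise InputError(f"k must be >= 1, got {self.k}")
        if self.min_genes < 1 or self.min_lncrnas < 0:
            raise InputError("min_genes must be >= 1 and min_lncrnas >= 0")


def mine_subpathways(pathway: PathwayGraph, k: int = 3) -> list:
    """Enumerate maximal gene sets with pairwise distance <= k.

    Returns frozensets ordered by descending size, then by sorted member
    list, so ordinal ids assigned from this list are stable across runs
    and input orderings. Components of a disconnected pathway are handled
    independently (cross-component distances are infinite).
    """
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    g = pathway.graph
    if g.number_of_nodes() == 0:
        return []
    aux = nx.Graph()
    aux.add_nodes_from(g.nodes)
    for source, dists in nx.all_pairs_shortest_path_length(g, cutoff=k):
        for target, d in dists.items():
            if source != target and d <= k:
                aux.add_edge(source, target)
    sets = {frozenset(c) for c in nx.find_cliques(aux)}
    return sorted(sets, key=lambda s: (-len(s), sorted(s)))


def embed_lncrnas(genes: frozenset, regs: RegulationTable) -> tuple:
    """Embed every lncRNA regulating >= 1 gene of the set.

    Returns ``(lncrna_set, reg_edge_set)`` where the edge set holds
    exactly the regulation pairs whose gene lies inside ``genes``.
    """
    genes = frozenset(genes)
    reg_edges = frozenset(p for p in regs.pairs if p[1] in genes)
    lncrnas = frozenset(p[0] for p in reg_edges)
    return lncrnas, reg_edges


def filter_subpathways(candidates: list, config: MiningConfig | None = None) -> list:
    """Keep subpathways with enough genes AND enough embedded lncRNAs."""
    config = config or MiningConfig()
    kept, few_genes, few_lncs = [], 0, 0
    for sub in candidates:
        if len(sub.genes) < config.min_genes:
            few_genes += 1
        elif len(sub.lncrnas) < config.min_lncrnas:
            few_lncs += 1
        else:
            kept.append(sub)
    logger.info(
        "filter: kept %d of %d subpathways (%d with < %d genes, %d with < %d lncRNAs)",
        len(kept), len(candidates), few_genes, config.min_genes,
        few_lncs, config.min_lncrnas,
    )
    return kept


def _induced_edges(pathway: PathwayGraph, genes: frozenset) -> frozenset:
    return frozenset(
        frozenset((u, v)) for u, v in pathway.graph.edges if u in genes and v in genes
    )


def build_subpathways(
    pathway: PathwayGraph,
    regs: RegulationTable,
    config: MiningConfig | None = None,
) -> list:
    """Mine, embed and filter: the full reconstruction for one pathway.

    Ordinals are assigned over the mined candidate list (size-descending,
    then lexicographic), before size filtering, so an id never changes
    when filter thresholds do; filtered results may therefore have gaps
    in their ordinal sequence.
    """
    config = config or MiningConfig()
    candidates = []
    for ordinal, genes in enumerate(mine_subpathways(pathway, config.k), start=1):
        lncrnas, reg_edges = embed_lncrnas(genes, regs)
        sub = SubpathwayGraph(
            subpathway_id=f"{pathway.pathway_id}_{ordinal}",
            parent_id=pathway.pathway_id,
            parent_name=pathway.name,
            genes=frozenset(genes),
            lncrnas=lncrnas,
            gene_edges=_induced_edges(pathway, frozenset(genes)),
            reg_edges=reg_edges,
        )
        sub.validate()
        candidates.append(sub)
    return filter_subpathways(candidates, config)


def reconstruct_pathway_graph(pathway: PathwayGraph, regs: RegulationTable) -> SubpathwayGraph:
    """Entire-pathway counterpart: one graph holding all pathway genes.

    Used for pathway-level vs subpathway-level activity comparison; the
    size filter does not apply, so the lncRNA set may be empty.
    """
    genes = frozenset(pathway.graph.nodes)
    lncrnas, reg_edges = embed_lncrnas(genes, regs)
    sub = SubpathwayGraph(
        subpathway_id=f"{pathway.pathway_id}_whole",
        parent_id=pathway.pathway_id,
        parent_name=pathway.name,
        genes=genes,
        lncrnas=lncrnas,
        gene_edges=frozenset(frozenset(e) for e in pathway.graph.edges),
        reg_edges=reg_edges,
    )
    sub.validate()
    return sub
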