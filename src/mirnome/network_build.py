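"""Assembly of the gene network from filtered target and interaction tables.

The network is the interaction graph *over target genes*: its node set is
every distinct gene appearing in the (score-filtered) miRNA→target table,
and its edges are the (confidence-filtered) interactions whose endpoints
are both target genes. miRNAs themselves are not nodes; they are carried
as per-gene provenance. Target genes with no retained interaction remain
as isolated nodes, which is what fragments the full network into many
single-node components while one large main component concentrates the
connectivity.

Gene identifiers are matched case-insensitively; the first-seen
capitalization is the one preserved in output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .data_io import InteractionRecord, TargetRecord


@dataclass
class GeneNetwork:
    """Undirected simple graph over gene identifiers.

    ``provenance`` maps each gene to the set of miRNAs that target it;
    ``label`` names the network (e.g. ``MiRNome``, ``MiRNome_MC``).
    No self-loops, no duplicate edges, isolated nodes permitted.
    """

    graph: nx.Graph
    provenance: dict[str, frozenset[str]] = field(default_factory=dict)
    label: str = "network"

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def induced(self, nodes: set[str], label: str | None = None) -> "GeneNetwork":
        """Induced subgraph on ``nodes``, provenance restricted accordingly."""
        sub = self.graph.subgraph(nodes).copy()
        return GeneNetwork(
            graph=sub,
            provenance={g: m for g, m in self.provenance.items() if g in nodes},
            label=label if label is not None else self.label,
        )


@dataclass
class ComponentDecomposition:
    """Connected components, largest first (ties: lexicographic smallest member)."""

    components: list[frozenset[str]]
    index: dict[str, int]

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]

    def __len__(self) -> int:
        return len(self.components)


def assemble_network(
    targets: list[TargetRecord],
    interactions: list[InteractionRecord],
    label: str = "MiRNome",
    bipartite: bool = False,
) -> GeneNetwork:
    """Build the gene network from pre-filtered target and interaction records.

    Node set = distinct target genes; edge set = interactions with both
    endpoints in the node set (self-loops dropped, duplicates collapsed).
    With ``bipartite=True`` miRNAs are added as nodes with miRNA→gene edges
    (exploratory mode; the gene-only graph is the analysis default).
    """
    if not targets:
        raise ValueError("no nodes: target list is empty")

    canon: dict[str, str] = {}

    def canon_id(name: str) -> str:
        return canon.setdefault(name.casefold(), name)

    g = nx.Graph()
    provenance: dict[str, set[str]] = {}
    for rec in targets:
        gene = canon_id(rec.gene_id)
        g.add_node(gene)
        provenance.setdefault(gene, set()).add(rec.mirna_id)

    gene_keys = set(canon)  # casefolded target genes
    for rec in interactions:
        ka, kb = rec.gene_a.casefold(), rec.gene_b.casefold()
        if ka == kb:
            continue  # self-loop
        if ka in gene_keys and kb in gene_keys:
            g.add_edge(canon[ka], canon[kb])

    if bipartite:
        for rec in targets:
            mirna = canon_id(rec.mirna_id)
            g.add_node(mirna)
            g.add_edge(mirna, canon[rec.gene_id.casefold()])

    return GeneNetwork(
        graph=g,
        provenance={k: frozenset(v) for k, v in provenance.items()},
        label=label,
    )


def connected_components(network: GeneNetwork) -> ComponentDecomposition:
    """Decompose into connected components with a deterministic ordering."""
    comps = [frozenset(c) for c in nx.connected_components(network.graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    index = {node: i for i, comp in enumerate(comps) for node in comp}
    return ComponentDecomposition(components=comps, index=index)


def main_component(network: GeneNetwork) -> tuple[GeneNetwork, float]:
    """Extract the largest connected component and its node percentage.

    Returns the induced subgraph (label suffixed ``_MC``) and
    ``100 * |MC| / |N|`` at full precision (display rounding is the
    report writer's concern). Size ties break toward the component holding
    the lexicographically smallest member.
    """
    if network.n_nodes == 0:
        raise ValueError("cannot extract the main component of an empty network")
    decomp = connected_components(network)
    mc_nodes = set(decomp.components[0])
    mc = network.induced(mc_nodes, label=f"{network.label}_MC")
    fraction = 100.0 * len(mc_nodes) / network.n_nodes
    return mc, fraction
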