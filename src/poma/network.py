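"""Bipartite miRNA-mRNA regulatory networks: reference build and disease trim.

The reference network is the union of all merged interaction records, one
directed edge per distinct (miRNA, gene) pair. The disease-specific network
restricts the gene side to differentially expressed genes ("unaltered mRNAs
are trimmed") and then prunes miRNAs left without any target, so every node
in either network has degree >= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .io import GeneSet, InteractionSet, ValidationError, normalize_gene, normalize_mirna

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryNetwork",
    "build_reference_network",
    "build_specific_network",
    "targets",
    "write_network",
    "read_network",
]

REFERENCE = "reference"
DISEASE_SPECIFIC = "disease_specific"


@dataclass
class RegulatoryNetwork:
    """Directed bipartite graph of miRNA -> gene regulation edges.

    ``graph`` is a networkx DiGraph whose nodes carry a ``kind`` attribute
    ("mirna" or "gene") and whose edges carry the unioned source tags.
    """

    graph: nx.DiGraph
    kind: str = REFERENCE

    def __post_init__(self) -> None:
        for u, v in self.graph.edges():
            if self.graph.nodes[u]["kind"] != "mirna" or self.graph.nodes[v]["kind"] != "gene":
                raise ValidationError(f"non-bipartite edge {u} -> {v}")
        isolated = [n for n in self.graph.nodes if self.graph.degree(n) == 0]
        if isolated:
            raise ValidationError(f"isolated nodes: {isolated[:5]}")

    @property
    def mirna_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "mirna"}

    @property
    def gene_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "gene"}

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    def summary(self) -> str:
        return (
            f"{len(self.mirna_nodes)} miRNAs, {len(self.gene_nodes)} genes, "
            f"{self.graph.number_of_edges()} edges ({self.kind})"
        )


def _graph_from_pairs(pairs, sources=None) -> nx.DiGraph:
    g = nx.DiGraph()
    for i, (m, t) in enumerate(pairs):
        g.add_node(m, kind="mirna")
        g.add_node(t, kind="gene")
        tags = sources[i] if sources is not None else frozenset()
        g.add_edge(m, t, sources=tags)
    return g


def build_reference_network(interactions: InteractionSet) -> RegulatoryNetwork:
    """Build the reference network: one edge per distinct interaction pair."""
    g = _graph_from_pairs(interactions.pairs(), list(interactions.records["sources"]))
    net = RegulatoryNetwork(g, kind=REFERENCE)
    logger.info("reference network: %s", net.summary())
    return net


def build_specific_network(reference: RegulatoryNetwork, de_genes: GeneSet) -> RegulatoryNetwork:
    """Trim the reference network to DE genes; prune target-less miRNAs.

    Gene nodes are restricted to ``reference.gene_nodes & de_genes`` (DE
    genes absent from the reference cannot contribute edges and are ignored
    with a logged count); miRNAs whose every target was trimmed are removed.
    """
    if reference.kind != REFERENCE:
        raise ValidationError("build_specific_network expects a reference-kind network")
    ref_genes = reference.gene_nodes
    kept_genes = ref_genes & set(de_genes.members)
    n_unmapped = len(de_genes.members) - len(kept_genes)
    if n_unmapped:
        logger.info("%d DE gene(s) not present in the reference network", n_unmapped)
    if not kept_genes:
        raise ValidationError(
            f"no DE genes map onto the reference network "
            f"({len(de_genes.members)} DE genes vs {len(ref_genes)} network genes)"
        )
    sub = nx.DiGraph()
    for m, t, data in reference.graph.edges(data=True):
        if t in kept_genes:
            sub.add_node(m, kind="mirna")
            sub.add_node(t, kind="gene")
            sub.add_edge(m, t, **data)
    net = RegulatoryNetwork(sub, kind=DISEASE_SPECIFIC)
    logger.info("disease-specific network: %s", net.summary())
    return net


def targets(network: RegulatoryNetwork, mirna: str) -> GeneSet:
    """Target genes of ``mirna`` in ``network`` as a GeneSet."""
    if mirna not in network.graph or network.graph.nodes[mirna]["kind"] != "mirna":
        raise KeyError(f"miRNA '{mirna}' not in {network.kind} network")
    return GeneSet(f"targets({mirna})", frozenset(network.graph.successors(mirna)))


def write_network(network: RegulatoryNetwork, path: str | Path) -> None:
    """Export as a sorted SIF-style edge list with a kind header comment."""
    with open(Path(path), "w") as fh:
        fh.write(f"# kind: {network.kind}\n")
        fh.write(f"# {network.summary()}\n")
        for m, t in sorted(network.graph.edges()):
            fh.write(f"{m}\ttargets\t{t}\n")


def read_network(path: str | Path) -> RegulatoryNetwork:
    """Read an edge list written by :func:`write_network`."""
    kind = REFERENCE
    pairs: list[tuple[str, str]] = []
    with open(Path(path)) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# kind:"):
                kind = line.split(":", 1)[1].strip()
                continue
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 or fields[1] != "targets":
                raise ValidationError(f"{path}: malformed edge line: {line!r}")
            pairs.append((normalize_mirna(fields[0]), normalize_gene(fields[2])))
    if not pairs:
        raise ValidationError(f"{path}: no edges")
    return RegulatoryNetwork(_graph_from_pairs(pairs), kind=kind)
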