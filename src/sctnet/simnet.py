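"""Synthetic ground-truth eQTL network generation.

Networks are DAGs over two node classes: genomic loci (head nodes, no
parents) and transcripts.  Construction proceeds in two steps.  Step 1
grows a forest of trees, one rooted at each locus, by attaching every
transcript to a uniformly chosen current leaf of a uniformly chosen locus
tree (the bare locus counts as the initial leaf).  Leaf attachment grows
deep branching trees; uniform attachment over *all* tree nodes was also
evaluated but produces far shallower trees in which fewer than half of the
transcripts descend from two or more loci, well short of the >=60%
characteristic of real segregant panels that this generator emulates.
Step 2 adds extra transcript-to-transcript edges, each classified as
inter-loci (endpoints in different Step-1 trees) with a configurable
probability and as feed-forward (ancestor to descendant within one tree)
otherwise.  The default classification probability of 0.9 yields the
target 9:1 inter-loci : feed-forward ratio, which produces networks where
a majority of transcripts are downstream of two or more loci.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "GeneNetwork",
    "NetGenConfig",
    "generate_network",
    "transcript_locus_distribution",
    "write_edge_list",
    "read_edge_list",
]

#: attempts per Step-2 edge before an over-constrained config is reported
MAX_EDGE_ATTEMPTS = 1000


@dataclass
class NetGenConfig:
    """Configuration for the two-step network generator.

    Defaults reproduce the published synthetic system: 2,200 transcripts,
    50 loci and 2,598 edges in total (2,200 Step-1 tree edges plus 398
    Step-2 edges).
    """

    n_transcripts: int = 2200
    n_loci: int = 50
    n_extra_edges: int = 398
    inter_loci_fraction: float = 0.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 0:
            raise ValueError("n_transcripts must be >= 0")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_extra_edges < 0:
            raise ValueError("n_extra_edges must be >= 0")
        if not 0.0 <= self.inter_loci_fraction <= 1.0:
            raise ValueError("inter_loci_fraction must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NetGenConfig":
        return cls(**json.loads(text))


@dataclass
class GeneNetwork:
    """Ground-truth DAG over loci and transcripts.

    ``locus_of_tree`` records which locus-rooted Step-1 tree each transcript
    was grown in; Step-2 edges never change tree membership.
    """

    loci: list[str]
    transcripts: list[str]
    edges: set[tuple[str, str]]
    locus_of_tree: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return self.loci + self.transcripts

    def to_digraph(self) -> nx.DiGraph:
        # sorted insertion keeps downstream traversal orders independent of
        # the process's string-hash seed
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(sorted(self.edges))
        return g

    def parents_of(self) -> dict[str, list[str]]:
        """Mapping child -> sorted list of parents (loci and transcripts)."""
        out: dict[str, list[str]] = {n: [] for n in self.nodes}
        for p, c in sorted(self.edges):
            out[c].append(p)
        return out

    def validate(self) -> None:
        g = self.to_digraph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("network contains a cycle")
        for locus in self.loci:
            if g.in_degree(locus) != 0:
                raise ValueError(f"locus {locus} has parents; loci must be head nodes")
        for t in self.transcripts:
            if g.in_degree(t) < 1:
                raise ValueError(f"transcript {t} has no parents")
        for p, c in self.edges:
            if p == c:
                raise ValueError(f"self edge on {p}")


def _locus_names(n: int) -> list[str]:
    return [f"L{i + 1}" for i in range(n)]


def _transcript_names(n: int) -> list[str]:
    return [f"T{j + 1}" for j in range(n)]


def generate_network(config: NetGenConfig) -> GeneNetwork:
    """Generate a ground-truth network by the two-step recipe.

    Returns a DAG with ``n_transcripts + n_loci`` nodes and exactly
    ``n_transcripts + n_extra_edges`` edges.  Raises ``RuntimeError`` when a
    Step-2 edge cannot be placed without creating a cycle or duplicate after
    ``MAX_EDGE_ATTEMPTS`` rejections.
    """
    rng = np.random.default_rng(config.rng_seed)
    loci = _locus_names(config.n_loci)
    transcripts = _transcript_names(config.n_transcripts)

    g = nx.DiGraph()
    g.add_nodes_from(loci)
    g.add_nodes_from(transcripts)

    # Step 1: forest of locus-rooted trees.  Transcripts are attached in a
    # random order, each to a uniformly chosen current leaf of the chosen
    # tree; the chosen leaf becomes internal.
    tree_leaves: dict[str, list[str]] = {l: [l] for l in loci}
    locus_of_tree: dict[str, str] = {}
    order = rng.permutation(config.n_transcripts)
    for idx in order:
        t = transcripts[idx]
        locus = loci[rng.integers(config.n_loci)]
        leaves = tree_leaves[locus]
        pick = int(rng.integers(len(leaves)))
        parent = leaves[pick]
        g.add_edge(parent, t)
        # replace the consumed leaf in place to keep the pool compact
        leaves[pick] = leaves[-1]
        leaves[-1] = t
        locus_of_tree[t] = locus

    # Step 2: extra transcript->transcript edges.
    for _ in range(config.n_extra_edges):
        inter = rng.random() < config.inter_loci_fraction
        placed = False
        for _attempt in range(MAX_EDGE_ATTEMPTS):
            if inter:
                edge = _propose_inter_loci(rng, transcripts, locus_of_tree, g)
            else:
                edge = _propose_feed_forward(rng, transcripts, locus_of_tree, g)
            if edge is not None:
                g.add_edge(*edge)
                placed = True
                break
        if not placed:
            kind = "inter-loci" if inter else "feed-forward"
            raise RuntimeError(
                f"could not place a {kind} edge after {MAX_EDGE_ATTEMPTS} attempts; "
                "config is over-constrained"
            )

    net = GeneNetwork(loci=loci, transcripts=transcripts, edges=set(g.edges()), locus_of_tree=locus_of_tree)
    net.validate()
    return net


def _propose_inter_loci(rng, transcripts, locus_of_tree, g) -> tuple[str, str] | None:
    if len(transcripts) < 2:
        return None
    i, j = rng.integers(len(transcripts), size=2)
    if i == j:
        return None
    a, b = transcripts[i], transcripts[j]
    if locus_of_tree[a] == locus_of_tree[b]:
        return None
    if g.has_edge(a, b):
        return None
    if nx.has_path(g, b, a):  # would close a cycle
        return None
    return a, b


def _propose_feed_forward(rng, transcripts, locus_of_tree, g) -> tuple[str, str] | None:
    if not transcripts:
        return None
    a = transcripts[rng.integers(len(transcripts))]
    tree = locus_of_tree[a]
    desc = [
        d
        for d in nx.descendants(g, a)
        if locus_of_tree.get(d) == tree and not g.has_edge(a, d)
    ]
    if not desc:
        return None
    desc.sort()
    return a, desc[rng.integers(len(desc))]


def transcript_locus_distribution(network: GeneNetwork) -> dict[int, int]:
    """Histogram of per-transcript ancestor-locus counts.

    For each transcript, counts the loci from which it is reachable by a
    directed path; returns ``{n_loci_reaching: n_transcripts}`` summing to
    the number of transcripts.
    """
    g = network.to_digraph()
    counts = dict.fromkeys(network.transcripts, 0)
    for locus in network.loci:
        for node in nx.descendants(g, locus):
            if node in counts:
                counts[node] += 1
    hist: dict[int, int] = {}
    for c in counts.values():
        hist[c] = hist.get(c, 0) + 1
    return hist


def fraction_multi_locus(network: GeneNetwork, min_loci: int = 2) -> float:
    """Fraction of transcripts reachable from at least ``min_loci`` loci."""
    hist = transcript_locus_distribution(network)
    total = sum(hist.values())
    if total == 0:
        return 0.0
    return sum(n for k, n in hist.items() if k >= min_loci) / total


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    """Write the network as a two-column tab-separated edge list."""
    with open(path, "w") as fh:
        fh.write("parent\tchild\n")
        for p, c in sorted(network.edges):
            fh.write(f"{p}\t{c}\n")


def read_edge_list(path: str | Path) -> GeneNetwork:
    """Read a network written by :func:`write_edge_list`.

    Node class is recovered from the name prefix ("L" locus, "T" transcript);
    ``locus_of_tree`` is rebuilt as the first locus reaching each transcript
    and is therefore only meaningful for freshly generated forests.
    """
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            p, c = line.split()
            edges.add((p, c))
            nodes.update((p, c))
    loci = sorted((n for n in nodes if n.startswith("L")), key=lambda s: int(s[1:]))
    transcripts = sorted((n for n in nodes if n.startswith("T")), key=lambda s: int(s[1:]))
    net = GeneNetwork(loci=loci, transcripts=transcripts, edges=edges)
    g = net.to_digraph()
    for locus in loci:
        for d in nx.descendants(g, locus):
            net.locus_of_tree.setdefault(d, locus)
    return net
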