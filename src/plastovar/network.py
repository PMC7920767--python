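"""Haplotype collapsing and statistical-parsimony (TCS-style) networks.

Individuals sharing an allele vector over the variant sites collapse
into one haplotype.  Haplotypes are then connected agglomeratively in
order of increasing absolute pairwise distance; a pair at distance d is
joined through d-1 inferred intermediate nodes, but only while d does
not exceed the parsimony connection limit.  The limit is the largest
number of mutational steps for which the probability that no two of
them struck the same aligned site (no superimposed change) still
reaches ``alpha`` — the quantity classical statistical parsimony bounds
at 95%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .types import Haplotype, VariantSite


def collapse_haplotypes(
    sites: list[VariantSite],
    regions: dict[str, str] | None = None,
    include_indels: bool = False,
    exclude: set[str] = frozenset(),
) -> list[Haplotype]:
    """Collapse individuals into unique allele-vector haplotypes.

    SNP sites only by default (``include_indels`` adds InDels, matching
    the optional distance mode); homopolymer sites are never used.
    Individuals missing an allele at any used site are excluded with a
    warning.  Ids are deterministic: H1, H2, ... in order of each
    haplotype's first member (members sorted lexicographically).
    """
    import warnings

    classes = {"SNP"} | ({"InDel"} if include_indels else set())
    used = [s for s in sites if s.var_class in classes and not s.ambiguous]
    individuals = sorted({g for s in used for g in s.alleles} - set(exclude))
    complete = []
    for ind in individuals:
        if all(ind in s.alleles for s in used):
            complete.append(ind)
        else:
            warnings.warn(f"{ind}: missing alleles, excluded from haplotyping")
    vectors: dict[tuple, list[str]] = {}
    for ind in complete:
        vec = tuple(s.alleles[ind] for s in used)
        vectors.setdefault(vec, []).append(ind)
    ordered = sorted(vectors.items(), key=lambda kv: sorted(kv[1])[0])
    out = []
    for i, (vec, members) in enumerate(ordered, start=1):
        members = sorted(members)
        out.append(
            Haplotype(
                id=f"H{i}",
                alleles=vec,
                members=members,
                regions=[(regions or {}).get(m, "") for m in members],
            )
        )
    return out


def haplotype_distances(haplotypes: list[Haplotype]) -> pd.DataFrame:
    """Absolute count of differing alleles between haplotype vectors."""
    ids = [h.id for h in haplotypes]
    mat = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i, a in enumerate(haplotypes):
        for b in haplotypes[i + 1:]:
            d = sum(x != y for x, y in zip(a.alleles, b.alleles))
            mat.loc[a.id, b.id] = d
            mat.loc[b.id, a.id] = d
    return mat


def parsimony_probability(j: int, aligned_length: int) -> float:
    """Probability that j mutational steps between two sequences of
    ``aligned_length`` sites all struck distinct sites, under uniform
    per-site mutation: prod_{i=1..j} (1 - i/L)."""
    if j < 0 or aligned_length < 2:
        raise ValueError("need j >= 0 and aligned_length >= 2")
    if j >= aligned_length:
        return 0.0
    # log-sum for numerical robustness at large L
    return math.exp(sum(math.log1p(-i / aligned_length) for i in range(1, j + 1)))


def connection_limit(aligned_length: int, alpha: float = 0.95) -> int:
    """Largest number of steps whose parsimony probability is >= alpha;
    monotone non-decreasing in ``aligned_length``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if aligned_length < 2:
        raise ValueError("aligned_length must be >= 2")
    j = 0
    while parsimony_probability(j + 1, aligned_length) >= alpha:
        j += 1
    return j


@dataclass
class ParsimonyNetwork:
    """Haplotype graph with inferred intermediates.

    Observed haplotypes are nodes with ``kind='observed'``; inferred
    intermediates (``kind='intermediate'``) subdivide each join so every
    edge is a single mutational step.
    """

    graph: nx.Graph
    limit: int
    alpha: float = 0.95
    haplotypes: list[Haplotype] = field(default_factory=list)

    @property
    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "observed"]


def build_tcs_network(
    haplotypes: list[Haplotype],
    distances: pd.DataFrame,
    limit: int,
    alpha: float = 0.95,
) -> ParsimonyNetwork:
    """Agglomerative statistical-parsimony network.

    Pairs are visited in order of (distance, lexicographic id pair);
    a pair in different components at distance d <= limit is joined via
    d-1 intermediates.  Pairs beyond the limit stay disconnected.
    """
    g = nx.Graph()
    for h in haplotypes:
        g.add_node(h.id, kind="observed", size=len(h.members), members=h.members, regions=h.regions)
    pairs = []
    ids = [h.id for h in haplotypes]
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            pairs.append((int(distances.loc[a, b]), *sorted((a, b))))
    pairs.sort()
    n_inter = 0
    for d, a, b in pairs:
        if d > limit:
            continue
        if nx.has_path(g, a, b):
            continue
        prev = a
        for _ in range(d - 1):
            n_inter += 1
            node = f"i{n_inter}"
            g.add_node(node, kind="intermediate", size=0)
            g.add_edge(prev, node, steps=1)
            prev = node
        g.add_edge(prev, b, steps=1)
    return ParsimonyNetwork(graph=g, limit=limit, alpha=alpha, haplotypes=haplotypes)


# ---------------------------------------------------------------------------
# export / import


def export_network(network: ParsimonyNetwork, path, fmt: str = "tsv") -> None:
    """Write the network as a TSV edge list, GML, or a PopART-style
    NEXUS with a Network block."""
    g = network.graph
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tsteps\n")
            for a, b, d in sorted(g.edges(data=True)):
                fh.write(f"{a}\t{b}\t{d.get('steps', 1)}\n")
            for n in sorted(nx.isolates(g)):
                fh.write(f"{n}\t\t0\n")
    elif fmt == "gml":
        h = nx.Graph()
        for n, d in g.nodes(data=True):
            h.add_node(n, kind=d.get("kind", ""), size=int(d.get("size", 0)))
        for a, b, d in g.edges(data=True):
            h.add_edge(a, b, steps=int(d.get("steps", 1)))
        nx.write_gml(h, str(path))
    elif fmt == "nexus":
        with open(path, "w") as fh:
            nodes = sorted(g.nodes)
            fh.write("#NEXUS\n\nBEGIN TAXA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(nodes)};\n  TAXLABELS\n")
            for n in nodes:
                fh.write(f"    {n}\n")
            fh.write("  ;\nEND;\n\nBEGIN NETWORK;\n")
            fh.write(f"  DIMENSIONS NVERTICES={len(nodes)} NEDGES={g.number_of_edges()};\n")
            fh.write("  VERTICES\n")
            for i, n in enumerate(nodes, 1):
                kind = g.nodes[n].get("kind", "observed")
                fh.write(f"    {i} {n} [{kind}]\n")
            fh.write("  ;\n  EDGES\n")
            idx = {n: i for i, n in enumerate(nodes, 1)}
            for k, (a, b) in enumerate(sorted(g.edges), 1):
                fh.write(f"    {k} {idx[a]} {idx[b]}\n")
            fh.write("  ;\nEND;\n")
    else:
        raise ValueError(f"unknown network format: {fmt}")


def import_network(path, fmt: str = "tsv") -> nx.Graph:
    """Re-read an exported network (nodes + edges; attributes as written)."""
    if fmt == "tsv":
        g = nx.Graph()
        with open(path) as fh:
            next(fh)
            for line in fh:
                a, b, steps = line.rstrip("\n").split("\t")
                if b:
                    g.add_edge(a, b, steps=int(steps))
                else:
                    g.add_node(a)
        return g
    if fmt == "gml":
        return nx.read_gml(str(path))
    if fmt == "nexus":
        g = nx.Graph()
        names = {}
        section = None
        with open(path) as fh:
            for line in fh:
                token = line.strip()
                if token.upper().startswith("VERTICES"):
                    section = "v"
                    continue
                if token.upper().startswith("EDGES"):
                    section = "e"
                    continue
                if token == ";":
                    section = None
                    continue
                if section == "v":
                    parts = token.split()
                    names[parts[0]] = parts[1]
                    g.add_node(parts[1], kind=parts[2].strip("[]") if len(parts) > 2 else "")
                elif section == "e":
                    _k, i, jj = token.split()
                    g.add_edge(names[i], names[jj])
        return g
    raise ValueError(f"unknown network format: {fmt}")
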