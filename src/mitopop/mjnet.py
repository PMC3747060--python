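"""Haplotype condensation and median-joining network construction.

Identical sequences (over segregating characters, after site masking)
are condensed into haplotypes with multiplicities and per-population
counts. The median-joining algorithm then connects them: starting from
the minimum spanning network (all edges co-minimal with a minimum
spanning tree, relaxed by an integer ``epsilon``), consensus median
(Steiner) vectors of linked triplets are added whenever they shorten the
local connection, the network is rebuilt, and the process repeats to
convergence; median vectors that end up with degree < 3 are pruned.

Characters are segregating substitution columns plus indel
presence/absence coded as a substitution-like character (so a shared
insertion with two alleles separates its carriers), all equally
weighted. With ``epsilon = 0`` the result contains the minimum spanning
network over its final node set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import networkx as nx

from .popgen import PopulationSet
from .refvar import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    ReferenceGenome,
    VariantProfile,
)


class ConvergenceError(RuntimeError):
    """Raised when median addition fails to converge within the round cap."""


@dataclass
class Haplotype:
    """A condensed haplotype over the segregating characters.

    Sampled haplotypes carry ``multiplicity >= 1`` (the number of input
    samples sharing the state vector) and per-population counts; median
    vectors are unsampled inferred nodes with multiplicity 0.
    """

    id: str
    vector: tuple[str, ...]
    multiplicity: int
    population_counts: dict[str, int] = field(default_factory=dict)
    sample_ids: tuple[str, ...] = ()
    median: bool = False

    def __post_init__(self) -> None:
        if self.median:
            if self.multiplicity != 0:
                raise ValueError("median vectors must have multiplicity 0")
        else:
            if self.multiplicity < 1:
                raise ValueError("sampled haplotypes must have multiplicity >= 1")
            if sum(self.population_counts.values()) != self.multiplicity:
                raise ValueError("population counts must sum to the multiplicity")


@dataclass
class HaplotypeNetwork:
    """Nodes (sampled + median vectors), weighted edges, and epsilon."""

    nodes: list[Haplotype]
    edges: list[tuple[str, str, int]]
    epsilon: int

    def node(self, node_id: str) -> Haplotype:
        for h in self.nodes:
            if h.id == node_id:
                return h
        raise KeyError(node_id)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(epsilon=self.epsilon)
        for h in self.nodes:
            g.add_node(
                h.id,
                multiplicity=h.multiplicity,
                median=int(h.median),
                populations=";".join(
                    f"{k}={v}" for k, v in sorted(h.population_counts.items())
                ),
                vector="".join(h.vector),
            )
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=int(w))
        return g


# ---------------------------------------------------------------------------
# Condensation
# ---------------------------------------------------------------------------

def _condense_vectors(
    rows: Sequence[tuple[str, str, tuple[str, ...]]]
) -> list[Haplotype]:
    groups: dict[tuple[str, ...], Haplotype] = {}
    for sid, pop, vec in rows:
        if vec in groups:
            h = groups[vec]
            h.multiplicity += 1
            h.population_counts[pop] = h.population_counts.get(pop, 0) + 1
            h.sample_ids = h.sample_ids + (sid,)
        else:
            groups[vec] = Haplotype(
                id=sid,
                vector=vec,
                multiplicity=1,
                population_counts={pop: 1},
                sample_ids=(sid,),
            )
    return list(groups.values())


def condense_haplotypes(
    samples: Union[PopulationSet, Iterable],
    *,
    site_mask: Iterable[int] = (),
    reference: ReferenceGenome | None = None,
) -> list[Haplotype]:
    """Group identical samples into haplotypes over segregating characters.

    Accepts a :class:`PopulationSet`, an iterable of
    ``(sample_id, population, sequence)`` tuples, or an iterable of
    :class:`VariantProfile`. Haplotype ids are the first-seen sample id,
    making the output deterministic for a given input order.
    """
    if isinstance(samples, PopulationSet):
        mask = set(site_mask) | set(samples.site_mask)
        rows = list(samples.samples())
        return _condense_from_sequences(rows, mask)
    samples = list(samples)
    if samples and isinstance(samples[0], VariantProfile):
        return _condense_from_profiles(samples, reference)
    return _condense_from_sequences(list(samples), set(site_mask))


def _condense_from_sequences(
    rows: Sequence[tuple[str, str, str]], mask: set[int]
) -> list[Haplotype]:
    if not rows:
        return []
    seqs = [seq.upper() for _, _, seq in rows]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences are not aligned to one length")
    seg_cols = []
    for c in range(L):
        if (c + 1) in mask:
            continue
        states = {s[c] for s in seqs} - {"N"}
        if len(states) >= 2:
            seg_cols.append(c)
    vec_rows = [
        (sid, pop, tuple(seq.upper()[c] for c in seg_cols)) for sid, pop, seq in rows
    ]
    return _condense_vectors(vec_rows)


def _condense_from_profiles(
    profiles: Sequence[VariantProfile], reference: ReferenceGenome | None
) -> list[Haplotype]:
    # characters: all (position, kind) seen in any profile; states are the
    # alt allele when present, otherwise the reference state ('.' when no
    # reference is available, '-' for an absent insertion).
    characters = sorted(
        {(v.position, v.kind) for p in profiles for v in p}
    )

    def state(profile: VariantProfile, pos: int, kind: str) -> str:
        if kind == SUBSTITUTION:
            v = profile.substitution_at(pos)
            if v is not None:
                return v.alt_allele
            return reference.base(pos) if reference is not None else "."
        if kind == INSERTION:
            v = profile.insertion_at(pos)
            return v.alt_allele if v is not None else "-"
        v = profile.deletion_at(pos)
        return "-" if v is not None else "."

    state_rows = [
        [state(p, pos, kind) for pos, kind in characters] for p in profiles
    ]
    seg_idx = [
        j for j in range(len(characters))
        if len({row[j] for row in state_rows}) >= 2
    ]
    vec_rows = [
        (p.sample_id, p.population, tuple(row[j] for j in seg_idx))
        for p, row in zip(profiles, state_rows)
    ]
    return _condense_vectors(vec_rows)


# ---------------------------------------------------------------------------
# Median-joining network
# ---------------------------------------------------------------------------

def _distance(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    """Hamming distance over characters; ambiguous states never mismatch."""
    return sum(x != y and x != "N" and y != "N" for x, y in zip(a, b))


def _msn_edges(
    vectors: dict[str, tuple[str, ...]], epsilon: int
) -> list[tuple[str, str, int]]:
    """Epsilon-relaxed minimum spanning network over the given vectors.

    An edge (u, v) is included iff d(u, v) <= minimax(u, v) + epsilon,
    where minimax is the bottleneck (max edge weight) of the u-v path in
    a minimum spanning tree. With epsilon = 0 this yields exactly the
    union of all minimum spanning trees.
    """
    ids = sorted(vectors)
    if len(ids) < 2:
        return []
    g = nx.Graph()
    for u, v in itertools.combinations(ids, 2):
        g.add_edge(u, v, weight=_distance(vectors[u], vectors[v]))
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    # bottleneck weights between every pair, via per-node traversal of the MST
    minimax: dict[tuple[str, str], int] = {}
    for source in ids:
        best = {source: 0}
        stack = [source]
        seen = {source}
        while stack:
            cur = stack.pop()
            for nbr in mst[cur]:
                if nbr in seen:
                    continue
                seen.add(nbr)
                best[nbr] = max(best[cur], mst[cur][nbr]["weight"])
                stack.append(nbr)
        for target, w in best.items():
            minimax[(source, target)] = w
    edges = []
    for u, v in itertools.combinations(ids, 2):
        d = g[u][v]["weight"]
        if d <= minimax[(u, v)] + epsilon:
            edges.append((u, v, d))
    return edges


def _median_vector(
    trio: Sequence[tuple[str, ...]]
) -> tuple[str, ...]:
    """Per-character majority consensus; a three-way tie keeps the first
    (lexicographically smallest node id) state, for determinism."""
    out = []
    for states in zip(*trio):
        a, b, c = states
        if b == c:
            out.append(b)
        else:
            out.append(a)  # covers a==b, a==c and the all-distinct tie
    return tuple(out)


def median_joining(
    haplotypes: Sequence[Haplotype],
    epsilon: int = 0,
    *,
    max_rounds: int = 20,
) -> HaplotypeNetwork:
    """Build a median-joining network over condensed haplotypes.

    Raises :class:`ConvergenceError` if median addition has not settled
    within ``max_rounds`` rebuild rounds (a diagnostic rather than an
    endless loop; pathological inputs aside, mitogenome data converges
    in a handful of rounds).
    """
    if isinstance(epsilon, bool) or not isinstance(epsilon, int):
        raise TypeError(f"epsilon must be a non-negative integer, got {epsilon!r}")
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    if not haplotypes:
        raise ValueError("median_joining requires at least one haplotype")
    ids = [h.id for h in haplotypes]
    if len(set(ids)) != len(ids):
        raise ValueError("haplotype ids must be unique")
    vlen = {len(h.vector) for h in haplotypes}
    if len(vlen) > 1:
        raise ValueError("haplotype vectors must share one character set")

    vectors: dict[str, tuple[str, ...]] = {h.id: h.vector for h in haplotypes}
    sampled = set(vectors)
    known_vectors = set(vectors.values())
    mv_counter = itertools.count(1)

    for _ in range(max_rounds):
        edges = _msn_edges(vectors, epsilon)
        adj: dict[str, set[str]] = {i: set() for i in vectors}
        for u, v, _w in edges:
            adj[u].add(v)
            adj[v].add(u)
        new_vectors: set[tuple[str, ...]] = set()
        for u, v, _w in edges:
            for w_id in sorted((adj[u] | adj[v]) - {u, v}):
                trio = sorted((u, v, w_id))
                med = _median_vector([vectors[t] for t in trio])
                if med in known_vectors or med in new_vectors:
                    continue
                pair_d = [
                    _distance(vectors[a], vectors[b])
                    for a, b in itertools.combinations(trio, 2)
                ]
                cost_without = sum(pair_d) - max(pair_d)  # spanning cost of the trio
                cost_with = sum(_distance(med, vectors[t]) for t in trio)
                if cost_with < cost_without:
                    new_vectors.add(med)
        if not new_vectors:
            break
        for med in sorted(new_vectors):
            vectors[f"MV{next(mv_counter)}"] = med
            known_vectors.add(med)
    else:
        raise ConvergenceError(
            f"median addition did not converge within {max_rounds} rounds"
        )

    # prune median vectors of degree < 3 (they are never terminal nodes)
    while True:
        edges = _msn_edges(vectors, epsilon)
        degree: dict[str, int] = {i: 0 for i in vectors}
        for u, v, _w in edges:
            degree[u] += 1
            degree[v] += 1
        drop = [i for i in vectors if i not in sampled and degree[i] < 3]
        if not drop:
            break
        for i in drop:
            del vectors[i]

    by_id = {h.id: h for h in haplotypes}
    nodes = [by_id[i] for i in vectors if i in sampled]
    nodes += [
        Haplotype(id=i, vector=vectors[i], multiplicity=0, median=True)
        for i in sorted(vectors)
        if i not in sampled
    ]
    return HaplotypeNetwork(nodes=nodes, edges=edges, epsilon=epsilon)


# ---------------------------------------------------------------------------
# Exporters
# ---------------------------------------------------------------------------

EXPORT_FORMATS = ("gml", "tsv-edgelist", "nexus-network")


def export_network(
    network: HaplotypeNetwork, fmt: str, path: Union[str, Path]
) -> Path:
    """Write the network losslessly in one of the supported formats.

    ``tsv-edgelist`` writes the edges to ``path`` and the node table
    (multiplicity, median flag, population counts) to a sibling file
    with a ``.nodes.tsv`` suffix.
    """
    path = Path(path)
    if fmt == "gml":
        nx.write_gml(network.to_networkx(), path)
    elif fmt == "tsv-edgelist":
        with path.open("w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, w in sorted(
                (min(u, v), max(u, v), w) for u, v, w in network.edges
            ):
                fh.write(f"{u}\t{v}\t{w}\n")
        nodes_path = path.with_name(path.name + ".nodes.tsv")
        with nodes_path.open("w") as fh:
            fh.write("id\tmultiplicity\tmedian\tpopulations\tvector\n")
            for h in network.nodes:
                pops = ";".join(f"{k}={v}" for k, v in sorted(h.population_counts.items()))
                fh.write(
                    f"{h.id}\t{h.multiplicity}\t{int(h.median)}\t{pops}\t{''.join(h.vector)}\n"
                )
    elif fmt == "nexus-network":
        with path.open("w") as fh:
            fh.write("#NEXUS\n\nBEGIN Taxa;\n")
            fh.write(f"DIMENSIONS ntax={len(network.nodes)};\nTAXLABELS\n")
            for h in network.nodes:
                fh.write(f"    {h.id}\n")
            fh.write(";\nEND;\n\nBEGIN Network;\n")
            fh.write(
                f"DIMENSIONS nvertices={len(network.nodes)} "
                f"nedges={len(network.edges)};\n"
            )
            fh.write(f"[epsilon={network.epsilon}]\n")
            fh.write("VERTICES\n")
            for h in network.nodes:
                pops = ";".join(f"{k}={v}" for k, v in sorted(h.population_counts.items()))
                fh.write(
                    f"    {h.id} multiplicity={h.multiplicity} "
                    f"median={int(h.median)} populations={pops or '-'}\n"
                )
            fh.write("EDGES\n")
            for u, v, w in network.edges:
                fh.write(f"    {u} {v} weight={w}\n")
            fh.write(";\nEND;\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}; expected one of {EXPORT_FORMATS}")
    return path


def read_tsv_edgelist(path: Union[str, Path]) -> set[tuple[str, str, int]]:
    """Read back a ``tsv-edgelist`` export as a normalised edge set."""
    edges = set()
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        u, v, w = line.split("\t")
        edges.add((min(u, v), max(u, v), int(w)))
    return edges
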