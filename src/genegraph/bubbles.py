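"""Generalized bibubbles: localized gene-content variation in bidirected graphs.

A *bibubble* is the bidirected analogue of a (weak) superbubble: a pair of
oriented genes (x, y) enclosing a nonempty interior U that is reachable
symmetrically from both ends, with every interior gene on some x->y walk, and
minimal (no interior orientation closes a smaller such pair).  The interior
U(x, y) is the set of genes reachable from x without passing through x, ~x or
y; walks through ~y are deliberately allowed, which is what makes inversions
representable.

Detection runs on the *net graph*: split each gene v into endpoint nodes
(v, s) and (v, e) joined by a gray edge (the biedged view), contract all
adjacency (link) edges, and read each gene as one undirected net edge.  If
(x, y) is a bibubble then {nu(x), nu(y)} is a two-edge cut-set of the net
graph, which holds exactly when the two net edges are *cycle equivalent*
(every cycle containing one contains the other).  Cycle-equivalence classes
therefore prune the candidate exits for each entry; every candidate is still
validated against the definition, because the reverse implication does not
hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .model import (FORWARD, REVERSE, BidirectedGraph, ContigWalk,
                    OrientedGene, flip)

START = "s"
END = "e"

Endpoint = tuple[str, str]  # (gene, "s"|"e")


def _head(x: OrientedGene) -> Endpoint:
    return (x.gene, END if x.orient == FORWARD else START)


def _tail(x: OrientedGene) -> Endpoint:
    return (x.gene, START if x.orient == FORWARD else END)


@dataclass
class BiedgedGraph:
    """Genes split into start/end nodes joined by gray edges; adjacencies
    become undirected link edges between endpoints."""

    nodes: list[Endpoint]
    gray_edges: list[tuple[Endpoint, Endpoint]]
    link_edges: list[tuple[Endpoint, Endpoint]]


def to_biedged(graph: BidirectedGraph) -> BiedgedGraph:
    """Edge x->y links the head endpoint of x with the tail endpoint of y."""
    genes = sorted(graph.genes)
    nodes = [(g, s) for g in genes for s in (START, END)]
    gray = [((g, START), (g, END)) for g in genes]
    links = []
    for (x, y) in sorted(graph.edges, key=lambda e: (e[0].sort_key(), e[1].sort_key())):
        links.append((_head(x), _tail(y)))
    return BiedgedGraph(nodes=nodes, gray_edges=gray, link_edges=links)


@dataclass
class NetGraph:
    """Undirected multigraph of link-edge components; one net edge per gene.

    ``graph`` is a networkx MultiGraph whose nodes are integer component ids
    and whose edge keys are gene names (self-loops and parallel edges are
    meaningful).  ``vertex_of`` maps each biedged endpoint to its component.
    """

    graph: nx.MultiGraph
    vertex_of: dict[Endpoint, int]
    edge_of_gene: dict[str, tuple[int, int]]

    def endpoints_of(self, gene: str) -> tuple[int, int]:
        return self.edge_of_gene[gene]


def to_net(biedged: BiedgedGraph) -> NetGraph:
    """Contract all link edges of the biedged graph (union-find)."""
    parent: dict[Endpoint, Endpoint] = {n: n for n in biedged.nodes}

    def find(a: Endpoint) -> Endpoint:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in biedged.link_edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    roots = sorted({find(n) for n in biedged.nodes})
    comp_id = {r: i for i, r in enumerate(roots)}
    vertex_of = {n: comp_id[find(n)] for n in biedged.nodes}

    g = nx.MultiGraph()
    g.add_nodes_from(range(len(roots)))
    edge_of_gene: dict[str, tuple[int, int]] = {}
    for (s, e) in biedged.gray_edges:
        gene = s[0]
        u, v = vertex_of[s], vertex_of[e]
        g.add_edge(u, v, key=gene)
        edge_of_gene[gene] = (u, v)
    return NetGraph(graph=g, vertex_of=vertex_of, edge_of_gene=edge_of_gene)


def net_graph(graph: BidirectedGraph) -> NetGraph:
    return to_net(to_biedged(graph))


@dataclass(frozen=True)
class NetFeatures:
    """Structural gene classes of the net graph used by the bubble check.

    ``bridges`` — genes whose net edge lies on no cycle (mandatory corridors
    with no variation anywhere); ``self_loops`` — genes whose two endpoints
    contract to one net vertex (copy-number loop genes).
    """

    bridges: frozenset[str]
    self_loops: frozenset[str]


def net_features(graph: BidirectedGraph, net: NetGraph | None = None) -> NetFeatures:
    if net is None:
        net = net_graph(graph)
    g = net.graph
    loops = {k for u, v, k in g.edges(keys=True) if u == v}
    h = nx.MultiGraph()
    h.add_nodes_from(g.nodes)
    for u, v, k in g.edges(keys=True):
        if u != v:
            h.add_edge(u, v, key=k)
    bridges: set[str] = set()
    for comp in nx.connected_components(h):
        comp = sorted(comp)
        if len(comp) == 1:
            continue
        brackets, _ = _dfs_brackets(h, comp)
        for key, bset in brackets.items():
            if not bset:
                bridges.add(key)
    return NetFeatures(bridges=frozenset(bridges), self_loops=frozenset(loops))


def net_bridges(graph: BidirectedGraph, net: NetGraph | None = None) -> set[str]:
    """Genes whose net edge is a bridge (lies on no cycle of the net graph)."""
    return set(net_features(graph, net).bridges)


# ---------------------------------------------------------------------------
# cycle equivalence

@dataclass
class CycleClasses:
    """Partition of net edges into cycle-equivalence classes.

    All bridges (edges on no cycle) share one vacuous class — required so
    that the boundary genes of deletion bubbles, which lie on no net cycle,
    remain mutual candidates.  Self-loops are singleton classes.
    """

    class_of: dict[str, int]
    bridge_class: int | None = None

    def same(self, a: str, b: str) -> bool:
        return self.class_of[a] == self.class_of[b]

    def classes(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for k, c in self.class_of.items():
            out.setdefault(c, set()).add(k)
        return out


def _dfs_brackets(g: nx.MultiGraph, component: list) -> tuple[dict, list]:
    """DFS one component; return bracket sets per tree edge and misc info.

    Returns (bracket_of_tree_edge: {edge_key: frozenset of backedge keys},
    backedges: list of edge keys).  Self-loops must have been removed.
    """
    root = min(component)
    dfsnum: dict = {}
    parent: dict = {}
    parent_edge: dict = {}
    children: dict = {v: [] for v in component}
    order: list = []
    used: set[str] = set()
    tree_edges: set[str] = set()
    backedges: list[tuple[str, object, object]] = []  # (key, descendant, ancestor)

    dfsnum[root] = 0
    order.append(root)

    def neighbor_edges(v):
        for w in sorted(g.adj[v], key=str):
            for key in sorted(g.adj[v][w]):
                yield w, key

    stack = [(root, neighbor_edges(root))]
    while stack:
        v, it = stack[-1]
        advanced = False
        for w, key in it:
            if key in used:
                continue
            used.add(key)
            if w not in dfsnum:
                dfsnum[w] = len(order)
                order.append(w)
                parent[w] = v
                parent_edge[w] = key
                children[v].append(w)
                tree_edges.add(key)
                stack.append((w, neighbor_edges(w)))
                advanced = True
                break
            else:
                # non-tree edge: orient descendant -> ancestor
                if dfsnum[w] <= dfsnum[v]:
                    backedges.append((key, v, w))
                else:  # pragma: no cover - cannot happen in undirected DFS
                    backedges.append((key, w, v))
        if not advanced:
            stack.pop()

    starts: dict = {}
    ends: dict = {}
    for key, d, a in backedges:
        starts.setdefault(d, set()).add(key)
        ends.setdefault(a, set()).add(key)

    brackets: dict[str, frozenset] = {}
    acc: dict = {}  # vertex -> set of open brackets in its subtree
    for v in reversed(order):
        s: set = set()
        for c in children[v]:
            s |= acc[c]
        s |= starts.get(v, set())
        s -= ends.get(v, set())
        acc[v] = s
        if v != root:
            brackets[parent_edge[v]] = frozenset(s)
    return brackets, [k for k, _, _ in backedges]


def cycle_equivalence(net: NetGraph) -> CycleClasses:
    """Cycle-equivalence classes via DFS bracket sets (the fast algorithm).

    Within each component a DFS spanning tree is built; each backedge is a
    bracket spanning the tree edges between its endpoints.  Two tree edges
    are cycle equivalent exactly when their bracket sets coincide; a backedge
    joins a tree edge exactly when it is that edge's only bracket.  Tree
    edges with no bracket are bridges and share the vacuous class; self-loops
    are singletons.
    """
    g = net.graph
    class_of: dict[str, int] = {}
    next_class = 0
    bridge_class: int | None = None

    self_loops = [k for u, v, k in g.edges(keys=True) if u == v]
    for k in sorted(self_loops):
        class_of[k] = next_class
        next_class += 1

    h = nx.MultiGraph()
    h.add_nodes_from(g.nodes)
    for u, v, k in g.edges(keys=True):
        if u != v:
            h.add_edge(u, v, key=k)

    for comp in sorted(nx.connected_components(h), key=min):
        comp = sorted(comp)
        if len(comp) == 1 and not h.adj[comp[0]]:
            continue
        brackets, backedge_keys = _dfs_brackets(h, comp)
        by_set: dict[frozenset, list[str]] = {}
        for key, bset in brackets.items():
            if not bset:
                if bridge_class is None:
                    bridge_class = next_class
                    next_class += 1
                class_of[key] = bridge_class
            else:
                by_set.setdefault(bset, []).append(key)
        for bset in sorted(by_set, key=lambda s: sorted(s)):
            cid = next_class
            next_class += 1
            for key in by_set[bset]:
                class_of[key] = cid
            if len(bset) == 1:
                # a backedge that is some tree edge's only bracket closes a
                # simple chain of equivalent edges and joins their class
                class_of[next(iter(bset))] = cid
        for key in backedge_keys:
            if key not in class_of:
                class_of[key] = next_class
                next_class += 1
    return CycleClasses(class_of=class_of, bridge_class=bridge_class)


def cycle_equiv_oracle(net: NetGraph) -> CycleClasses:
    """Definitional oracle: {e1, e2} is a cut-set iff e1, e2 cycle equivalent.

    Brute force for small graphs: bridges are found by single-edge removal
    and share the vacuous class; a non-bridge pair is equivalent when
    removing both edges disconnects their component.  Used as an independent
    cross-check of :func:`cycle_equivalence`.
    """
    g = net.graph
    keys = sorted(k for _, _, k in g.edges(keys=True))
    locate = {k: (u, v) for u, v, k in g.edges(keys=True)}

    def without(drop: set[str]) -> nx.MultiGraph:
        h = nx.MultiGraph()
        h.add_nodes_from(g.nodes)
        for u, v, k in g.edges(keys=True):
            if k not in drop:
                h.add_edge(u, v, key=k)
        return h

    comp_of = {}
    for i, comp in enumerate(nx.connected_components(g)):
        for v in comp:
            comp_of[v] = i

    def connected_in_component(h: nx.MultiGraph, u) -> bool:
        target = {v for v in g.nodes if comp_of[v] == comp_of[u]}
        seen = set(nx.node_connected_component(h, u))
        return target <= seen

    bridges = set()
    for k in keys:
        u, v = locate[k]
        if u == v:
            continue
        if not connected_in_component(without({k}), u):
            bridges.add(k)

    parent = {k: k for k in keys}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, k1 in enumerate(keys):
        if k1 in bridges or locate[k1][0] == locate[k1][1]:
            continue
        for k2 in keys[i + 1:]:
            if k2 in bridges or locate[k2][0] == locate[k2][1]:
                continue
            if comp_of[locate[k1][0]] != comp_of[locate[k2][0]]:
                continue
            if not connected_in_component(without({k1, k2}), locate[k1][0]):
                parent[find(k2)] = find(k1)

    class_of: dict[str, int] = {}
    next_class = 0
    bridge_class = None
    if bridges:
        bridge_class = next_class
        next_class += 1
        for k in bridges:
            class_of[k] = bridge_class
    root_class: dict[str, int] = {}
    for k in keys:
        if k in bridges:
            continue
        r = find(k)
        if r not in root_class:
            root_class[r] = next_class
            next_class += 1
        class_of[k] = root_class[r]
    return CycleClasses(class_of=class_of, bridge_class=bridge_class)


# ---------------------------------------------------------------------------
# U sets and the bibubble definition

def _oriented_reach(graph: BidirectedGraph, x: OrientedGene,
                    y: OrientedGene) -> set[OrientedGene]:
    """Oriented nodes reachable from x without passing x, ~x or y.

    The blocked nodes are never expanded and never counted; ~y is counted
    and expanded (walks through ~y are allowed by construction).
    """
    blocked = {x, x.flipped, y}
    seen: set[OrientedGene] = set()
    queue = [w for w in graph.out_neighbors(x) if w not in blocked]
    for w in queue:
        seen.add(w)
    head = 0
    while head < len(queue):
        w = queue[head]
        head += 1
        for nxt in graph.out_neighbors(w):
            if nxt in blocked or nxt in seen:
                continue
            seen.add(nxt)
            queue.append(nxt)
    return seen


def u_set(graph: BidirectedGraph, x: OrientedGene, y: OrientedGene) -> set[str]:
    """U(x, y): genes reachable from x without passing through x, ~x or y."""
    return {w.gene for w in _oriented_reach(graph, x, y)}


@dataclass(frozen=True)
class Bibubble:
    """An entry/exit pair of oriented genes with its interior gene set."""

    entry: OrientedGene
    exit: OrientedGene
    interior: frozenset[str]
    contains_inversion: bool = False

    def canonical(self) -> tuple[OrientedGene, OrientedGene]:
        a = (self.entry, self.exit)
        b = (self.exit.flipped, self.entry.flipped)
        ka = (a[0].sort_key(), a[1].sort_key())
        kb = (b[0].sort_key(), b[1].sort_key())
        return a if ka <= kb else b

    def mirrored(self) -> "Bibubble":
        return Bibubble(self.exit.flipped, self.entry.flipped,
                        self.interior, self.contains_inversion)


def is_bibubble(graph: BidirectedGraph, x: OrientedGene, y: OrientedGene,
                features: NetFeatures | None = None) -> Bibubble | None:
    """Test the bibubble definition for an oriented pair; return the bubble.

    (i) U(x,y) = U(~y,~x), nonempty, containing neither boundary gene, with
    entry and exit on distinct genes (the boundary {nu(x), nu(y)} must be a
    two-edge cut-set, which a single net edge cannot form);
    (ii) every interior gene lies on a net-graph cycle — a bridge interior
    would be a mandatory corridor with no alternative walk, as in a plain
    chain, whose enclosing pair is not a variation;
    (iii) every interior gene lies on a walk from x to y (forward reach from
    x intersected, orientation-wise, with the mirror reach from ~y);
    (iv) minimality: no interior orientation z splits the pair by satisfying
    the condition-(i) set equality against x or against y.  Equality of
    empty sets counts as a split — it marks z as a plain chain waypoint —
    except when nu(z) is a net self-loop: a copy-number loop gene has empty
    flank sets on both sides yet is itself the variation and must stay
    enclosed.

    ``features`` may carry a precomputed :func:`net_features` result when
    testing many pairs of one graph.
    """
    if x.gene == y.gene:
        return None
    r_fwd = _oriented_reach(graph, x, y)
    u1 = {w.gene for w in r_fwd}
    if not u1:
        return None
    if features is None:
        features = net_features(graph)
    if u1 & features.bridges:
        return None
    r_mirror = _oriented_reach(graph, y.flipped, x.flipped)
    u2 = {w.gene for w in r_mirror}
    if u1 != u2:
        return None
    if x.gene in u1 or y.gene in u1:
        return None
    for v in u1:
        on_walk = False
        for orient in (FORWARD, REVERSE):
            w = OrientedGene(v, orient)
            if w in r_fwd and w.flipped in r_mirror:
                on_walk = True
                break
        if not on_walk:
            return None
    for v in sorted(u1):
        empty_splits = v not in features.self_loops
        for orient in (FORWARD, REVERSE):
            z = OrientedGene(v, orient)
            u_xz = u_set(graph, x, z)
            if (u_xz or empty_splits) and \
                    u_xz == u_set(graph, z.flipped, x.flipped):
                return None
            u_zy = u_set(graph, z, y)
            if (u_zy or empty_splits) and \
                    u_zy == u_set(graph, y.flipped, z.flipped):
                return None
    inversion = any(OrientedGene(v, FORWARD) in r_fwd and
                    OrientedGene(v, REVERSE) in r_fwd for v in u1)
    return Bibubble(entry=x, exit=y, interior=frozenset(u1),
                    contains_inversion=inversion)


def _dedup_sorted(bubbles: Iterable[Bibubble]) -> list[Bibubble]:
    seen: dict[tuple, Bibubble] = {}
    for b in bubbles:
        key = b.canonical()
        if key not in seen:
            cx, cy = key
            seen[key] = b if (b.entry, b.exit) == key else b.mirrored()
    return [seen[k] for k in sorted(
        seen, key=lambda p: (p[0].sort_key(), p[1].sort_key()))]


def find_bibubbles_naive(graph: BidirectedGraph) -> list[Bibubble]:
    """Definitional enumeration over all ordered oriented pairs.

    Quadratic in the number of oriented genes times the definitional check;
    intended for small graphs and as the oracle for :func:`find_bibubbles`.
    """
    oriented = graph.oriented_genes()
    features = net_features(graph)
    found = []
    for x in oriented:
        if not graph.out_neighbors(x):
            continue
        for y in oriented:
            if y == x:
                continue
            b = is_bibubble(graph, x, y, features=features)
            if b is not None:
                found.append(b)
    return _dedup_sorted(found)


def find_bibubbles(graph: BidirectedGraph, m: int = 100) -> list[Bibubble]:
    """Cycle-equivalence guided bibubble search (the default algorithm).

    For each candidate entry x — an oriented gene that branches, or whose
    single successor already sits on a net cycle — a BFS visits up to ``m``
    genes reachable from x; oriented genes whose underlying gene shares x's
    cycle-equivalence class are candidate exits, tested in BFS order with the
    definitional check.  The first success is x's bubble (an entry admits at
    most one); a failed candidate is traversed through so that exits behind
    it stay reachable.  Mirrors are deduplicated.
    """
    net = net_graph(graph)
    classes = cycle_equivalence(net)
    features = net_features(graph, net)
    found: list[Bibubble] = []
    for x in graph.oriented_genes():
        out = graph.out_neighbors(x)
        if not out:
            continue
        # a bubble entry either branches or leads straight into a gene that
        # lies on a net cycle (the interior of a copy-number loop)
        if len(out) < 2 and all(w.gene in features.bridges for w in out):
            continue
        xclass = classes.class_of.get(x.gene)
        blocked = {x, x.flipped}
        queue: list[OrientedGene] = []
        seen: set[OrientedGene] = set()
        genes_seen: set[str] = {x.gene}
        for w in out:
            if w not in blocked and w not in seen:
                seen.add(w)
                queue.append(w)
                genes_seen.add(w.gene)
        head = 0
        success = None
        x_loop = x.gene in features.self_loops
        while head < len(queue):
            w = queue[head]
            head += 1
            # a duplicated boundary gene is a net self-loop and falls out of
            # its flank's cycle class, so self-loop boundaries stay candidates
            if (classes.class_of.get(w.gene) == xclass or x_loop
                    or w.gene in features.self_loops):
                b = is_bibubble(graph, x, w, features=features)
                if b is not None:
                    success = b
                    break
            for nxt in graph.out_neighbors(w):
                if nxt in blocked or nxt in seen:
                    continue
                if nxt.gene not in genes_seen and len(genes_seen) >= m:
                    continue
                genes_seen.add(nxt.gene)
                seen.add(nxt)
                queue.append(nxt)
        if success is not None:
            found.append(success)
    return _dedup_sorted(found)


# ---------------------------------------------------------------------------
# SESE-style candidate generation (non-default alternative)

P0 = "__p0__"


def sese_candidates(net: NetGraph, walks: Sequence[ContigWalk],
                    reference: str | None = None) -> list[tuple[str, str]]:
    """Candidate gene pairs from cycle equivalence on a rooted net graph.

    A dummy vertex p0 is connected to every degree-one net vertex and to the
    outer endpoints of the first and last gene of each reference contig, so
    that every net vertex lies on a cycle with p0.  Gene pairs sharing a
    cycle-equivalence class in the rooted graph are single-entry/single-exit
    region boundaries and hence bubble candidates; each still needs the
    definitional check.
    """
    genomes = sorted({w.genome for w in walks})
    if reference is None and genomes:
        reference = genomes[0]
    g = nx.MultiGraph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, k in net.graph.edges(keys=True):
        g.add_edge(u, v, key=k)
    p0 = max(net.graph.nodes, default=-1) + 1
    g.add_node(p0)
    targets: set[int] = set()
    for v in net.graph.nodes:
        if net.graph.degree(v) == 1:
            targets.add(v)
    for w in walks:
        if w.genome != reference:
            continue
        first, last = w.steps[0].gene, w.steps[-1].gene
        targets.add(net.vertex_of[_tail(first)])
        targets.add(net.vertex_of[_head(last)])
    for i, v in enumerate(sorted(targets - {p0})):
        g.add_edge(p0, v, key=f"{P0}{i}")
    rooted = NetGraph(graph=g, vertex_of=dict(net.vertex_of),
                      edge_of_gene=dict(net.edge_of_gene))
    classes = cycle_equivalence(rooted)
    pairs: list[tuple[str, str]] = []
    for members in classes.classes().values():
        genes = sorted(k for k in members if not k.startswith(P0))
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                pairs.append((a, b))
    return sorted(pairs)


def find_bibubbles_sese(graph: BidirectedGraph,
                        reference: str | None = None) -> list[Bibubble]:
    """Bibubbles via SESE-style candidates (validated definitionally).

    The p0 placement is heuristic; on unusual topologies (e.g. palindromic
    contigs) it may miss bubbles that the default algorithm finds.
    """
    net = net_graph(graph)
    features = net_features(graph, net)
    found: dict[OrientedGene, Bibubble] = {}
    for (u, v) in sese_candidates(net, graph.walks, reference):
        for ou in (FORWARD, REVERSE):
            for ov in (FORWARD, REVERSE):
                x = OrientedGene(u, ou)
                y = OrientedGene(v, ov)
                for (a, b) in ((x, y), (y, x)):
                    if a not in found:
                        bub = is_bibubble(graph, a, b, features=features)
                        if bub is not None:
                            found[a] = bub
    return _dedup_sorted(found.values())
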