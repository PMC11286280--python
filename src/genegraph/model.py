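"""Core domain model: oriented genes, contig walks and the bidirected gene graph.

A pangenome gene graph takes genes as vertices.  Each gene can be traversed
forward (``>v``) or reverse-complemented (``<v``), so the directed view of the
graph lives on *oriented genes*.  An adjacency ``x -> y`` observed on a contig
implies, by the strand symmetry of DNA, the mirror adjacency ``~y -> ~x``; the
two are a single biological edge and are stored once under a canonical key
(skew symmetry).  Every input contig is recorded as a walk of oriented genes,
and edge support/score bookkeeping is derived from those walks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .util import DuplicateWalkError, MissingEdgeError

FORWARD = ">"
REVERSE = "<"

# ">" sorts before "<" in the canonical order (byte order on gene names first).
_ORIENT_RANK = {FORWARD: 0, REVERSE: 1}


@dataclass(frozen=True, order=False)
class OrientedGene:
    """A gene identifier plus a strand marker.

    ``>v`` reads the gene forward, ``<v`` reverse-complemented.  Flipping the
    orientation twice is the identity.
    """

    gene: str
    orient: str  # ">" or "<"

    def __post_init__(self):
        if self.orient not in (FORWARD, REVERSE):
            raise ValueError(f"orientation must be '>' or '<', got {self.orient!r}")

    @property
    def flipped(self) -> "OrientedGene":
        return OrientedGene(self.gene, REVERSE if self.orient == FORWARD else FORWARD)

    def sort_key(self) -> tuple[str, int]:
        return (self.gene, _ORIENT_RANK[self.orient])

    def __str__(self) -> str:
        return f"{self.orient}{self.gene}"

    @classmethod
    def parse(cls, text: str) -> "OrientedGene":
        if not text or text[0] not in (FORWARD, REVERSE):
            raise ValueError(f"cannot parse oriented gene from {text!r}")
        return cls(text[1:], text[0])


def flip(x: OrientedGene) -> OrientedGene:
    """Return the opposite orientation of the same gene; an involution."""
    return x.flipped


def nu(x: OrientedGene) -> str:
    """The underlying gene behind an oriented gene."""
    return x.gene


DirectedEdge = tuple[OrientedGene, OrientedGene]


def canonical_edge(x: OrientedGene, y: OrientedGene) -> DirectedEdge:
    """Canonical key of the unordered oriented pair {x->y, ~y->~x}.

    The lexicographically smaller of the two directed renderings wins, using
    byte order on gene names and ">" before "<".  Both renderings of one
    biological adjacency map to the same key.
    """
    mirror = (y.flipped, x.flipped)
    fwd = (x, y)
    kf = (x.sort_key(), y.sort_key())
    km = (mirror[0].sort_key(), mirror[1].sort_key())
    return fwd if kf <= km else mirror


@dataclass
class GeneCatalog:
    """The gene universe: one chosen protein per gene plus exon-count metadata."""

    genes: set[str] = field(default_factory=set)
    protein_of: dict[str, str] = field(default_factory=dict)
    # (gene, genome) -> max exon count observed in that genome's alignments
    exon_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    protein_len: dict[str, int] = field(default_factory=dict)

    def add_gene(self, gene: str, protein: str | None = None) -> None:
        self.genes.add(gene)
        if protein is not None:
            self.protein_of[gene] = protein

    def max_exons(self, gene: str) -> int:
        counts = [n for (g, _), n in self.exon_counts.items() if g == gene]
        return max(counts, default=0)


@dataclass(frozen=True)
class WalkStep:
    gene: OrientedGene
    score: int
    start: int  # 0-based half-open genomic interval
    end: int


@dataclass
class ContigWalk:
    """The ordered, oriented gene content of one input contig.

    Steps are sorted by interval start.  A walk read on the opposite strand
    (reverse the order, flip every orientation) represents the same contig;
    walks are stored as read from input.  ``part`` distinguishes fragments of
    a contig after filter-induced splits.
    """

    genome: str
    contig: str
    steps: list[WalkStep]
    part: int = 0

    def __post_init__(self):
        starts = [s.start for s in self.steps]
        if starts != sorted(starts):
            raise ValueError(f"walk steps on {self.genome}/{self.contig} not sorted by start")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.genome, self.contig, self.part)

    @property
    def contig_key(self) -> tuple[str, str]:
        return (self.genome, self.contig)

    def oriented(self) -> list[OrientedGene]:
        return [s.gene for s in self.steps]

    def reversed_view(self) -> list[OrientedGene]:
        return [s.gene.flipped for s in reversed(self.steps)]

    def adjacencies(self) -> Iterator[tuple[WalkStep, WalkStep]]:
        for a, b in zip(self.steps, self.steps[1:]):
            yield a, b


def walk_from_tokens(genome: str, contig: str, tokens: Iterable[str | OrientedGene],
                     scores: Iterable[int] | None = None,
                     intervals: Iterable[tuple[int, int]] | None = None,
                     part: int = 0) -> ContigWalk:
    """Convenience constructor: build a walk from ">A"/"<B" tokens.

    Without explicit coordinates, genes are laid end to end with unit length.
    """
    genes = [t if isinstance(t, OrientedGene) else OrientedGene.parse(t) for t in tokens]
    if scores is None:
        scores = [0] * len(genes)
    if intervals is None:
        intervals = [(i, i + 1) for i in range(len(genes))]
    steps = [WalkStep(g, s, a, b) for g, s, (a, b) in zip(genes, scores, intervals)]
    return ContigWalk(genome, contig, steps, part=part)


class EdgeData:
    """Support and score bookkeeping for one canonical edge.

    ``S(x|y, t)`` is the alignment score of the occurrence of ``x`` on contig
    ``t`` when the adjacency ``x -> y`` is supported by ``t``.  For the
    canonical direction ``cx -> cy`` the forward list holds per-contig scores
    of ``cx`` and the reverse list per-contig scores of ``cy`` (i.e. of
    ``~cy`` read along ``~cy -> ~cx``).  If one contig realizes the adjacency
    several times, its contribution is the mean over its occurrences, so both
    score lists stay parallel to the supporting-contig set.
    """

    __slots__ = ("_per_contig", "false_edge", "low_priority",
                 "_declared_support", "_declared_means")

    def __init__(self):
        # (genome, contig) -> [sum_fwd, sum_rev, n_occurrences]
        self._per_contig: dict[tuple[str, str], list[float]] = {}
        self.false_edge = False
        self.low_priority = False
        # populated only for edges read from GFA link lines that no walk covers
        self._declared_support: int | None = None
        self._declared_means: tuple[float, float] | None = None

    def add_observation(self, genome: str, contig: str, score_fwd: float, score_rev: float) -> None:
        acc = self._per_contig.setdefault((genome, contig), [0.0, 0.0, 0])
        acc[0] += score_fwd
        acc[1] += score_rev
        acc[2] += 1

    @property
    def supporting_contigs(self) -> set[tuple[str, str]]:
        return set(self._per_contig)

    @property
    def support(self) -> int:
        if self._per_contig:
            return len(self._per_contig)
        return self._declared_support or 0

    @property
    def scores_fwd(self) -> list[float]:
        return [a[0] / a[2] for a in self._per_contig.values()]

    @property
    def scores_rev(self) -> list[float]:
        return [a[1] / a[2] for a in self._per_contig.values()]

    def mean_fwd(self) -> float:
        s = self.scores_fwd
        if not s:
            return self._declared_means[0] if self._declared_means else 0.0
        return sum(s) / len(s)

    def mean_rev(self) -> float:
        s = self.scores_rev
        if not s:
            return self._declared_means[1] if self._declared_means else 0.0
        return sum(s) / len(s)


class BidirectedGraph:
    """Genes as vertices, skew-symmetric oriented adjacencies, per-contig walks."""

    def __init__(self, catalog: GeneCatalog | None = None):
        self.catalog = catalog if catalog is not None else GeneCatalog()
        self.edges: dict[DirectedEdge, EdgeData] = {}
        self.walks: list[ContigWalk] = []
        self._walk_keys: set[tuple[str, str, int]] = set()
        self._adj: dict[OrientedGene, list[OrientedGene]] | None = None

    # -- vertices ---------------------------------------------------------
    @property
    def genes(self) -> set[str]:
        return set(self.catalog.genes)

    def add_gene(self, gene: str) -> None:
        self.catalog.genes.add(gene)
        self._adj = None

    # -- edges ------------------------------------------------------------
    def has_edge(self, x: OrientedGene, y: OrientedGene) -> bool:
        return canonical_edge(x, y) in self.edges

    def edge_data(self, x: OrientedGene, y: OrientedGene) -> EdgeData:
        key = canonical_edge(x, y)
        if key not in self.edges:
            raise MissingEdgeError(f"no adjacency {x} -> {y} in graph")
        return self.edges[key]

    def _ensure_edge(self, x: OrientedGene, y: OrientedGene) -> tuple[DirectedEdge, EdgeData]:
        key = canonical_edge(x, y)
        data = self.edges.get(key)
        if data is None:
            data = EdgeData()
            self.edges[key] = data
            self._adj = None
        return key, data

    def remove_edge(self, x: OrientedGene, y: OrientedGene) -> None:
        self.edges.pop(canonical_edge(x, y), None)
        self._adj = None

    # -- walks ------------------------------------------------------------
    def add_walk(self, walk: ContigWalk) -> None:
        """Register a contig walk and insert every adjacency it supports.

        Each consecutive pair (x, y) supports the canonical edge {x->y};
        support is counted per contig, not per occurrence.  Two walks may not
        share a (genome, contig, part) key.
        """
        if not walk.steps:
            raise ValueError("walk must have at least one step")
        if walk.key in self._walk_keys:
            raise DuplicateWalkError(
                f"duplicate contig {walk.contig!r} (part {walk.part}) in genome {walk.genome!r}")
        self._walk_keys.add(walk.key)
        self.walks.append(walk)
        for step in walk.steps:
            self.catalog.genes.add(step.gene.gene)
        for a, b in walk.adjacencies():
            key, data = self._ensure_edge(a.gene, b.gene)
            if key == (a.gene, b.gene):
                data.add_observation(walk.genome, walk.contig, a.score, b.score)
            else:
                data.add_observation(walk.genome, walk.contig, b.score, a.score)
        self._adj = None

    # -- oriented adjacency view ------------------------------------------
    def _build_adj(self) -> dict[OrientedGene, list[OrientedGene]]:
        adj: dict[OrientedGene, list[OrientedGene]] = {}
        for (x, y) in self.edges:
            adj.setdefault(x, []).append(y)
            adj.setdefault(y.flipped, []).append(x.flipped)
        for lst in adj.values():
            lst.sort(key=OrientedGene.sort_key)
        return adj

    def out_neighbors(self, x: OrientedGene) -> list[OrientedGene]:
        if self._adj is None:
            self._adj = self._build_adj()
        return self._adj.get(x, [])

    def oriented_genes(self) -> list[OrientedGene]:
        out = []
        for g in sorted(self.catalog.genes):
            out.append(OrientedGene(g, FORWARD))
            out.append(OrientedGene(g, REVERSE))
        return out

    def degree(self, gene: str) -> int:
        """Number of distinct canonical edges incident to a gene."""
        n = 0
        for (x, y) in self.edges:
            if x.gene == gene or y.gene == gene:
                n += 1
        return n


def edge_score(graph: BidirectedGraph, x: OrientedGene, y: OrientedGene) -> float:
    """Mean alignment score S(x|y) of x over the contigs supporting x -> y.

    Note S(x|y) and S(~y|~x) generally differ: they average the scores of
    different genes over the same supporting contigs.
    """
    key = canonical_edge(x, y)
    data = graph.edge_data(x, y)
    if key == (x, y):
        return data.mean_fwd()
    return data.mean_rev()


def add_walk_edges(graph: BidirectedGraph, walk: ContigWalk) -> BidirectedGraph:
    """Insert a walk and all its adjacencies into the graph (in place)."""
    graph.add_walk(walk)
    return graph
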