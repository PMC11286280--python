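"""Graph construction, score-based adjustment heuristics, and gene filters.

Two annotation artifacts are corrected from graph topology plus alignment
scores:

* **False edges** — a gene whose true locus is missing from a haplotype (for
  example an X-chromosome gene in a male assembly) gets placed at a paralogous
  locus, wiring it to neighbors it never co-occurs with elsewhere.  An edge
  x->y is false when some alternative x->z exists with y and z never on one
  contig in any genome and S(x|y) < S(x|z) * r1.  Alignments of x incident to
  a false edge are dropped and the walks rebuilt.

* **Low-priority placements** — when a gene's real copy was deleted, its
  protein can still outscore the resident paralog at the paralog's locus.  An
  edge x->y is low priority when some x->z exists with y and z on the same
  contig in some genome and S(x|y) < S(x|z) * r2.  Incident alignments of x
  are demoted so that an unflagged competitor wins the locus on rebuild.

After adjustment, structural filters remove weakly supported edges,
single-coding-exon genes, promiscuous genes (too many edges) and genes
connecting too many distinct loci; finally genes are classified core or
accessory from their presence fraction across genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .alignments import AlignmentRecord
from .model import (BidirectedGraph, ContigWalk, GeneCatalog, OrientedGene,
                    canonical_edge, edge_score)
from .orthology import build_walks_with_records, compute_dominance, select_genes
from .util import ConfigError

log = logging.getLogger(__name__)


@dataclass
class AdjustParams:
    """Tunables of graph adjustment, filtering and classification.

    The score-ratio thresholds r1 (false edge, 0.95) and r2 (low priority,
    0.98), the bubble BFS cap m=100, the degree cap 10 and the locus cap 3
    are the tool's shipped defaults.
    """

    r1: float = 0.95
    r2: float = 0.98
    rounds: int = 2
    min_edge_support: int = 1
    max_degree: int = 10
    max_loci: int = 3
    presence_floor: float = 0.05
    core_fraction: float = 0.99
    drop_single_exon: bool = False
    overlap_frac: float = 0.5
    unspliced_mode: str = "cross_sample"
    decrement_rule: str = "score_gated"
    bubble_cap: int = 100

    def __post_init__(self):
        for name in ("r1", "r2"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.r1 > self.r2:
            log.warning("r1=%g > r2=%g: the false-edge threshold normally "
                        "sits below the low-priority threshold", self.r1, self.r2)
        if self.rounds < 1:
            raise ConfigError("rounds must be >= 1")


def build_graph(walks: Sequence[ContigWalk],
                catalog: GeneCatalog | None = None) -> BidirectedGraph:
    """Bidirected graph with every walk adjacency as a supported, scored edge."""
    graph = BidirectedGraph(catalog)
    for walk in walks:
        graph.add_walk(walk)
    return graph


def _contigs_of_gene(graph: BidirectedGraph) -> dict[str, set[tuple[str, str]]]:
    occ: dict[str, set[tuple[str, str]]] = {}
    for walk in graph.walks:
        for step in walk.steps:
            occ.setdefault(step.gene.gene, set()).add(walk.contig_key)
    return occ


def _flag_edges(graph: BidirectedGraph, ratio: float,
                same_contig: bool) -> set[tuple[OrientedGene, OrientedGene]]:
    """Directed pairs x->y dominated by an alternative x->z at ``ratio``.

    ``same_contig`` selects the co-occurrence condition: low-priority flags
    need y and z together on one contig somewhere; false-edge flags need them
    on different contigs in every genome.
    """
    occ = _contigs_of_gene(graph)
    flagged: set[tuple[OrientedGene, OrientedGene]] = set()
    oriented = sorted({x for (x, y) in graph.edges} |
                      {y.flipped for (x, y) in graph.edges},
                      key=OrientedGene.sort_key)
    for x in oriented:
        out = graph.out_neighbors(x)
        if len(out) < 2:
            continue
        scores = {y: edge_score(graph, x, y) for y in out}
        for y in out:
            for z in out:
                if y == z or y.gene == z.gene:
                    continue
                share = bool(occ.get(y.gene, set()) & occ.get(z.gene, set()))
                if share != same_contig:
                    continue
                if scores[y] < scores[z] * ratio:
                    flagged.add((x, y))
                    break
    return flagged


def mark_false_edges(graph: BidirectedGraph, r1: float = 0.95) \
        -> set[tuple[OrientedGene, OrientedGene]]:
    """Flag directed edges x->y outcompeted by a never-co-occurring x->z.

    The canonical edge also gets its ``false_edge`` flag set (covering the
    mirror direction).  The inequality is strict: S(x|y) = S(x|z)*r1 exactly
    does not flag.
    """
    flagged = _flag_edges(graph, r1, same_contig=False)
    for (x, y) in flagged:
        graph.edge_data(x, y).false_edge = True
    return flagged


def mark_low_priority(graph: BidirectedGraph, r2: float = 0.98) \
        -> set[tuple[OrientedGene, OrientedGene]]:
    """Flag directed edges x->y outcompeted by a same-contig alternative x->z."""
    flagged = _flag_edges(graph, r2, same_contig=True)
    for (x, y) in flagged:
        graph.edge_data(x, y).low_priority = True
    return flagged


def _incident_records(
        walks: Sequence[ContigWalk],
        placements: dict[tuple[str, str, int], list[AlignmentRecord]],
        flagged: set[tuple[OrientedGene, OrientedGene]]) -> set[AlignmentRecord]:
    """Alignments whose walk placement realizes a flagged directed edge x->y
    on the x side (in either reading direction of the contig)."""
    hit: set[AlignmentRecord] = set()
    for walk in walks:
        recs = placements[walk.key]
        genes = [s.gene for s in walk.steps]
        for i, g in enumerate(genes):
            if i + 1 < len(genes) and (g, genes[i + 1]) in flagged:
                hit.add(recs[i])
            if i > 0 and (g.flipped, genes[i - 1].flipped) in flagged:
                hit.add(recs[i])
    return hit


@dataclass
class AdjustResult:
    graph: BidirectedGraph
    walks: list[ContigWalk]
    catalog: GeneCatalog
    selected: set[str]
    removed_records: set[AlignmentRecord]
    low_priority_records: set[AlignmentRecord]
    log: list[tuple] = field(default_factory=list)  # (round, rule, x, y, S(x|y))


def adjust(records: Iterable[AlignmentRecord], params: AdjustParams,
           catalog: GeneCatalog | None = None) -> AdjustResult:
    """Select genes, build walks and iterate flag-and-rebuild adjustment.

    Each round builds the walks and graph, marks false edges (dropping the
    incident alignments) and low-priority edges (demoting the incident
    alignments), then rebuilds.  A round without new flags is a fixed point;
    otherwise iteration stops at the round limit.  Setting r1 = r2 -> 0
    disables all flags and reduces this to plain walk/graph construction.
    """
    records = list(records)
    if catalog is None:
        catalog = GeneCatalog()
        for r in records:
            catalog.add_gene(r.gene, r.protein)
    table = compute_dominance(records, params.overlap_frac)
    selected = select_genes(table, params.decrement_rule)

    removed: set[AlignmentRecord] = set()
    lowprio: set[AlignmentRecord] = set()
    logrows: list[tuple] = []
    walks: list[ContigWalk] = []
    graph = BidirectedGraph(catalog)
    for rnd in range(params.rounds):
        walks, placements = build_walks_with_records(
            records, selected, params.overlap_frac,
            low_priority=lowprio, removed=removed)
        graph = build_graph(walks, catalog)
        if rnd == params.rounds - 1:
            break
        false_dir = mark_false_edges(graph, params.r1)
        low_dir = mark_low_priority(graph, params.r2)
        new_removed = _incident_records(walks, placements, false_dir) - removed
        new_low = _incident_records(walks, placements, low_dir) - lowprio - removed
        for (x, y) in sorted(false_dir, key=lambda e: (e[0].sort_key(), e[1].sort_key())):
            logrows.append((rnd, "false_edge", str(x), str(y), edge_score(graph, x, y)))
        for (x, y) in sorted(low_dir, key=lambda e: (e[0].sort_key(), e[1].sort_key())):
            logrows.append((rnd, "low_priority", str(x), str(y), edge_score(graph, x, y)))
        if not new_removed and not new_low:
            break
        removed |= new_removed
        lowprio |= new_low
    else:  # pragma: no cover - loop always breaks at the last round
        pass
    if removed or lowprio:
        # annotate the final graph's flags for reporting
        mark_false_edges(graph, params.r1)
        mark_low_priority(graph, params.r2)
    return AdjustResult(graph=graph, walks=walks, catalog=catalog,
                        selected=selected, removed_records=removed,
                        low_priority_records=lowprio, log=logrows)


# ---------------------------------------------------------------------------
# walk surgery

def _renumber_parts(walks: list[ContigWalk]) -> list[ContigWalk]:
    counter: dict[tuple[str, str], int] = {}
    out = []
    for w in walks:
        part = counter.get(w.contig_key, 0)
        counter[w.contig_key] = part + 1
        out.append(ContigWalk(w.genome, w.contig, w.steps, part=part))
    return out


def _split_walks_on_edges(walks: Sequence[ContigWalk], bad: set) -> list[ContigWalk]:
    out: list[ContigWalk] = []
    for w in walks:
        run = [w.steps[0]]
        for a, b in w.adjacencies():
            if canonical_edge(a.gene, b.gene) in bad:
                out.append(ContigWalk(w.genome, w.contig, run))
                run = [b]
            else:
                run.append(b)
        out.append(ContigWalk(w.genome, w.contig, run))
    return _renumber_parts(out)


def _excise_genes(walks: Sequence[ContigWalk], genes: set[str]) -> list[ContigWalk]:
    """Remove every step of the given genes; walks split at removals (the
    severed flanks do not become adjacent)."""
    out: list[ContigWalk] = []
    for w in walks:
        run: list = []
        for step in w.steps:
            if step.gene.gene in genes:
                if run:
                    out.append(ContigWalk(w.genome, w.contig, run))
                run = []
            else:
                run.append(step)
        if run:
            out.append(ContigWalk(w.genome, w.contig, run))
    return _renumber_parts(out)


def _locus_count(graph: BidirectedGraph, gene: str) -> int:
    """Number of distinct flank contexts a gene occurs in.

    Each occurrence contributes its (left, right) neighbor pair, normalized
    for orientation; contexts sharing either flank merge into one locus.
    """
    contexts: list[tuple[str | None, str | None]] = []
    for walk in graph.walks:
        steps = walk.steps
        for i, s in enumerate(steps):
            if s.gene.gene != gene:
                continue
            left = steps[i - 1].gene.gene if i > 0 else None
            right = steps[i + 1].gene.gene if i + 1 < len(steps) else None
            if s.gene.orient == "<":
                left, right = right, left
            contexts.append((left, right))
    if not contexts:
        return 0
    parent = list(range(len(contexts)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(contexts)):
        for j in range(i + 1, len(contexts)):
            li, ri = contexts[i]
            lj, rj = contexts[j]
            if (li is not None and li == lj) or (ri is not None and ri == rj):
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pj] = pi
    return len({find(i) for i in range(len(contexts))})


def _rebuild(walks: list[ContigWalk], catalog: GeneCatalog) -> BidirectedGraph:
    """Fresh graph over the surviving walks; the catalog is restricted to the
    genes still present so removed genes leave the vertex set too."""
    kept = {s.gene.gene for w in walks for s in w.steps}
    sub = GeneCatalog(
        genes=kept,
        protein_of={g: p for g, p in catalog.protein_of.items() if g in kept},
        exon_counts={k: v for k, v in catalog.exon_counts.items()
                     if k[0] in kept},
        protein_len={g: v for g, v in catalog.protein_len.items() if g in kept})
    g = BidirectedGraph(sub)
    for w in walks:
        g.add_walk(w)
    return g


def apply_filters(graph: BidirectedGraph, params: AdjustParams) -> BidirectedGraph:
    """Structural filters in fixed order: edge support, single-exon genes,
    degree cap, locus cap.  Removed genes are excised from walks (walks split
    at the removals) and the graph is rebuilt after each stage."""
    catalog = graph.catalog
    walks = list(graph.walks)

    if params.min_edge_support > 1:
        weak = {key for key, d in graph.edges.items()
                if d.support < params.min_edge_support}
        if weak:
            walks = _split_walks_on_edges(walks, weak)
            graph = _rebuild(walks, catalog)

    if params.drop_single_exon:
        single = {g for g in graph.genes if catalog.max_exons(g) == 1}
        if single:
            walks = _excise_genes(walks, single)
            graph = _rebuild(walks, catalog)

    busy = {g for g in graph.genes if graph.degree(g) > params.max_degree}
    if busy:
        walks = _excise_genes(walks, busy)
        graph = _rebuild(walks, catalog)

    sprawling = {g for g in graph.genes if _locus_count(graph, g) > params.max_loci}
    if sprawling:
        walks = _excise_genes(walks, sprawling)
        graph = _rebuild(walks, catalog)
    return graph


@dataclass
class PresenceMatrix:
    """Per-gene per-genome copy numbers observed in the walks."""

    counts: dict[tuple[str, str], int]
    genomes: list[str]
    genes: list[str]

    def copy_number(self, gene: str, genome: str) -> int:
        return self.counts.get((gene, genome), 0)

    def presence_fraction(self, gene: str) -> float:
        if not self.genomes:
            return 0.0
        n = sum(1 for gm in self.genomes if self.counts.get((gene, gm), 0) > 0)
        return n / len(self.genomes)

    def pav_genes(self, max_fraction: float) -> list[str]:
        """Genes present in at most the given fraction of genomes."""
        return [g for g in self.genes if self.presence_fraction(g) <= max_fraction]

    def to_dataframe(self):
        import pandas as pd
        data = {gm: [self.counts.get((g, gm), 0) for g in self.genes]
                for gm in self.genomes}
        return pd.DataFrame(data, index=self.genes)


def presence_matrix(graph: BidirectedGraph,
                    all_genomes: Sequence[str] | None = None) -> PresenceMatrix:
    counts: dict[tuple[str, str], int] = {}
    genomes = set(all_genomes) if all_genomes else set()
    for walk in graph.walks:
        genomes.add(walk.genome)
        for step in walk.steps:
            key = (step.gene.gene, walk.genome)
            counts[key] = counts.get(key, 0) + 1
    return PresenceMatrix(counts=counts, genomes=sorted(genomes),
                          genes=sorted(graph.genes))


def presence_and_core(graph: BidirectedGraph, params: AdjustParams,
                      all_genomes: Sequence[str] | None = None
                      ) -> tuple[PresenceMatrix, dict[str, str], BidirectedGraph]:
    """Copy-number matrix, core/accessory labels and the presence-filtered graph.

    Genes below the presence floor p are excised; remaining genes are labeled
    ``core`` when present in at least ``core_fraction`` of genomes, otherwise
    ``accessory``.
    """
    matrix = presence_matrix(graph, all_genomes)
    rare = {g for g in matrix.genes if matrix.presence_fraction(g) < params.presence_floor}
    if rare:
        walks = _excise_genes(list(graph.walks), rare)
        graph = _rebuild(walks, graph.catalog)
        matrix = presence_matrix(graph, all_genomes)
    labels = {g: ("core" if matrix.presence_fraction(g) >= params.core_fraction
                  else "accessory")
              for g in matrix.genes}
    return matrix, labels, graph
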