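"""Non-orthologous gene selection and per-contig walk assembly.

When the input protein set contains two orthologous genes, their best hits
land on the same locus in every genome, and a per-locus best-score annotation
would split the locus between them across genomes, turning a core gene into
two spurious accessory genes.  The selection below elects one representative
per locus: each gene v earns a dominance count b(v) — the number of genomes
where its best hit outscores every overlapping gene's best hit — and genes
are then accepted greedily in descending order of the *current* b(v), with
competitors at the claimed locus paying for the lost genome.

Paralogs have disjoint best loci, earn independent dominance and are all
retained.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alignments import AlignmentRecord, records_overlap
from .model import FORWARD, REVERSE, ContigWalk, GeneCatalog, OrientedGene, WalkStep
from .util import fnv1a64


@dataclass
class BestHitTable:
    """Best hit per (gene, genome), the per-genome overlap relation between
    best hits, and the dominance counts b."""

    best: dict[tuple[str, str], AlignmentRecord] = field(default_factory=dict)
    # genome -> gene -> set of genes whose best hits overlap this gene's best
    overlaps: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    b: dict[str, int] = field(default_factory=dict)
    genomes: set[str] = field(default_factory=set)

    def to_rows(self) -> list[tuple[str, str, int, int]]:
        """Debug dump: (gene, genome, best score, b)."""
        return sorted((g, gm, r.score, self.b.get(g, 0))
                      for (g, gm), r in self.best.items())


def _beats(score_a: int, gene_a: str, score_b: int, gene_b: str) -> bool:
    """Strict score comparison with the FNV-1a name hash as tie-break."""
    if score_a != score_b:
        return score_a > score_b
    return fnv1a64(gene_a) < fnv1a64(gene_b)


def compute_dominance(records: Iterable[AlignmentRecord],
                      overlap_frac: float = 0.5) -> BestHitTable:
    """Best hit per gene per genome and the dominance count b(v).

    b(v) counts the genomes in which v's best hit outscores the best hit of
    every gene overlapping it (overlap = at least ``overlap_frac`` of the
    shorter interval on the same contig); exact score ties are resolved by
    name hash.
    """
    table = BestHitTable()
    for r in records:
        table.genomes.add(r.genome)
        key = (r.gene, r.genome)
        cur = table.best.get(key)
        # highest score wins; among equal scores keep the smallest
        # (contig, start, end) so the choice is input-order independent
        if cur is None or r.score > cur.score or (
                r.score == cur.score and
                (r.contig, r.start, r.end) < (cur.contig, cur.start, cur.end)):
            table.best[key] = r

    by_genome_contig: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for (gene, genome), r in table.best.items():
        by_genome_contig.setdefault((genome, r.contig), []).append(r)

    for (genome, _), hits in by_genome_contig.items():
        omap = table.overlaps.setdefault(genome, {})
        hits.sort(key=lambda r: (r.start, r.end, r.gene))
        for i, a in enumerate(hits):
            for b_rec in hits[i + 1:]:
                if b_rec.start >= a.end:
                    break
                if records_overlap(a, b_rec, overlap_frac):
                    omap.setdefault(a.gene, set()).add(b_rec.gene)
                    omap.setdefault(b_rec.gene, set()).add(a.gene)

    genes = {g for (g, _) in table.best}
    for g in genes:
        table.b[g] = 0
    for (gene, genome), r in table.best.items():
        rivals = table.overlaps.get(genome, {}).get(gene, set())
        dominant = all(
            _beats(r.score, gene, table.best[(w, genome)].score, w)
            for w in rivals)
        if dominant:
            table.b[gene] += 1
    return table


def select_genes(table: BestHitTable, rule: str = "score_gated") -> set[str]:
    """Greedy non-ortholog selection in descending order of current b(v).

    When v is selected, every unprocessed gene w whose best mapping overlaps
    v's best mapping in some genome loses one count for that genome — under
    the default ``score_gated`` rule only when w's best hit there outscores
    v's (v absorbs the genomes where a better-scoring competitor would
    otherwise have split the locus); under ``claim_locus`` unconditionally.
    Genes whose current b reaches 0 before their turn are not selected.
    """
    if rule not in ("score_gated", "claim_locus"):
        raise ValueError(f"unknown decrement rule {rule!r}")
    b = dict(table.b)
    heap = [(-n, fnv1a64(g), g) for g, n in b.items()]
    heapq.heapify(heap)
    processed: set[str] = set()
    selected: set[str] = set()
    while heap:
        negn, _, v = heapq.heappop(heap)
        if v in processed:
            continue
        if -negn != b[v]:  # stale entry: re-queue with the current count
            heapq.heappush(heap, (-b[v], fnv1a64(v), v))
            continue
        processed.add(v)
        if b[v] <= 0:
            continue
        selected.add(v)
        for genome in table.genomes:
            key = (v, genome)
            if key not in table.best:
                continue
            v_score = table.best[key].score
            for w in table.overlaps.get(genome, {}).get(v, set()):
                if w in processed:
                    continue
                if rule == "score_gated" and not _beats(
                        table.best[(w, genome)].score, w, v_score, v):
                    continue
                if b[w] > 0:
                    b[w] -= 1
                    heapq.heappush(heap, (-b[w], fnv1a64(w), w))
    return selected


def build_walks_with_records(
        records: Iterable[AlignmentRecord],
        selected: set[str],
        overlap_frac: float = 0.5,
        low_priority: frozenset | set = frozenset(),
        removed: frozenset | set = frozenset(),
) -> tuple[list[ContigWalk], dict[tuple[str, str, int], list[AlignmentRecord]]]:
    """Greedy per-contig placement of selected genes' alignments.

    Alignments are accepted per contig in priority order — unflagged before
    low-priority, then by descending score, ties by gene-name hash — skipping
    any hit that overlaps an accepted one by more than the overlap tolerance.
    Accepted hits sorted by start become the contig walk; orientation follows
    the alignment strand.  Contigs with no accepted hit yield no walk.
    """
    by_contig: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for r in records:
        if r.gene not in selected or r in removed:
            continue
        by_contig.setdefault((r.genome, r.contig), []).append(r)

    walks: list[ContigWalk] = []
    placements: dict[tuple[str, str, int], list[AlignmentRecord]] = {}
    for (genome, contig) in sorted(by_contig):
        hits = by_contig[(genome, contig)]
        hits.sort(key=lambda r: (r in low_priority, -r.score,
                                 fnv1a64(r.gene), r.start, r.end))
        accepted: list[AlignmentRecord] = []
        for r in hits:
            if any(records_overlap(r, a, overlap_frac) for a in accepted):
                continue
            accepted.append(r)
        if not accepted:
            continue
        accepted.sort(key=lambda r: (r.start, r.end))
        steps = [WalkStep(OrientedGene(r.gene, FORWARD if r.strand == "+" else REVERSE),
                          r.score, r.start, r.end)
                 for r in accepted]
        walk = ContigWalk(genome, contig, steps)
        walks.append(walk)
        placements[walk.key] = accepted
    return walks, placements


def build_walks(records: Iterable[AlignmentRecord], selected: set[str],
                catalog: GeneCatalog | None = None,
                overlap_frac: float = 0.5) -> list[ContigWalk]:
    walks, _ = build_walks_with_records(records, selected, overlap_frac)
    return walks
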