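"""GFA 1.1 serialization of gene graphs.

Segments are genes (not DNA), so S lines carry no sequence; the length tag is
the chosen protein length when known, else 1.  Each canonical edge becomes one
L line with overlap "0M" plus custom tags:

* ``sc:i`` — number of distinct supporting contigs,
* ``sf:f`` / ``sr:f`` — mean alignment score of the source gene in the
  canonical and the mirror direction respectively.

Each contig walk becomes a W line (sample = genome, SeqId = contig) whose
optional tags preserve per-step metadata so that a written graph reads back
losslessly:

* ``ss:Z`` — comma-separated per-step alignment scores,
* ``iv:Z`` — comma-separated 0-based half-open step intervals ``start-end``.
"""

from __future__ import annotations

import io
import re
from typing import TextIO

from .model import (FORWARD, REVERSE, BidirectedGraph, ContigWalk, EdgeData,
                    OrientedGene, WalkStep, canonical_edge)
from .util import GFAParseError, GFAValidationError

_ORIENT_TO_PM = {FORWARD: "+", REVERSE: "-"}
_PM_TO_ORIENT = {"+": FORWARD, "-": REVERSE}
_WALK_RE = re.compile(r"([><])([^><\s]+)")


def _fmt_score(v: float) -> str:
    return f"{v:g}"


def write_gfa(graph: BidirectedGraph, stream: TextIO) -> None:
    """Serialize a bidirected gene graph as GFA 1.1 text."""
    stream.write("H\tVN:Z:1.1\n")
    for gene in sorted(graph.catalog.genes):
        ln = graph.catalog.protein_len.get(gene, 1)
        stream.write(f"S\t{gene}\t*\tLN:i:{ln}\n")
    for (x, y) in sorted(graph.edges, key=lambda e: (e[0].sort_key(), e[1].sort_key())):
        d = graph.edges[(x, y)]
        stream.write(
            "L\t{}\t{}\t{}\t{}\t0M\tsc:i:{}\tsf:f:{}\tsr:f:{}\n".format(
                x.gene, _ORIENT_TO_PM[x.orient], y.gene, _ORIENT_TO_PM[y.orient],
                d.support, _fmt_score(d.mean_fwd()), _fmt_score(d.mean_rev())))
    for walk in graph.walks:
        path = "".join(f"{s.gene.orient}{s.gene.gene}" for s in walk.steps)
        ss = ",".join(str(int(s.score)) for s in walk.steps)
        iv = ",".join(f"{s.start}-{s.end}" for s in walk.steps)
        stream.write(
            f"W\t{walk.genome}\t0\t{walk.contig}\t{walk.steps[0].start}\t"
            f"{walk.steps[-1].end}\t{path}\tss:Z:{ss}\tiv:Z:{iv}\n")


def graph_to_gfa_string(graph: BidirectedGraph) -> str:
    buf = io.StringIO()
    write_gfa(graph, buf)
    return buf.getvalue()


def _parse_tags(fields: list[str], lineno: int) -> dict[str, str]:
    tags: dict[str, str] = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) != 3:
            raise GFAParseError(f"malformed tag {f!r}", lineno)
        tags[parts[0]] = parts[2]
    return tags


def read_gfa(stream: TextIO) -> BidirectedGraph:
    """Parse GFA 1.1 into a bidirected gene graph.

    Edges and their support are rebuilt from the walks when walks are present;
    every walk adjacency must be declared by an L line.  L-line edges that no
    walk covers are kept with their declared support/score tags (this is the
    situation for externally produced, walk-free GFA).
    """
    graph = BidirectedGraph()
    declared: dict[tuple, tuple[int, float, float]] = {}
    walk_specs: list[tuple[int, str, str, list[WalkStep]]] = []

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        kind = fields[0]
        if kind == "H":
            continue
        if kind == "S":
            if len(fields) < 3:
                raise GFAParseError("S line needs at least 3 fields", lineno)
            gene = fields[1]
            graph.add_gene(gene)
            tags = _parse_tags(fields[3:], lineno)
            if "LN" in tags:
                try:
                    graph.catalog.protein_len[gene] = int(tags["LN"])
                except ValueError:
                    raise GFAParseError(f"bad LN tag {tags['LN']!r}", lineno)
        elif kind == "L":
            if len(fields) < 6:
                raise GFAParseError("L line needs at least 6 fields", lineno)
            g1, o1, g2, o2 = fields[1], fields[2], fields[3], fields[4]
            if o1 not in _PM_TO_ORIENT or o2 not in _PM_TO_ORIENT:
                raise GFAParseError(f"bad orientation {o1!r}/{o2!r}", lineno)
            for g in (g1, g2):
                if g not in graph.catalog.genes:
                    raise GFAParseError(f"L line references unknown segment {g!r}", lineno)
            x = OrientedGene(g1, _PM_TO_ORIENT[o1])
            y = OrientedGene(g2, _PM_TO_ORIENT[o2])
            tags = _parse_tags(fields[6:], lineno)
            try:
                sup = int(tags.get("sc", "0"))
                sf = float(tags.get("sf", "0"))
                sr = float(tags.get("sr", "0"))
            except ValueError:
                raise GFAParseError("bad numeric tag on L line", lineno)
            key = canonical_edge(x, y)
            if key != (x, y):  # normalize declared direction to canonical
                sf, sr = sr, sf
            declared[key] = (sup, sf, sr)
        elif kind == "W":
            if len(fields) < 7:
                raise GFAParseError("W line needs at least 7 fields", lineno)
            genome, contig, path = fields[1], fields[3], fields[6]
            tokens = _WALK_RE.findall(path)
            if not tokens or "".join(o + g for o, g in tokens) != path:
                raise GFAParseError(f"malformed walk string {path!r}", lineno)
            tags = _parse_tags(fields[7:], lineno)
            if "ss" in tags:
                try:
                    scores = [int(v) for v in tags["ss"].split(",")]
                except ValueError:
                    raise GFAParseError("bad ss tag", lineno)
            else:
                scores = [0] * len(tokens)
            if "iv" in tags:
                try:
                    ivs = [tuple(int(p) for p in v.split("-")) for v in tags["iv"].split(",")]
                except ValueError:
                    raise GFAParseError("bad iv tag", lineno)
            else:
                ivs = [(i, i + 1) for i in range(len(tokens))]
            if len(scores) != len(tokens) or len(ivs) != len(tokens):
                raise GFAParseError("walk tag length mismatch", lineno)
            steps = []
            for (orient, g), sc, (a, b) in zip(tokens, scores, ivs):
                if g not in graph.catalog.genes:
                    raise GFAParseError(f"walk references unknown segment {g!r}", lineno)
                steps.append(WalkStep(OrientedGene(g, orient), sc, a, b))
            walk_specs.append((lineno, genome, contig, steps))
        else:
            raise GFAParseError(f"unknown record type {kind!r}", lineno)

    part_counter: dict[tuple[str, str], int] = {}
    for lineno, genome, contig, steps in walk_specs:
        part = part_counter.get((genome, contig), 0)
        part_counter[(genome, contig)] = part + 1
        walk = ContigWalk(genome, contig, steps, part=part)
        for a, b in walk.adjacencies():
            if canonical_edge(a.gene, b.gene) not in declared:
                raise GFAValidationError(
                    f"walk step {a.gene} -> {b.gene} (line {lineno}) has no matching L line")
        graph.add_walk(walk)

    # L-line edges not covered by any walk keep their declared annotation.
    for key, (sup, sf, sr) in declared.items():
        if key not in graph.edges:
            data = EdgeData()
            data._declared_support = sup
            data._declared_means = (sf, sr)
            graph.edges[key] = data
    graph._adj = None
    return graph


def graph_from_gfa_string(text: str) -> BidirectedGraph:
    return read_gfa(io.StringIO(text))
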