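"""Shared fixtures: small hand-built graphs and simulation-backed graphs."""

from __future__ import annotations

import pytest

import genegraph as gg
from genegraph.model import OrientedGene


def og(token: str) -> OrientedGene:
    return OrientedGene.parse(token)


def graph_from_walks(*walks, scores=None):
    """Build a graph from (genome, [">A", ...]) pairs; one contig per walk."""
    g = gg.BidirectedGraph()
    counters = {}
    for spec in walks:
        genome, tokens = spec[0], spec[1]
        idx = counters.get(genome, 0)
        counters[genome] = idx + 1
        sc = spec[2] if len(spec) > 2 else None
        g.add_walk(gg.walk_from_tokens(genome, f"c{idx}", tokens, scores=sc))
    return g


def sim_graph(cfg: gg.SimConfig):
    """Graph built directly from simulated gene walks (no alignment noise)."""
    genomes, truth = gg.simulate(cfg)
    g = gg.BidirectedGraph()
    for genome, contigs in genomes.items():
        for ci, walk in enumerate(contigs):
            g.add_walk(gg.walk_from_tokens(genome, f"chr{ci + 1}", walk))
    return g, truth


def bubble_keys(bubbles):
    return [(str(b.entry), str(b.exit), tuple(sorted(b.interior)))
            for b in bubbles]


@pytest.fixture
def inversion_graph():
    """Gene B inverted between A and C; (>A, <C) is the bibubble."""
    return graph_from_walks(("s1", [">A", ">B", "<C"]),
                            ("s2", [">A", "<B", "<C"]))


@pytest.fixture
def partial_inversion_graph():
    """Four-gene graph where (>A, >D) is the bibubble while (>A, <C) fails
    the symmetric-interior condition: U(>A,<C) = {B, C} but U(>C,<A) = {B}."""
    return graph_from_walks(("s1", [">A", ">B", "<C", ">D"]),
                            ("s2", [">A", ">C"]))


@pytest.fixture
def asymmetric_inversion_graph():
    """Inversions wired asymmetrically; contains no bibubble at all."""
    return graph_from_walks(("s1", [">A", ">B", "<C"]),
                            ("s2", [">A", "<B", ">C"]))


@pytest.fixture
def two_allele_graph():
    """C and D are alternative alleles between A and B: they are cycle
    equivalent in the net graph, yet no (C, D) pair is a bibubble."""
    return graph_from_walks(("s1", [">A", ">C", ">B"]),
                            ("s2", [">A", ">D", ">B"]))


@pytest.fixture
def deletion_graph():
    """B deleted in one genome: edges A->B, B->C, A->C."""
    return graph_from_walks(("s1", [">A", ">B", ">C"]),
                            ("s2", [">A", ">C"]))
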