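"""Graph construction, adjustment heuristics, structural filters, presence."""

import pytest

import genegraph as gg
from genegraph.buildgraph import _locus_count
from genegraph.util import ConfigError

from conftest import graph_from_walks, og


class TestBuildGraph:
    def test_chain(self):
        g = graph_from_walks(("s1", [">A", ">B", ">C"]))
        assert len(g.genes) == 3 and len(g.edges) == 2

    def test_deletion_creates_branch(self):
        g = graph_from_walks(("s1", [">A", ">B", ">C"]), ("s2", [">A", ">C"]))
        assert len(g.edges) == 3
        assert {str(w) for w in g.out_neighbors(og(">A"))} == {">B", ">C"}

    def test_inversion_edges(self):
        g = graph_from_walks(("s1", [">A", "<B", ">C"]))
        assert g.has_edge(og(">A"), og("<B"))
        assert g.has_edge(og("<B"), og(">C"))


class TestAdjustParams:
    def test_shipped_defaults(self):
        p = gg.AdjustParams()
        assert (p.r1, p.r2) == (0.95, 0.98)
        assert p.bubble_cap == 100
        assert p.max_degree == 10 and p.max_loci == 3
        assert p.min_edge_support == 1 and p.rounds == 2

    def test_ratio_bounds_enforced(self):
        with pytest.raises(ConfigError):
            gg.AdjustParams(r1=0.0)
        with pytest.raises(ConfigError):
            gg.AdjustParams(r2=1.5)


def scored(*walks):
    return graph_from_walks(*walks)


class TestFalseEdges:
    def graph(self, decoy_score):
        # x=>V has alternatives >Q (one contig) and >X2 (others); Q and X2
        # never share a contig
        return graph_from_walks(
            ("m", [">P", ">V", ">Q"], [1000, decoy_score, 1000]),
            ("f1", [">X1", ">V", ">X2"], [1000, 1000, 1000]),
            ("f1", [">P", ">Q"], [1000, 1000]),
        )

    def test_weak_cross_contig_alternative_flagged(self):
        flagged = gg.mark_false_edges(self.graph(930), r1=0.95)
        assert (og(">V"), og(">Q")) in flagged
        assert (og("<V"), og("<P")) in flagged

    def test_exact_threshold_not_flagged(self):
        flagged = gg.mark_false_edges(self.graph(950), r1=0.95)
        assert flagged == set()

    def test_same_contig_somewhere_never_false(self):
        # Q and X2 co-occur on one contig: no false edge however low the score
        g = graph_from_walks(
            ("m", [">V", ">Q"], [500, 1000]),
            ("f1", [">V", ">X2"], [1000, 1000]),
            ("f1", [">Q", ">X2"], [1000, 1000]),
        )
        assert gg.mark_false_edges(g, r1=0.95) == set()


class TestLowPriority:
    def graph(self, score_h2):
        return graph_from_walks(
            ("h1", [">T", ">D7", ">D6", ">W"], [1000, 980, 1000, 1000]),
            ("h2", [">T", ">D6", ">W"], [1000, score_h2, 1000]),
        )

    def test_same_contig_alternative_flagged(self):
        flagged = gg.mark_low_priority(self.graph(970), r2=0.98)
        assert (og("<D6"), og("<T")) in flagged

    def test_at_threshold_not_flagged(self):
        flagged = gg.mark_low_priority(self.graph(980), r2=0.98)
        assert flagged == set()


class TestAdjust:
    def test_missing_contig_decoy_removed(self):
        res = gg.adjust(gg.missing_contig_fixture(), gg.AdjustParams())
        male = next(w for w in res.walks if w.genome == "s04")
        assert [str(s.gene) for s in male.steps] == [">A1", ">P", ">Q", ">A2"]
        assert not res.graph.has_edge(og(">P"), og(">V"))
        assert not res.graph.has_edge(og(">V"), og(">Q"))
        assert res.graph.has_edge(og(">P"), og(">Q"))
        # the real locus on the other contig is untouched
        assert res.graph.has_edge(og(">X1"), og(">V"))

    def test_same_contig_paralog_reannotated(self):
        res = gg.adjust(gg.same_contig_paralog_fixture(), gg.AdjustParams())
        h2 = next(w for w in res.walks if w.genome == "h2")
        assert [str(s.gene) for s in h2.steps] == [">T", ">D7", ">W"]
        assert not res.graph.has_edge(og(">T"), og(">D6"))
        assert res.graph.has_edge(og(">T"), og(">D7"))

    def test_clean_input_is_fixed_point(self):
        cfg = gg.SimConfig(n_genes=20, n_genomes=4, seed=5)
        genomes, _ = gg.simulate(cfg)
        records = gg.emit_alignments(genomes, cfg)
        res1 = gg.adjust(records, gg.AdjustParams(rounds=1))
        res2 = gg.adjust(records, gg.AdjustParams(rounds=3))
        assert set(res1.graph.edges) == set(res2.graph.edges)
        assert not res2.removed_records and not res2.low_priority_records

    def test_higher_r1_flags_more(self):
        # score ratio 0.97 sits between r1=0.95 (no flag) and r1=1.0 (flag)
        records = gg.missing_contig_fixture(decoy_ratio=0.97)
        lo = gg.adjust(records, gg.AdjustParams(r1=0.95))
        hi = gg.adjust(records, gg.AdjustParams(r1=0.999))
        assert len(lo.removed_records) == 0
        assert len(hi.removed_records) > 0

    def test_tiny_thresholds_disable_adjustment(self):
        records = gg.missing_contig_fixture()
        off = gg.adjust(records, gg.AdjustParams(r1=1e-9, r2=1e-9))
        plain = gg.adjust(records, gg.AdjustParams(rounds=1))
        assert set(off.graph.edges) == set(plain.graph.edges)

    def test_adjustment_never_adds_edges(self):
        records = gg.missing_contig_fixture()
        initial = gg.adjust(records, gg.AdjustParams(rounds=1))
        adjusted = gg.adjust(records, gg.AdjustParams())
        assert set(adjusted.graph.edges) <= set(initial.graph.edges) | {
            k for k in adjusted.graph.edges
            if k not in initial.graph.edges}
        # only the closure edge P-Q may appear; no edge involving the
        # removed placement survives
        new = set(adjusted.graph.edges) - set(initial.graph.edges)
        assert all({x.gene, y.gene} == {"P", "Q"} for x, y in new)


class TestFilters:
    def test_support_pruning_splits_walks(self):
        g = graph_from_walks(("s1", [">A", ">B", ">C"]),
                             ("s2", [">A", ">B"]),
                             ("s3", [">A", ">B"]))
        out = gg.apply_filters(g, gg.AdjustParams(min_edge_support=2))
        assert out.has_edge(og(">A"), og(">B"))
        assert not out.has_edge(og(">B"), og(">C"))
        assert {tuple(str(s.gene) for s in w.steps) for w in out.walks} == \
            {(">A", ">B"), (">C",)}

    def test_degree_cap_removes_promiscuous_gene(self):
        walks = [(f"s{i}", [f">L{i}", ">HUB", f">R{i}"]) for i in range(6)]
        g = graph_from_walks(*walks)
        assert g.degree("HUB") == 12
        out = gg.apply_filters(g, gg.AdjustParams(max_degree=10))
        assert "HUB" not in {s.gene.gene for w in out.walks for s in w.steps}
        out2 = gg.apply_filters(g, gg.AdjustParams(max_degree=12, max_loci=99))
        assert any(s.gene.gene == "HUB" for w in out2.walks for s in w.steps)

    def test_single_exon_gene_dropped_when_configured(self):
        g = graph_from_walks(("s1", [">A", ">E1", ">B"]))
        g.catalog.exon_counts.update({("A", "s1"): 5, ("E1", "s1"): 1,
                                      ("B", "s1"): 4})
        out = gg.apply_filters(g, gg.AdjustParams(drop_single_exon=True))
        assert "E1" not in {s.gene.gene for w in out.walks for s in w.steps}
        # severed flanks do not become adjacent
        assert not out.has_edge(og(">A"), og(">B"))

    def test_locus_count_merges_shared_flanks(self):
        g = graph_from_walks(("s1", [">A", ">V", ">B"]),
                             ("s2", [">A", ">V", ">C"]),   # shares left flank
                             ("s3", [">D", ">V", ">E"]))
        assert _locus_count(g, "V") == 2

    def test_permissive_settings_leave_graph_unchanged(self):
        g = graph_from_walks(("s1", [">A", ">B", ">C"]), ("s2", [">A", ">C"]))
        out = gg.apply_filters(g, gg.AdjustParams())
        assert set(out.edges) == set(g.edges)
        assert len(out.walks) == len(g.walks)

    def test_filters_preserve_skew_symmetry(self):
        from genegraph.model import canonical_edge, flip
        cfg = gg.SimConfig(n_genes=25, n_genomes=4, deletion_rate=1.5,
                           duplication_rate=1.0, inversion_rate=1.0, seed=11)
        from conftest import sim_graph
        g, _ = sim_graph(cfg)
        out = gg.apply_filters(g, gg.AdjustParams(min_edge_support=2,
                                                  max_degree=4, max_loci=2))
        for (x, y) in out.edges:
            assert canonical_edge(flip(y), flip(x)) == (x, y)
            assert out.has_edge(flip(y), flip(x))


class TestPresence:
    def graph(self):
        return graph_from_walks(
            ("g1", [">A", ">B", ">B", ">C"]),
            ("g2", [">A", ">C"]),
            ("g3", [">A", ">B", ">C"]),
            ("g4", [">A", ">C"]),
        )

    def test_copy_numbers_and_fractions(self):
        matrix = gg.presence_matrix(self.graph())
        assert matrix.copy_number("B", "g1") == 2
        assert matrix.copy_number("B", "g2") == 0
        assert matrix.presence_fraction("B") == 0.5
        assert matrix.presence_fraction("A") == 1.0

    def test_core_accessory_labels(self):
        matrix, labels, _ = gg.presence_and_core(
            self.graph(), gg.AdjustParams(core_fraction=0.99))
        assert labels["A"] == "core" and labels["C"] == "core"
        assert labels["B"] == "accessory"
        assert "B" in matrix.pav_genes(0.5)
        assert "A" not in matrix.pav_genes(0.5)

    def test_presence_floor_excises_rare_gene(self):
        g = self.graph()
        _, labels, out = gg.presence_and_core(
            g, gg.AdjustParams(presence_floor=0.6))
        assert "B" not in labels
        assert "B" not in {s.gene.gene for w in out.walks for s in w.steps}

    def test_tiny_floor_keeps_everything(self):
        _, labels, _ = gg.presence_and_core(
            self.graph(), gg.AdjustParams(presence_floor=0.001))
        assert set(labels) == {"A", "B", "C"}

    def test_absent_genomes_counted_in_denominator(self):
        g = graph_from_walks(("g1", [">A", ">B"]))
        matrix = gg.presence_matrix(g, all_genomes=["g1", "g2"])
        assert matrix.presence_fraction("A") == 0.5
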