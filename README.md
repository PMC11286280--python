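# genegraph

Gene-level pangenome graphs: build a bidirected gene graph from
protein-to-genome alignments of many assemblies, clean it with score-based
heuristics, classify core and accessory genes, and report localized gene
order / copy-number / orientation variation as **generalized bibubbles**.

## Who this is for

Comparative and population genomicists with a set of annotated (or
protein-alignable) genome assemblies — human haplotypes, great-ape
assemblies, bacterial strain collections — who want a concise, gene-level
view of structural variation instead of a base-level sequence graph.
Whole-genome pangenome builders collapse paralogs or miss genes inside
segmental duplications; gene-annotation pipelines give per-genome gene lists
but no joint structure. This package takes the middle road: each gene is a
vertex, each contig is a walk, and variation is a subgraph.

## The model

Let `V` be the gene set and `X = V × {>, <}` the oriented genes (`>v`
forward, `<v` reverse-complemented; `~x` flips orientation, `nu(x)` drops
it). A pair `(x, y)` is an edge `x -> y` when `y` immediately follows `x` on
some input contig; by DNA strand symmetry `~y -> ~x` is the same adjacency
(*skew symmetry*), stored once. Each edge carries its supporting contigs and
the mean alignment score `S(x|y)` of `x` over those contigs.

Construction has to survive redundant proteins, orthologs, paralogs and
annotation errors:

* **one protein per gene** — for `GeneID:ProteinID` inputs the
  highest-scoring protein represents the gene;
* **non-ortholog selection** — each gene earns a dominance count `b(v)`, the
  number of genomes where its best hit outscores every overlapping gene's
  best hit; genes are elected greedily by descending current `b(v)`, and a
  selected gene debits its displaced competitors, so orthologs collapse to
  one representative while paralogs (disjoint loci) all survive;
* **false edges** — `x -> y` is false when an alternative `x -> z` exists
  with `y`, `z` never on one contig in any genome and
  `S(x|y) < S(x|z) · r1` (default 0.95); incident alignments of `x` are
  dropped (a gene stranded on a paralogous contig because its own contig is
  missing);
* **low-priority placements** — same test with `y`, `z` on one contig
  somewhere and threshold `r2` (default 0.98); incident alignments are
  demoted so the resident paralog wins the locus on rebuild;
* **structural filters** — prune weakly supported edges, optionally drop
  single-coding-exon genes, drop genes with more than 10 distinct edges or
  connecting more than 3 distinct loci, then classify genes **core**
  (presence ≥ 99% of genomes) or **accessory**.

A **generalized bibubble** is a pair of oriented genes `(x, y)` with interior
`U(x, y)` — the genes reachable from `x` without passing `x`, `~x` or `y`
(passing `~y` is allowed, which is what lets inversions close a bubble) —
such that `U(x, y) = U(~y, ~x) ≠ ∅`, every interior gene lies on an `x → y`
walk, and the pair is minimal. Detection transforms the graph to a *net
graph* (split genes into endpoints, contract adjacency links; each gene is
one undirected net edge): a bubble boundary `{nu(x), nu(y)}` is a two-edge
cut-set, equivalently the two net edges are *cycle equivalent*. Classes are
computed in near-linear time with a DFS bracket-set algorithm and prune the
candidate exits for each entry; every candidate is validated against the
definition. A naive `O(|V|² (|V|+|E|))` enumeration of the definition ships
as an independent oracle, as does a SESE-style (single-entry single-exit,
dummy-rooted) candidate generator.

## Worked example

Simulate a 40-gene, 6-genome pangenome with deletions, tandem duplications
and inversions, build the graph, and mine it:

```sh
genegraph simulate --n-genes 40 --n-genomes 6 --seed 7 -o sim
# [INFO] wrote 6 genomes, 12 events, 1 expected bubbles to sim
genegraph build sim/manifest.tsv -o out
# [INFO] graph: 40 genes, 53 edges, 6 walks
genegraph bubble out/graph.gfa -o bubbles.tsv
# [INFO] 8 bibubbles
genegraph call out/graph.gfa -o calls
# [INFO] 30 core, 10 accessory, 1 PAV genes (<= 50%)
```

The first data rows of `bubbles.tsv`:

```
entry    exit     interior_size  interior              contains_inversion  alleles
>g0001   >g0005   3              g0002,g0003,g0004     1                   -:1;>g0002,<g0003,>g0004:1;>g0002,>g0003,>g0004:4
>g0002   >g0004   1              g0003                 1                   <g0003:1;>g0003:4
```

Read: between `g0001` and `g0005`, one genome lost the whole block (`-`),
one carries `g0003` inverted, four carry the ancestral arrangement; nested
inside, the single-gene inversion of `g0003` is itself a bibubble. The
`call` output labels each gene core/accessory with per-genome copy numbers,
and `pav.txt` lists genes present in at most half the genomes.

`genegraph build` writes the graph as GFA 1.1: `S` lines are genes (`LN` is
the chosen protein length, or 1 when unknown), `L` lines are canonical edges
with custom tags `sc:i` (supporting-contig count) and `sf:f`/`sr:f` (mean
forward/reverse scores), and `W` lines are contig walks with `ss:Z`
(per-step scores) and `iv:Z` (per-step intervals) tags so a written graph
reads back losslessly.

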