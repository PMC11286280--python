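# Methods

## Graph model

A pangenome gene graph is stored as a set of canonical edges over oriented
genes plus the contig walks that induced them. The canonical key of the
adjacency `{x -> y, ~y -> ~x}` is the lexicographically smaller of the two
directed renderings (byte order on gene names, `>` before `<`), which makes
storage, GFA emission and every downstream iteration order deterministic.
Edge support is counted per contig, not per occurrence; when one contig
realizes the same adjacency several times, its score contribution is the
mean over occurrences so the score lists stay parallel to the supporting
contig set. `S(x|y)` — the mean alignment score of `x` over contigs
supporting `x -> y` — and `S(~y|~x)` are kept separately: they average the
scores of different genes.

Coordinates are 0-based half-open throughout. Walks are stored as read from
the input; reversal equivalence is recognized but not normalized, and GFA W
lines emit the stored direction.

## Alignment input and protein choice

Input is the PAF dialect of spliced protein-to-genome aligners: 12 mandatory
columns plus typed tags. The score comes from `AS:i` (records without it are
dropped), the intron count from `np:i` with a fallback to counting intron
operations (`N`/`U`/`V`) in the `cg:Z` CIGAR; with neither, a record is
treated as unspliced and a warning is logged once per genome. Intronless
hits of a protein that is spliced in a *different* genome are dropped as
likely processed-pseudogene alignments (`cross_sample`); `strict` mode
additionally drops proteins never spliced anywhere, `off` disables the
filter. One protein represents each gene: the one maximizing the sum over
genomes of its best score there; exact ties go to the smaller 64-bit FNV-1a
hash of the protein name. FNV-1a over name bytes is the single tie-breaking
device everywhere in the package.

## Non-ortholog selection

For every gene and genome the best hit is recorded; two best hits compete
when they overlap by at least half of the shorter interval on one contig
(`--overlap-frac`, default 0.5 — the fraction is a package choice, exposed
because no principled value exists). `b(v)` counts genomes where `v` beats
all overlapping rivals (score, then hash). Selection pops genes by
descending *current* `b` from a lazy priority queue; electing `v` decrements
`b(w)` for each genome where `w`'s best mapping overlaps `v`'s **and `w`'s
hit outscores `v`'s there** (the score-gated rule). The rationale: `v`'s
election claims exactly the genomes where a better-scoring competitor would
otherwise have split the locus, while a competitor that merely strays onto
`v`'s locus in a genome where it scored *worse* keeps the credit it earned
at its own locus elsewhere. The unconditional variant (every overlap
decrements) is available as `decrement_rule="claim_locus"`; it collapses
orthologs equally well but also deselects a paralog whose own locus was
deleted in some genomes — precisely the case the low-priority heuristic is
designed to repair — so score-gating is the default. Selection is
single-pass, as the greedy formulation implies.

## Walk building and adjustment

Per contig, alignments of selected genes are accepted greedily — unflagged
before low-priority, then descending score, ties by gene-name hash — and an
alignment overlapping an accepted one beyond the tolerance is skipped;
accepted hits sorted by start become the walk. Adjustment iterates
(default `rounds=2`, i.e. one initial build and one rebuild): build walks
and graph, flag false edges (`r1`) and drop the incident alignments of the
flagged direction's source gene, flag low-priority edges (`r2`) and demote
their incident alignments, rebuild. A round producing no new flags is a
fixed point; `r1 = r2 → 0` disables all flags, making `adjust` equal plain
construction. Flags are directional for removal purposes (only the `x` side
of `x -> y` loses alignments) even though the canonical edge carries the
flag for reporting.

Structural filters run in fixed order — edge support, single-exon genes,
degree cap, locus cap, then the presence floor inside classification —
because each stage's removals change the quantities the next stage measures;
reordering changes results. A removed gene is excised from walks and the
walk splits at the removal (the severed flanks do not become adjacent),
which is why filtering can only remove edges. "Distinct loci" for the locus
cap: each occurrence contributes its orientation-normalized (left, right)
flank pair; contexts sharing either flank merge; the cluster count is the
locus count. This captures "connects multiple loci" without needing
coordinates across genomes.

## Bibubbles

`U(x, y)` is computed by directed BFS over oriented adjacencies: `x`, `~x`
and `y` are never expanded nor counted; `~y` is counted (contributing
`nu(y)`) and expanded — allowing walks through `~y` is what lets an
inversion close a bubble. The definitional check accepts `(x, y)` when:

1. `U(x, y) = U(~y, ~x) ≠ ∅`, the interior contains neither boundary gene,
   and the boundary genes are distinct — a bubble boundary must be a
   two-edge cut-set of the net graph, which a single net edge cannot form;
2. every interior gene lies on a net-graph cycle (see below);
3. every interior gene lies on some `x → y` walk, tested per orientation as
   membership in the forward reach from `x` intersected with the flipped
   mirror reach from `~y` under the same blocking rules;
4. minimality: no interior orientation `z` satisfies the condition-1 set
   equality against `x` or against `y`. Equality of *empty* sets counts as
   a violation — an interior vertex with empty symmetric flank sets is a
   plain chain waypoint and the pair spans no variation — **except** when
   `nu(z)` is a net self-loop: a tandem-duplicated gene has empty flank
   sets on both sides yet is itself the variation and must stay enclosed.

Conditions 2 and the self-loop exception in 4 are where this implementation
resolves a genuine tension in the definition: with empty-set equality
always counting, a single-gene tandem duplication (`L → b`, `b → b`,
`b → R`) has no bubble at all, because `(L, b)` and `(b, R)` both show empty
symmetric sets; with empty-set equality never counting, every three-gene
stretch of a plain chain becomes a "bubble". Treating net self-loop genes
as legitimate interiors and all other empty-equality cases as chain splits
gives copy-number bubbles and chain rejection simultaneously, and makes the
fast search and the naive enumeration agree on every random pangenome we
generate (the headline property test). Condition 2 (no bridge interiors) is
the same principle from the other side: an interior gene on no net cycle
has no alternative walk anywhere, so the enclosing pair spans no variation.

### Net graph and cycle equivalence

The biedged view splits gene `v` into `(v, s)` and `(v, e)`; an edge
`x -> y` links head(`x`) to tail(`y`) (`>v` exposes `(v, e)` forward).
Contracting all link edges by union-find gives the net graph, a `networkx`
MultiGraph whose vertices are adjacency components and whose edges are
genes; parallel edges and self-loops are meaningful.

Cycle-equivalence classes (`e1 ≡ e2` iff every cycle through one passes the
other) are computed per connected component by DFS bracket sets: each
backedge is a bracket spanning the tree edges between its endpoints; two
tree edges are equivalent exactly when their bracket sets are equal, and a
backedge joins a tree edge exactly when it is that edge's only bracket.
Bracket sets are compared as whole frozensets, so the capping-bracket
machinery needed for constant-size compressed comparisons is unnecessary.
Tree edges with empty bracket sets are bridges; all bridges share one
vacuous class (vacuously, no cycle contains any of them), which is required
so that the flanks of a deletion bubble — plain chain edges — remain mutual
candidates. Self-loops are singleton classes. The brute-force oracle
implements the cut-set characterization directly: bridges by single-edge
removal; a non-bridge pair is equivalent iff removing both disconnects
their component. The two implementations agree on every random multigraph
tested (hundreds of seeds, up to 30 edges).

### Search

For each candidate entry — an oriented gene that branches, or whose single
successor already lies on a net cycle (the entry of a pure copy-number
loop) — a BFS visits up to `m` genes (default 100, a gene-count cap).
Oriented genes sharing the entry's cycle class are candidate exits, tested
in BFS order; the first success is the entry's bubble (an entry admits at
most one) and the search moves on. A failed candidate is traversed through
so exits behind it stay reachable. Because a tandem-duplicated *boundary*
gene becomes a net self-loop and drops out of its flank's class, candidates
also include exits where either boundary gene is a self-loop. Mirrors
`(x, y) ≡ (~y, ~x)` are deduplicated to the lexicographically smaller
rendering. The SESE variant roots the net graph with a dummy vertex joined
to every degree-one vertex and to the outer endpoints of the first and last
gene of each reference contig, takes same-class gene pairs in the rooted
graph as candidates, and validates each definitionally; the rooting is
heuristic and may miss bubbles (it is not the default).

## Synthetic pangenomes

The generator mutates an ancestral single-contig chromosome of `n_genes`
(default 200) independently in each of `n_genomes` (default 20) genomes.
Event counts per genome are Poisson with means 1.0 (deletion), 0.5 (tandem
duplication), 0.5 (inversion) and 0.0 (translocation, available but off by
default since a move predicts no single local bubble); deletion/inversion
block lengths are uniform on 1–3 genes; tandem duplications copy one gene —
the most common copy-number unit, and the shape whose bubble decomposition
is unambiguous (longer tandem loops entangle into several minimal bubbles).
Events keep a 2-gene spacer apart; an event is *isolated* when no other
event in any genome touches its spacer zone, and each isolated event
predicts exactly one bibubble between its ancestral flanks. Alignment
emission lays genes end to end (1 kb genes, 200 bp gaps), draws scores as
1000 ± 1% jitter, assigns each gene a fixed exon count uniform on 2–12, and
can add paralog decoy cross-hits at a configurable score ratio
(0.93–0.99). Coordinates are synthetic; only order and orientation matter
downstream.

What the generator does *not* emulate: alignment breakpoint noise, partial
or frame-broken hits, assembly gaps, nested or overlapping events, and
sequence-level paralogy beyond the decoy score model. Passing tests
therefore demonstrate the graph and bubble machinery on clean, known-truth
inputs, not robustness to real aligner output.

Two fixtures target the adjustment heuristics specifically: a genome
missing one contig so that a gene survives only as a 0.93-ratio decoy at a
paralogous locus on another contig (false-edge case), and a two-haplotype
paralog pair where the deleted gene's protein outscores the resident
paralog at the shared locus at ratio 0.97 (low-priority case).

## Numerical and degenerate-input choices

Scores are integers in, float means out; all threshold comparisons
(`S(x|y) < S(x|z) · r`) are strict, so a ratio exactly at `r1` or `r2` does
not flag. Walks of length one contribute a vertex and presence count but no
edge. Contigs with no accepted alignment yield no walk. Duplicate
(genome, contig) walk keys are rejected; filter-induced walk fragments get
explicit part indices. The empty graph serializes to a header-only GFA and
round-trips.

## Problem sizes

The shipped test suite and acceptance script run simulations of up to 20
genomes × 200 genes (hundreds of seeds at smaller sizes for the
equivalence and invariant properties), sizes at which every property is
checked against an exhaustive oracle in a few minutes on one core; the
algorithms themselves are near-linear in walks and edges apart from the
definitional validation, which is quadratic only in candidate pairs.

## Known limitations

* The bubble definition's empty-set/minimality resolution is this package's
  own (documented above); other implementations of the same idea may
  partition tangled multi-event regions into different minimal bubbles.
* Chromosome-scale rearrangements (translocations, large inversions) do not
  form bibubbles by design; they surface only as broken local topology.
* The SESE candidate generator can miss bubbles whose boundary geometry the
  dummy-vertex rooting misrepresents (e.g. palindromic contigs).
* Selection is single-pass; pathological dominance-count ties could elect a
  different ortholog representative than an iterated scheme, though never a
  different count of genes in the cases covered by tests.
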