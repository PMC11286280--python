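"""Synthetic pangenomes with known gene-level variation.

An ancestral chromosome of ``n_genes`` single-copy genes is mutated
independently in each genome by structural events — block deletions, tandem
duplications, block inversions and translocations — at configurable expected
counts per genome.  The generator records a truth set: every event whose
neighborhood (plus a spacer margin) is untouched by any other event in any
genome predicts exactly one bibubble between its flanking genes.  Tandem
duplications default to single-gene blocks, the most common copy-number unit;
longer duplication blocks produce entangled cycles whose decomposition into
bubbles is not unique and are therefore excluded from exact-recovery truth.

``emit_alignments`` converts the simulated gene walks into the PAF dialect
the pipeline consumes, laying genes end to end with fixed gaps, adding score
noise, a per-gene exon model, and optional paralog decoy hits at controlled
score ratios.  Two dedicated fixtures reproduce the classic annotation-error
scenarios: a gene stranded on a paralogous contig because its own contig is
missing from one genome, and a same-contig paralog whose protein outscores
the resident gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import TextIO

import numpy as np

from .alignments import AlignmentRecord
from .model import FORWARD, REVERSE, OrientedGene
from .util import ConfigError


@dataclass
class SimConfig:
    n_genes: int = 200
    n_genomes: int = 20
    deletion_rate: float = 1.0       # expected events per genome
    duplication_rate: float = 0.5
    inversion_rate: float = 0.5
    translocation_rate: float = 0.0
    block_len_max: int = 3           # deletion/inversion block length, uniform
    dup_block_len: int = 1           # tandem duplications copy this many genes
    spacer: int = 2                  # genes kept intact around every event
    paralog_families: int = 0
    paralog_ratio: tuple[float, float] = (0.93, 0.99)
    score_scale: int = 1000
    score_noise: float = 0.01        # fractional score jitter
    exon_range: tuple[int, int] = (2, 12)
    gene_len: int = 1000
    gene_gap: int = 200
    seed: int = 0

    def __post_init__(self):
        for name in ("deletion_rate", "duplication_rate", "inversion_rate",
                     "translocation_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.n_genes < 5 or self.n_genomes < 1:
            raise ConfigError("need at least 5 genes and 1 genome")
        if self.block_len_max < 1 or self.block_len_max > self.n_genes - 4:
            raise ConfigError("block length must fit inside the chromosome")
        if self.dup_block_len < 1 or self.dup_block_len > self.n_genes - 4:
            raise ConfigError("duplication block length must fit inside the chromosome")
        if not (0 <= self.score_noise < 0.5):
            raise ConfigError("score_noise must be in [0, 0.5)")


@dataclass
class SimEvent:
    genome: str
    kind: str                  # deletion | duplication | inversion | translocation
    block: tuple[int, int]     # inclusive ancestral gene index range
    target: int | None = None  # translocation insertion index
    isolated: bool = True


@dataclass
class ExpectedBubble:
    entry: str       # ">gene" token
    exit: str
    interior: frozenset[str]
    contains_inversion: bool


@dataclass
class TruthSet:
    events: list[SimEvent] = field(default_factory=list)
    expected_bubbles: list[ExpectedBubble] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "events": [asdict(e) for e in self.events],
            "expected_bubbles": [
                {"entry": b.entry, "exit": b.exit,
                 "interior": sorted(b.interior),
                 "contains_inversion": b.contains_inversion}
                for b in self.expected_bubbles],
        }


def _gene_name(i: int) -> str:
    return f"g{i:04d}"


def _genome_name(i: int) -> str:
    return f"s{i:02d}"


def _sample_events(cfg: SimConfig, rng: np.random.Generator) -> list[SimEvent]:
    events: list[SimEvent] = []
    margin = max(2, cfg.spacer)
    for gi in range(cfg.n_genomes):
        genome = _genome_name(gi)
        occupied: list[tuple[int, int]] = []

        def free(lo: int, hi: int) -> bool:
            return all(hi + cfg.spacer < a or b + cfg.spacer < lo
                       for a, b in occupied)

        plan = []
        for kind, rate in (("deletion", cfg.deletion_rate),
                           ("duplication", cfg.duplication_rate),
                           ("inversion", cfg.inversion_rate),
                           ("translocation", cfg.translocation_rate)):
            plan.extend([kind] * int(rng.poisson(rate)))
        for kind in plan:
            if kind == "duplication":
                blen = cfg.dup_block_len
            else:
                blen = int(rng.integers(1, cfg.block_len_max + 1))
            placed = False
            for _ in range(50):
                i = int(rng.integers(margin, cfg.n_genes - margin - blen + 1))
                j = i + blen - 1
                target = None
                if kind == "translocation":
                    target = int(rng.integers(margin, cfg.n_genes - margin))
                    if not free(target, target) or (i - cfg.spacer <= target <= j + cfg.spacer):
                        continue
                if free(i, j):
                    occupied.append((i, j))
                    if target is not None:
                        occupied.append((target, target))
                    events.append(SimEvent(genome=genome, kind=kind,
                                           block=(i, j), target=target))
                    placed = True
                    break
            if not placed:
                continue
    return events


def _apply_events(cfg: SimConfig, events: list[SimEvent],
                  genome: str) -> list[OrientedGene]:
    walk = [OrientedGene(_gene_name(i), FORWARD) for i in range(cfg.n_genes)]
    mine = sorted((e for e in events if e.genome == genome),
                  key=lambda e: -e.block[0])
    # positions are ancestral indices; events within a genome are disjoint
    # and applied right to left so earlier indices stay valid
    pending_insert: list[tuple[int, list[OrientedGene]]] = []
    for e in mine:
        i, j = e.block
        if e.kind == "deletion":
            del walk[i:j + 1]
        elif e.kind == "duplication":
            walk[j + 1:j + 1] = walk[i:j + 1]
        elif e.kind == "inversion":
            walk[i:j + 1] = [g.flipped for g in reversed(walk[i:j + 1])]
        elif e.kind == "translocation":
            block = walk[i:j + 1]
            del walk[i:j + 1]
            pending_insert.append((e.target, block))
    for target, block in sorted(pending_insert, key=lambda t: -t[0]):
        pos = min(target, len(walk))
        walk[pos:pos] = block
    return walk


def _truth(cfg: SimConfig, events: list[SimEvent]) -> TruthSet:
    zones: list[tuple[int, int, SimEvent]] = []
    for e in events:
        i, j = e.block
        zones.append((i - cfg.spacer, j + cfg.spacer, e))
        if e.target is not None:
            zones.append((e.target - cfg.spacer, e.target + cfg.spacer, e))
    for e in events:
        i, j = e.block
        lo, hi = i - cfg.spacer, j + cfg.spacer
        for (a, b, other) in zones:
            if other is e:
                continue
            same_shape = (other.kind == e.kind and other.block == e.block
                          and other.target == e.target)
            if same_shape:
                continue
            if not (b < lo or hi < a):
                e.isolated = False
        if e.kind == "translocation":
            e.isolated = False  # moves do not predict a single local bubble
        if e.kind == "duplication" and (j - i + 1) > 1:
            e.isolated = False  # multi-gene tandem loops are not a single bubble
        if e.target is not None:
            pass
    expected: dict[tuple, ExpectedBubble] = {}
    for e in events:
        if not e.isolated:
            continue
        i, j = e.block
        entry = f">{_gene_name(i - 1)}"
        exit_ = f">{_gene_name(j + 1)}"
        interior = frozenset(_gene_name(k) for k in range(i, j + 1))
        expected[(entry, exit_, interior)] = ExpectedBubble(
            entry=entry, exit=exit_, interior=interior,
            contains_inversion=(e.kind == "inversion"))
    return TruthSet(events=events,
                    expected_bubbles=sorted(expected.values(),
                                            key=lambda b: b.entry))


def simulate(config: SimConfig) -> tuple[dict[str, list[list[OrientedGene]]], TruthSet]:
    """Mutate the ancestral gene walk independently per genome.

    Returns one contig walk per genome plus the truth set.  Deterministic
    for a fixed config (the seed drives all randomness).
    """
    rng = np.random.default_rng(config.seed)
    events = _sample_events(config, rng)
    genomes = {}
    for gi in range(config.n_genomes):
        name = _genome_name(gi)
        genomes[name] = [_apply_events(config, events, name)]
    return genomes, _truth(config, events)


# ---------------------------------------------------------------------------
# alignment emission

def _exon_model(cfg: SimConfig) -> dict[str, int]:
    rng = np.random.default_rng(cfg.seed + 1)
    lo, hi = cfg.exon_range
    return {_gene_name(i): int(rng.integers(lo, hi + 1))
            for i in range(cfg.n_genes)}


def emit_alignments(genomes: dict[str, list[list[OrientedGene]]],
                    config: SimConfig) -> list[AlignmentRecord]:
    """One true hit per gene occurrence plus optional paralog decoy hits.

    Genes are laid end to end with fixed gaps; scores are the scale with a
    small jitter; intron counts follow the per-gene exon model.  With
    ``paralog_families`` > 0, gene pairs are designated paralogs and each
    member also hits its partner's loci at a score ratio drawn from
    ``paralog_ratio`` — below the locus owner, so decoys lose placement but
    create the cross-hit structure the adjustment heuristics act on.
    """
    rng = np.random.default_rng(config.seed + 2)
    exons = _exon_model(config)
    families: dict[str, str] = {}
    if config.paralog_families:
        idx = rng.choice(np.arange(2, config.n_genes - 2),
                         size=2 * config.paralog_families, replace=False)
        for k in range(config.paralog_families):
            a, b = _gene_name(int(idx[2 * k])), _gene_name(int(idx[2 * k + 1]))
            families[a] = b
            families[b] = a

    records: list[AlignmentRecord] = []
    span = config.gene_len + config.gene_gap
    for genome in sorted(genomes):
        for ci, walk in enumerate(genomes[genome]):
            contig = f"chr{ci + 1}"
            for k, og in enumerate(walk):
                start = k * span
                end = start + config.gene_len
                noise = 1.0 + float(rng.uniform(-config.score_noise,
                                                config.score_noise))
                score = max(1, int(round(config.score_scale * noise)))
                records.append(AlignmentRecord(
                    protein=og.gene, genome=genome, contig=contig,
                    start=start, end=end,
                    strand="+" if og.orient == FORWARD else "-",
                    score=score, introns=exons.get(og.gene, 2) - 1,
                    identity=1.0, protein_len=config.gene_len // 3))
                partner = families.get(og.gene)
                if partner is not None:
                    ratio = float(rng.uniform(*config.paralog_ratio))
                    records.append(AlignmentRecord(
                        protein=partner, genome=genome, contig=contig,
                        start=start, end=end,
                        strand="+" if og.orient == FORWARD else "-",
                        score=max(1, int(round(score * ratio))),
                        introns=exons.get(partner, 2) - 1,
                        identity=ratio, protein_len=config.gene_len // 3))
    return records


def write_paf(records: list[AlignmentRecord], stream: TextIO) -> None:
    """Serialize records in the PAF dialect consumed by the pipeline."""
    for r in records:
        qlen = r.protein_len or 300
        blocklen = r.end - r.start
        nmatch = int(round(r.identity * blocklen))
        stream.write("\t".join(map(str, [
            r.protein, qlen, 0, qlen, r.strand, r.contig, 10 ** 7,
            r.start, r.end, nmatch, blocklen, 60,
            f"AS:i:{r.score}", f"np:i:{r.introns}",
        ])) + "\n")


# ---------------------------------------------------------------------------
# targeted fixtures for the adjustment heuristics

def missing_contig_fixture(n_backgrounds: int = 3,
                           decoy_ratio: float = 0.93,
                           score: int = 1000) -> list[AlignmentRecord]:
    """A gene stranded on a paralogous contig when its own contig is absent.

    Genomes s01..s0n carry two contigs: an autosome [A1, P, Q, A2] and a
    second chromosome [X1, V, X2].  The last genome lacks the second contig,
    so gene V's only hit is a decoy between P and Q on the autosome at
    ``decoy_ratio`` of its true score.  With the default false-edge threshold
    the spurious V placement is dropped and the autosome walk closes P-Q.
    """
    records: list[AlignmentRecord] = []
    span = 1200

    def rec(protein, genome, contig, idx, sc, introns=3):
        return AlignmentRecord(protein=protein, genome=genome, contig=contig,
                               start=idx * span, end=idx * span + 1000,
                               strand="+", score=sc, introns=introns,
                               identity=1.0, protein_len=333)

    n_total = n_backgrounds + 1
    for gi in range(n_total):
        genome = _genome_name(gi + 1)
        male = gi == n_total - 1
        for idx, gene in enumerate(["A1", "P", "Q", "A2"]):
            records.append(rec(gene, genome, "auto", idx if idx < 2 else idx + 1, score))
        if male:
            # decoy locus sits between P (idx 1) and Q (idx 3)
            records.append(rec("V", genome, "auto", 2,
                               int(round(score * decoy_ratio))))
        else:
            for idx, gene in enumerate(["X1", "V", "X2"]):
                records.append(rec(gene, genome, "sex", idx, score))
    return records


def same_contig_paralog_fixture(score: int = 1000,
                                decoy_ratio: float = 0.97) -> list[AlignmentRecord]:
    """Two haplotypes of a paralog pair where the deleted gene's protein
    outscores the resident paralog at the shared locus.

    Haplotype h1 carries [T, D7, D6, W]; haplotype h2 really carries
    [T, D7, W] but gene D6's protein hits the D7 locus at ``decoy_ratio`` of
    its true score — higher than D7's own hit there — so the initial walk
    places D6.  The low-priority heuristic (threshold r2) demotes that
    placement and the rebuilt walk restores D7.
    """
    records: list[AlignmentRecord] = []
    span = 1200

    def rec(protein, genome, contig, idx, sc, introns=4):
        return AlignmentRecord(protein=protein, genome=genome, contig=contig,
                               start=idx * span, end=idx * span + 1000,
                               strand="+", score=sc, introns=introns,
                               identity=1.0, protein_len=333)

    h1 = [("T", score), ("D7", score - 20), ("D6", score), ("W", score)]
    for idx, (gene, sc) in enumerate(h1):
        records.append(rec(gene, "h1", "c1", idx, sc))
    records.append(rec("T", "h2", "c2", 0, score))
    records.append(rec("D6", "h2", "c2", 1, int(round(score * decoy_ratio))))
    records.append(rec("D7", "h2", "c2", 1, int(round(score * decoy_ratio)) - 10))
    records.append(rec("W", "h2", "c2", 2, score))
    return records
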