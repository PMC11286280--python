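"""Protein-to-genome alignment input.

Consumes the PAF dialect produced by spliced protein aligners: 12 mandatory
tab-separated columns plus typed tags.  The alignment score is read from the
``AS:i`` tag (records without it are dropped), the intron count from an
``np:i`` tag with a fallback to counting intron operations (N/U/V) in the
``cg:Z`` CIGAR.  Protein names of the form ``GeneID:ProteinID`` are split so
that one gene may arrive with several candidate proteins; a bare name is its
own gene.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from .model import GeneCatalog
from .util import PAFParseError, fnv1a64

log = logging.getLogger(__name__)

_CIGAR_OP_RE = re.compile(r"(\d+)([A-Z=])")
_INTRON_OPS = {"N", "U", "V"}


@dataclass(eq=False)
class AlignmentRecord:
    """One protein hit on one contig of one genome.

    Coordinates are 0-based half-open on the genome.  ``gene`` is the part of
    the protein name before the first ":" (the whole name if there is none).
    """

    protein: str
    genome: str
    contig: str
    start: int
    end: int
    strand: str  # "+" or "-"
    score: int
    introns: int = 0
    identity: float = 1.0
    protein_len: int = 0
    gene: str = field(init=False)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.start}-{self.end} for {self.protein}")
        if self.score < 0 or self.introns < 0:
            raise ValueError("score and intron count must be nonnegative")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        self.gene = self.protein.split(":", 1)[0]

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "AlignmentRecord") -> int:
        if self.contig != other.contig or self.genome != other.genome:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def records_overlap(a: AlignmentRecord, b: AlignmentRecord, frac: float = 0.5) -> bool:
    """True when two hits overlap by at least ``frac`` of the shorter one."""
    ov = a.overlap_len(b)
    if ov == 0:
        return False
    return ov >= frac * min(a.length, b.length)


def _cigar_introns(cigar: str) -> int:
    return sum(1 for _, op in _CIGAR_OP_RE.findall(cigar) if op in _INTRON_OPS)


def read_alignments(stream: TextIO, genome: str) -> list[AlignmentRecord]:
    """Parse one genome's PAF records.

    Records without an AS score tag are dropped.  A missing mandatory column
    raises; an empty genome label raises.
    """
    if not genome:
        raise ValueError("a genome label is required for every alignment file")
    records: list[AlignmentRecord] = []
    n_noscore = 0
    warned_no_introns = False
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise PAFParseError(
                f"expected 12 mandatory PAF columns, got {len(fields)}", lineno)
        try:
            qname = fields[0]
            qlen = int(fields[1])
            strand = fields[4]
            tname = fields[5]
            tstart = int(fields[7])
            tend = int(fields[8])
            nmatch = int(fields[9])
            blocklen = int(fields[10])
        except ValueError as exc:
            raise PAFParseError(f"bad mandatory column: {exc}", lineno)
        tags: dict[str, tuple[str, str]] = {}
        for f in fields[12:]:
            parts = f.split(":", 2)
            if len(parts) == 3:
                tags[parts[0]] = (parts[1], parts[2])
        if "AS" not in tags:
            n_noscore += 1
            continue
        try:
            score = int(tags["AS"][1])
        except ValueError:
            raise PAFParseError(f"bad AS tag {tags['AS'][1]!r}", lineno)
        if "np" in tags:
            introns = int(tags["np"][1])
        elif "cg" in tags:
            introns = _cigar_introns(tags["cg"][1])
        else:
            introns = 0
            if not warned_no_introns:
                log.warning(
                    "genome %s: no intron tag or CIGAR on some records; "
                    "treating them as unspliced", genome)
                warned_no_introns = True
        if "de" in tags:
            identity = max(0.0, min(1.0, 1.0 - float(tags["de"][1])))
        else:
            identity = nmatch / blocklen if blocklen else 0.0
        records.append(AlignmentRecord(
            protein=qname, genome=genome, contig=tname, start=tstart, end=tend,
            strand=strand, score=score, introns=introns, identity=identity,
            protein_len=qlen))
    if n_noscore:
        log.warning("genome %s: dropped %d records without an AS score tag",
                    genome, n_noscore)
    return records


def read_alignment_files(manifest: dict[str, str | Path]) -> list[AlignmentRecord]:
    """Read one PAF file per genome; the manifest maps genome label -> path."""
    records: list[AlignmentRecord] = []
    for genome, path in manifest.items():
        with open(path) as fh:
            records.extend(read_alignments(fh, genome))
    return records


def filter_unspliced(records: Iterable[AlignmentRecord],
                     mode: str = "cross_sample") -> list[AlignmentRecord]:
    """Drop putative processed-pseudogene alignments based on splicing.

    ``cross_sample`` (default): an intronless hit of a protein is dropped when
    the same protein has a spliced alignment in a *different* genome —
    unspliced copies elsewhere are the signature of a retrotransposed
    pseudogene.  ``strict``: drop every record of proteins that are never
    spliced in any genome.  ``off``: return the input unchanged.
    """
    records = list(records)
    if mode == "off":
        return records
    if mode not in ("cross_sample", "strict"):
        raise ValueError(f"unknown unspliced-filter mode {mode!r}")
    spliced_genomes: dict[str, set[str]] = {}
    for r in records:
        if r.introns > 0:
            spliced_genomes.setdefault(r.protein, set()).add(r.genome)
    out = []
    for r in records:
        genomes = spliced_genomes.get(r.protein, set())
        if mode == "strict":
            if not genomes:
                continue
            if r.introns == 0 and genomes - {r.genome}:
                continue
        else:  # cross_sample
            if r.introns == 0 and genomes - {r.genome}:
                continue
        out.append(r)
    return out


def choose_protein(records: Iterable[AlignmentRecord]) -> GeneCatalog:
    """Select one representative protein per gene.

    The winner maximizes the total best-hit score across genomes (the sum over
    genomes of its top score there); exact ties go to the protein with the
    smaller FNV-1a name hash.  The catalog also collects per-(gene, genome)
    max exon counts of the chosen protein.
    """
    best: dict[tuple[str, str, str], int] = {}  # (gene, protein, genome) -> top score
    by_gene: dict[str, set[str]] = {}
    for r in records:
        by_gene.setdefault(r.gene, set()).add(r.protein)
        key = (r.gene, r.protein, r.genome)
        if r.score > best.get(key, -1):
            best[key] = r.score
    totals: dict[tuple[str, str], int] = {}
    for (gene, protein, _), sc in best.items():
        totals[(gene, protein)] = totals.get((gene, protein), 0) + sc

    catalog = GeneCatalog()
    for gene, proteins in by_gene.items():
        chosen = min(proteins, key=lambda p: (-totals.get((gene, p), 0), fnv1a64(p)))
        catalog.add_gene(gene, chosen)

    for r in records:
        if catalog.protein_of.get(r.gene) != r.protein:
            continue
        key = (r.gene, r.genome)
        exons = r.introns + 1
        if exons > catalog.exon_counts.get(key, 0):
            catalog.exon_counts[key] = exons
        if r.protein_len:
            catalog.protein_len[r.gene] = r.protein_len
    return catalog


def chosen_records(records: Iterable[AlignmentRecord],
                   catalog: GeneCatalog) -> list[AlignmentRecord]:
    """Keep only records of each gene's chosen protein."""
    return [r for r in records if catalog.protein_of.get(r.gene) == r.protein]
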