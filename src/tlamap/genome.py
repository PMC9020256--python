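"""Genomes, gene models, transgene constructs, and transgenic-allele assembly.

A :class:`Genome` is a set of named chromosome sequences with interval
annotations (genes and exons, 0-based half-open). Synthetic host genomes
carry a two-gene test locus: one gene entirely inside a designated deletion
window (so an integration deletes it completely) and a second, multi-exon
gene straddling the window's edge (so the same integration truncates it and
the transgene lands in one of its introns). This mirrors the configuration
in which a randomly integrated transgene wiped out one gene wholly and
disrupted its neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .restriction import reverse_complement

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class Annotation:
    """A named feature on a chromosome (0-based half-open)."""

    name: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"annotation {self.name}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"annotation {self.name}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, delta: int) -> "Annotation":
        return replace(self, start=self.start + delta, end=self.end + delta)


@dataclass
class Genome:
    """Named nucleotide sequences plus interval annotations."""

    sequences: dict[str, str]
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ann in self.annotations:
            self._check(ann)

    def _check(self, ann: Annotation) -> None:
        if ann.chromosome not in self.sequences:
            raise ValueError(f"annotation {ann.name}: unknown chromosome {ann.chromosome}")
        if ann.end > len(self.sequences[ann.chromosome]):
            raise ValueError(f"annotation {ann.name}: interval exceeds chromosome length")

    def add(self, ann: Annotation) -> None:
        self._check(ann)
        self.annotations.append(ann)

    def features(self, kind: str | None = None, chromosome: str | None = None):
        for ann in self.annotations:
            if kind is not None and ann.feature_kind != kind:
                continue
            if chromosome is not None and ann.chromosome != chromosome:
                continue
            yield ann

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters for a synthetic host genome.

    ``gene_locus`` fixes where the two-gene test locus is planted on the
    first chromosome: a window whose contents a transgene integration will
    delete. Defaults put it mid-chromosome.
    """

    chromosome_names: tuple[str, ...] = ("chr5",)
    chromosome_lengths: tuple[int, ...] = (300_000,)
    gc_fraction: float = 0.42
    seed: int = 0
    window_width: int | None = None   # None → min(50 kb, 15% of chromosome)

    def __post_init__(self) -> None:
        if self.window_width is not None and self.window_width < 0:
            raise ValueError("window_width must be >= 0")
        if len(self.chromosome_names) != len(self.chromosome_lengths):
            raise ValueError("chromosome_names and chromosome_lengths differ in length")
        if len(set(self.chromosome_names)) != len(self.chromosome_names):
            raise ValueError("chromosome_names: duplicate identifiers")
        for n, l in zip(self.chromosome_names, self.chromosome_lengths):
            if l <= 0:
                raise ValueError(f"chromosome_lengths: {n} has non-positive length {l}")
        if not 0 < self.gc_fraction < 1:
            raise ValueError(f"gc_fraction must be in (0,1), got {self.gc_fraction}")


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """i.i.d. nucleotide sequence with the stated GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode()


def generate_genome(spec: GenomeSpec) -> Genome:
    """Deterministic synthetic host genome with the two-gene test locus.

    On the first chromosome, a deletion window is centred at 45% of the
    chromosome length (width ≈ 15% of the chromosome, capped at 50 kb).
    Gene B (*Serpine1* analogue, single exon span) lies entirely inside the
    window; gene A (*Ap1s1* analogue, 4 exons) starts inside the window and
    extends beyond its right edge, with the window boundary falling in the
    intron between its exon 2 and exon 3. Deleting the window therefore
    removes gene B completely, truncates gene A, and leaves the insertion
    point intronic between exons 2 and 3 of gene A.
    """
    rng = np.random.default_rng(spec.seed)
    sequences = {
        name: random_sequence(length, spec.gc_fraction, rng)
        for name, length in zip(spec.chromosome_names, spec.chromosome_lengths)
    }
    genome = Genome(sequences)
    chrom = spec.chromosome_names[0]
    clen = spec.chromosome_lengths[0]
    width = (
        spec.window_width
        if spec.window_width
        else min(50_000, max(2_000, int(0.15 * clen)))
    )
    win_start = int(0.45 * clen) - width // 2
    win_end = win_start + width
    if win_start < 1_000 or win_end > clen - 1_000:
        raise ValueError("chromosome too short to host the two-gene locus")
    genome.add(Annotation("deletion_window", chrom, win_start, win_end,
                          feature_kind="region"))

    # gene B: fully inside the window
    b_len = max(400, width // 8)
    b_start = win_start + width // 6
    genome.add(Annotation("GeneB", chrom, b_start, b_start + b_len, "+", "gene"))
    genome.add(Annotation("GeneB_exon1", chrom, b_start, b_start + b_len, "+", "exon"))

    # gene A: 4 exons; exons 1-2 inside the window, exons 3-4 beyond its
    # right edge, so the window boundary sits in intron 2 (between exon 2
    # and exon 3).
    exon = max(150, width // 20)
    intron = max(300, width // 10)
    a_start = win_end - 2 * exon - intron - intron // 2
    if a_start <= b_start + b_len:
        raise ValueError("deletion window too narrow to fit both test genes")
    exons = []
    pos = a_start
    for i in range(4):
        exons.append((pos, pos + exon))
        pos += exon + intron
    a_end = exons[-1][1]
    if a_end > clen - 500:
        raise ValueError("chromosome too short for gene A model")
    # window right edge must fall between exon 2 end and exon 3 start
    assert exons[1][1] < win_end < exons[2][0], "locus layout invariant violated"
    genome.add(Annotation("GeneA", chrom, a_start, a_end, "+", "gene"))
    for i, (s, e) in enumerate(exons, start=1):
        genome.add(Annotation(f"GeneA_exon{i}", chrom, s, e, "+", "exon"))
    return genome


@dataclass(frozen=True)
class TransgeneConstruct:
    """A linear transgene: ordered, non-overlapping elements tiling part of it.

    The canonical synthetic construct mimics a promoter–Cre–ires–EGFP–3′UTR
    cassette cut from a larger plasmid (~4.5 kb between two restriction
    sites in the original construct).
    """

    sequence: str
    elements: tuple[Annotation, ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for el in self.elements:
            if el.start < prev_end:
                raise ValueError(f"transgene elements overlap or are unordered at {el.name}")
            if el.end > len(self.sequence):
                raise ValueError(f"transgene element {el.name} exceeds construct length")
            prev_end = el.end

    def __len__(self) -> int:
        return len(self.sequence)

    def element(self, name: str) -> Annotation:
        for el in self.elements:
            if el.name == name:
                return el
        raise KeyError(name)


ELEMENT_ORDER = ("promoter_5prime", "cre", "ires", "egfp", "regulatory_3prime")
_DEFAULT_ELEMENT_LENGTHS = (1100, 1029, 580, 717, 1074)  # ≈4.5 kb total


def make_transgene(seed: int = 1, gc: float = 0.55) -> TransgeneConstruct:
    """Synthetic promoter–Cre–ires–EGFP–3′ construct (~4.5 kb), deterministic."""
    rng = np.random.default_rng(seed)
    total = sum(_DEFAULT_ELEMENT_LENGTHS)
    seq = random_sequence(total, gc, rng)
    elements = []
    pos = 0
    for name, length in zip(ELEMENT_ORDER, _DEFAULT_ELEMENT_LENGTHS):
        elements.append(Annotation(name, "transgene", pos, pos + length,
                                   "+", "element"))
        pos += length
    return TransgeneConstruct(seq, tuple(elements))


@dataclass(frozen=True)
class IntegrationEvent:
    """Ground truth: where the transgene sits and what host interval it deleted."""

    chromosome: str
    deletion_start: int
    deletion_end: int
    copies: int = 1
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if self.deletion_start < 0 or self.deletion_end < self.deletion_start:
            raise ValueError("deletion interval must satisfy 0 <= start <= end")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be forward|reverse")

    @property
    def deletion_length(self) -> int:
        return self.deletion_end - self.deletion_start


@dataclass(frozen=True)
class AlleleTruth:
    """Ground-truth coordinates of the assembled transgenic allele."""

    event: IntegrationEvent
    left_junction: int       # allele coord where host ends / transgene begins
    right_junction: int      # allele coord where transgene ends / host resumes
    insert_length: int
    self_junctions: tuple[int, ...]  # allele coords of tandem copy boundaries


def build_transgenic_allele(
    host: Genome, construct: TransgeneConstruct, event: IntegrationEvent
) -> tuple[Genome, AlleleTruth]:
    """Assemble the transgenic allele: host left flank + N×construct + right flank.

    Annotations are lifted: features entirely left of the deletion keep
    their coordinates; features entirely right of it shift by
    ``copies*len(construct) - deletion_length``; features overlapping the
    deletion are dropped (they are the disruption downstream code must
    rediscover). Transgene element annotations are added per copy.
    """
    if event.chromosome not in host.sequences:
        raise ValueError(f"unknown chromosome {event.chromosome}")
    chrom_seq = host.sequences[event.chromosome]
    if event.deletion_end > len(chrom_seq):
        raise ValueError("integration event extends beyond chromosome end")

    insert = construct.sequence
    if event.orientation == "reverse":
        insert = reverse_complement(insert)
    cassette = insert * event.copies

    allele_name = f"{event.chromosome}_tg"
    new_seq = (
        chrom_seq[: event.deletion_start] + cassette + chrom_seq[event.deletion_end :]
    )
    sequences = dict(host.sequences)
    del sequences[event.chromosome]
    sequences[allele_name] = new_seq

    delta = len(cassette) - event.deletion_length
    annotations: list[Annotation] = []
    for ann in host.annotations:
        if ann.chromosome != event.chromosome:
            annotations.append(ann)
        elif ann.end <= event.deletion_start:
            annotations.append(replace(ann, chromosome=allele_name))
        elif ann.start >= event.deletion_end:
            annotations.append(replace(ann.shifted(delta), chromosome=allele_name))
        # overlapping features are dropped from the allele

    for copy in range(event.copies):
        base = event.deletion_start + copy * len(construct)
        for el in construct.elements:
            s, e = el.start, el.end
            if event.orientation == "reverse":
                s, e = len(construct) - el.end, len(construct) - el.start
            annotations.append(
                Annotation(f"{el.name}_copy{copy + 1}", allele_name,
                           base + s, base + e, el.strand, "element")
            )

    allele = Genome(sequences, annotations)
    left = event.deletion_start
    right = event.deletion_start + len(cassette)
    selfj = tuple(
        event.deletion_start + i * len(construct) for i in range(1, event.copies)
    )
    truth = AlleleTruth(event, left, right, len(cassette), selfj)
    return allele, truth
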