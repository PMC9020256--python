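"""Simulation of targeted locus amplification (TLA) sequencing reads.

The library model follows the TLA chemistry: genomic DNA is crosslinked and
digested with NlaIII (CATG); because the sample is subsequently trimmed with
NspI (RCATGY, which encompasses CATG) only a subset of NlaIII sites end up
cut, leaving restriction fragments of roughly 2 kb. Spatially proximal
fragments ligate into circular chimeric molecules that are amplified by
inverse PCR from a primer pair inside the transgene (the *viewpoint*).
Sequencing such circles yields reads in which fragments from the viewpoint's
genomic neighbourhood — including host/transgene fusion fragments — are
concatenated in arbitrary order and orientation.

Here each simulated circle contains the viewpoint fragment plus ``k``
fragments drawn with probability proportional to ``(1 + d/d0)**(-alpha)``
of their genomic distance ``d`` from the viewpoint (a standard
proximity-ligation contact decay), plus occasional trans-chromosomal
fragments. Circles are linearized at the viewpoint and paired-end reads are
sampled uniformly across the linear molecule, so a predictable fraction
span ligation junctions. Every read carries full provenance (which allele
intervals it covers, on which strand), written alongside the FASTQ as a
tab-separated truth file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import AlleleTruth, Genome
from .restriction import ENZYMES, digest, reverse_complement


@dataclass(frozen=True)
class TLAParams:
    """Tunable knobs of the TLA library simulation.

    ``partial_digestion_keep_prob=None`` asks the simulator to calibrate the
    Bernoulli cut-retention probability at start-up so the expected fragment
    length is ``target_fragment_len`` (default 2 kb, the fragment size the
    chemistry produces).
    """

    viewpoint_primers: tuple[str, str]
    nlaiii_motif: str = "CATG"
    nspi_motif: str = "RCATGY"
    partial_digestion_keep_prob: float | None = None
    target_fragment_len: int = 2_000
    distance_decay_alpha: float = 1.0
    decay_scale_d0: float = 20_000.0
    fragments_per_circle: tuple[int, int] = (3, 8)
    read_length: int = 150
    read_pairs: int = 6_000
    insert_size: int = 320
    n_circles: int = 500
    substitution_error_rate: float = 0.0
    trans_ligation_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.viewpoint_primers or not all(self.viewpoint_primers):
            raise ValueError("viewpoint_primers must be two non-empty sequences")
        if self.partial_digestion_keep_prob is not None and not (
            0 < self.partial_digestion_keep_prob <= 1
        ):
            raise ValueError("partial_digestion_keep_prob must be in (0,1]")
        if self.distance_decay_alpha <= 0 or self.decay_scale_d0 <= 0:
            raise ValueError("decay parameters must be positive")
        if not 0 <= self.substitution_error_rate < 1:
            raise ValueError("substitution_error_rate must be in [0,1)")
        if not 0 <= self.trans_ligation_rate < 1:
            raise ValueError("trans_ligation_rate must be in [0,1)")
        lo, hi = self.fragments_per_circle
        if lo < 1 or hi < lo:
            raise ValueError("fragments_per_circle must be a valid (lo, hi) range")
        if self.read_length < 40:
            raise ValueError("read_length must be >= 40 (2x minimum split-fragment length)")


@dataclass(frozen=True)
class ProvenancePiece:
    """One contiguous origin interval of a read (allele coordinates)."""

    source_ref: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    mate: int            # 1 or 2
    sequence: str
    circle_id: str
    pieces: tuple[ProvenancePiece, ...]


@dataclass
class SimulatedReadSet:
    """All reads of one simulated TLA library plus their ground truth."""

    reads: list[SimulatedRead]
    params: TLAParams
    keep_prob_used: float
    viewpoint_ref: str
    viewpoint_interval: tuple[int, int]
    fragments: list[tuple[str, int, int]] = field(default_factory=list)

    def read_pairs(self):
        for i in range(0, len(self.reads), 2):
            yield self.reads[i], self.reads[i + 1]


class ViewpointNotFoundError(ValueError):
    pass


def _find_viewpoint(allele: Genome, primers: tuple[str, str]) -> tuple[str, int, int]:
    """Locate the region bracketed by the two viewpoint primers.

    Each primer may match either strand; the viewpoint is the smallest
    interval containing both matches on one reference.
    """
    for ref, seq in allele.sequences.items():
        hits = []
        for p in primers:
            pos = seq.find(p)
            if pos == -1:
                pos = seq.find(reverse_complement(p))
            if pos == -1:
                hits = []
                break
            hits.append((pos, pos + len(p)))
        if hits:
            start = min(h[0] for h in hits)
            end = max(h[1] for h in hits)
            return ref, start, end
    raise ViewpointNotFoundError("viewpoint not found: no reference carries both primers")


def calibrate_keep_prob(seq_len: int, n_cuts: int, target_fragment_len: int) -> float:
    """Cut-retention probability giving expected fragment length ≈ target."""
    if n_cuts == 0:
        return 1.0
    wanted_cuts = seq_len / target_fragment_len
    return float(min(1.0, max(1e-6, wanted_cuts / n_cuts)))


def simulate_tla_reads(allele: Genome, params: TLAParams) -> SimulatedReadSet:
    """Simulate a TLA library from a (transgenic) allele genome.

    Deterministic given ``params.seed``. Returns reads with per-read
    provenance in allele coordinates; use :func:`write_fastq` /
    :func:`write_truth` to serialize.
    """
    rng = np.random.default_rng(params.seed)
    enzyme = ENZYMES["NlaIII"]
    vp_ref, vp_start, vp_end = _find_viewpoint(allele, params.viewpoint_primers)

    # partial digestion of every reference
    vp_seq = allele.sequences[vp_ref]
    full_cuts = len(digest(vp_seq, enzyme, 1.0)) - 1
    keep = params.partial_digestion_keep_prob or calibrate_keep_prob(
        len(vp_seq), full_cuts, params.target_fragment_len
    )
    frags_by_ref: dict[str, list[tuple[int, int]]] = {}
    for ref, seq in allele.sequences.items():
        sub_seed = int(rng.integers(0, 2**31 - 1))
        frags_by_ref[ref] = digest(seq, enzyme, keep, sub_seed)

    # the viewpoint fragment must stay intact (inverse PCR needs both
    # primers on one fragment): merge any fragments the viewpoint straddles
    vp_frags = _merge_over(frags_by_ref[vp_ref], vp_start, vp_end)
    frags_by_ref[vp_ref] = vp_frags
    vp_idx = next(
        i for i, (s, e) in enumerate(vp_frags) if s <= vp_start and vp_end <= e
    )
    vp_s, vp_e = vp_frags[vp_idx]
    vp_mid = (vp_s + vp_e) / 2

    # sampling weights for cis fragments (viewpoint excluded)
    cis = [(s, e) for i, (s, e) in enumerate(vp_frags) if i != vp_idx]
    mids = np.array([(s + e) / 2 for s, e in cis])
    d = np.abs(mids - vp_mid)
    w = (1.0 + d / params.decay_scale_d0) ** (-params.distance_decay_alpha)
    w /= w.sum()
    trans_refs = [r for r in allele.sequences if r != vp_ref]

    L = params.read_length
    if params.insert_size < L:
        raise ValueError("insert_size must be >= read_length")

    # pre-build circles
    lo, hi = params.fragments_per_circle
    circles: list[list[tuple[str, int, int, str]]] = []
    for _ in range(params.n_circles):
        k = int(rng.integers(lo, hi + 1))
        # viewpoint fragment first, forward
        circle = [(vp_ref, vp_s, vp_e, "+")]
        idx = rng.choice(len(cis), size=min(k, len(cis)), replace=False, p=w)
        for i in idx:
            ref, (s, e) = vp_ref, cis[int(i)]
            if trans_refs and rng.random() < params.trans_ligation_rate:
                tref = trans_refs[int(rng.integers(len(trans_refs)))]
                tf = frags_by_ref[tref]
                s, e = tf[int(rng.integers(len(tf)))]
                ref = tref
            strand = "+" if rng.random() < 0.5 else "-"
            circle.append((ref, s, e, strand))
        circles.append(circle)

    # materialize molecule sequences + coordinate maps
    molecules: list[tuple[str, list[tuple[int, int, str, int, int, str]]]] = []
    for circle in circles:
        parts = []
        cmap = []  # (mol_start, mol_end, ref, ref_start, ref_end, strand)
        pos = 0
        for ref, s, e, strand in circle:
            frag = allele.sequences[ref][s:e]
            if strand == "-":
                frag = reverse_complement(frag)
            cmap.append((pos, pos + len(frag), ref, s, e, strand))
            parts.append(frag)
            pos += len(frag)
        molecules.append(("".join(parts), cmap))

    min_mol = min(len(m[0]) for m in molecules)
    if L > min_mol:
        raise ValueError(
            f"read_length {L} exceeds shortest circle length {min_mol}"
        )

    reads: list[SimulatedRead] = []
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for pair_i in range(params.read_pairs):
        ci = int(rng.integers(len(molecules)))
        mol, cmap = molecules[ci]
        ins = min(params.insert_size, len(mol))
        start = int(rng.integers(0, len(mol) - ins + 1))
        r1_iv = (start, start + L)
        r2_iv = (start + ins - L, start + ins)
        for mate, (a, b), flip in ((1, r1_iv, False), (2, r2_iv, True)):
            seq = mol[a:b]
            pieces = _pieces_for(cmap, a, b, flip)
            if flip:
                seq = reverse_complement(seq)
            if params.substitution_error_rate > 0:
                seq = _add_substitutions(seq, params.substitution_error_rate, rng, bases)
            reads.append(
                SimulatedRead(
                    read_id=f"tla_{pair_i:06d}",
                    mate=mate,
                    sequence=seq,
                    circle_id=f"circle_{ci:05d}",
                    pieces=tuple(pieces),
                )
            )

    frag_list = [(ref, s, e) for ref, fr in frags_by_ref.items() for s, e in fr]
    return SimulatedReadSet(
        reads=reads,
        params=params,
        keep_prob_used=keep,
        viewpoint_ref=vp_ref,
        viewpoint_interval=(vp_s, vp_e),
        fragments=frag_list,
    )


def _merge_over(frags: list[tuple[int, int]], start: int, end: int) -> list[tuple[int, int]]:
    """Merge consecutive fragments overlapping [start, end) into one."""
    out: list[tuple[int, int]] = []
    acc: tuple[int, int] | None = None
    for s, e in frags:
        if e > start and s < end:
            acc = (acc[0], e) if acc else (s, e)
        else:
            if acc:
                out.append(acc)
                acc = None
            out.append((s, e))
    if acc:
        out.append(acc)
    out.sort()
    return out


def _pieces_for(cmap, a: int, b: int, flip: bool) -> list[ProvenancePiece]:
    """Project molecule interval [a,b) onto allele coordinates."""
    out = []
    for ms, me, ref, fs, fe, strand in cmap:
        lo, hi = max(a, ms), min(b, me)
        if lo >= hi:
            continue
        if strand == "+":
            rs, re = fs + (lo - ms), fs + (hi - ms)
        else:
            rs, re = fs + (me - hi), fs + (me - lo)
        piece_strand = strand
        if flip:
            piece_strand = "-" if piece_strand == "+" else "+"
        out.append(ProvenancePiece(ref, rs, re, piece_strand))
    if flip:
        out.reverse()
    return out


def _add_substitutions(seq: str, rate: float, rng: np.random.Generator, bases) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.where(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# truth projection: allele coordinates -> host / transgene references

def project_allele_interval(
    truth: AlleleTruth,
    construct_len: int,
    start: int,
    end: int,
) -> list[tuple[str, int, int, str]]:
    """Map an allele interval onto (host chromosome | 'transgene') intervals.

    The transgenic allele is host[0:del_start] + N×construct + host[del_end:].
    Returns (ref, start, end, strand) tuples; strand is '-' for transgene
    pieces when the cassette was integrated in reverse orientation.
    """
    ev = truth.event
    left, right = truth.left_junction, truth.right_junction
    out: list[tuple[str, int, int, str]] = []
    # split at left, right, and internal copy boundaries
    bounds = [left + i * construct_len for i in range(ev.copies + 1)]
    cutpoints = sorted({start, end, left, right, *bounds})
    cutpoints = [c for c in cutpoints if start <= c <= end]
    for a, b in zip(cutpoints, cutpoints[1:]):
        if a == b:
            continue
        if b <= left:
            out.append((ev.chromosome, a, b, "+"))
        elif a >= right:
            shift = ev.deletion_end - right
            out.append((ev.chromosome, a + shift, b + shift, "+"))
        else:
            off_a, off_b = a - left, b - left
            block = off_a // construct_len
            ia, ib = off_a - block * construct_len, off_b - block * construct_len
            if ev.orientation == "forward":
                out.append(("transgene", ia, ib, "+"))
            else:
                out.append(("transgene", construct_len - ib, construct_len - ia, "-"))
    return out


def classify_read(
    read: SimulatedRead, truth: AlleleTruth, construct_len: int, allele_ref: str
) -> str:
    """Classify a read's true origin: 'host', 'transgene', 'junction', 'trans'.

    'junction' means the read covers both host and transgene sequence (a
    fusion read); 'trans' means it includes a trans-chromosomal ligation
    fragment from another chromosome.
    """
    refs = set()
    for piece in read.pieces:
        if piece.source_ref != allele_ref:
            refs.add("other")
            continue
        for ref, *_ in project_allele_interval(
            truth, construct_len, piece.start, piece.end
        ):
            refs.add("transgene" if ref == "transgene" else "host")
    if "other" in refs:
        return "trans"
    if refs == {"host"}:
        return "host"
    if refs == {"transgene"}:
        return "transgene"
    return "junction"


# ---------------------------------------------------------------------------
# serialization

def write_fastq(readset: SimulatedReadSet, r1_path, r2_path) -> None:
    """Paired FASTQ (Phred+33, uniform quality 'I')."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for read in readset.reads:
            fh = f1 if read.mate == 1 else f2
            fh.write(
                f"@{read.read_id}/{read.mate}\n{read.sequence}\n+\n"
                f"{'I' * len(read.sequence)}\n"
            )


def write_truth(readset: SimulatedReadSet, path) -> None:
    """Provenance TSV: read_id, mate, circle_id, source_ref, start, end, strand."""
    with open(path, "w") as fh:
        fh.write("read_id\tmate\tcircle_id\tsource_ref\tstart\tend\tstrand\n")
        for read in readset.reads:
            for p in read.pieces:
                fh.write(
                    f"{read.read_id}\t{read.mate}\t{read.circle_id}\t"
                    f"{p.source_ref}\t{p.start}\t{p.end}\t{p.strand}\n"
                )


def read_truth(path) -> dict[tuple[str, int], list[ProvenancePiece]]:
    """Inverse of :func:`write_truth` (keyed by (read_id, mate))."""
    out: dict[tuple[str, int], list[ProvenancePiece]] = {}
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("read_id")
        for line in fh:
            rid, mate, _circle, ref, s, e, strand = line.rstrip("\n").split("\t")
            out.setdefault((rid, int(mate)), []).append(
                ProvenancePiece(ref, int(s), int(e), strand)
            )
    return out


def default_viewpoint_primers(
    allele: Genome, element_prefix: str = "cre", primer_len: int = 22
) -> tuple[str, str]:
    """Derive an inverse-PCR primer pair from inside a transgene element.

    Mimics the real assay's primers inside Cre (or EGFP): two outward-facing
    primers ~100 bp apart near the element midpoint. Returned as plain
    sequences present on the allele's forward strand.
    """
    for ann in allele.annotations:
        if ann.feature_kind == "element" and ann.name.startswith(element_prefix):
            seq = allele.sequences[ann.chromosome]
            mid = (ann.start + ann.end) // 2
            p1 = seq[mid - 60 : mid - 60 + primer_len]
            p2 = seq[mid + 60 : mid + 60 + primer_len]
            return p1, p2
    raise ValueError(f"no transgene element matching prefix {element_prefix!r}")
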