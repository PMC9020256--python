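"""Seed-and-extend read mapping and the two-step TLA mapping strategy.

TLA circularization reshuffles genomic fragments, so many informative reads
are chimeric: they cross a ligation junction or the transgene integration
junction itself and cannot align end-to-end. The two-step strategy that
maximises mappability is implemented here: (1) map every read whole against
the host and transgene references; (2) reads without a near-full-length
alignment are digested in silico at the NlaIII motif and each sub-fragment
is remapped, its coordinates lifted back into parent-read space. Mates of a
pair are treated as independent single-end reads throughout, because pairing
geometry is meaningless after reshuffling.

The mapper is a classic seed-and-extend local aligner, ungapped by design
(junction detection needs split mapping, not small-indel alignment): exact
k-mer seeds on both strands propose diagonals; on each diagonal the
best-scoring contiguous stretch (match +1, mismatch −2) is taken, so a
chimeric read is clipped at the junction where the reference stops matching.
A segment is reported when it contains a seed-length run and its mismatch
count is within ``floor(max_mismatch_rate × length)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

from .genome import Genome
from .restriction import ENZYMES, RestrictionEnzyme, reverse_complement, split_read_at_sites

DEFAULT_K = 21
DEFAULT_MAX_MISMATCH_RATE = 0.04
DEFAULT_COVERED_FRACTION = 0.8
MISMATCH_PENALTY = 2


@dataclass(frozen=True)
class AlignmentSegment:
    """A maximal ungapped local match of (part of) a read to one reference.

    Read coordinates are 0-based half-open in the read's own orientation
    (as sequenced); for ``strand == '-'`` the read's reverse complement
    matches the reference forward strand over [ref_start, ref_end).
    """

    read_id: str
    read_start: int
    read_end: int
    reference_id: str
    ref_start: int
    ref_end: int
    strand: str
    mismatches: int
    pass_label: str = "primary_pass"   # primary_pass | split_pass
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.read_end - self.read_start != self.ref_end - self.ref_start:
            raise ValueError("ungapped segment: read and reference spans must be equal")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def length(self) -> int:
        return self.read_end - self.read_start

    @property
    def score(self) -> int:
        return self.length - (1 + MISMATCH_PENALTY) * self.mismatches

    def read_overlap(self, other: "AlignmentSegment") -> int:
        return max(
            0, min(self.read_end, other.read_end) - max(self.read_start, other.read_start)
        )


class SeedIndex:
    """Exact k-mer index over a reference set. Forward-strand k-mers are
    stored; reverse-strand hits are resolved by querying the reverse
    complement, so both strands are effectively indexed."""

    def __init__(self, refs: Genome, k: int = DEFAULT_K):
        if k < 11:
            raise ValueError("k must be >= 11")
        if not refs.sequences:
            raise ValueError("reference set is empty")
        shortest = min(len(s) for s in refs.sequences.values())
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest reference ({shortest} bp)")
        self.k = k
        self.refs = dict(refs.sequences)
        self.arrays = {
            name: np.frombuffer(seq.encode(), dtype=np.uint8)
            for name, seq in self.refs.items()
        }
        table: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.refs.items():
            for i in range(len(seq) - k + 1):
                table.setdefault(seq[i : i + k], []).append((name, i))
        self.table = table

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All (reference, position, strand) exact matches of ``kmer``."""
        fwd = [(r, p, "+") for r, p in self.table.get(kmer, ())]
        rev = [(r, p, "-") for r, p in self.table.get(reverse_complement(kmer), ())]
        return fwd + rev


def build_seed_index(refs: Genome, k: int = DEFAULT_K) -> SeedIndex:
    return SeedIndex(refs, k)


def _best_local(q_arr: np.ndarray, ref_arr: np.ndarray, diag: int) -> tuple[int, int, int] | None:
    """Best-scoring contiguous stretch of the read on one diagonal.

    Kadane's algorithm over per-base scores (+1 match, −2 mismatch); ties
    broken toward the longer, then leftmost stretch. Returns
    (read_start, read_end, mismatches) in query coordinates, or None.
    """
    qs = max(0, -diag)
    qe = min(len(q_arr), len(ref_arr) - diag)
    if qe - qs < 1:
        return None
    mism = q_arr[qs:qe] != ref_arr[qs + diag : qe + diag]
    best_sum = 0
    best = None           # (sum, a, b)
    cur = 0
    cur_a = 0
    n_mm_best = 0
    cur_mm = 0
    for i, bad in enumerate(mism):
        sc = -MISMATCH_PENALTY if bad else 1
        if cur <= 0:
            cur, cur_a, cur_mm = 0, i, 0
        cur += sc
        cur_mm += int(bad)
        if cur > best_sum or (
            best is not None and cur == best_sum and (i + 1 - cur_a) > (best[2] - best[1])
        ):
            best_sum = cur
            best = (cur, cur_a, i + 1)
            n_mm_best = cur_mm
    if best is None:
        return None
    _, a, b = best
    return qs + a, qs + b, n_mm_best


def map_sequence(
    seq: str,
    index: SeedIndex,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    read_id: str = "read",
    report: str = "best",
    seed_stride: int = 1,
) -> list[AlignmentSegment]:
    """Map one sequence against an index; empty list means unaligned.

    ``report='best'`` keeps only the top-scoring locus (all tied loci,
    each flagged ambiguous); ``report='all'`` returns every locus whose
    best local segment meets the mismatch budget, sorted by score.
    """
    n = len(seq)
    k = index.k
    if n < k:
        return []
    segments: list[AlignmentSegment] = []
    table = index.table
    for strand, query in (("+", seq), ("-", reverse_complement(seq))):
        q_arr = np.frombuffer(query.encode(), dtype=np.uint8)
        diagonals: set[tuple[str, int]] = set()
        # forward-table probes only: scanning the reverse-complement query
        # against forward k-mers covers the minus strand
        for i in range(0, n - k + 1, seed_stride):
            hits = table.get(query[i : i + k])
            if hits:
                for ref, pos in hits:
                    diagonals.add((ref, pos - i))
        for ref, diag in diagonals:
            hit = _best_local(q_arr, index.arrays[ref], diag)
            if hit is None:
                continue
            qs, qe, mm = hit
            if qe - qs < k or mm > int(max_mismatch_rate * (qe - qs)):
                continue
            if strand == "+":
                rs, re_ = qs, qe
            else:
                rs, re_ = n - qe, n - qs
            segments.append(
                AlignmentSegment(read_id, rs, re_, ref, qs + diag, qe + diag,
                                 strand, mm)
            )
    if not segments:
        return []
    uniq = {(s.reference_id, s.ref_start, s.ref_end, s.strand, s.read_start): s
            for s in segments}
    segments = sorted(
        uniq.values(),
        key=lambda s: (-s.score, s.reference_id, s.ref_start, s.strand),
    )
    if report == "all":
        return segments
    best = segments[0].score
    top = [s for s in segments if s.score == best]
    if len(top) > 1:
        top = [replace(s, ambiguous=True) for s in top]
    return top


def chain_segments(candidates: list[AlignmentSegment]) -> list[AlignmentSegment]:
    """Greedy read-interval chaining: keep the best-scoring segments whose
    read intervals do not substantially overlap an already kept one, so a
    chimeric read yields one segment per constituent fragment. A kept
    segment is flagged ambiguous when an equally scoring candidate covers
    (nearly) the same read interval on a different locus."""
    kept: list[AlignmentSegment] = []
    for s in sorted(candidates, key=lambda x: (-x.score, x.reference_id, x.ref_start, x.strand)):
        clash = None
        for t in kept:
            if s.read_overlap(t) > 0.5 * min(s.length, t.length):
                clash = t
                break
        if clash is None:
            kept.append(s)
        elif (
            s.score == clash.score
            and not clash.ambiguous
            and s.read_overlap(clash) >= 0.9 * max(s.length, clash.length)
            and (s.reference_id, s.ref_start) != (clash.reference_id, clash.ref_start)
        ):
            kept[kept.index(clash)] = replace(clash, ambiguous=True)
    return sorted(kept, key=lambda s: s.read_start)


@dataclass
class TwoStepParams:
    k: int = DEFAULT_K
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE
    covered_fraction: float = DEFAULT_COVERED_FRACTION
    min_split_len: int = 20
    enzyme: RestrictionEnzyme = field(default_factory=lambda: ENZYMES["NlaIII"])


def map_read_both(
    seq: str,
    host_index: SeedIndex,
    transgene_index: SeedIndex,
    rate: float = DEFAULT_MAX_MISMATCH_RATE,
    read_id: str = "read",
) -> list[AlignmentSegment]:
    """Chained local segments of one read against host + transgene jointly."""
    hits = map_sequence(seq, host_index, rate, read_id, report="all")
    hits += map_sequence(seq, transgene_index, rate, read_id, report="all")
    return chain_segments(hits) if hits else []


def tla_two_step_map(
    reads: Iterable[tuple[str, str]],
    host_index: SeedIndex,
    transgene_index: SeedIndex,
    params: TwoStepParams | None = None,
) -> list[AlignmentSegment]:
    """Two-pass TLA mapping against host and transgene references jointly.

    Pass 1 maps each read whole. If no single segment covers at least
    ``covered_fraction`` of the read, the read is digested in silico at the
    enzyme motif and each sub-fragment remapped in pass 2 (``split_pass``),
    sub-read coordinates lifted back to parent-read coordinates. Output is
    the union of both passes.
    """
    params = params or TwoStepParams()
    out: list[AlignmentSegment] = []
    for read_id, seq in reads:
        hits = map_read_both(seq, host_index, transgene_index,
                             params.max_mismatch_rate, read_id)
        if hits and max(s.length for s in hits) >= params.covered_fraction * len(seq):
            out.extend(hits)
            continue
        out.extend(hits)  # partial pass-1 evidence is kept
        for sub, offset in split_read_at_sites(seq, params.enzyme, params.min_split_len):
            for s in map_read_both(sub, host_index, transgene_index,
                                   params.max_mismatch_rate, read_id):
                out.append(
                    replace(
                        s,
                        read_start=s.read_start + offset,
                        read_end=s.read_end + offset,
                        pass_label="split_pass",
                    )
                )
    return out


# ---------------------------------------------------------------------------
# FASTQ input and SAM output

def iter_fastq_reads(*paths) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from FASTQ files; mates stay independent."""
    from Bio import SeqIO

    for path in paths:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield rec.id, str(rec.seq)


def write_sam(
    segments: list[AlignmentSegment],
    references: dict[str, int],
    read_seqs: dict[str, str] | None,
    path,
) -> None:
    """Write segments as SAM text. Split segments of one read are linked via
    an SA tag; non-primary segments carry the supplementary flag. Soft clips
    stand for the unaligned read ends; POS is 1-based per SAM."""
    read_seqs = read_seqs or {}
    by_read: dict[str, list[AlignmentSegment]] = {}
    for s in segments:
        by_read.setdefault(s.read_id, []).append(s)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        fh.write("@PG\tID:tlamap\tPN:tlamap\n")
        for read_id, segs in by_read.items():
            seq = read_seqs.get(read_id, "")
            primary = max(segs, key=lambda s: s.score)
            for s in segs:
                flag = 0
                if s.strand == "-":
                    flag |= 0x10
                if s is not primary:
                    flag |= 0x800
                n = len(seq) if seq else s.read_end
                if s.strand == "+":
                    left, right = s.read_start, max(0, n - s.read_end)
                    out_seq = seq or "*"
                else:
                    left, right = max(0, n - s.read_end), s.read_start
                    out_seq = reverse_complement(seq) if seq else "*"
                cigar = (f"{left}S" if left else "") + f"{s.length}M" + (
                    f"{right}S" if right else ""
                )
                tags = [f"NM:i:{s.mismatches}", f"XP:Z:{s.pass_label}"]
                if s.ambiguous:
                    tags.append("XA:i:1")
                others = [o for o in segs if o is not s]
                if others:
                    sa = ";".join(
                        f"{o.reference_id},{o.ref_start + 1},{o.strand},"
                        f"{o.length}M,0,{o.mismatches}"
                        for o in others
                    )
                    tags.append(f"SA:Z:{sa};")
                fields = [
                    read_id, str(flag), s.reference_id, str(s.ref_start + 1),
                    "0" if s.ambiguous else "60", cigar, "*", "0", "0",
                    out_seq, "*", *tags,
                ]
                fh.write("\t".join(fields) + "\n")


def read_sam_segments(path) -> list[AlignmentSegment]:
    """Parse SAM written by :func:`write_sam` back into segments."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            read_id, flag, ref, pos, _mapq, cigar = (
                f[0], int(f[1]), f[2], int(f[3]), f[4], f[5]
            )
            tags = {}
            for t in f[11:]:
                key, _typ, val = t.split(":", 2)
                tags[key] = val
            strand = "-" if flag & 0x10 else "+"
            num = ""
            ops: list[tuple[int, str]] = []
            for ch in cigar:
                if ch.isdigit():
                    num += ch
                else:
                    ops.append((int(num), ch))
                    num = ""
            lead = ops[0][0] if ops and ops[0][1] == "S" else 0
            trail = ops[-1][0] if len(ops) > 1 and ops[-1][1] == "S" else 0
            mlen = sum(n for n, op in ops if op == "M")
            if strand == "+":
                rs, re_ = lead, lead + mlen
            else:
                rs, re_ = trail, trail + mlen
            out.append(
                AlignmentSegment(
                    read_id, rs, re_, ref, pos - 1, pos - 1 + mlen, strand,
                    int(tags.get("NM", 0)),
                    tags.get("XP", "primary_pass"),
                    tags.get("XA") == "1",
                )
            )
    return out
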