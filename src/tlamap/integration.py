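"""Integration-site calling from TLA alignments.

Turns split-read alignments into the quantities of interest for a random
transgene integration: the host chromosome and the two breakpoints flanking
the insertion, the host interval deleted by the integration (confirmed by a
coverage drop), a tandem copy-number estimate from transgene self-junction
reads, base-pair-resolution junction consensus sequences, and per-gene
disruption calls (complete deletion, partial deletion, intronic insertion).

Coordinate conventions: everything internal is 0-based half-open. Reported
breakpoints are 1-based: ``left_breakpoint`` is the first deleted host base
and ``right_breakpoint`` the first host base retained after the deletion,
so ``right − left`` equals the deletion length in bp.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .genome import Annotation, Genome
from .mapping import AlignmentSegment
from .restriction import reverse_complement

DEFAULT_MIN_SUPPORT = 3
DEFAULT_CLUSTER_WINDOW = 10
DEFAULT_JUNCTION_SLOP = 5
TRANSGENE_REF = "transgene"


class IntegrationError(Exception):
    """Base class for typed integration-calling failures."""


class NoEvidenceError(IntegrationError):
    pass


class OneSidedSupportError(IntegrationError):
    """Only one junction side has sufficient base-exact support."""


class AmbiguousIntegrationError(IntegrationError):
    """Top-supported junction clusters disagree on the chromosome."""

    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(f"ambiguous integration: candidates {candidates}")


class JunctionNotReconstructableError(IntegrationError):
    pass


@dataclass(frozen=True)
class FusionEvidence:
    """One read's evidence of a host↔transgene (or transgene self) junction.

    ``base_exact`` is True when the two segments are adjacent in read
    coordinates (|gap| ≤ junction_slop), localizing the junction to base-pair
    resolution; otherwise the record is ligation-level proximity evidence.
    ``host_boundary`` / ``tg_boundary`` are the reference coordinates of the
    segment ends that face the junction.
    """

    read_id: str
    host_segment: AlignmentSegment | None
    transgene_segment: AlignmentSegment
    junction_kind: str   # host_to_transgene_5prime | transgene_3prime_to_host | transgene_self
    base_exact: bool
    host_boundary: int | None
    tg_boundary: int
    gap: int
    second_tg_boundary: int | None = None   # transgene_self only
    at_cassette_edge: bool = False


@dataclass
class JunctionSequence:
    """Consensus sequence across one host↔transgene junction.

    The host part is rendered lowercase and the transgene part uppercase
    (replacing a colour-coded figure convention in plain text).
    """

    kind: str
    consensus: str
    host_part_length: int
    transgene_part_length: int
    supporting_reads: int

    def __post_init__(self) -> None:
        if len(self.consensus) != self.host_part_length + self.transgene_part_length:
            raise ValueError("consensus length must equal host + transgene part lengths")
        if self.supporting_reads < 1:
            raise ValueError("supporting_reads must be >= 1")


@dataclass
class IntegrationCall:
    """The called integration: breakpoints, deletion, copies, junctions."""

    chromosome: str
    left_breakpoint: int          # 1-based, first deleted base
    right_breakpoint: int         # 1-based, first retained base after deletion
    support_left: int
    support_right: int
    deletion_interval: tuple[int, int] | None = None   # 0-based half-open
    deletion_length_bp: int | None = None
    deletion_kb: str | None = None
    deletion_confirmed: bool | None = None
    copies_estimate: int | None = None
    copies_is_lower_bound: bool = False
    copies_support: int = 0
    junctions: list[JunctionSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        # equality is the pure-insertion (zero-width deletion) case
        if self.left_breakpoint > self.right_breakpoint:
            raise ValueError("left breakpoint must be <= right breakpoint")

    @property
    def interval0(self) -> tuple[int, int]:
        """Deletion interval, 0-based half-open."""
        return self.left_breakpoint - 1, self.right_breakpoint - 1

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "left_breakpoint": self.left_breakpoint,
            "right_breakpoint": self.right_breakpoint,
            "support_left": self.support_left,
            "support_right": self.support_right,
            "deletion_length_bp": self.deletion_length_bp,
            "deletion_kb": self.deletion_kb,
            "deletion_confirmed": self.deletion_confirmed,
            "copies_estimate": self.copies_estimate,
            "copies_is_lower_bound": self.copies_is_lower_bound,
            "copies_support": self.copies_support,
            "junctions": [
                {
                    "kind": j.kind,
                    "consensus": j.consensus,
                    "host_part_length": j.host_part_length,
                    "transgene_part_length": j.transgene_part_length,
                    "supporting_reads": j.supporting_reads,
                }
                for j in self.junctions
            ],
        }


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon sub-intervals (0-based half-open, host coordinates)."""

    name: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.name}: exon [{s},{e}) outside gene body")

    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


@dataclass(frozen=True)
class GeneImpact:
    gene_name: str
    impact: str     # complete_deletion | partial_deletion | intronic_insertion | unaffected
    detail: str = ""


# ---------------------------------------------------------------------------
# fusion evidence

def _junction_side_coord(seg: AlignmentSegment, touch_end: bool) -> int:
    """Reference coordinate of the segment end that faces the junction.

    ``touch_end`` means the junction sits at the segment's read_end side.
    For a forward-strand segment the read_end side corresponds to ref_end;
    for a reverse-strand segment it corresponds to ref_start.
    """
    if touch_end:
        return seg.ref_end if seg.strand == "+" else seg.ref_start
    return seg.ref_start if seg.strand == "+" else seg.ref_end


def _dedupe(segments: list[AlignmentSegment]) -> list[AlignmentSegment]:
    seen = {}
    for s in segments:
        key = (s.read_id, s.reference_id, s.ref_start, s.ref_end, s.strand,
               s.read_start, s.read_end)
        if key not in seen:
            seen[key] = s
    return list(seen.values())


def collect_fusion_evidence(
    alignments: list[AlignmentSegment],
    transgene_length: int,
    junction_slop: int = DEFAULT_JUNCTION_SLOP,
    transgene_ref: str = TRANSGENE_REF,
    max_overlap: int = 30,
) -> list[FusionEvidence]:
    """Extract host/transgene junction evidence from split alignments.

    Every read carrying at least one unambiguous host segment and one
    unambiguous transgene segment yields one record per segment adjacency;
    transgene→transgene adjacencies joining the cassette 3' end to its 5'
    start are recorded as ``transgene_self`` (tandem-copy) evidence.
    Ambiguous (multi-mapping) segments are ignored — conservative.

    TLA circles join the viewpoint restriction fragment to arbitrary nearby
    fragments, so host↔transgene adjacencies arise at every ligation
    junction, not only at the integration junction. The two are separated by
    where the transgene is touched: a genuine integration junction abuts the
    cassette at one of its ends (transgene coordinate ~0 or ~length), while
    ligation artifacts abut internal restriction-fragment boundaries.
    ``at_cassette_edge`` records this test; breakpoint calling uses only
    edge-anchored evidence.
    """
    by_read: dict[str, list[AlignmentSegment]] = {}
    for s in alignments:
        if not s.ambiguous:
            by_read.setdefault(s.read_id, []).append(s)

    out: list[FusionEvidence] = []
    for read_id, segs in by_read.items():
        segs = sorted(_dedupe(segs), key=lambda s: (s.read_start, s.read_end))
        host = [s for s in segs if s.reference_id != transgene_ref]
        tg = [s for s in segs if s.reference_id == transgene_ref]
        for h in host:
            for t in tg:
                first, second = (h, t) if h.read_start <= t.read_start else (t, h)
                gap = second.read_start - first.read_end
                # a negative gap is junction microhomology — the overlap is
                # resolved exactly below by anchoring on the cassette edge,
                # so it may be generous; unexplained positive gaps stay tight
                base_exact = -max_overlap <= gap <= junction_slop
                host_first = first is h
                hb = _junction_side_coord(h, touch_end=host_first)
                tb = _junction_side_coord(t, touch_end=not host_first)
                if gap < 0:
                    # junction microhomology: the host segment over-extends
                    # into cassette sequence it happens to share. The
                    # transgene segment is clipped at the cassette edge and
                    # cannot over-extend, so the junction sits at the
                    # transgene side of the overlap; re-read the host
                    # boundary at that read position.
                    p = t.read_start if host_first else t.read_end
                    hb = (
                        h.ref_start + (p - h.read_start)
                        if h.strand == "+"
                        else h.ref_end - (p - h.read_start)
                    )
                kind = (
                    "host_to_transgene_5prime"
                    if tb <= transgene_length / 2
                    else "transgene_3prime_to_host"
                )
                edge = tb <= junction_slop or tb >= transgene_length - junction_slop
                out.append(
                    FusionEvidence(read_id, h, t, kind, base_exact, hb, tb, gap,
                                   at_cassette_edge=edge)
                )
        # transgene self-junctions (tandem head-to-tail copies): a 3'-end to
        # 5'-start adjacency; internal splits and ligation artifacts do not
        # join the two cassette extremities
        for i in range(len(tg)):
            for j in range(i + 1, len(tg)):
                a, b = tg[i], tg[j]
                gap = b.read_start - a.read_end
                if not (-max_overlap <= gap <= junction_slop):
                    continue
                ba = _junction_side_coord(a, touch_end=True)
                bb = _junction_side_coord(b, touch_end=False)
                lo, hi = min(ba, bb), max(ba, bb)
                if lo > junction_slop or hi < transgene_length - junction_slop:
                    continue
                out.append(
                    FusionEvidence(
                        read_id, None, a, "transgene_self", True,
                        None, lo, gap, second_tg_boundary=hi,
                        at_cassette_edge=True,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# breakpoint clustering

def _cluster(coords: list[int], window: int) -> list[list[int]]:
    """Greedy 1-D clustering: consecutive sorted coords within ``window``."""
    if not coords:
        return []
    coords = sorted(coords)
    clusters = [[coords[0]]]
    for c in coords[1:]:
        if c - clusters[-1][-1] <= window:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    return clusters


def _mode(values: list[int]) -> int:
    counts = Counter(values)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def call_integration_site(
    evidence: list[FusionEvidence],
    min_support: int = DEFAULT_MIN_SUPPORT,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
) -> IntegrationCall:
    """Cluster base-exact junction evidence into the two breakpoints.

    The top-supported cluster of each junction kind (host→transgene-5′ and
    transgene-3′→host) gives one breakpoint; both must lie on the same
    chromosome and carry at least ``min_support`` base-exact reads.
    Breakpoints are the modal coordinate of each cluster, reported 1-based.
    """
    base = [
        e for e in evidence
        if e.base_exact and e.at_cassette_edge and e.junction_kind != "transgene_self"
    ]
    if not base:
        raise NoEvidenceError("no base-exact cassette-edge fusion evidence")

    top: dict[str, tuple[str, int, int]] = {}   # kind -> (chrom, modal coord, support)
    for kind in ("host_to_transgene_5prime", "transgene_3prime_to_host"):
        per_chrom: list[tuple[str, int, int]] = []
        for chrom in {e.host_segment.reference_id for e in base}:
            coords = [
                e.host_boundary
                for e in base
                if e.junction_kind == kind and e.host_segment.reference_id == chrom
            ]
            for cl in _cluster(coords, cluster_window):
                per_chrom.append((chrom, _mode(cl), len(cl)))
        if per_chrom:
            per_chrom.sort(key=lambda x: (-x[2], x[0], x[1]))
            top[kind] = per_chrom[0]

    if len(top) < 2:
        raise OneSidedSupportError(
            f"one-sided support: only {list(top)} junction kind(s) observed"
        )
    (c1, m1, s1), (c2, m2, s2) = top.values()
    if c1 != c2:
        raise AmbiguousIntegrationError(sorted(top.values()))
    if s1 < min_support or s2 < min_support:
        raise OneSidedSupportError(
            f"insufficient support: {s1} and {s2} base-exact reads (need {min_support})"
        )
    (left, sup_left), (right, sup_right) = sorted([(m1, s1), (m2, s2)])
    return IntegrationCall(
        chromosome=c1,
        left_breakpoint=left + 1,
        right_breakpoint=right + 1,
        support_left=sup_left,
        support_right=sup_right,
    )


# ---------------------------------------------------------------------------
# deletion

def deletion_metrics(left_breakpoint: int, right_breakpoint: int) -> tuple[int, str]:
    """Deletion length and its kb rendering from reported (1-based) breakpoints."""
    length = right_breakpoint - left_breakpoint
    return length, f"{round(length / 1000)} kb"


def coverage_from_segments(
    segments: list[AlignmentSegment], reference_id: str, length: int
) -> np.ndarray:
    """Per-base alignment depth on one reference."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for s in segments:
        if s.reference_id == reference_id and not s.ambiguous:
            diff[s.ref_start] += 1
            diff[s.ref_end] -= 1
    return np.cumsum(diff[:-1])


def call_deletion(
    call: IntegrationCall,
    coverage_profile: np.ndarray | None,
    flank_window: int = 5_000,
    max_internal_ratio: float = 0.2,
) -> IntegrationCall:
    """Attach deletion interval/length to a call and confirm it by coverage.

    The deletion is confirmed when mean host coverage strictly inside the
    interval is at most ``max_internal_ratio`` times the mean coverage in a
    ``flank_window`` outside each breakpoint. A zero-width interval skips
    confirmation. An unconfirmed deletion keeps its interval but is flagged.
    """
    l0, r0 = call.interval0
    call.deletion_interval = (l0, r0)
    call.deletion_length_bp, call.deletion_kb = deletion_metrics(
        call.left_breakpoint, call.right_breakpoint
    )
    if call.deletion_length_bp == 0 or coverage_profile is None:
        call.deletion_confirmed = None
        return call
    n = len(coverage_profile)
    inside = coverage_profile[l0:r0]
    flanks = np.concatenate(
        [
            coverage_profile[max(0, l0 - flank_window) : l0],
            coverage_profile[r0 : min(n, r0 + flank_window)],
        ]
    )
    mean_in = float(inside.mean()) if inside.size else 0.0
    mean_fl = float(flanks.mean()) if flanks.size else 0.0
    call.deletion_confirmed = bool(mean_fl > 0 and mean_in <= max_internal_ratio * mean_fl)
    return call


# ---------------------------------------------------------------------------
# copy number

def estimate_tandem_copy_number(
    evidence: list[FusionEvidence],
    call: IntegrationCall,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
) -> IntegrationCall:
    """Copies from transgene self-junction reads: 1 + distinct self-junction
    clusters. Identical head-to-tail junctions collapse, so any estimate
    ≥ 2 is a lower bound."""
    selfs = [e for e in evidence if e.junction_kind == "transgene_self" and e.base_exact]
    if not selfs:
        call.copies_estimate = 1
        call.copies_is_lower_bound = False
        call.copies_support = 0
        return call
    pairs = sorted((e.tg_boundary, e.second_tg_boundary) for e in selfs)
    clusters = 1
    for (a1, b1), (a2, b2) in zip(pairs, pairs[1:]):
        if abs(a2 - a1) > cluster_window or abs(b2 - b1) > cluster_window:
            clusters += 1
    call.copies_estimate = 1 + clusters
    call.copies_is_lower_bound = True
    call.copies_support = len(selfs)
    return call


# ---------------------------------------------------------------------------
# junction consensus

def _oriented_read(seq: str, h: AlignmentSegment, j: int) -> tuple[str, int]:
    """Orient a read so its host segment matches the reference forward
    strand; ``j`` is the junction position in read coordinates."""
    if h.strand == "-":
        return reverse_complement(seq), len(seq) - j
    return seq, j


def evidence_allele_side(e: FusionEvidence) -> str:
    """Which side of the cassette the host flank of this evidence lies on.

    Determined purely by read geometry: orienting the read so the host
    segment matches the forward reference, the host flank precedes the
    cassette at the left junction and follows it at the right one. Robust to
    cassette orientation and to zero-width deletions, where both junctions
    share one host coordinate.
    """
    h = e.host_segment
    host_first = h.read_start <= e.transgene_segment.read_start
    return "left" if host_first == (h.strand == "+") else "right"


def reconstruct_junctions(
    read_seqs: dict[str, str],
    evidence: list[FusionEvidence],
    call: IntegrationCall,
    flank: int = 30,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
) -> list[JunctionSequence]:
    """Per-column majority consensus over ±``flank`` bp around each junction.

    Supporting reads are anchored at the breakpoint; the host part is
    rendered lowercase and the transgene part uppercase. The consensus is
    trimmed to the columns covered by at least one read.
    """
    l0, r0 = call.interval0
    out = []
    for side, bp0 in (("left", l0), ("right", r0)):
        support = [
            e for e in evidence
            if e.base_exact
            and e.at_cassette_edge
            and e.junction_kind != "transgene_self"
            and e.host_segment.reference_id == call.chromosome
            and abs(e.host_boundary - bp0) <= cluster_window
            and evidence_allele_side(e) == side
        ]
        if not support:
            raise JunctionNotReconstructableError(
                f"no base-exact reads span the {side} junction"
            )
        kind = Counter(e.junction_kind for e in support).most_common(1)[0][0]
        cols: dict[int, Counter] = {}
        for e in support:
            seq = read_seqs.get(e.read_id)
            if seq is None:
                continue
            h = e.host_segment
            t = e.transgene_segment
            host_first = h.read_start <= t.read_start
            # anchor at the cassette edge — immune to junction microhomology
            j_read = t.read_start if host_first else t.read_end
            oriented, j = _oriented_read(seq, h, j_read)
            # after orientation the host segment matches the forward
            # reference; at the left junction host precedes transgene, at
            # the right it follows, whichever way the read was sequenced
            for off, pos in zip(range(-flank, flank), range(j - flank, j + flank)):
                if 0 <= pos < len(oriented):
                    cols.setdefault(off, Counter())[oriented[pos]] += 1
        if not cols:
            raise JunctionNotReconstructableError(
                f"{side} junction reads lack usable sequence"
            )
        lo = min(cols)
        hi = max(cols) + 1
        consensus_chars = []
        host_len = tg_len = 0
        for off in range(lo, hi):
            counter = cols.get(off)
            if counter is None:
                base = "N"
            else:
                topn = max(counter.values())
                base = min(b for b, c in counter.items() if c == topn)
            host_side = (off < 0) if side == "left" else (off >= 0)
            consensus_chars.append(base.lower() if host_side else base.upper())
            if host_side:
                host_len += 1
            else:
                tg_len += 1
        out.append(
            JunctionSequence(
                kind=kind,
                consensus="".join(consensus_chars),
                host_part_length=host_len,
                transgene_part_length=tg_len,
                supporting_reads=len(support),
            )
        )
    call.junctions = out
    return out


# ---------------------------------------------------------------------------
# gene disruption

def gene_models_from_genome(genome: Genome, chromosome: str | None = None) -> list[GeneModel]:
    """Assemble GeneModel objects from gene + exon annotations.

    Exons are attached to the gene whose interval contains them (name
    prefix ``<gene>_`` preferred when present).
    """
    genes = [a for a in genome.annotations if a.feature_kind == "gene"
             and (chromosome is None or a.chromosome == chromosome)]
    exons = [a for a in genome.annotations if a.feature_kind == "exon"]
    models = []
    for g in genes:
        ex = [
            (a.start, a.end)
            for a in exons
            if a.chromosome == g.chromosome
            and a.start >= g.start and a.end <= g.end
            and (a.name.startswith(f"{g.name}_") or not a.name)
        ]
        models.append(GeneModel(g.name, g.chromosome, g.start, g.end, g.strand,
                                tuple(sorted(ex))))
    return models


def _intron_ordinal(gene: GeneModel, point: int) -> int | None:
    """1-based index i such that ``point`` lies between exon i and exon i+1
    (in transcription order)."""
    introns = gene.introns()
    for i, (s, e) in enumerate(introns, start=1):
        if s <= point < e:
            if gene.strand == "-":
                return len(gene.exons) - i
            return i
    return None


def annotate_gene_disruption(
    call: IntegrationCall, gene_models: list[GeneModel]
) -> list[GeneImpact]:
    """Classify each gene against the deletion/insertion by interval arithmetic.

    A gene contained in the deletion (closed containment) is completely
    deleted; a gene partially overlapping it is partially deleted, with the
    surviving breakpoint located to an intron when it falls in one; a gene
    merely hosting a zero-width insertion point in an intron is an intronic
    insertion; everything else is unaffected. Pure interval computation —
    input order never matters.
    """
    l0, r0 = call.interval0
    out = []
    for g in sorted(gene_models, key=lambda g: (g.chromosome, g.start, g.name)):
        if g.chromosome != call.chromosome:
            out.append(GeneImpact(g.name, "unaffected"))
            continue
        overlaps = g.start < r0 and g.end > l0
        contained = g.start >= l0 and g.end <= r0
        if contained and r0 > l0:
            out.append(GeneImpact(g.name, "complete_deletion"))
            continue
        if overlaps and r0 > l0:
            # the breakpoint surviving inside the gene is the insertion point
            point = r0 if g.end > r0 else max(l0 - 1, g.start)
            intron = _intron_ordinal(g, point)
            detail = (
                f"insertion between exon {intron} and exon {intron + 1}"
                if intron is not None
                else "breakpoint within exon"
            )
            out.append(GeneImpact(g.name, "partial_deletion", detail))
            continue
        if r0 == l0 and g.start < l0 < g.end:
            intron = _intron_ordinal(g, l0)
            if intron is not None:
                out.append(
                    GeneImpact(
                        g.name, "intronic_insertion",
                        f"insertion between exon {intron} and exon {intron + 1}",
                    )
                )
                continue
            out.append(GeneImpact(g.name, "partial_deletion", "insertion within exon"))
            continue
        out.append(GeneImpact(g.name, "unaffected"))
    return out


# ---------------------------------------------------------------------------
# gene-model I/O (minimal GFF3)

def read_gff3_genes(path) -> list[GeneModel]:
    """Minimal GFF3 reader: gene features with exon children (Parent= or ID
    prefix linkage). Coordinates converted from 1-based inclusive to 0-based
    half-open."""
    genes: dict[str, dict] = {}
    exons: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _src, kind, start, end, _score, strand, _frame, attrs = f[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if kind == "gene":
                gid = attr.get("ID", attr.get("Name", f"gene{len(genes)}"))
                genes[gid] = dict(
                    name=attr.get("Name", gid), chromosome=chrom,
                    start=int(start) - 1, end=int(end), strand=strand,
                )
            elif kind == "exon":
                parent = attr.get("Parent", "")
                exons.append((parent, chrom, int(start) - 1, int(end)))
    models = []
    for gid, g in genes.items():
        ex = tuple(sorted((s, e) for p, c, s, e in exons if p == gid))
        models.append(GeneModel(g["name"], g["chromosome"], g["start"], g["end"],
                                g["strand"], ex))
    return models


def write_gff3_genes(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            fh.write(
                f"{g.chromosome}\ttlamap\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.name};Name={g.name}\n"
            )
            for i, (s, e) in enumerate(sorted(g.exons), start=1):
                fh.write(
                    f"{g.chromosome}\ttlamap\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tID={g.name}.exon{i};Parent={g.name}\n"
                )
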