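"""Seed-and-extend mapper and two-step TLA mapping."""

import numpy as np
import pytest

from tlamap.genome import Genome
from tlamap.mapping import (
    AlignmentSegment,
    TwoStepParams,
    build_seed_index,
    map_read_both,
    map_sequence,
    read_sam_segments,
    tla_two_step_map,
    write_sam,
)
from tlamap.restriction import reverse_complement
from tlamap.simulate import classify_read


def random_genome(rng, name="ref", n=50_000) -> Genome:
    return Genome({name: "".join(rng.choice(list("ACGT"), size=n))})


def test_index_enumeration_and_misses():
    seq = "ACGTACGTACGTACG"  # "ACGTACGTACG" (k=11) at 0 and 4
    idx = build_seed_index(Genome({"r": seq}), k=11)
    hits = idx.lookup("ACGTACGTACG")
    assert [(r, p) for r, p, s in hits if s == "+"] == [("r", 0), ("r", 4)]
    assert idx.lookup("T" * 11) == []
    # reverse-strand hit resolved through the reverse complement
    rc_hits = idx.lookup(reverse_complement("ACGTACGTACG"))
    assert ("r", 0, "-") in rc_hits


def test_index_validation():
    g = Genome({"r": "ACGT" * 100})
    with pytest.raises(ValueError, match="k must be"):
        build_seed_index(g, k=5)
    with pytest.raises(ValueError, match="shortest reference"):
        build_seed_index(Genome({"r": "ACGTACGT"}), k=11)
    with pytest.raises(ValueError, match="empty"):
        build_seed_index(Genome({}), k=11)


def test_seed_hits_match_substring_search():
    """Seed lookups for random 30-mers equal brute-force substring search."""
    rng = np.random.default_rng(41)
    g = random_genome(rng)
    ref = g.sequences["ref"]
    idx = build_seed_index(g, k=21)
    for _ in range(100):
        start = int(rng.integers(0, len(ref) - 30))
        kmer = ref[start : start + 21]
        brute = []
        pos = ref.find(kmer)
        while pos != -1:
            brute.append(pos)
            pos = ref.find(kmer, pos + 1)
        assert [p for r, p, s in idx.lookup(kmer) if s == "+"] == brute


def test_exact_substring_maps_full_length():
    rng = np.random.default_rng(42)
    g = random_genome(rng)
    idx = build_seed_index(g)
    start = 12_345
    read = g.sequences["ref"][start : start + 150]
    (seg,) = map_sequence(read, idx)
    assert (seg.read_start, seg.read_end) == (0, 150)
    assert (seg.ref_start, seg.ref_end, seg.strand) == (start, start + 150, "+")
    assert seg.mismatches == 0


def test_reverse_complement_maps_minus_strand():
    rng = np.random.default_rng(43)
    g = random_genome(rng)
    idx = build_seed_index(g)
    start = 30_000
    read = reverse_complement(g.sequences["ref"][start : start + 150])
    (seg,) = map_sequence(read, idx)
    assert seg.strand == "-"
    assert (seg.ref_start, seg.ref_end) == (start, start + 150)


def exhaustive_loci(read, ref, rate):
    """Oracle: all (diagonal, strand) placements where the full read aligns
    with at most floor(rate*len) mismatches."""
    out = set()
    n, m = len(ref), len(read)
    budget = int(rate * m)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    for strand, q in (("+", read), ("-", reverse_complement(read))):
        q_arr = np.frombuffer(q.encode(), dtype=np.uint8)
        for pos in range(n - m + 1):
            if int((q_arr != ref_arr[pos : pos + m]).sum()) <= budget:
                out.add((pos, strand))
    return out


def test_mapper_matches_exhaustive_scan_oracle():
    """Reported loci equal a brute-force scan of every reference offset at
    the same mismatch threshold, for reads placed with ≤ budget mismatches."""
    rng = np.random.default_rng(44)
    g = random_genome(rng, n=50_000)
    ref = g.sequences["ref"]
    idx = build_seed_index(g)
    rate = 0.04
    for trial in range(100):
        start = int(rng.integers(0, len(ref) - 150))
        read = list(ref[start : start + 150])
        n_mm = int(rng.integers(0, 6))  # ≤ 5 < budget 6, never edge-trimmed away
        for pos in rng.choice(150, size=n_mm, replace=False):
            choices = [b for b in "ACGT" if b != read[pos]]
            read[pos] = choices[int(rng.integers(3))]
        read = "".join(read)
        if trial % 2:
            read = reverse_complement(read)
        # compare loci as (diagonal, strand): local alignment may trim an
        # edge mismatch off the segment, but the placement is identical
        got = set()
        for s in map_sequence(read, idx, rate, report="all"):
            diag = (
                s.ref_start - s.read_start
                if s.strand == "+"
                else s.ref_start - (len(read) - s.read_end)
            )
            got.add((diag, s.strand))
        assert got == exhaustive_loci(read, ref, rate)


def test_unrelated_read_is_unaligned():
    rng = np.random.default_rng(45)
    g = random_genome(rng, n=30_000)
    idx = build_seed_index(g)
    other = "".join(np.random.default_rng(46).choice(list("ACGT"), size=150))
    assert map_sequence(other, idx) == []


def test_chimeric_read_split_into_two_segments():
    """70 bp host + CATG + 76 bp transgene: no near-full-length alignment in
    pass 1; pass 2 yields adjacent segments on the two references."""
    rng = np.random.default_rng(47)
    host = random_genome(rng, "chr5", 40_000)
    tg = random_genome(rng, "transgene", 5_000)
    h_idx, t_idx = build_seed_index(host), build_seed_index(tg)
    left = host.sequences["chr5"][10_000:10_066] + "CATG"
    right = tg.sequences["transgene"][2_000:2_076]
    read = left + right
    segs = tla_two_step_map([("chimera", read)], h_idx, t_idx)
    refs = {s.reference_id for s in segs}
    assert refs == {"chr5", "transgene"}
    split = [s for s in segs if s.pass_label == "split_pass"]
    assert split, "in-silico digestion must contribute split-pass segments"
    host_seg = max((s for s in segs if s.reference_id == "chr5"), key=lambda s: s.length)
    tg_seg = max((s for s in segs if s.reference_id == "transgene"), key=lambda s: s.length)
    assert abs(tg_seg.read_start - host_seg.read_end) <= 5
    # host side ends at/near the CATG cut (chance matches may creep ±few bp)
    assert 64 <= host_seg.read_end <= 70
    assert tg_seg.read_start == 70
    # no pass-1 segment covers >=80% of the read
    assert all(
        s.length < 0.8 * len(read) for s in segs if s.pass_label == "primary_pass"
    )


def test_pure_host_read_stays_primary_pass():
    rng = np.random.default_rng(48)
    host = random_genome(rng, "chr5", 40_000)
    tg = random_genome(rng, "transgene", 5_000)
    h_idx, t_idx = build_seed_index(host), build_seed_index(tg)
    read = host.sequences["chr5"][5_000:5_150]
    segs = tla_two_step_map([("r1", read)], h_idx, t_idx)
    assert len(segs) == 1
    assert segs[0].pass_label == "primary_pass"
    assert segs[0].reference_id == "chr5"


def test_empty_read_set_gives_empty_output():
    rng = np.random.default_rng(49)
    host = random_genome(rng, "chr5", 30_000)
    tg = random_genome(rng, "transgene", 5_000)
    assert tla_two_step_map([], build_seed_index(host), build_seed_index(tg)) == []


def test_single_reference_reads_map_correctly(sim):
    """≥99% of reads whose true origin is one reference get a correct
    primary-pass segment (simulator provenance as truth)."""
    L = len(sim.construct.sequence)
    allele_ref = f"{sim.event.chromosome}_tg"
    by_read = {}
    for s in sim.segments:
        by_read.setdefault(s.read_id, []).append(s)
    total = correct = 0
    for read in sim.readset.reads:
        kind = classify_read(read, sim.truth, L, allele_ref)
        if kind not in ("host", "transgene"):
            continue
        if len(read.pieces) > 1:
            continue  # single contiguous origin only
        total += 1
        rid = f"{read.read_id}/{read.mate}"
        want_ref = "transgene" if kind == "transgene" else None
        for s in by_read.get(rid, []):
            if s.pass_label != "primary_pass":
                continue
            if kind == "transgene" and s.reference_id == "transgene":
                correct += 1
                break
            if kind == "host" and s.reference_id != "transgene":
                p = read.pieces[0]
                # host piece is in allele coordinates; map to host coords
                ev = sim.event
                if p.start < sim.truth.left_junction:
                    host_start = p.start
                else:
                    host_start = p.start - sim.truth.right_junction + ev.deletion_end
                if s.reference_id == p.source_ref.replace("_tg", "") and (
                    abs(s.ref_start - host_start) <= 5 or p.source_ref != allele_ref
                ):
                    correct += 1
                    break
    assert total > 1_000
    assert correct / total >= 0.99


def test_segment_bounds_and_split_non_overlap(sim):
    refs = {**{n: len(s) for n, s in sim.host.sequences.items()},
            "transgene": len(sim.construct.sequence)}
    by_read = {}
    for s in sim.segments:
        assert 0 <= s.ref_start < s.ref_end <= refs[s.reference_id]
        assert 0 <= s.read_start < s.read_end
        by_read.setdefault((s.read_id, s.pass_label), []).append(s)
    for (rid, label), segs in by_read.items():
        if label != "split_pass":
            continue
        segs = sorted(segs, key=lambda s: s.read_start)
        for a, b in zip(segs, segs[1:]):
            if (a.read_start, a.read_end) == (b.read_start, b.read_end):
                continue  # ambiguous multi-hits of one sub-read
            assert a.read_end <= b.read_start + 5


def test_sam_round_trip(tmp_path, sim):
    path = tmp_path / "out.sam"
    subset = sim.segments[:500]
    read_seqs = dict(sim.reads)
    refs = {**{n: len(s) for n, s in sim.host.sequences.items()},
            "transgene": len(sim.construct.sequence)}
    write_sam(subset, refs, read_seqs, path)
    back = read_sam_segments(path)
    assert len(back) == len(subset)
    for orig, rt in zip(
        sorted(subset, key=lambda s: (s.read_id, s.reference_id, s.ref_start)),
        sorted(back, key=lambda s: (s.read_id, s.reference_id, s.ref_start)),
    ):
        assert (orig.read_id, orig.reference_id, orig.ref_start, orig.ref_end,
                orig.strand, orig.mismatches, orig.pass_label, orig.ambiguous) == (
            rt.read_id, rt.reference_id, rt.ref_start, rt.ref_end,
            rt.strand, rt.mismatches, rt.pass_label, rt.ambiguous)
        assert (orig.read_start, orig.read_end) == (rt.read_start, rt.read_end)


def test_sam_parses_with_pysam(tmp_path, sim):
    pysam = pytest.importorskip("pysam")
    path = tmp_path / "out.sam"
    refs = {**{n: len(s) for n, s in sim.host.sequences.items()},
            "transgene": len(sim.construct.sequence)}
    write_sam(sim.segments[:200], refs, dict(sim.reads), path)
    with pysam.AlignmentFile(str(path), "r") as fh:
        n = sum(1 for _ in fh)
    assert n == 200
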