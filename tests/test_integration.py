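"""Fusion evidence, breakpoint calling, deletion, copies, junctions, genes."""

import numpy as np
import pytest

from tlamap.genome import GenomeSpec, generate_genome
from tlamap.integration import (
    FusionEvidence,
    GeneModel,
    IntegrationCall,
    JunctionNotReconstructableError,
    OneSidedSupportError,
    annotate_gene_disruption,
    call_deletion,
    call_integration_site,
    collect_fusion_evidence,
    coverage_from_segments,
    deletion_metrics,
    estimate_tandem_copy_number,
    gene_models_from_genome,
    read_gff3_genes,
    reconstruct_junctions,
    write_gff3_genes,
)
from tlamap.mapping import AlignmentSegment


def seg(read_id, rs, re_, ref, fs, strand="+", **kw):
    return AlignmentSegment(read_id, rs, re_, ref, fs, fs + (re_ - rs), strand, 0, **kw)


TG_LEN = 4_500


def test_adjacent_split_segments_give_base_exact_evidence():
    segs = [
        seg("r1", 0, 70, "chr5", 99_930),
        seg("r1", 70, 150, "transgene", 0),
    ]
    (ev,) = collect_fusion_evidence(segs, TG_LEN)
    assert ev.base_exact and ev.at_cassette_edge
    assert ev.junction_kind == "host_to_transgene_5prime"
    assert ev.host_boundary == 100_000
    assert ev.tg_boundary == 0


def test_host_only_read_yields_no_evidence():
    segs = [seg("r1", 0, 150, "chr5", 5_000)]
    assert collect_fusion_evidence(segs, TG_LEN) == []


def test_ambiguous_segments_are_ignored():
    segs = [
        seg("r1", 0, 70, "chr5", 99_930, ambiguous=True),
        seg("r1", 70, 150, "transgene", 0),
    ]
    assert collect_fusion_evidence(segs, TG_LEN) == []


def test_mid_cassette_adjacency_is_not_edge_evidence():
    """A ligation junction touching the transgene mid-sequence is recorded
    but flagged as non-edge, and excluded from breakpoint calling."""
    segs = [
        seg("r1", 0, 70, "chr5", 50_000),
        seg("r1", 70, 150, "transgene", 2_000),
    ]
    (ev,) = collect_fusion_evidence(segs, TG_LEN)
    assert ev.base_exact and not ev.at_cassette_edge


def make_junction_evidence(n_left=5, n_right=5, chrom="chr5",
                           left=112_500, right=157_500):
    out = []
    for i in range(n_left):
        out.append(collect_fusion_evidence(
            [seg(f"l{i}", 0, 70, chrom, left - 70),
             seg(f"l{i}", 70, 150, "transgene", 0)], TG_LEN)[0])
    for i in range(n_right):
        out.append(collect_fusion_evidence(
            [seg(f"r{i}", 0, 70, "transgene", TG_LEN - 70),
             seg(f"r{i}", 70, 150, chrom, right)], TG_LEN)[0])
    return out


def test_call_integration_site_from_constructed_evidence():
    ev = make_junction_evidence()
    call = call_integration_site(ev)
    assert call.chromosome == "chr5"
    assert (call.left_breakpoint, call.right_breakpoint) == (112_501, 157_501)
    assert call.interval0 == (112_500, 157_500)
    assert (call.support_left, call.support_right) == (5, 5)


def test_one_sided_support_is_typed_failure():
    ev = make_junction_evidence(n_left=5, n_right=0)
    with pytest.raises(OneSidedSupportError, match="one-sided"):
        call_integration_site(ev)
    ev = make_junction_evidence(n_left=5, n_right=2)
    with pytest.raises(OneSidedSupportError, match="insufficient"):
        call_integration_site(ev, min_support=3)


def test_deletion_metrics_and_call():
    assert deletion_metrics(101, 201) == (100, "0 kb")
    assert deletion_metrics(1_001, 45_001) == (44_000, "44 kb")
    call = IntegrationCall("chr5", 112_501, 157_501, 5, 5)
    cov = np.ones(300_000)
    cov[112_500:157_500] = 0.01
    call_deletion(call, cov)
    assert call.deletion_length_bp == 45_000
    assert call.deletion_kb == "45 kb"
    assert call.deletion_confirmed is True
    # flat coverage refutes the deletion but keeps the interval
    call2 = IntegrationCall("chr5", 112_501, 157_501, 5, 5)
    call_deletion(call2, np.ones(300_000))
    assert call2.deletion_confirmed is False
    assert call2.deletion_interval == (112_500, 157_500)


def test_zero_width_deletion_skips_confirmation():
    call = IntegrationCall("chr5", 1_000, 1_000, 5, 5)
    call_deletion(call, np.ones(10_000))
    assert call.deletion_length_bp == 0
    assert call.deletion_confirmed is None


def test_coverage_from_segments():
    segs = [seg("a", 0, 100, "chr1", 10), seg("b", 0, 50, "chr1", 60)]
    cov = coverage_from_segments(segs, "chr1", 200)
    assert cov[9] == 0 and cov[10] == 1 and cov[60] == 2 and cov[110] == 0


def self_junction_evidence(n, lo=0, hi=TG_LEN):
    out = []
    for i in range(n):
        segs = [
            seg(f"s{i}", 0, 70, "transgene", hi - 70),
            seg(f"s{i}", 70, 150, "transgene", lo),
        ]
        out.extend(collect_fusion_evidence(segs, TG_LEN))
    return out


def test_copy_number_estimation():
    base = IntegrationCall("chr5", 100, 200, 5, 5)
    # no self-junction evidence → single copy, not a lower bound
    call = estimate_tandem_copy_number([], base)
    assert (call.copies_estimate, call.copies_is_lower_bound) == (1, False)
    # one self-junction cluster → 2 copies, flagged lower bound (3 tandem
    # copies produce the identical junction and are indistinguishable)
    ev = self_junction_evidence(4)
    assert all(e.junction_kind == "transgene_self" for e in ev)
    call = estimate_tandem_copy_number(ev, IntegrationCall("chr5", 100, 200, 5, 5))
    assert (call.copies_estimate, call.copies_is_lower_bound) == (2, True)
    assert call.copies_support == 4


def test_internal_transgene_split_is_not_self_junction():
    """A read split inside one cassette copy (continuous transgene coords)
    must not be mistaken for a tandem junction."""
    segs = [
        seg("x", 0, 70, "transgene", 1_000),
        seg("x", 70, 150, "transgene", 1_070),
    ]
    assert all(
        e.junction_kind != "transgene_self"
        for e in collect_fusion_evidence(segs, TG_LEN)
    )


# ---------------------------------------------------------------------------
# junction consensus

def test_single_read_consensus_is_that_read():
    rng = np.random.default_rng(3)
    host_flank = "".join(rng.choice(list("ACGT"), 70))
    tg_flank = "".join(rng.choice(list("ACGT"), 80))
    left_read = host_flank + tg_flank
    right_read = "".join(rng.choice(list("ACGT"), 150))
    segs = [
        seg("L1", 0, 70, "chr5", 112_430),
        seg("L1", 70, 150, "transgene", 0),
    ]
    ev = collect_fusion_evidence(segs, TG_LEN)
    ev += make_junction_evidence(n_left=0, n_right=3)
    call = call_integration_site(ev, min_support=1)
    with pytest.raises(JunctionNotReconstructableError):
        # the right-junction reads carry no sequence to vote with
        reconstruct_junctions({"L1": left_read}, ev, call, flank=30)
    reads = {"L1": left_read, **{f"r{i}": right_read for i in range(3)}}
    junctions = reconstruct_junctions(reads, ev, call, flank=30)
    left = junctions[0]
    assert left.supporting_reads == 1
    assert left.consensus == host_flank[-30:].lower() + tg_flank[:30].upper()
    assert left.host_part_length == 30 and left.transgene_part_length == 30
    right = junctions[1]
    assert right.supporting_reads == 3
    assert right.consensus == right_read[40:70].upper() + right_read[70:100].lower()


def test_junction_consensus_on_simulated_run(sim):
    """Error-free simulation: consensus equals the true allele sequence
    around each junction, host part lowercase / transgene part uppercase."""
    from tlamap.integration import collect_fusion_evidence as cfe

    L = len(sim.construct.sequence)
    evidence = cfe(sim.segments, L)
    call = call_integration_site(evidence)
    reads = dict(sim.reads)
    junctions = reconstruct_junctions(reads, evidence, call)
    allele_seq = sim.allele.sequences[f"{sim.event.chromosome}_tg"]
    lj, rj = sim.truth.left_junction, sim.truth.right_junction
    expected = {
        allele_seq[lj - 30 : lj + 30].upper(),
        allele_seq[rj - 30 : rj + 30].upper(),
    }
    got = {j.consensus.upper() for j in junctions}
    assert got == expected
    for j in junctions:
        assert j.supporting_reads >= 3
        # case encodes origin: exactly one case switch at the junction
        host_part = j.consensus[:30] if j.consensus[0].islower() else j.consensus[30:]
        assert host_part.islower()


# ---------------------------------------------------------------------------
# gene disruption

def models():
    return [
        GeneModel("inside", "chr5", 120_000, 130_000, "+",
                  ((120_000, 121_000), (129_000, 130_000))),
        GeneModel("straddler", "chr5", 150_000, 170_000, "+",
                  ((150_000, 151_000), (153_000, 154_000),
                   (160_000, 161_000), (169_000, 170_000))),
        GeneModel("outside", "chr5", 200_000, 210_000, "+",
                  ((200_000, 210_000),)),
        GeneModel("other_chrom", "chr8", 120_000, 130_000, "+",
                  ((120_000, 130_000),)),
    ]


def test_gene_disruption_classification():
    call = IntegrationCall("chr5", 112_501, 157_501, 5, 5)
    impacts = {g.gene_name: g for g in annotate_gene_disruption(call, models())}
    assert impacts["inside"].impact == "complete_deletion"
    assert impacts["straddler"].impact == "partial_deletion"
    assert impacts["straddler"].detail == "insertion between exon 2 and exon 3"
    assert impacts["outside"].impact == "unaffected"
    assert impacts["other_chrom"].impact == "unaffected"


def test_gene_equal_to_deletion_is_complete_deletion():
    call = IntegrationCall("chr5", 120_001, 130_001, 5, 5)
    gm = [GeneModel("exact", "chr5", 120_000, 130_000, "+", ((120_000, 130_000),))]
    (impact,) = annotate_gene_disruption(call, gm)
    assert impact.impact == "complete_deletion"


def test_intronic_insertion_for_zero_width_event():
    call = IntegrationCall("chr5", 155_001, 155_001, 5, 5)  # inside intron 2
    impacts = {g.gene_name: g for g in annotate_gene_disruption(call, models())}
    assert impacts["straddler"].impact == "intronic_insertion"
    assert impacts["straddler"].detail == "insertion between exon 2 and exon 3"
    assert impacts["inside"].impact == "unaffected"


def test_gene_disruption_is_order_invariant():
    call = IntegrationCall("chr5", 112_501, 157_501, 5, 5)
    a = annotate_gene_disruption(call, models())
    b = annotate_gene_disruption(call, list(reversed(models())))
    assert a == b


def test_malformed_gene_model_rejected():
    with pytest.raises(ValueError, match="outside gene body"):
        GeneModel("bad", "chr5", 100, 200, "+", ((50, 150),))


def test_gene_models_from_synthetic_genome_and_gff_round_trip(tmp_path):
    g = generate_genome(GenomeSpec(seed=5))
    gm = gene_models_from_genome(g)
    names = {m.name for m in gm}
    assert names == {"GeneA", "GeneB"}
    gene_a = next(m for m in gm if m.name == "GeneA")
    assert len(gene_a.exons) == 4
    path = tmp_path / "genes.gff3"
    write_gff3_genes(gm, path)
    back = read_gff3_genes(path)
    assert sorted((m.name, m.start, m.end, m.exons) for m in back) == sorted(
        (m.name, m.start, m.end, m.exons) for m in gm
    )


def test_end_to_end_call_on_simulated_run(sim):
    """Integration call on the default simulation equals the ground truth."""
    L = len(sim.construct.sequence)
    evidence = collect_fusion_evidence(sim.segments, L)
    call = call_integration_site(evidence)
    assert call.chromosome == sim.event.chromosome
    assert call.interval0 == (sim.event.deletion_start, sim.event.deletion_end)
    cov = coverage_from_segments(
        sim.segments, call.chromosome, len(sim.host.sequences[call.chromosome])
    )
    call_deletion(call, cov)
    assert call.deletion_confirmed is True
    estimate_tandem_copy_number(evidence, call)
    assert call.copies_estimate == sim.event.copies == 1
    assert call.copies_support == 0  # single copy: no self-junction reads
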