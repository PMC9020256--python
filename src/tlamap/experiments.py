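"""Reproducible validation experiments built from the library primitives.

These drive the package end to end on batches of simulated ground truths and
measure how well it recovers them: breakpoint recovery across varied
integration events, genotype round trips across random loci, the value of
the second (split) mapping pass for junction-spanning reads, and the
calibration of the segregation statistics. They are used both by the test
suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import genotyping, integration, mapping, simulate
from .genome import (
    AlleleTruth,
    Genome,
    GenomeSpec,
    IntegrationEvent,
    TransgeneConstruct,
    build_transgenic_allele,
    generate_genome,
    make_transgene,
)


@dataclass
class ExperimentRun:
    """One simulated TLA experiment: inputs, ground truth, and alignments."""

    host: Genome
    construct: TransgeneConstruct
    event: IntegrationEvent
    allele: Genome
    truth: AlleleTruth
    readset: simulate.SimulatedReadSet
    host_index: mapping.SeedIndex
    tg_index: mapping.SeedIndex
    reads: list[tuple[str, str]] = field(default_factory=list)
    segments: list[mapping.AlignmentSegment] = field(default_factory=list)


def simulate_and_map(
    seed: int,
    chrom_len: int = 300_000,
    window_width: int | None = None,
    copies: int = 1,
    orientation: str = "forward",
    zero_width: bool = False,
    read_pairs: int = 6_000,
    error_rate: float = 0.0,
) -> ExperimentRun:
    """Build a ground-truth integration, simulate its TLA library, and map it."""
    spec = GenomeSpec(("chr5", "chr8"), (chrom_len, 120_000), 0.42, seed,
                      window_width)
    host = generate_genome(spec)
    construct = make_transgene(seed=seed + 1)
    window = next(host.features(kind="region"))
    ds, de = window.start, (window.start if zero_width else window.end)
    event = IntegrationEvent(window.chromosome, ds, de, copies, orientation)
    allele, truth = build_transgenic_allele(host, construct, event)
    primers = simulate.default_viewpoint_primers(allele, "cre")
    params = simulate.TLAParams(
        viewpoint_primers=primers, read_pairs=read_pairs,
        substitution_error_rate=error_rate, seed=seed + 2,
    )
    readset = simulate.simulate_tla_reads(allele, params)
    host_index = mapping.build_seed_index(host)
    tg_index = mapping.build_seed_index(Genome({"transgene": construct.sequence}))
    reads = [(f"{r.read_id}/{r.mate}", r.sequence) for r in readset.reads]
    segments = mapping.tla_two_step_map(reads, host_index, tg_index)
    return ExperimentRun(host, construct, event, allele, truth, readset,
                         host_index, tg_index, reads, segments)


@dataclass
class RecoveryResult:
    seed: int
    chrom_len: int
    deletion_len: int
    copies: int
    orientation: str
    called: bool
    exact: bool
    gene_impacts_ok: bool | None   # None for zero-width events (no deletion)
    copies_ok: bool | None
    error: str = ""


def run_single_event(seed: int, **kwargs) -> RecoveryResult:
    """Simulate one integration event and try to recover it end to end."""
    run = simulate_and_map(seed, **kwargs)
    event = run.event
    ds, de = event.deletion_start, event.deletion_end
    evidence = integration.collect_fusion_evidence(
        run.segments, len(run.construct.sequence)
    )
    result = RecoveryResult(
        seed, len(run.host.sequences[event.chromosome]), de - ds,
        event.copies, event.orientation,
        called=False, exact=False, gene_impacts_ok=None, copies_ok=None,
    )
    try:
        call = integration.call_integration_site(evidence)
    except integration.IntegrationError as exc:
        result.error = str(exc)
        return result
    result.called = True
    result.exact = (
        call.interval0 == (ds, de) and call.chromosome == event.chromosome
    )
    integration.estimate_tandem_copy_number(evidence, call)
    # three or more tandem copies collapse to the same self-junction
    result.copies_ok = call.copies_estimate == min(event.copies, 2)
    if de > ds:
        impacts = {
            g.gene_name: g
            for g in integration.annotate_gene_disruption(
                call, integration.gene_models_from_genome(run.host)
            )
        }
        result.gene_impacts_ok = (
            impacts["GeneB"].impact == "complete_deletion"
            and impacts["GeneA"].impact == "partial_deletion"
            and impacts["GeneA"].detail == "insertion between exon 2 and exon 3"
        )
    return result


#: The 20-event layout grid: chromosome size, deletion width (None → the
#: genome default, 15% of the chromosome capped at 50 kb), tandem copies,
#: cassette orientation, and pure-insertion events.
RECOVERY_LAYOUTS = [
    (240_000, None, 1, "forward", False),
    (300_000, None, 1, "reverse", False),
    (300_000, None, 2, "forward", False),
    (360_000, None, 1, "forward", False),
    (300_000, 8_000, 1, "reverse", False),
    (500_000, None, 2, "reverse", False),
    (700_000, 95_000, 1, "forward", False),
    (300_000, None, 1, "forward", True),    # pure insertion, 0 bp deletion
    (240_000, None, 2, "reverse", False),
    (360_000, 20_000, 1, "forward", False),
]


def breakpoint_recovery_experiment(
    base_seed: int = 300,
    n_events: int = 20,
    error_rate: float = 0.0,
) -> list[RecoveryResult]:
    """≥20 integration events varying chromosome size, deletion width
    (0–95 kb, including pure insertions), tandem copies and orientation."""
    out = []
    for i in range(n_events):
        chrom_len, width, copies, orientation, zero = RECOVERY_LAYOUTS[
            i % len(RECOVERY_LAYOUTS)
        ]
        # depth sized per target: junction-spanning coverage scales inversely
        # with the number of competing restriction fragments, so the library
        # grows proportionally with the chromosome
        read_pairs = round(6_000 * chrom_len / 300_000)
        out.append(
            run_single_event(
                base_seed + 13 * i, chrom_len=chrom_len, window_width=width,
                copies=copies, orientation=orientation, zero_width=zero,
                error_rate=error_rate, read_pairs=read_pairs,
            )
        )
    return out


def genotyping_round_trip_experiment(
    base_seed: int = 900, n_loci: int = 50
) -> tuple[int, int]:
    """Design an assay for each random synthetic locus and genotype the three
    diploid allele pairs in silico. Returns (correct, total) genotype calls."""
    correct = total = 0
    for i in range(n_loci):
        seed = base_seed + 7 * i
        host = generate_genome(GenomeSpec(("chr5",), (120_000,), 0.42, seed))
        construct = make_transgene(seed=seed + 1)
        window = next(host.features(kind="region"))
        event = IntegrationEvent(window.chromosome, window.start, window.end)
        allele, _ = build_transgenic_allele(host, construct, event)
        wt = host.sequences["chr5"]
        tg = allele.sequences["chr5_tg"]
        call = integration.IntegrationCall(
            "chr5", event.deletion_start + 1, event.deletion_end + 1, 5, 5
        )
        assay = genotyping.design_three_primer_assay(wt, tg, call)
        for pair, expected in (((wt, wt), "WT"), ((wt, tg), "HET"),
                               ((tg, tg), "HOM")):
            total += 1
            correct += genotyping.genotype_allele_pair(pair, assay) == expected
    return correct, total


def junction_mappability_experiment(run: ExperimentRun, min_flank: int = 40) -> dict:
    """How junction-spanning reads fare in the two mapping passes.

    A read counts as junction-spanning when its true content includes at
    least ``min_flank`` bp of both host and transgene sequence across the
    integration junction — enough flank to anchor an alignment on each side.
    Measures (a) the fraction of such reads without a near-full-length
    pass-1 alignment (hence routed to in-silico digestion and remapping) and
    (b) the fraction ending up with correct dual-reference split segments.
    """
    L = len(run.construct.sequence)
    allele_ref = f"{run.event.chromosome}_tg"

    def flanks(read):
        host_bp = tg_bp = 0
        crosses = False
        for p in read.pieces:
            if p.source_ref != allele_ref:
                return 0, 0, False
            parts = simulate.project_allele_interval(run.truth, L, p.start, p.end)
            for ref, s, e, _ in parts:
                if ref == "transgene":
                    tg_bp += e - s
                else:
                    host_bp += e - s
            if len(parts) > 1:
                crosses = True
        return host_bp, tg_bp, crosses

    by_read: dict[str, list] = {}
    for s in run.segments:
        by_read.setdefault(s.read_id, []).append(s)

    n_spanning = n_routed = n_rescued = 0
    covered = mapping.DEFAULT_COVERED_FRACTION
    for read in run.readset.reads:
        host_bp, tg_bp, crosses = flanks(read)
        if not crosses or host_bp < min_flank or tg_bp < min_flank:
            continue
        n_spanning += 1
        rid = f"{read.read_id}/{read.mate}"
        segs = by_read.get(rid, [])
        pass1 = [s for s in segs if s.pass_label == "primary_pass"]
        routed = not any(s.length >= covered * len(read.sequence) for s in pass1)
        n_routed += routed
        refs = {("transgene" if s.reference_id == "transgene" else "host")
                for s in segs}
        n_rescued += routed and refs >= {"host", "transgene"}
    return {
        "n_junction_spanning": n_spanning,
        "n_routed_to_split_pass": n_routed,
        "n_rescued_dual_reference": n_rescued,
    }


def segregation_calibration_experiment(
    seed: int = 0, n_mc: int = 2_000, n_offspring: int = 68, alpha: float = 0.05
) -> dict:
    """Monte-Carlo calibration of the segregation tests.

    Under the 2:1 survivor model (homozygotes die), measures the exact
    binomial test's rejection rate at ``alpha`` and compares it with the
    test's analytic size (the null rejection probability, computed by
    summing the binomial pmf over the rejection region — for a discrete
    exact test this sits at or below the nominal level). Under full 1:2:1
    viability, measures the frequency of zero homozygotes against (3/4)^n.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_mc):
        counts = genotyping.simulate_het_cross(n_offspring, True, rng)
        res = genotyping.segregation_tests(counts)
        rejections += res.exact_binomial_p_het_vs_wt < alpha
    # analytic size of the minlike exact test at p0 = 2/3: sum the null pmf
    # over the region where the (independently recomputed) p-value < alpha
    pmf = stats.binom.pmf(np.arange(n_offspring + 1), n_offspring, 2 / 3)
    pvals = np.array([
        pmf[pmf <= pmf[k] * (1 + 1e-12)].sum() for k in range(n_offspring + 1)
    ])
    analytic_region = pvals < alpha
    analytic_size = float(pmf[analytic_region].sum())
    # exact cross-check: the implementation's rejection region must equal
    # the analytic one at every possible count — calibration with zero slack
    impl_region = np.array([
        stats.binomtest(k, n_offspring, 2 / 3).pvalue < alpha
        for k in range(n_offspring + 1)
    ])
    region_matches = bool((impl_region == analytic_region).all())
    # two-sided exact consistency of the MC count with Binomial(n_mc, size)
    mc_consistency_p = float(
        stats.binomtest(rejections, n_mc, analytic_size).pvalue
    )

    zero_hom = 0
    for _ in range(n_mc):
        counts = genotyping.simulate_het_cross(n_offspring, False, rng)
        zero_hom += counts.n_hom == 0
    return {
        "n_mc": n_mc,
        "rejection_rate": rejections / n_mc,
        "analytic_size": analytic_size,
        "region_matches_analytic": region_matches,
        "mc_consistency_p": mc_consistency_p,
        "nominal_alpha": alpha,
        "zero_hom_frequency": zero_hom / n_mc,
        "zero_hom_closed_form": 0.75 ** n_offspring,
    }
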