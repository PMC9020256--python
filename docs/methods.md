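# Methods

`tlamap` re-creates, on fully synthetic data, the computational arc of a
targeted locus amplification (TLA) study of a transgenic mouse line: locate
a randomly integrated transgene, characterise the host deletion it caused,
reconstruct the junction sequences, derive a genotyping assay from them, and
make the segregation-ratio lethality argument explicit. This note documents
the models, the parameters that matter, the numerical conventions, and what
the synthetic data can and cannot show.

## The TLA library model

TLA crosslinks chromatin, digests it with NlaIII (CATG), ligates spatially
proximal fragments into circles, and amplifies each circle by inverse PCR
from a primer pair (the *viewpoint*) inside the locus of interest — here,
inside the Cre element of the transgene cassette. Because the sample is
trimmed with NspI (RCATGY, a superset of CATG) before circularisation, only
a subset of NlaIII sites end up cut and the effective restriction fragments
are roughly 2 kb.

The simulator (`tlamap.simulate`) models this as:

* **Partial digestion** — every NlaIII cut is retained independently with
  probability `partial_digestion_keep_prob`. By default the probability is
  calibrated at start-up from the input sequence so the expected fragment
  length equals `target_fragment_len` (2,000 bp): `keep = (len / target) /
  n_sites`, clamped to (0, 1]. The cut is placed immediately after the last
  base of the motif, so the motif stays with the upstream fragment; the same
  convention is used for digestion, read splitting and site reporting.
  The fragment containing both viewpoint primers is kept intact (inverse PCR
  requires it), merging across any retained cut inside it.
* **Contact decay** — each circle contains the viewpoint fragment plus
  `fragments_per_circle` (uniform in [3, 8]) fragments drawn without
  replacement with probability proportional to `(1 + d/d0)^(-alpha)` of
  their distance `d` from the viewpoint (defaults `alpha = 1.0`,
  `d0 = 20 kb`, a standard proximity-ligation contact law; the source
  protocol states no law, only the outcome). Each non-viewpoint fragment is
  independently replaced by a random fragment from another chromosome with
  probability `trans_ligation_rate` (default 0.01) and flipped in
  orientation with probability 1/2.
* **Read sampling** — circles are linearised at the viewpoint and 2×150 bp
  read pairs (insert 320 bp) are sampled uniformly along the molecule, so a
  predictable fraction cross ligation junctions. Substitution errors are
  applied per base at `substitution_error_rate`; indels, quality decay, PCR
  duplicates and chimeric artifacts are not modelled. Mates are written as
  R1/R2 FASTQ but all downstream analysis treats them as independent
  single-end reads, because circularisation destroys pairing geometry.
* **Ground truth** — every read carries provenance (which allele intervals
  it covers, on which strand), serialised as a TSV that round-trips
  losslessly. All outputs are pure functions of (inputs, seed).

**Library depth.** The default is 6,000 read pairs for a 300 kb target
chromosome. A read is junction-informative only if it crosses the
integration junction — a ~150 bp window inside ~10 kb circles that contain
the junction fragment ~10% of the time — so 12,000 reads yield roughly
10–20 base-exact junction reads per side, comfortably above the
`min_support = 3` calling threshold. Experiments on larger chromosomes scale
the depth proportionally (`read_pairs = 6000 × len / 300 kb`), the same
per-target sizing rule.

## The synthetic host locus

`generate_genome` plants a deletion window (15% of the chromosome, capped at
50 kb, or `window_width`) centred at 45% of the first chromosome, with two
genes: **GeneB** entirely inside the window (single exon span) and
**GeneA** (4 exons) starting inside the window and extending past its right
edge, with the edge falling in the intron between exons 2 and 3. An
integration that deletes the window therefore removes GeneB completely,
truncates GeneA, and leaves the insertion point intronic between GeneA's
exons 2 and 3 — the configuration the pipeline must rediscover from reads
alone. Sequences are i.i.d. with GC 0.42 (mouse-like); no repeats, so
mapping ambiguity is rare by construction (see *Limitations*).

The transgene is a ~4.5 kb cassette of five elements
(promoter–Cre–ires–EGFP–3′ regulatory region) tiling the construct.
`build_transgenic_allele` splices `copies` tandem head-to-tail cassettes
(optionally reverse-complemented) in place of the deleted interval, lifts
all annotations, and records the true junction coordinates.

## Mapping

The mapper is a deterministic seed-and-extend local aligner: exact 21-mer
seeds on both strands propose diagonals; on each diagonal the best-scoring
contiguous stretch (match +1, mismatch −2, Kadane's algorithm with
longest-then-leftmost tie-breaking) is reported if it contains a seed-length
run and has at most `floor(0.04 × length)` mismatches. Extension is ungapped
by design: junction detection needs split mapping, not indel alignment. A
consequence worth knowing: local alignment trims mismatches at segment
edges, so a read with an edge error maps at the same locus with a slightly
shorter segment; oracle tests therefore compare placements (diagonals), not
segment ends.

Two-step TLA mapping maps each read whole against host and transgene
jointly (greedy read-interval chaining keeps the best non-overlapping
segments, so a chimeric read yields one segment per constituent); reads
without a segment covering ≥80% of their length are digested in silico at
CATG (sub-fragments ≥20 bp) and remapped, with coordinates lifted back to
the parent read. Equally scoring multi-hits are all reported and flagged
ambiguous; ambiguous segments never count as breakpoint support. SAM output
uses soft clips, supplementary flags and SA tags; internally everything is
0-based half-open, SAM is 1-based per its specification.

## Integration calling

TLA creates base-exact host↔transgene adjacencies at *every* ligation
junction involving the viewpoint fragment, not only at the integration
junction. The discriminating property — this package's own design, since
the source describes no filter — is **where the transgene is touched**: a
genuine integration junction abuts the cassette at one of its extremities
(transgene coordinate ≈0 or ≈length), whereas ligation artifacts abut
internal restriction-fragment boundaries. Only cassette-edge-anchored,
base-exact evidence enters breakpoint clustering.

**Microhomology.** When the cassette's terminal bases happen to match the
adjacent host sequence, the host segment over-extends across the junction by
the homology length and the two segments overlap in read coordinates. The
transgene segment is clipped at the cassette edge and cannot over-extend, so
the junction is re-read at the transgene-anchored read position. Base-exact
evidence therefore tolerates read-coordinate overlaps up to 30 bp while
unexplained positive gaps must stay within `junction_slop` (5 bp). Within a
homology tract the breakpoint is intrinsically ambiguous; the cassette-edge
anchor makes the reported coordinate the one consistent with the cassette
boundary.

Breakpoints are the modal coordinates of the top-supported cluster (10 bp
greedy clustering) of each junction kind; both sides must exceed
`min_support = 3` reads and agree on a chromosome (conflicts raise a typed
"ambiguous integration" failure listing candidates; a missing side raises
"one-sided support"). Reported coordinates are 1-based: the left breakpoint
is the first deleted base, the right breakpoint the first retained base
after the deletion, so `right − left` is the deletion length and
`round(bp/1000)` its kb rendering. Feeding the published mouse chr5
coordinates (137,042,580 and 137,086,690) through this arithmetic yields
44,110 bp → "44 kb". Whether the printed coordinates include the last
deleted base is not decidable from the source text; this convention is the
one that reproduces the printed 44 kb figure exactly, and carries a ±1
ambiguity otherwise.

The deletion is **confirmed by coverage**: mean host-reference depth
strictly inside the interval must be ≤ `max_internal_ratio` (0.2) times the
mean depth in 5 kb flanks. Zero-width calls (pure insertions, left = right)
skip confirmation. **Copy number** uses transgene self-junction reads
(cassette 3′ end adjacent to cassette 5′ start): `1 + distinct self-junction
clusters`, flagged as a lower bound whenever ≥2 because identical
head-to-tail junctions collapse — depth ratios are deliberately not used,
as TLA coverage is viewpoint-biased. **Junction consensus** anchors
supporting reads at the cassette edge, orients them to the host forward
strand, and takes a per-column majority over ±30 bp (ties broken to the
lexicographically smallest base); the host part is rendered lowercase and
the transgene part uppercase, a plain-text stand-in for a colour-coded
figure. **Gene disruption** is pure interval arithmetic on WT gene models:
closed containment in the deletion → complete deletion; partial overlap →
partial deletion, with the surviving breakpoint located to an intron
("between exon i and exon i+1", transcription order) where applicable; a
zero-width insertion point inside an intron → intronic insertion (inside an
exon it is reported as a disruption with an exon detail).

## Genotyping and segregation statistics

`design_three_primer_assay` places a shared forward primer (25 nt) in host
sequence upstream of the left breakpoint, a WT-specific reverse primer
inside the deleted interval (for pure insertions: straddling the insertion
point, which the transgenic allele interrupts), and a transgene-specific
reverse primer in the cassette's 5′ region. Candidate product sizes start
at the published assay's 574/230 bp spacing and walk the allowed window
until a triple passes: unique functional binding (the transgene reverse
necessarily recurs once per tandem copy; uniqueness is enforced as exactly
one product per allele within the size window), both products inside
[120, 900] bp, and a gap ≥100 bp. Primer binding is exact-match with an
optional internal-mismatch allowance and a mandatory exact 3′ base;
melting-temperature modelling is out of scope (the published assay's 68 °C
protocol is metadata). Product size runs from the forward primer's 5′ end
to the reverse primer's 5′ end inclusive — what a gel band reports. The
published primer triple and its 574/230 bp bands ship as a reference
fixture: they were designed against the real mouse genome and cannot be
recomputed from synthetic data.

`segregation_tests` makes the lethality inference explicit for a het×het
cross: the probability of zero homozygotes among n offspring under full
1:2:1 viability is (3/4)^n (for the published 68-pup tally, 3.19×10⁻⁹); the
surviving het:WT ratio is tested against 2:1 with an exact binomial test
(two-sided by the minlike convention — the sum of point probabilities no
larger than the observed one, stated explicitly because two-sided exact
tests have competing definitions) and a Pearson chi-square (0.1176 for
44:24). The verdict is "lethality-consistent" when no homozygote was seen,
zero homozygotes would be improbable under full viability (p < alpha,
default 0.01), and the survivor ratio is compatible with 2:1.

**Calibration of the exact test.** The minlike test is discrete, so its true
size sits below the nominal level: at n = 68, p₀ = 2/3 and alpha = 0.05 the
analytic size (null pmf summed over the rejection region) is 0.0390. A
Monte-Carlo rejection rate should therefore be compared against that
analytic size, not against 0.05 — a 2σ band centred on the nominal level
fails in expectation for any correct implementation. The test suite asserts
the sharp property (the implementation's rejection region equals the
analytic region at every possible count) and checks the seeded Monte-Carlo
rate by an exact consistency test at the 0.1% level, which avoids the ~5%
intrinsic false-alarm rate a 2σ band has on any frozen seed.

## Experiment sizes and numerical conventions

* Breakpoint recovery: 20 events over a layout grid — chromosomes 240–700 kb,
  deletions 0 (pure insertion) to 95 kb, 1–2 tandem copies, both cassette
  orientations, error-free reads, depth scaled per target size. Runs in
  ~2 minutes on one CPU.
* Oracle checks: motif scan vs regex on 1,000 random sequences; mapper vs
  exhaustive alignment of every offset of a 50 kb reference for 100 reads;
  in-silico PCR vs brute-force placement enumeration on 5 kb templates.
* Genotyping round trip: 50 random loci (120 kb chromosomes), three diploid
  combinations each.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; identical config + seed reproduces byte-identical FASTQ and
  reports. Ties are always broken deterministically (lexicographic or
  leftmost-longest, as documented at each site).

## What passing on synthetic data does and does not show

The generator produces i.i.d. sequence: no repeats, no segmental
duplications, no SNPs against the reference, and uniform base quality. Exact
breakpoint recovery on such data demonstrates the pipeline's logic —
two-pass split mapping, cassette-edge evidence filtering, microhomology
anchoring, coverage confirmation — but not robustness to repetitive
integration sites, multi-site integrations (the ambiguity error path is the
only concession), indel sequencing errors, or reference divergence. Copy
number is validated only on simulation and is an honest lower bound ≥2.
The published chromosome-5 result itself is not reproducible here: it
requires the original reads and the mm10 reference, neither of which is
deposited; the paper-anchored quantities that *are* recomputed exactly are
the deletion arithmetic and the segregation statistics of the printed
offspring counts.
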