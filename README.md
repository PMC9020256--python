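# tlamap

Targeted locus amplification (TLA) analysis of transgene integration sites,
end to end on synthetic data: simulate a TLA sequencing library from a
transgenic allele, map the chimeric reads with a two-pass split-read
strategy, call the integration breakpoints and the host deletion they
flank, reconstruct the junction sequences, design a junction-aware
three-primer genotyping assay, and test offspring ratios for segregation
distortion.

## Who this is for

Transgenic mouse lines made by pronuclear microinjection carry their
cassette at an unknown genomic position, often with collateral damage to the
host locus. TLA sequencing resolves this: crosslinked DNA is digested with
NlaIII (CATG), ligated into circles, and amplified by inverse PCR from a
viewpoint inside the transgene, so everything physically linked to the
cassette gets sequenced. The motivating case is an hMRP8-Cre/ires-EGFP
line whose cassette landed in mouse chromosome 5, deleting ~44 kb of host
sequence — removing one gene entirely (*Serpine1*) and truncating its
neighbour (*Ap1s1*) intron 2, with heterozygote crosses yielding a 2:1
het:WT ratio and no homozygotes (homozygous lethality). No raw reads are
deposited for that study, so this package ships a faithful synthetic-data
generator and validates every step against simulated ground truth.

## The core quantities

* **Breakpoints** — reads crossing a host↔transgene junction fail to map
  end-to-end; after in-silico NlaIII digestion and remapping, their split
  segments abut in read coordinates and localise each junction to the base.
  The left/right breakpoints are the modal cluster coordinates of
  cassette-edge-anchored evidence; the deletion length is
  `right − left` (reported 1-based: first deleted base, first retained
  base), confirmed by the internal-vs-flank coverage ratio.
* **Copy number** — tandem head-to-tail copies reveal themselves through
  cassette-3′→cassette-5′ self-junction reads; the estimate
  `1 + #clusters` is a stated lower bound.
* **Genotyping** — one forward primer in the shared host flank, one reverse
  primer inside the deleted interval (WT allele only), one reverse primer
  inside the cassette (transgenic allele only): WT animals show one band,
  homozygotes the other, heterozygotes both.
* **Segregation** — for a het×het cross, P(zero homozygotes among n | full
  1:2:1 viability) = (3/4)^n, and the surviving het:WT counts are tested
  against 2:1 by exact binomial (minlike two-sided) and Pearson chi-square.

## Worked example

```bash
python examples/02_map_and_call_integration.py
```

prints (seed 11, 6,000 simulated read pairs on a 300 kb synthetic
chromosome):

```
truth:  chr5:112,501-157,501 (1 copy)
called: chr5:112,501-157,501 (45 kb), support 161+10 reads, deletion confirmed by coverage: True, copies: 1
junction host_to_transgene_5prime (161 reads):
  ccctcattgctttcattattctattgcacaCTAACCGATTAGACCCCTCAGTTTATGTCA
junction transgene_3prime_to_host (10 reads):
  AGGCTGGCGCAGAATCGGAGGGCAGTTCTGaaaggcgtcgaataccaaggcagcttaaag
gene GeneB: complete_deletion
gene GeneA: partial_deletion (insertion between exon 2 and exon 3)
```

The called interval equals the simulated truth exactly; the junction
consensus switches from host sequence (lowercase) to transgene sequence
(UPPERCASE) at the recovered breakpoint; the fully contained gene is
reported deleted and the straddling gene truncated, with the insertion
point located to the intron between its exons 2 and 3.

Other examples: `01_simulate_tla_library.py` (the library model and its
read classes), `03_genotyping_assay_design.py` (primer design and in-silico
PCR: a 574 bp WT band vs a 230 bp transgene band, WT/HET/HOM calls),
`04_segregation_lethality.py` (the 68-pup cross: (3/4)^68 ≈ 3.2×10⁻⁹,
chi-square 0.1176 vs 2:1, verdict "lethality-consistent"),
`05_full_pipeline.py` (one-call pipeline with persisted stage outputs).

The same stages are available as a CLI for shell use:

```bash
tlamap run-all --out out/ --seed 1
tlamap segregation-test --het 44 --wt 24 --hom 0
```

## Layout

```
src/tlamap/
  genome.py        synthetic genomes, gene models, transgenic-allele assembly
  restriction.py   IUPAC motif scan, partial digestion, read splitting
  simulate.py      TLA library simulator with per-read ground truth
  mapping.py       seed-and-extend local mapper, two-pass TLA mapping, SAM I/O
  integration.py   fusion evidence, breakpoint/deletion/copy calls, junctions,
                   gene disruption
  genotyping.py    in-silico PCR, three-primer assay design, segregation tests
  experiments.py   batched validation experiments
  pipeline.py      single-call pipeline with manifest + deterministic report
  cli.py           thin click CLI over the library
docs/methods.md    models, parameter defaults and rationale, limitations
examples/          one narrative script per capability
tests/             pytest suite (unit, property-based, acceptance)
```
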