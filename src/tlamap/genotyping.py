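"""Junction-aware three-primer genotyping and segregation-ratio statistics.

Once the integration breakpoints are known, a single PCR with three primers
distinguishes all three genotypes: a shared forward primer upstream of the
left breakpoint, one reverse primer inside the deleted host interval (binds
the wild-type allele only) and one reverse primer inside the transgene
(binds the transgenic allele only). Wild-type animals show only the WT-size
band, homozygous transgenics only the transgene-size band, heterozygotes
both.

The published assay for the MRP8-Cre/ires-EGFP line ships as a reference
fixture (:data:`PUBLISHED_ASSAY`): its primers and the 574 bp / 230 bp band
sizes were designed against the real mouse genome and cannot be recomputed
from synthetic data, so they serve as documentation and test fixtures only.

Segregation statistics make the lethality argument explicit: under a
heterozygote×heterozygote cross, offspring are 1 WT : 2 het : 1 hom; if the
homozygote is lethal, survivors are 2:1 het:WT and the probability of
observing zero homozygotes among n pups under full viability is (3/4)^n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .integration import IntegrationCall
from .restriction import reverse_complement


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not 18 <= len(self.sequence) <= 35:
            raise ValueError(
                f"primer {self.name}: length {len(self.sequence)} outside 18-35 nt"
            )
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"primer {self.name}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


#: The published genotyping assay for the MRP8-Cre/ires-EGFP line — designed
#: against the real mouse genome; reference fixture, not recomputable here.
PUBLISHED_ASSAY = {
    "forward": "AGACAGGGTAGTAGCTCTGTGTAGC",
    "reverse_wt": "GTGGAGGGACCTCAAAGTTGTCTATAAG",
    "reverse_tg": "GCTCACTGTAGCCTCGAACAC",
    "wt_amplicon_bp": 574,
    "tg_amplicon_bp": 230,
}


@dataclass
class GenotypeAssay:
    """Three-primer design with its two allele-specific amplicon sizes."""

    forward: Primer
    reverse_wt: Primer
    reverse_tg: Primer
    predicted_wt_amplicon_bp: int
    predicted_tg_amplicon_bp: int

    def __post_init__(self) -> None:
        if self.predicted_wt_amplicon_bp <= 0 or self.predicted_tg_amplicon_bp <= 0:
            raise ValueError("amplicon sizes must be positive")

    def to_dict(self) -> dict:
        return {
            "forward": self.forward.sequence,
            "reverse_wt": self.reverse_wt.sequence,
            "reverse_tg": self.reverse_tg.sequence,
            "predicted_wt_amplicon_bp": self.predicted_wt_amplicon_bp,
            "predicted_tg_amplicon_bp": self.predicted_tg_amplicon_bp,
        }


@dataclass(frozen=True)
class Amplicon:
    size: int
    forward: Primer
    reverse: Primer
    start: int    # template coord of forward primer 5' end
    end: int      # template coord one past reverse primer 5' end


class AssayDesignError(ValueError):
    """No primer triple satisfies the design constraints."""


@dataclass(frozen=True)
class AssayConstraints:
    primer_len: int = 25
    min_len: int = 120
    max_len: int = 900
    min_size_gap: int = 100
    # default target sizes follow the published assay's band spacing
    wt_target: int = 574
    tg_target: int = 230
    forward_offset: int = 60     # bp upstream of the left breakpoint

    def __post_init__(self) -> None:
        if self.max_len < self.min_len:
            raise ValueError("max_len < min_len")


# ---------------------------------------------------------------------------
# in-silico PCR

def _binding_sites(template: str, primer: Primer, max_mismatch: int) -> tuple[list[int], list[int]]:
    """(plus-strand starts, minus-strand starts) of primer binding sites.

    A plus-strand site at i means the primer matches template[i:i+len) and
    can prime rightward; a minus-strand site at j means the primer matches
    the reverse complement of template[j:j+len) and primes leftward. The
    3'-terminal base must match exactly in both cases.
    """
    p = primer.sequence
    rc = reverse_complement(p)
    n, m = len(template), len(p)
    if m > n:
        return [], []
    if max_mismatch == 0:
        plus, minus = [], []
        for hits, pat in ((plus, p), (minus, rc)):
            start = 0
            while (i := template.find(pat, start)) != -1:
                hits.append(i)
                start = i + 1
        return plus, minus
    t_arr = np.frombuffer(template.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t_arr, m)
    p_arr = np.frombuffer(p.encode(), dtype=np.uint8)
    rc_arr = np.frombuffer(rc.encode(), dtype=np.uint8)
    mm_plus = (windows != p_arr).sum(axis=1)
    mm_minus = (windows != rc_arr).sum(axis=1)
    # exact 3' base: last base for plus sites, first base for minus sites
    plus = np.where((mm_plus <= max_mismatch) & (windows[:, -1] == p_arr[-1]))[0]
    minus = np.where((mm_minus <= max_mismatch) & (windows[:, 0] == rc_arr[0]))[0]
    return [int(i) for i in plus], [int(j) for j in minus]


def insilico_pcr(
    template: str,
    primers: list[Primer],
    max_product_len: int = 2_000,
    max_mismatch: int = 0,
) -> list[Amplicon]:
    """Predict PCR products: every (forward-binding, reverse-binding) primer
    placement pair with the forward site entirely upstream and a span within
    ``max_product_len`` yields one amplicon. Size runs from the forward
    primer's 5' end to the reverse primer's 5' end inclusive — the length a
    gel band reports."""
    if not template:
        raise ValueError("template must be non-empty")
    sites = [(_binding_sites(template, p, max_mismatch), p) for p in primers]
    out = []
    for (plus_a, _), pa in sites:
        for (_, minus_b), pb in sites:
            for i in plus_a:
                for j in minus_b:
                    if i + len(pa) > j:
                        continue
                    size = j + len(pb) - i
                    if size <= max_product_len:
                        out.append(Amplicon(size, pa, pb, i, j + len(pb)))
    return sorted(out, key=lambda a: (a.start, a.end, a.forward.name, a.reverse.name))


# ---------------------------------------------------------------------------
# assay design

def _unique_plus_site(template: str, primer: Primer) -> bool:
    plus, minus = _binding_sites(template, primer, 0)
    return len(plus) + len(minus) == 1


def _count_sites(template: str, primer: Primer) -> int:
    plus, minus = _binding_sites(template, primer, 0)
    return len(plus) + len(minus)


def design_three_primer_assay(
    wt_allele: str,
    tg_allele: str,
    call: IntegrationCall,
    constraints: AssayConstraints | None = None,
) -> GenotypeAssay:
    """Design the forward + two-reverse genotyping triple around a call.

    The forward primer sits in shared host sequence upstream of the left
    breakpoint; the WT-specific reverse sits inside the deleted interval
    (or, for a zero-width deletion, across the uninterrupted host span);
    the transgene-specific reverse sits near the cassette 5' end. Predicted
    amplicon sizes come from an in-silico PCR round trip on each allele and
    must satisfy the size window and gap; each primer must bind uniquely.
    """
    c = constraints or AssayConstraints()
    l0, r0 = call.interval0
    plen = c.primer_len
    if c.max_len < c.forward_offset + 2 * plen:
        raise AssayDesignError(
            f"size window max_len={c.max_len} cannot accommodate primer spacing "
            f"(need >= {c.forward_offset + 2 * plen})"
        )
    deletion_len = r0 - l0

    def try_design(f_off: int, wt_size: int, tg_size: int) -> GenotypeAssay | None:
        f_start = l0 - f_off
        if f_start < 0 or f_start + plen > len(wt_allele):
            return None
        fwd = Primer("forward", wt_allele[f_start : f_start + plen])
        # WT-specific reverse: 5' end at f_start + wt_size - 1
        r1_end = f_start + wt_size          # one past the 5' end
        r1_start = r1_end - plen
        if r1_end > len(wt_allele) or f_start + tg_size > len(tg_allele):
            return None
        if deletion_len > 0:
            if not (l0 <= r1_start and r1_end <= r0):
                return None
        else:
            # zero-width deletion: the site must straddle the insertion point
            if not (r1_start < l0 - 3 and r1_end > l0 + 3):
                return None
        rev_wt = Primer("reverse_wt", reverse_complement(wt_allele[r1_start:r1_end]))
        # transgene-specific reverse: 5' end at tg allele f_start + tg_size - 1
        r2_end = f_start + tg_size
        r2_start = r2_end - plen
        if r2_start < l0:
            return None
        rev_tg = Primer("reverse_tg", reverse_complement(tg_allele[r2_start:r2_end]))

        # rev_tg recurs once per tandem cassette copy; that is fine as long
        # as only the first copy's site is within amplifiable range of the
        # forward primer, which the single-amplicon round-trip check below
        # enforces
        if not (
            _unique_plus_site(wt_allele, fwd)
            and _unique_plus_site(tg_allele, fwd)
            and _count_sites(wt_allele, rev_wt) == 1
            and _count_sites(tg_allele, rev_wt) == 0
            and _count_sites(tg_allele, rev_tg) >= 1
            and _count_sites(wt_allele, rev_tg) == 0
        ):
            return None
        primers = [fwd, rev_wt, rev_tg]
        wt_amps = insilico_pcr(wt_allele, primers, c.max_len)
        tg_amps = insilico_pcr(tg_allele, primers, c.max_len)
        if len(wt_amps) != 1 or len(tg_amps) != 1:
            return None
        s_wt, s_tg = wt_amps[0].size, tg_amps[0].size
        if not (c.min_len <= s_wt <= c.max_len and c.min_len <= s_tg <= c.max_len):
            return None
        if abs(s_wt - s_tg) < c.min_size_gap:
            return None
        return GenotypeAssay(fwd, rev_wt, rev_tg, s_wt, s_tg)

    wt_floor = max(c.min_len, c.forward_offset + plen)
    tg_floor = max(c.min_len, c.forward_offset + plen)
    wt_candidates = [c.wt_target] + [
        s for s in range(wt_floor, c.max_len, 17) if s != c.wt_target
    ]
    tg_candidates = [c.tg_target] + [
        s for s in range(tg_floor, c.max_len, 13) if s != c.tg_target
    ]
    for f_off in (c.forward_offset, c.forward_offset + 37, c.forward_offset + 89):
        for wt_size in wt_candidates:
            if deletion_len > 0 and wt_size - f_off > deletion_len:
                continue
            for tg_size in tg_candidates:
                if abs(wt_size - tg_size) < c.min_size_gap:
                    continue
                assay = try_design(f_off, wt_size, tg_size)
                if assay is not None:
                    return assay
    raise AssayDesignError(
        "no primer triple satisfies the constraints "
        f"(size window [{c.min_len}, {c.max_len}], gap >= {c.min_size_gap})"
    )


def call_genotype(
    band_sizes: list[int],
    assay: GenotypeAssay,
    size_tolerance: int = 10,
) -> str:
    """Interpret gel bands: {wt}→WT, {wt,tg}→HET, {tg}→HOM, else FAIL.

    Total over band multisets and invariant to band order; any unmatched
    band (or no band) fails the sample rather than guessing.
    """
    matched = set()
    for b in band_sizes:
        if abs(b - assay.predicted_wt_amplicon_bp) <= size_tolerance:
            matched.add("wt")
        elif abs(b - assay.predicted_tg_amplicon_bp) <= size_tolerance:
            matched.add("tg")
        else:
            return "FAIL"
    if matched == {"wt"}:
        return "WT"
    if matched == {"wt", "tg"}:
        return "HET"
    if matched == {"tg"}:
        return "HOM"
    return "FAIL"


def genotype_allele_pair(
    alleles: tuple[str, str],
    assay: GenotypeAssay,
    max_product_len: int = 2_000,
) -> str:
    """Run the assay in silico on a diploid pair of allele sequences."""
    primers = [assay.forward, assay.reverse_wt, assay.reverse_tg]
    bands = []
    for allele in alleles:
        bands.extend(a.size for a in insilico_pcr(allele, primers, max_product_len))
    return call_genotype(sorted(set(bands)), assay)


# ---------------------------------------------------------------------------
# segregation statistics

@dataclass(frozen=True)
class CrossCounts:
    """Genotype tallies among offspring of a het × het cross."""

    n_offspring: int
    n_het: int
    n_wt: int
    n_hom: int

    def __post_init__(self) -> None:
        if min(self.n_offspring, self.n_het, self.n_wt, self.n_hom) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_het + self.n_wt + self.n_hom != self.n_offspring:
            raise ValueError("genotype counts must sum to n_offspring")


@dataclass(frozen=True)
class RatioTestResult:
    expected_ratio_het_to_wt: str
    chi_square_statistic: float
    chi_square_p: float
    p_zero_hom_under_mendelian: float
    exact_binomial_p_het_vs_wt: float
    verdict: str

    def to_dict(self) -> dict:
        return {
            "expected_ratio_het_to_wt": self.expected_ratio_het_to_wt,
            "chi_square_statistic": self.chi_square_statistic,
            "chi_square_p": self.chi_square_p,
            "p_zero_hom_under_mendelian": self.p_zero_hom_under_mendelian,
            "exact_binomial_p_het_vs_wt": self.exact_binomial_p_het_vs_wt,
            "verdict": self.verdict,
        }


def segregation_tests(counts: CrossCounts, alpha: float = 0.01) -> RatioTestResult:
    """Segregation-distortion tests for a het × het cross.

    * ``p_zero_hom_under_mendelian`` — exact probability of seeing zero
      homozygotes among n offspring under 1 WT : 2 het : 1 hom, i.e. (3/4)^n.
    * ``exact_binomial_p_het_vs_wt`` — two-sided exact binomial test of the
      het count among het+WT survivors against p = 2/3 (the 2:1 survivor
      ratio expected if homozygotes die). Two-sidedness by the minlike
      convention: sum of point probabilities no larger than the observed one.
    * ``chi_square_statistic`` — Pearson chi-square of (het, WT) against 2:1.

    Verdict is "lethality-consistent" when no homozygote was seen, zero
    homozygotes would be improbable under full viability (p < alpha), and
    the survivor ratio is compatible with 2:1 (binomial p ≥ alpha).
    """
    if counts.n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    p_zero = 0.75 ** counts.n_offspring
    m = counts.n_het + counts.n_wt
    if m > 0:
        binom = stats.binomtest(counts.n_het, m, 2 / 3, alternative="two-sided")
        p_binom = float(binom.pvalue)
        chi = stats.chisquare(
            [counts.n_het, counts.n_wt], f_exp=[2 * m / 3, m / 3]
        )
        chi_stat, chi_p = float(chi.statistic), float(chi.pvalue)
    else:
        p_binom, chi_stat, chi_p = float("nan"), float("nan"), float("nan")
    if counts.n_hom > 0:
        verdict = "no lethality signal"
    elif p_zero < alpha and p_binom >= alpha:
        verdict = "lethality-consistent"
    else:
        verdict = "inconclusive"
    return RatioTestResult(
        expected_ratio_het_to_wt="2:1",
        chi_square_statistic=chi_stat,
        chi_square_p=chi_p,
        p_zero_hom_under_mendelian=p_zero,
        exact_binomial_p_het_vs_wt=p_binom,
        verdict=verdict,
    )


def simulate_het_cross(
    n_offspring: int, lethal_hom: bool, rng: np.random.Generator
) -> CrossCounts:
    """Draw one het × het litter tally.

    Full viability gives 1 WT : 2 het : 1 hom; under homozygous lethality
    the same number of surviving pups is tallied at 2:1 het:WT.
    """
    if lethal_hom:
        n_het = int(rng.binomial(n_offspring, 2 / 3))
        return CrossCounts(n_offspring, n_het, n_offspring - n_het, 0)
    wt, het, hom = rng.multinomial(n_offspring, [0.25, 0.5, 0.25])
    return CrossCounts(n_offspring, int(het), int(wt), int(hom))
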