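"""IUPAC-aware restriction-site finding, digestion, and in-silico read splitting.

TLA libraries are built by NlaIII (CATG) digestion followed by NspI (RCATGY)
trimming; the same CATG motif later drives the second mapping pass, where
unaligned reads are digested in silico and their sub-fragments remapped.
One boundary convention is used everywhere: the cut is placed immediately
after the last base of the motif, so the motif stays with the upstream
fragment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme identified by its IUPAC recognition motif."""

    name: str
    motif: str

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("enzyme motif must be non-empty")
        bad = set(self.motif.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC codes in motif: {sorted(bad)}")
        object.__setattr__(self, "motif", self.motif.upper())

    def matches(self, seq: str, pos: int) -> bool:
        """Does the motif match ``seq`` starting at ``pos``?"""
        if pos < 0 or pos + len(self.motif) > len(seq):
            return False
        return all(seq[pos + i] in IUPAC[m] for i, m in enumerate(self.motif))


#: Built-in enzymes used by the TLA chemistry.
ENZYMES: dict[str, RestrictionEnzyme] = {
    "NlaIII": RestrictionEnzyme("NlaIII", "CATG"),
    "NspI": RestrictionEnzyme("NspI", "RCATGY"),
}

_VALID_BASES = frozenset("ACGT")


def _check_seq(seq: str) -> None:
    if set(seq) - _VALID_BASES:
        bad = sorted(set(seq) - _VALID_BASES)
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")


def find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All 0-based start positions where the enzyme motif matches ``seq``.

    Overlapping matches are all reported. Only the forward strand is
    scanned: CATG and RCATGY are their own reverse complements under IUPAC
    expansion, so a forward scan already covers both strands.
    """
    _check_seq(seq)
    motif = enzyme.motif
    m = len(motif)
    # expand the degenerate motif into per-position allowed sets once
    allowed = [frozenset(IUPAC[c]) for c in motif]
    # anchor the scan on the first non-degenerate run if any; simple scan
    # with str.find on the literal core (CATG appears in both motifs)
    runs = _literal_runs(motif)
    s, e = max(runs, key=lambda r: r[1] - r[0])
    lit, off = motif[s:e], s
    sites: list[int] = []
    start = 0
    while True:
        hit = seq.find(lit, start)
        if hit == -1:
            break
        pos = hit - off
        if 0 <= pos <= len(seq) - m and all(
            seq[pos + i] in allowed[i] for i in range(m)
        ):
            sites.append(pos)
        start = hit + 1
    return sites


def _literal_runs(motif: str) -> list[tuple[int, int]]:
    """Maximal runs of non-degenerate bases in a motif, as (start, end)."""
    runs = []
    i = 0
    while i < len(motif):
        if motif[i] in "ACGT":
            j = i
            while j < len(motif) and motif[j] in "ACGT":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:  # fully degenerate motif: scan every position
        runs.append((0, 0))
    return runs


def cut_positions(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Cut coordinates implied by the sites: just after each motif end."""
    m = len(enzyme.motif)
    n = len(seq)
    return [p + m for p in find_sites(seq, enzyme) if 0 < p + m < n]


def digest(
    seq: str,
    enzyme: RestrictionEnzyme,
    keep_prob: float = 1.0,
    seed: int | None = None,
) -> list[tuple[int, int]]:
    """Partially digest ``seq``: each cut is retained with ``keep_prob``.

    Returns fragment intervals (0-based half-open) that tile the sequence
    exactly. ``keep_prob=1`` gives the full digestion.
    """
    if not 0 < keep_prob <= 1:
        raise ValueError(f"keep_prob must be in (0, 1], got {keep_prob}")
    cuts = cut_positions(seq, enzyme)
    if keep_prob < 1.0:
        rng = np.random.default_rng(seed)
        keep = rng.random(len(cuts)) < keep_prob
        cuts = [c for c, k in zip(cuts, keep) if k]
    bounds = [0, *cuts, len(seq)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def split_read_at_sites(
    read: str, enzyme: RestrictionEnzyme, min_len: int = 20
) -> list[tuple[str, int]]:
    """Cut a read at every motif occurrence; drop sub-reads below ``min_len``.

    Returns (sub-read, offset-into-parent) pairs, offsets ascending. This is
    the in-silico digestion applied to reads left unaligned by the first
    mapping pass.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    fragments = [(read[s:e], s) for s, e in digest(read, enzyme, 1.0)]
    return [(sub, off) for sub, off in fragments if len(sub) >= min_len]
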