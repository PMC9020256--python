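"""Small I/O helpers: FASTA (via Biopython), TSV tallies, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Genome


def write_fasta(sequences: dict[str, str], path) -> None:
    """Wrapped (60-column) FASTA."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_genome(path) -> Genome:
    return Genome(read_fasta(path))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_offspring_counts_tsv(path) -> tuple[int, int, int]:
    """(n_het, n_wt, n_hom) from a two-column TSV of (litter, genotype)."""
    tally = {"HET": 0, "WT": 0, "HOM": 0}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("litter"):
                continue
            parts = line.split("\t")
            genotype = parts[-1].upper()
            if genotype not in tally:
                raise ValueError(f"unknown genotype {genotype!r} in {path}")
            tally[genotype] += 1
    return tally["HET"], tally["WT"], tally["HOM"]
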