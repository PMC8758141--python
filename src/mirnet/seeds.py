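"""miRNA seed derivation and canonical seed-site scanning in 3'UTRs.

The seed is miRNA nucleotides 2–8 (5'→3'). A canonical site in a 3'UTR is a
Watson–Crick match to the reverse complement of (part of) the seed, in the
standard four-type taxonomy:

* **6mer** — match to seed positions 2–7;
* **7mer-A1** — 6mer plus an adenosine opposite miRNA position 1;
* **7mer-m8** — match extended to position 8;
* **8mer** — match to positions 2–8 plus the A1 adenosine.

The A1 base is a literal ``A`` in the UTR regardless of the miRNA's first
nucleotide. Each 6mer core occurrence is reported once, at the longest type
it supports; coordinates are 0-based half-open on the given (+) strand and
cover the full reported match. ``N`` never matches.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

__all__ = [
    "MatureMirna",
    "SeedSite",
    "seed_of",
    "scan_utr",
    "read_mirna_fasta",
    "read_utr_fasta",
    "write_sites",
]

_RNA_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_DNA_OF_RNA = {"A": "A", "U": "T", "C": "C", "G": "G"}


@dataclass(frozen=True)
class MatureMirna:
    """A mature miRNA sequence, 5'→3', RNA alphabet (T normalized to U)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.strip().upper().replace("T", "U")
        if len(seq) < 8:
            raise ValueError(
                f"{self.id}: mature miRNA must be >=8 nt to define a seed, got {len(seq)}"
            )
        bad = set(seq) - set("ACGU")
        if bad:
            raise ValueError(f"{self.id}: invalid nucleotides {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class SeedSite:
    """One seed-match site on a UTR; ``start``/``end`` are 0-based half-open."""

    utr_id: str
    mirna_id: str
    site_type: str  # 6mer | 7mer-A1 | 7mer-m8 | 8mer
    start: int
    end: int

    def __post_init__(self) -> None:
        length = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[self.site_type]
        if self.end - self.start != length:
            raise ValueError(
                f"{self.site_type} site must span {length} nt, got {self.end - self.start}"
            )


def seed_of(mirna: MatureMirna) -> str:
    """The 7-nt seed: miRNA positions 2–8 (1-based), 5'→3'."""
    return mirna.sequence[1:8]


def _revcomp_rna_as_dna(rna: str) -> str:
    """Reverse complement of an RNA string, written in DNA alphabet (the UTR
    side of the duplex as it appears in a DNA-alphabet sequence)."""
    return "".join(_DNA_OF_RNA[_RNA_COMPLEMENT[b]] for b in reversed(rna))


def scan_utr(mirna: MatureMirna, utr_seq: str, utr_id: str = "utr") -> list[SeedSite]:
    """Locate all canonical seed-match sites of ``mirna`` in one UTR.

    The UTR may be DNA or RNA (U is normalized to T); only the given strand
    is scanned. Every occurrence of the 6mer core (reverse complement of
    seed positions 2–7) is classified at the longest applicable type.
    """
    utr = utr_seq.strip().upper().replace("U", "T")
    bad = set(utr) - set("ACGTN")
    if bad:
        raise ValueError(f"{utr_id}: invalid UTR characters {sorted(bad)}")
    seed = seed_of(mirna)
    core = _revcomp_rna_as_dna(seed[:6])        # matches miRNA positions 2-7
    m8_base = _DNA_OF_RNA[_RNA_COMPLEMENT[seed[6]]]  # pairs miRNA position 8
    sites: list[SeedSite] = []
    pos = utr.find(core)
    while pos != -1:
        has_m8 = pos > 0 and utr[pos - 1] == m8_base
        has_a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        if has_m8 and has_a1:
            site = SeedSite(utr_id, mirna.id, "8mer", pos - 1, pos + 7)
        elif has_m8:
            site = SeedSite(utr_id, mirna.id, "7mer-m8", pos - 1, pos + 6)
        elif has_a1:
            site = SeedSite(utr_id, mirna.id, "7mer-A1", pos, pos + 7)
        else:
            site = SeedSite(utr_id, mirna.id, "6mer", pos, pos + 6)
        sites.append(site)
        pos = utr.find(core, pos + 1)
    return sites


def read_mirna_fasta(path) -> list[MatureMirna]:
    return [MatureMirna(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_mirna_tsv(path) -> list[MatureMirna]:
    """Two-column TSV: mirna_id, mature sequence."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            mirna_id, seq = line.split("\t")[:2]
            out.append(MatureMirna(mirna_id.strip(), seq))
    return out


def read_utr_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_sites(sites: list[SeedSite], path) -> None:
    """BED-like TSV: utr_id, start, end, site_type, mirna_id."""
    frame = pd.DataFrame(
        [
            {
                "utr_id": s.utr_id,
                "start": s.start,
                "end": s.end,
                "site_type": s.site_type,
                "mirna_id": s.mirna_id,
            }
            for s in sites
        ],
        columns=["utr_id", "start", "end", "site_type", "mirna_id"],
    )
    frame.to_csv(path, sep="\t", index=False)
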