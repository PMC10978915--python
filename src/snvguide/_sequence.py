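"""Low-level DNA sequence helpers shared across the package.

All coordinates at module boundaries are 1-based inclusive (MAF/VCF
convention); 0-based slicing is confined to function bodies.
"""

from __future__ import annotations

import numpy as np

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC nucleotide codes -> set of concrete bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# byte -> code translation table for fast encoding; 255 marks non-ACGT
_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c
    _ENCODE_TABLE[ord(_b.lower())] = _c


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_acgt(seq: str) -> bool:
    return bool(seq) and all(c in "ACGT" for c in seq)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(1 for c in seq if c in "GC") / len(seq)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0 C=1 G=2 T=3, other=255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_TABLE[raw]


def iupac_match(base: str, motif_char: str) -> bool:
    return base in IUPAC.get(motif_char, "")


def matches_motif(seq: str, motif: str) -> bool:
    """True when a concrete DNA string matches an IUPAC motif of equal length."""
    if len(seq) != len(motif):
        return False
    return all(iupac_match(b, m) for b, m in zip(seq, motif))


def fetch(genome, chrom: str, start1: int, end1: int) -> str:
    """Fetch genome[chrom][start1..end1] (1-based inclusive), uppercased.

    Accepts either a mapping of contig name -> sequence string or a
    pyfaidx.Fasta handle.
    """
    if hasattr(genome, "keys") and isinstance(genome.get(chrom, None) if isinstance(genome, dict) else None, str):
        return genome[chrom][start1 - 1:end1].upper()
    if isinstance(genome, dict):
        return genome[chrom][start1 - 1:end1].upper()
    # pyfaidx.Fasta
    return str(genome[chrom][start1 - 1:end1]).upper()


def contig_length(genome, chrom: str) -> int:
    if isinstance(genome, dict):
        return len(genome[chrom])
    return len(genome[chrom])


def contig_names(genome) -> list[str]:
    if isinstance(genome, dict):
        return list(genome.keys())
    return list(genome.keys())
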