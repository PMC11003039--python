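"""Low-level sequence helpers: complementing, translation, k-mer encoding."""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: codon -> single-letter amino acid under the standard genetic code
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_TABLE if CODON_TABLE[c] != "*"))

#: amino acid -> list of synonymous codons (stops excluded)
SYNONYMOUS_FAMILIES: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    SYNONYMOUS_FAMILIES.setdefault(CODON_TABLE[_codon], []).append(_codon)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate(cds: str) -> str:
    """Translate an in-frame DNA sequence; stops render as '*'."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    cds = cds.upper()
    return "".join(CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds), 3))


def encode(seq: str) -> np.ndarray:
    """2-bit encode ACGT; ambiguity codes map to 255 (never match a k-mer)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Rolling k-mer integer codes; positions containing ambiguity get -1.

    Returns an int64 array of length ``len(seq) - k + 1`` (empty if shorter).
    """
    codes = encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = codes != 255
    vals = np.where(valid, codes, 0).astype(np.int64)
    out = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        out = (out << 2) | vals[j : j + n]
        ok &= valid[j : j + n]
    out[~ok] = -1
    return out


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases")
    return gc / (gc + at)
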