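"""Nucleotide encoding shared by all modules.

Haplotypes are stored as ``uint8`` arrays with codes A=0, C=1, G=2, T=3,
N=4 (missing data), '-'=5 (alignment gap).  IUPAC ambiguity codes appear
only at I/O boundaries and in diploid consensus sequences, where a
heterozygous site is collapsed to the two-allele ambiguity symbol.

Gaps ('-') are distinct from missing data ('N'): a gap is an observed
single-column insertion/deletion state, missing data is absence of
information.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N, GAP = 0, 1, 2, 3, 4, 5

BASES = "ACGTN-"
_CODE_OF = {b: i for i, b in enumerate(BASES)}
_CODE_OF.update({b.lower(): i for i, b in enumerate(BASES)})

#: IUPAC symbol for an unordered pair of distinct bases.
_PAIR_TO_IUPAC = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
IUPAC_TO_PAIR = {v: tuple(sorted(k)) for k, v in _PAIR_TO_IUPAC.items()}

#: bitmask per character: A=1, C=2, G=4, T=8; N and '-' map to 0 (excluded
#: pairwise from distance computations).
CHAR_MASK = {}
for ch, bit in zip("ACGT", (1, 2, 4, 8)):
    CHAR_MASK[ch] = bit
for ch, pair in IUPAC_TO_PAIR.items():
    CHAR_MASK[ch] = CHAR_MASK[pair[0]] | CHAR_MASK[pair[1]]
CHAR_MASK["N"] = 0
CHAR_MASK["-"] = 0
for ch in list(CHAR_MASK):
    CHAR_MASK[ch.lower()] = CHAR_MASK[ch]

_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for ch, m in CHAR_MASK.items():
    _MASK_TABLE[ord(ch)] = m

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an unambiguous sequence (ACGTN-) as a uint8 code array."""
    out = np.empty(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq):
        try:
            out[i] = _CODE_OF[ch]
        except KeyError:
            raise ValueError(f"unknown residue {ch!r} at position {i}") from None
    return out


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def masks_from_string(seq: str) -> np.ndarray:
    """Per-character base bitmasks (IUPAC aware) for distance computations."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _MASK_TABLE[raw]


def consensus(hap_a: np.ndarray, hap_b: np.ndarray) -> str:
    """Diploid consensus of two haplotype code arrays, IUPAC-coded.

    Matching bases pass through; a heterozygous site becomes its two-base
    ambiguity code; a site missing (N) or gapped (-) on either haplotype is
    reported missing/gapped.
    """
    out = []
    for x, y in zip(hap_a.tolist(), hap_b.tolist()):
        if x == GAP or y == GAP:
            out.append("-")
        elif x == N or y == N:
            out.append("N")
        elif x == y:
            out.append(BASES[x])
        else:
            out.append(_PAIR_TO_IUPAC[frozenset((BASES[x], BASES[y]))])
    return "".join(out)


def split_consensus(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Expand an IUPAC consensus into an (arbitrarily phased) haplotype pair.

    Heterozygous codes split alphabetically (first allele to haplotype a),
    so phase information is not preserved — only the unordered genotype.
    """
    a = np.empty(len(seq), dtype=np.uint8)
    b = np.empty(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq):
        up = ch.upper()
        if up in _CODE_OF:
            a[i] = b[i] = _CODE_OF[up]
        elif up in IUPAC_TO_PAIR:
            x, y = IUPAC_TO_PAIR[up]
            a[i], b[i] = _CODE_OF[x], _CODE_OF[y]
        else:
            raise ValueError(f"unknown residue {ch!r} at position {i}")
    return a, b
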