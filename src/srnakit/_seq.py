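"""Sequence alphabet helpers.

All internal sequence handling uses the RNA alphabet {A, C, G, U} (plus N
for ambiguity in references); DNA input is converted on read.
"""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGUN")

_COMP = str.maketrans("ACGUN", "UGCAN")

#: Base pairs counted as paired in folding and target scoring.
WATSON_CRICK = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")})
WOBBLE = frozenset({("G", "U"), ("U", "G")})
PAIRABLE = WATSON_CRICK | WOBBLE


def to_rna(seq: str) -> str:
    """Uppercase and convert T->U."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement in the RNA alphabet."""
    return seq.translate(_COMP)[::-1]


def validate_rna(seq: str, *, name: str = "sequence") -> str:
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-ACGUN characters: {sorted(bad)}")
    return seq


def is_pair(a: str, b: str) -> bool:
    return (a, b) in PAIRABLE


def is_watson_crick(a: str, b: str) -> bool:
    return (a, b) in WATSON_CRICK


def hamming(a: str, b: str) -> int:
    """Substitution count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
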