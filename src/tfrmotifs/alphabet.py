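"""The 20-letter amino-acid alphabet used throughout the package.

Alphabet order follows the MEME protein convention (alphabetical one-letter
codes). ``X`` is accepted in sequences as an unknown residue: it scores zero
in PWM scanning and matches only wildcards in PROSITE patterns. The ambiguity
letters B, Z and J appear only in consensus strings, never in sequences.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
UNKNOWN: str = "X"
SEQUENCE_ALPHABET: frozenset[str] = frozenset(AMINO_ACIDS + UNKNOWN)

# Consensus-string ambiguity codes: most-informative-pair letters.
AMBIGUITY: dict[str, frozenset[str]] = {
    "B": frozenset("DN"),
    "Z": frozenset("EQ"),
    "J": frozenset("IL"),
}


def expand_ambiguity(letter: str) -> frozenset[str]:
    """Residues compatible with a consensus letter (identity for plain letters)."""
    if letter in AMBIGUITY:
        return AMBIGUITY[letter]
    if letter in AA_INDEX:
        return frozenset(letter)
    raise ValueError(f"not a consensus letter: {letter!r}")
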