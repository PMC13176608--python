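"""PROSITE patterns: parsing, matching, derivation and expected random matches.

A pattern is an ordered list of elements — fixed residues, bracketed residue
sets, and x / x(n) wildcards — joined by "-". Letter runs without separators
(as printed in some published patterns, e.g. ``IN-x-[VI]-LK-[GPE]-YL``) parse
as consecutive fixed positions. Excluded sets ``{..}`` and the anchors ``<``,
``>`` are accepted by the parser but are outside derivation scope.

The expected-random-match count (ERM) of a pattern is the product over elements
of their background class probabilities (wildcards contribute 1) times the
number of residues searched, by default 50,000,000 (~100,000 sequences) —
edge effects ignored, matching the "approximate" count reported by ScanProsite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS
from .conservation import ColumnProfile
from .io import load_swissprot_composition

__all__ = [
    "Element",
    "PrositePattern",
    "ResidueFrequencyTable",
    "parse_pattern",
    "derive_pattern",
    "match_pattern",
    "expected_random_matches",
    "signature_report",
    "SignatureReport",
]

_ALL_RESIDUES = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class Element:
    """One pattern element: kind in {fixed, set, excluded, wildcard}."""

    kind: str
    residues: tuple[str, ...] = ()
    count: int = 1  # repeat length (wildcards only may exceed 1 here)

    def __post_init__(self) -> None:
        if self.kind not in {"fixed", "set", "excluded", "wildcard"}:
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.count < 1:
            raise ValueError("element repeat count must be >= 1")

    @property
    def length(self) -> int:
        return self.count

    def allowed(self) -> frozenset[str]:
        """Residues this element matches at each of its positions (X only via wildcard)."""
        if self.kind == "fixed":
            return frozenset(self.residues)
        if self.kind == "set":
            return frozenset(self.residues)
        if self.kind == "excluded":
            return _ALL_RESIDUES - frozenset(self.residues)
        return _ALL_RESIDUES | {"X"}

    def text(self) -> str:
        if self.kind == "fixed":
            return self.residues[0]
        if self.kind == "set":
            return "[" + "".join(self.residues) + "]"
        if self.kind == "excluded":
            return "{" + "".join(self.residues) + "}"
        return "x" if self.count == 1 else f"x({self.count})"


@dataclass(frozen=True)
class PrositePattern:
    """A parsed pattern; ``text`` gives the canonical hyphen-joined form."""

    elements: tuple[Element, ...]
    source_motif_id: str | None = None
    anchored_start: bool = False
    anchored_end: bool = False

    @property
    def min_length(self) -> int:
        return sum(e.length for e in self.elements)

    @property
    def text(self) -> str:
        body = "-".join(e.text() for e in self.elements)
        return ("<" if self.anchored_start else "") + body + (
            ">" if self.anchored_end else ""
        )

    def position_sets(self) -> list[frozenset[str]]:
        sets: list[frozenset[str]] = []
        for e in self.elements:
            sets.extend([e.allowed()] * e.length)
        return sets


def _parse_repeat(text: str, i: int) -> tuple[int, int]:
    """Parse an optional (n) at text[i:]; returns (count, next index)."""
    if i < len(text) and text[i] == "(":
        j = text.find(")", i)
        if j < 0:
            raise ValueError(f"pattern column {i}: unbalanced parenthesis")
        digits = text[i + 1 : j]
        if not digits.isdigit() or int(digits) == 0:
            raise ValueError(f"pattern column {i}: invalid repeat count {digits!r}")
        return int(digits), j + 1
    return 1, i


def parse_pattern(text: str, source_motif_id: str | None = None) -> PrositePattern:
    """Parse PROSITE pattern syntax (letters, [sets], {excluded}, x, x(n), '-')."""
    s = text.strip().rstrip(".")
    if not s:
        raise ValueError("empty pattern")
    anchored_start = s.startswith("<")
    anchored_end = s.endswith(">")
    s = s.removeprefix("<").removesuffix(">")
    elements: list[Element] = []
    for chunk in s.split("-"):
        if not chunk:
            raise ValueError(f"empty element in pattern {text!r}")
        i = 0
        while i < len(chunk):
            ch = chunk[i]
            if ch == "x":
                count, i = _parse_repeat(chunk, i + 1)
                elements.append(Element("wildcard", count=count))
            elif ch in "[{":
                closer = "]" if ch == "[" else "}"
                j = chunk.find(closer, i)
                if j < 0:
                    raise ValueError(f"pattern column {i}: unbalanced {ch!r}")
                members = chunk[i + 1 : j]
                if not members:
                    raise ValueError(f"pattern column {i}: empty residue set")
                bad = [m for m in members if m not in AA_INDEX]
                if bad:
                    raise ValueError(f"pattern column {i}: invalid residues {bad}")
                kind = "set" if ch == "[" else "excluded"
                count, i = _parse_repeat(chunk, j + 1)
                for _ in range(count):
                    elements.append(Element(kind, tuple(members)))
            elif ch in AA_INDEX:
                count, i = _parse_repeat(chunk, i + 1)
                for _ in range(count):
                    elements.append(Element("fixed", (ch,)))
            else:
                raise ValueError(f"pattern column {i}: unexpected character {ch!r}")
    return PrositePattern(
        tuple(elements), source_motif_id, anchored_start, anchored_end
    )


def derive_pattern(
    profiles: list[ColumnProfile],
    t_fixed: float = 0.98,
    t_set: float = 0.95,
    max_set: int = 4,
    source_motif_id: str | None = None,
) -> PrositePattern:
    """Propose a pattern from column profiles.

    Per column: a fixed residue if the top frequency reaches ``t_fixed``;
    otherwise the smallest residue set (at most ``max_set`` members, ordered by
    descending frequency) whose combined frequency reaches ``t_set``; otherwise
    a wildcard. Consecutive wildcards are merged into x(n). This formalizes the
    manual logo/alignment curation behind published patterns; thresholds are
    configurable.
    """
    if not profiles:
        raise ValueError("cannot derive a pattern from an empty profile list")
    if not (0 < t_fixed <= 1 and 0 < t_set <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    elements: list[Element] = []
    for p in profiles:
        order = np.argsort(-p.freqs, kind="stable")
        if p.freqs[order[0]] >= t_fixed:
            elements.append(Element("fixed", (AMINO_ACIDS[order[0]],)))
            continue
        cum = np.cumsum(p.freqs[order])
        size = int(np.searchsorted(cum, t_set) + 1)
        if 2 <= size <= max_set:
            members = tuple(AMINO_ACIDS[i] for i in order[:size])
            elements.append(Element("set", members))
        elif size == 1:
            elements.append(Element("fixed", (AMINO_ACIDS[order[0]],)))
        else:
            if elements and elements[-1].kind == "wildcard":
                elements[-1] = Element("wildcard", count=elements[-1].count + 1)
            else:
                elements.append(Element("wildcard"))
    return PrositePattern(tuple(elements), source_motif_id)


def match_pattern(pattern: PrositePattern, sequence: str) -> list[int]:
    """All (possibly overlapping) 1-based start positions of contiguous matches.

    X in the sequence matches only wildcard positions.
    """
    sets = pattern.position_sets()
    L = len(sets)
    starts = []
    positions = range(len(sequence) - L + 1)
    if pattern.anchored_start:
        positions = range(0, 1) if len(sequence) >= L else range(0)
    for s in positions:
        if pattern.anchored_end and s + L != len(sequence):
            continue
        if all(sequence[s + i] in sets[i] for i in range(L)):
            starts.append(s + 1)
    return starts


@dataclass
class ResidueFrequencyTable:
    """Background residue composition for ERM arithmetic."""

    freqs: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (20,) or (f <= 0).any():
            raise ValueError("composition must be 20 positive frequencies")
        self.freqs = f / f.sum()

    @classmethod
    def swissprot(cls) -> "ResidueFrequencyTable":
        return cls(load_swissprot_composition(), "UniProtKB/Swiss-Prot release statistics")


def window_probability(pattern: PrositePattern, freqs: ResidueFrequencyTable) -> float:
    """Probability that a random window matches the pattern."""
    p = 1.0
    f = freqs.freqs
    for e in pattern.elements:
        if e.kind == "wildcard":
            continue
        class_p = float(sum(f[AA_INDEX[a]] for a in e.allowed()))
        p *= class_p ** e.count
    return p


def expected_random_matches(
    pattern: PrositePattern,
    freqs: ResidueFrequencyTable | None = None,
    n_residues: int = 50_000_000,
) -> float:
    """Expected match count in ``n_residues`` of background sequence."""
    if freqs is None:
        freqs = ResidueFrequencyTable.swissprot()
    return window_probability(pattern, freqs) * n_residues


@dataclass
class SignatureReport:
    """YES/NO recommendation for using a pattern as a subfamily signature."""

    pattern: str
    erm: float
    recommendation: str
    rationale: str


def signature_report(
    pattern: PrositePattern,
    erm: float,
    hit_ids: list[str] | None = None,
    homolog_ids: set[str] | None = None,
    erm_threshold: float = 1e-2,
) -> SignatureReport:
    """Recommend a pattern when its ERM is low, or moderately low with only
    homologous hits in the reference search.

    YES when ERM <= ``erm_threshold``, or when ERM <= 0.1 and every reference
    hit is a homolog of the source protein; NO otherwise. The rationale names
    the branch that fired.
    """
    hit_ids = hit_ids or []
    homolog_ids = homolog_ids or set()
    if erm <= erm_threshold:
        return SignatureReport(
            pattern.text, erm, "YES", f"ERM {erm:.3g} <= threshold {erm_threshold:g}"
        )
    off_target = [h for h in hit_ids if h not in homolog_ids]
    if erm <= 0.1 and hit_ids and not off_target:
        return SignatureReport(
            pattern.text, erm, "YES",
            f"ERM {erm:.3g} <= 0.1 and all {len(hit_ids)} reference hits are source homologs",
        )
    reason = f"ERM {erm:.3g} above threshold"
    if off_target:
        reason += f"; {len(off_target)} off-target reference hits"
    return SignatureReport(pattern.text, erm, "NO", reason)
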