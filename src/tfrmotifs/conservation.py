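"""Per-column conservation of motif occurrence stacks.

A stack of fixed-width motif hits is an ungapped alignment; each column gets
residue frequencies, Shannon entropy H, information content IC = log2(20) - H
(bits, so a fully conserved column reaches log2(20) ~ 4.32), sequence-logo
letter heights freq * IC, and a 1-9 conservation grade (grade 9 = most
conserved) assigned by 9-quantile binning of IC across the stack's columns.
The grades are an in-package surrogate for phylogeny-aware conservation scores
such as ConSurf's, not a reimplementation of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alphabet import AA_INDEX, AMBIGUITY, AMINO_ACIDS
from .io import MotifMatrix, SequenceSet
from .scanner import MotifHit

__all__ = [
    "OccurrenceStack",
    "ColumnProfile",
    "occurrence_stack",
    "column_profile",
    "consensus_string",
    "logo_data",
]

MAX_IC = math.log2(20.0)


@dataclass
class OccurrenceStack:
    """Equal-length matched substrings of one motif, with reference numbering.

    ``reference_start`` is the 1-based full-protein position of the stack's
    first column in the named reference protein, as used on logo x-axes.
    """

    motif_id: str
    reference_id: str
    reference_start: int
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an occurrence stack needs at least 2 rows")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(f"mixed row widths in stack: {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def positions(self) -> list[int]:
        return list(range(self.reference_start, self.reference_start + self.width))


def occurrence_stack(
    hits: list[MotifHit],
    seqs: SequenceSet,
    motif: MotifMatrix,
    reference_id: str,
) -> OccurrenceStack:
    """Stack the matched substrings of one motif's hits.

    The reference start is taken from the hit in the reference sequence and
    shifted by the set's truncation offset, so positions are reported in
    full-protein numbering.
    """
    rows = [h for h in hits if h.motif_id == motif.motif_id]
    if any(h.motif_id != motif.motif_id for h in hits if h in rows):
        raise ValueError("hits from multiple motifs")
    ref_hits = [h for h in rows if h.seq_id == reference_id]
    if not ref_hits:
        raise ValueError(f"no hit of {motif.motif_id!r} in reference {reference_id!r}")
    ref = max(ref_hits, key=lambda h: h.score)
    return OccurrenceStack(
        motif.motif_id,
        reference_id,
        ref.start + seqs.truncated_prefix,
        [h.matched for h in rows],
    )


@dataclass
class ColumnProfile:
    """One alignment column: frequencies, entropy, IC, logo heights, grade."""

    position: int
    freqs: np.ndarray  # 20, alphabet order
    entropy: float  # bits
    ic: float  # bits
    heights: np.ndarray  # freq * ic
    grade: int  # 1 (variable) .. 9 (most conserved)


def _column_entropy(freqs: np.ndarray) -> float:
    nz = freqs[freqs > 0]
    return float(-(nz * np.log2(nz)).sum())


def column_profile(
    stack: OccurrenceStack,
    pseudocount: float = 0.0,
    miller_madow: bool = False,
) -> list[ColumnProfile]:
    """Per-column profiles of a stack.

    Frequencies are (count + pseudocount) / (n + 20 * pseudocount), counted over
    standard residues only (X never counts). ``miller_madow`` applies the
    Miller-Madow small-sample bias correction to the entropy; off by default
    since stacks in intended use carry hundreds of rows.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    profiles: list[ColumnProfile] = []
    ics = []
    raw = []
    for col in range(stack.width):
        counts = np.zeros(20)
        for row in stack.rows:
            i = AA_INDEX.get(row[col])
            if i is not None:
                counts[i] += 1
        n = counts.sum()
        freqs = (counts + pseudocount) / (n + 20.0 * pseudocount)
        h = _column_entropy(freqs)
        if miller_madow and n > 0:
            h += (np.count_nonzero(counts) - 1) / (2.0 * n * math.log(2.0))
        ic = max(0.0, min(MAX_IC, MAX_IC - h))
        raw.append((freqs, h, ic))
        ics.append(ic)
    edges = np.quantile(np.asarray(ics), np.arange(1, 9) / 9.0)
    for col, (freqs, h, ic) in enumerate(raw):
        grade = int(1 + np.searchsorted(edges, ic, side="right"))
        profiles.append(
            ColumnProfile(
                stack.reference_start + col, freqs, h, ic, freqs * ic, min(grade, 9)
            )
        )
    return profiles


def consensus_string(
    profiles: list[ColumnProfile],
    t_single: float = 0.6,
    t_pair: float = 0.9,
) -> str:
    """Consensus with ambiguity codes B (D/N), Z (E/Q), J (I/L).

    Per column: the most frequent residue if its frequency reaches ``t_single``;
    otherwise an ambiguity letter whose pair's combined frequency reaches
    ``t_pair``; otherwise the most frequent residue anyway (the consensus is the
    most informative letter, not a match pattern).
    """
    if not (0 < t_single <= 1 and 0 < t_pair <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    letters = []
    for p in profiles:
        top = int(p.freqs.argmax())
        if p.freqs[top] >= t_single:
            letters.append(AMINO_ACIDS[top])
            continue
        best_pair = None
        for code, pair in AMBIGUITY.items():
            combined = sum(p.freqs[AA_INDEX[a]] for a in pair)
            if combined >= t_pair and (best_pair is None or combined > best_pair[1]):
                best_pair = (code, combined)
        letters.append(best_pair[0] if best_pair else AMINO_ACIDS[top])
    return "".join(letters)


def logo_data(profiles: list[ColumnProfile]) -> list[list[tuple[str, float]]]:
    """Letter/height stacks per column, dominant letter first, zero heights dropped."""
    stacks = []
    for p in profiles:
        order = np.argsort(-p.heights, kind="stable")
        stacks.append(
            [(AMINO_ACIDS[i], float(p.heights[i])) for i in order if p.heights[i] > 0]
        )
    return stacks


def plot_logo(profiles: list[ColumnProfile], ax=None):
    """Render a simple stacked-letter logo (requires matplotlib)."""
    import matplotlib.pyplot as plt  # deferred; plotting is optional

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, len(profiles) * 0.5), 2.5))
    for x, (p, stack) in enumerate(zip(profiles, logo_data(profiles))):
        y = 0.0
        for letter, height in reversed(stack):
            ax.text(
                x, y + height / 2, letter,
                ha="center", va="center", fontsize=8 + 10 * height / MAX_IC,
            )
            y += height
    ax.set_xticks(range(len(profiles)), [p.position for p in profiles])
    ax.set_ylim(0, MAX_IC)
    ax.set_ylabel("bits")
    return ax
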