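"""FIMO-style PWM scanning of protein sequences.

Each motif is turned into a log-odds matrix in bits against a 0th-order
background; every window of every sequence is scored; p-values are exact tail
probabilities of the window score under the background, obtained by dynamic
programming over a discretized score axis (the standard lattice convolution used
for PWM p-values); q-values come from Benjamini-Hochberg correction per motif
across all scanned windows; and hits are kept at q <= 1e-4, the stringent cutoff
used for the curated TFR motif searches.

Unknown residues (X) contribute a score of zero at any motif position. Protein
scanning only: there is no reverse strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX
from .io import MotifMatrix, SequenceSet

__all__ = [
    "BackgroundModel",
    "LogOddsMatrix",
    "ScoreDistribution",
    "MotifHit",
    "log_odds",
    "window_score",
    "exact_pvalue_table",
    "scan",
    "best_scores",
    "score_distribution_summary",
]

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_GRANULARITY = 1000  # bins per bit
DEFAULT_Q_THRESHOLD = 1e-4


@dataclass
class BackgroundModel:
    """0th-order Markov residue model: 20 frequencies, floored at 1e-6."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (20,) or (f < 0).any():
            raise ValueError("background must be 20 non-negative frequencies")
        if f.sum() <= 0:
            raise ValueError("background has no mass")
        f = np.maximum(f / f.sum(), 1e-6)
        self.freqs = f / f.sum()

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(20, 1.0 / 20.0))

    @classmethod
    def from_sequences(cls, seqs: SequenceSet) -> "BackgroundModel":
        """Maximum-likelihood 0th-order model from observed residues (X ignored)."""
        counts = np.zeros(20)
        for rec in seqs:
            for ch in rec.residues:
                i = AA_INDEX.get(ch)
                if i is not None:
                    counts[i] += 1
        if counts.sum() == 0:
            raise ValueError("no standard residues to estimate a background from")
        return cls(counts / counts.sum())


@dataclass
class LogOddsMatrix:
    """Per-position log2 likelihood ratios (bits) of motif vs background.

    Entries may be -inf when a zero-probability cell meets a zero pseudocount;
    any positive pseudocount guarantees finite entries.
    """

    motif_id: str
    scores: np.ndarray  # width x 20

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.isnan(self.scores).any() or (self.scores == np.inf).any():
            raise ValueError(f"motif {self.motif_id!r}: invalid log-odds entries")

    @property
    def width(self) -> int:
        return self.scores.shape[0]


def log_odds(
    motif: MotifMatrix,
    background: BackgroundModel,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> LogOddsMatrix:
    """Log-odds matrix: log2((p + pc*bg) / ((1+pc)*bg)).

    The pseudocount is a fraction of the background added to each motif
    probability, guaranteeing finite entries for zero-probability cells.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    bg = background.freqs
    if (bg <= 0).any():
        raise ValueError("background contains zero frequencies")
    num = motif.probs + pseudocount * bg[None, :]
    with np.errstate(divide="ignore"):
        scores = np.log2(num / ((1.0 + pseudocount) * bg[None, :]))
    return LogOddsMatrix(motif.motif_id, scores)


def window_score(lom: LogOddsMatrix, window: str) -> float:
    """Score of one residue window: the sum of per-position entries (X scores 0)."""
    if len(window) != lom.width:
        raise ValueError(f"window length {len(window)} != motif width {lom.width}")
    total = 0.0
    for i, ch in enumerate(window):
        if ch == "X":
            continue
        j = AA_INDEX.get(ch)
        if j is None:
            raise ValueError(f"invalid residue {ch!r} in window")
        total += lom.scores[i, j]
    return float(total)


@dataclass
class ScoreDistribution:
    """Exact distribution of window scores under the i.i.d. background.

    Scores are discretized to ``1/granularity``-bit bins; ``pmf[k]`` is the
    probability of integer score ``offset + k`` and ``tail[k]`` the probability
    of scoring at least that. ``pvalue`` reports the conservative (upper) side
    of the query score's bin.
    """

    motif_id: str
    granularity: int
    offset: int  # integer score of pmf[0]
    pmf: np.ndarray
    tail: np.ndarray
    int_scores: np.ndarray = field(repr=False)  # width x 21 (X column = 0)

    @property
    def support(self) -> np.ndarray:
        return (self.offset + np.arange(len(self.pmf))) / self.granularity

    def pvalue_int(self, k: int | np.ndarray) -> np.ndarray:
        idx = np.asarray(k) - self.offset
        idx = np.clip(idx, 0, len(self.tail) - 1)
        p = self.tail[idx]
        return np.where(np.asarray(k) > self.offset + len(self.tail) - 1, 0.0, p)

    def pvalue(self, score_bits: float) -> float:
        k = int(np.floor(score_bits * self.granularity))
        return float(self.pvalue_int(np.array(k)))


def exact_pvalue_table(
    motif: MotifMatrix,
    background: BackgroundModel,
    granularity: int = DEFAULT_GRANULARITY,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ScoreDistribution:
    """Exact window-score null distribution by positionwise lattice convolution."""
    if granularity < 100:
        raise ValueError("granularity must give at least 100 bins per bit")
    lom = log_odds(motif, background, pseudocount)
    scores = lom.scores.copy()
    if np.isneginf(scores).any():
        # zero pseudocount: clamp impossible letters far below the finite range
        finite_min = scores[np.isfinite(scores)].min()
        scores[np.isneginf(scores)] = finite_min - 20.0
    ints = np.rint(scores * granularity).astype(np.int64)
    bg = background.freqs
    pmf = np.array([1.0])
    offset = 0
    for i in range(lom.width):
        row = ints[i]
        lo, hi = int(row.min()), int(row.max())
        new = np.zeros(len(pmf) + (hi - lo))
        for a in range(20):
            shift = int(row[a]) - lo
            new[shift : shift + len(pmf)] += bg[a] * pmf
        pmf = new
        offset += lo
    tail = np.cumsum(pmf[::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    int_scores = np.hstack([ints, np.zeros((lom.width, 1), dtype=np.int64)])
    return ScoreDistribution(motif.motif_id, granularity, offset, pmf, tail, int_scores)


@dataclass(frozen=True)
class MotifHit:
    """A q-value-filtered motif occurrence (1-based inclusive coordinates)."""

    motif_id: str
    seq_id: str
    start: int
    stop: int
    matched: str
    score: float  # bits
    p_value: float
    q_value: float


def _bh_qvalues(p: np.ndarray, order_keys: tuple[np.ndarray, ...]) -> np.ndarray:
    """Benjamini-Hochberg q-values; ties in p broken by the given keys."""
    m = len(p)
    order = np.lexsort(order_keys[::-1] + (p,))
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def scan(
    seqs: SequenceSet,
    motifs: list[MotifMatrix],
    background: BackgroundModel | None = None,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    granularity: int = DEFAULT_GRANULARITY,
) -> list[MotifHit]:
    """Scan every window of every sequence with every motif.

    q-values are computed per motif across all scanned windows; hits with
    q <= ``q_threshold`` are returned sorted by (seq_id, start, motif_id).
    Overlapping hits are all reported. Sequences shorter than a motif simply
    yield no windows for it.
    """
    if not motifs:
        raise ValueError("empty motif list")
    if background is None:
        background = BackgroundModel(motifs[0].background)

    # Concatenated residue indices (X -> 20) with per-sequence extents.
    index_map = np.full(128, -1, dtype=np.int64)
    for ch, i in AA_INDEX.items():
        index_map[ord(ch)] = i
    index_map[ord("X")] = 20
    chunks, extents, pos = [], [], 0
    for rec in seqs:
        arr = index_map[np.frombuffer(rec.residues.encode(), dtype=np.uint8)]
        chunks.append(arr)
        extents.append((pos, len(arr)))
        pos += len(arr)
    idx = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
    seq_starts = np.array([s for s, _ in extents])

    hits: list[MotifHit] = []
    for motif in motifs:
        sd = exact_pvalue_table(motif, background, granularity, pseudocount)
        lom = log_odds(motif, background, pseudocount)
        w = motif.width
        if len(idx) < w:
            continue
        n_win_total = len(idx) - w + 1
        ints = np.zeros(n_win_total, dtype=np.int64)
        for i in range(w):
            ints += sd.int_scores[i, idx[i : n_win_total + i]]
        valid = np.zeros(n_win_total, dtype=bool)
        for start, length in extents:
            if length >= w:
                valid[start : start + length - w + 1] = True
        offsets = np.nonzero(valid)[0]
        if offsets.size == 0:
            continue
        p = np.asarray(sd.pvalue_int(ints[offsets]), dtype=float)
        # windows of pure X carry no information: never significant
        x_run = np.cumsum(np.concatenate([[0], (idx == 20).astype(np.int64)]))
        all_x = (x_run[offsets + w] - x_run[offsets]) == w
        p[all_x] = 1.0
        seq_index = np.searchsorted(seq_starts, offsets, side="right") - 1
        local_start = offsets - seq_starts[seq_index] + 1  # 1-based
        q = _bh_qvalues(p, (seq_index, local_start))
        keep = np.nonzero(q <= q_threshold)[0]
        if keep.size:
            fl = np.hstack([lom.scores, np.zeros((w, 1))])
            for k in keep:
                o = offsets[k]
                rec = seqs.records[seq_index[k]]
                s = int(local_start[k])
                window = rec.residues[s - 1 : s - 1 + w]
                score = float(sum(fl[i, idx[o + i]] for i in range(w)))
                hits.append(
                    MotifHit(
                        motif.motif_id,
                        rec.id,
                        s,
                        s + w - 1,
                        window,
                        score,
                        float(p[k]),
                        float(q[k]),
                    )
                )
    hits.sort(key=lambda h: (h.seq_id, h.start, h.motif_id))
    return hits


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    """Tabular view of hits, mirroring FIMO's column order."""
    return pd.DataFrame(
        [
            (h.motif_id, h.seq_id, h.start, h.stop, h.score, h.p_value, h.q_value, h.matched)
            for h in hits
        ],
        columns=[
            "motif_id",
            "seq_id",
            "start",
            "stop",
            "score_bits",
            "p_value",
            "q_value",
            "matched",
        ],
    )


def best_scores(
    hits: list[MotifHit], seqs: SequenceSet, motifs: list[MotifMatrix]
) -> pd.DataFrame:
    """Sequences x motifs table of best hit scores; no hit scores zero.

    This is the raw (unscaled) feature table handed to the selection models.
    """
    table = pd.DataFrame(
        0.0, index=pd.Index(seqs.ids, name="seq_id"),
        columns=pd.Index([m.motif_id for m in motifs], name="motif_id"),
    )
    for h in hits:
        if h.score > table.at[h.seq_id, h.motif_id]:
            table.at[h.seq_id, h.motif_id] = h.score
    return table


def score_distribution_summary(hits: list[MotifHit]) -> pd.DataFrame:
    """Per-motif five-number score summary with 1.5*IQR whiskers.

    Whisker ends are the extreme scores inside [Q1 - 1.5*IQR, Q3 + 1.5*IQR],
    i.e. outliers are excluded, matching box-and-whisker convention.
    """
    rows = []
    by_motif: dict[str, list[float]] = {}
    for h in hits:
        by_motif.setdefault(h.motif_id, []).append(h.score)
    for motif_id, scores in by_motif.items():
        x = np.sort(np.asarray(scores))
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        inside = x[(x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)]
        rows.append((motif_id, len(x), inside.min(), q1, med, q3, inside.max()))
    return pd.DataFrame(
        rows, columns=["motif_id", "n", "min", "q1", "median", "q3", "max"]
    )
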