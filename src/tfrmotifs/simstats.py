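"""Pairwise-identity distributions and two-sample distribution diagnostics.

Identity between two proteins is computed from a global alignment (BLOSUM62
scoring, gap open -10 / extend -0.5) as 100 * identical columns / alignment
length. Distribution distances between identity samples use the 1-D Wasserstein
(Earth Mover's) distance, the two-sample Kolmogorov-Smirnov and Cramér-von Mises
tests, and the rank-biserial Mann-Whitney effect size r = 1 - 2U/(n1*n2).

``greedy_cluster`` is a deterministic longest-first redundancy-reduction
stand-in for CD-HIT-style clustering at 90/75/50% identity; it preserves the
construct being tested (redundancy removal before subsampling) without the
word-filter heuristics. ``sampling_stability`` replays the 30-draws-of-300
control used to rule out taxonomic overrepresentation artifacts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .io import LabelTable, SequenceRecord, SequenceSet

__all__ = [
    "IdentityDistribution",
    "DistanceReport",
    "make_aligner",
    "identity_pair",
    "pairwise_identity",
    "dist_compare",
    "greedy_cluster",
    "sampling_stability",
    "StabilityReport",
]


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def identity_pair(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Percent identity over the global alignment length of two sequences."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner()
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


@dataclass
class IdentityDistribution:
    """Sample of pairwise identity percentages with sampling provenance."""

    values: np.ndarray
    n_pairs: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if ((v < 0) | (v > 100)).any():
            raise ValueError("identities must lie in [0, 100]")
        self.values = v


def pairwise_identity(
    seqs: SequenceSet | list[SequenceRecord],
    cap: int | None = None,
    seed: int | None = None,
) -> IdentityDistribution:
    """Identity distribution over all sequence pairs (uniformly subsampled at ``cap``)."""
    records = list(seqs)
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    pairs = list(itertools.combinations(range(len(records)), 2))
    provenance = {"n_sequences": len(records), "cap": cap}
    if cap is not None and len(pairs) > cap:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(pairs), size=cap, replace=False)
        pairs = [pairs[i] for i in sorted(chosen)]
    aligner = make_aligner()
    values = np.array(
        [identity_pair(records[i].residues, records[j].residues, aligner) for i, j in pairs]
    )
    return IdentityDistribution(values, len(pairs), provenance)


@dataclass
class DistanceReport:
    """Two-sample distribution distances and the rank-biserial effect size."""

    wasserstein: float
    ks_stat: float
    ks_p: float
    cvm_stat: float
    cvm_p: float
    u_stat: float
    effect_size_r: float


def dist_compare(a: np.ndarray, b: np.ndarray) -> DistanceReport:
    """Compare two 1-D samples (each with >= 2 points)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 points")
    w = stats.wasserstein_distance(a, b)
    ks = stats.ks_2samp(a, b)
    cvm = stats.cramervonmises_2samp(a, b)
    u = stats.mannwhitneyu(a, b, alternative="two-sided")
    r = 1.0 - 2.0 * u.statistic / (len(a) * len(b))
    return DistanceReport(
        float(w),
        float(ks.statistic),
        float(ks.pvalue),
        float(cvm.statistic),
        float(cvm.pvalue),
        float(u.statistic),
        float(r),
    )


def greedy_cluster(
    seqs: SequenceSet | list[SequenceRecord], threshold: float
) -> list[list[str]]:
    """Longest-first greedy incremental clustering at a fractional identity threshold.

    Each sequence joins the first existing cluster whose representative (its
    founding, longest member) it matches at >= threshold identity, else founds a
    new cluster. Deterministic: ties in length broken by id.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    records = sorted(seqs, key=lambda r: (-len(r), r.id))
    aligner = make_aligner()
    reps: list[SequenceRecord] = []
    clusters: list[list[str]] = []
    for rec in records:
        placed = False
        for rep, cluster in zip(reps, clusters):
            if identity_pair(rep.residues, rec.residues, aligner) >= 100.0 * threshold:
                cluster.append(rec.id)
                placed = True
                break
        if not placed:
            reps.append(rec)
            clusters.append([rec.id])
    return clusters


@dataclass
class StabilityReport:
    """Per clustering level: identity distributions of repeated draws and
    between-draw distance summaries."""

    draws: dict  # (class, level) -> list[IdentityDistribution]
    summary: pd.DataFrame


def sampling_stability(
    seqs: SequenceSet,
    labels: LabelTable,
    n_draws: int = 30,
    n: int = 300,
    thresholds: tuple[float | None, ...] = (None, 0.90, 0.75, 0.50),
    seed: int | None = None,
    pair_cap: int = 200,
) -> StabilityReport:
    """Stability of identity distributions under repeated random subsampling.

    For each subfamily and each clustering level (no clustering, then greedy
    redundancy reduction at the given thresholds), draw ``n_draws`` random
    subsets of ``n`` sequences (or all, if fewer), compute each draw's identity
    distribution, and compare all draw pairs; the summary reports the median and
    maximum of each distance statistic per (class, level).
    """
    rng = np.random.default_rng(seed)
    draws: dict = {}
    rows = []
    for code in labels.vocabulary:
        members = [seqs[i] for i in labels.ids_for(code) if i in seqs]
        if len(members) < 2:
            raise ValueError(f"subfamily {code!r} has fewer than 2 sequences")
        for level in thresholds:
            if level is None:
                pool = members
            else:
                reps = {c[0] for c in greedy_cluster(members, level)}
                pool = [r for r in members if r.id in reps]
            if len(pool) < 2:
                warnings.warn(
                    f"subfamily {code!r}: clustering at {level} leaves fewer than 2"
                    " representatives; level skipped",
                    stacklevel=2,
                )
                continue
            level_draws = []
            for _ in range(n_draws):
                k = min(n, len(pool))
                chosen = rng.choice(len(pool), size=k, replace=False)
                subset = [pool[i] for i in sorted(chosen)]
                if len(subset) < 2:
                    raise ValueError(f"subfamily {code!r}: draw too small at level {level}")
                level_draws.append(
                    pairwise_identity(
                        subset, cap=pair_cap, seed=int(rng.integers(2**31))
                    )
                )
            draws[(code, level)] = level_draws
            reports = [
                dist_compare(x.values, y.values)
                for x, y in itertools.combinations(level_draws, 2)
            ]
            for stat in ["wasserstein", "ks_stat", "cvm_stat", "effect_size_r"]:
                vals = np.array([abs(getattr(r, stat)) for r in reports])
                rows.append(
                    (code, "none" if level is None else level, stat,
                     float(np.median(vals)), float(vals.max()))
                )
    summary = pd.DataFrame(
        rows, columns=["class", "level", "statistic", "median", "max"]
    )
    return StabilityReport(draws, summary)
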