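"""Readers/writers for the formats the pipeline touches, plus packaged fixtures.

Sequences travel as FASTA (via Bio.SeqIO), motifs as MEME minimal motif format
(hand-parsed here: Biopython's minimal-format reader is nucleotide-only), and
per-sequence subfamily labels as two-column TSV. The packaged fixtures transcribe
the published tables for the ten reference TetR-family regulators: the 37 curated
C-terminal-domain motifs and the PROSITE patterns proposed for them.

Coordinates are 1-based inclusive throughout. A ``SequenceSet`` records how many
N-terminal residues were trimmed (``truncated_prefix``) so motif positions can be
reported in full-protein numbering.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .alphabet import AA_INDEX, AMINO_ACIDS, SEQUENCE_ALPHABET

__all__ = [
    "SequenceRecord",
    "SequenceSet",
    "MotifMatrix",
    "LabelTable",
    "read_fasta",
    "write_fasta",
    "read_meme",
    "write_meme",
    "read_label_table",
    "write_label_table",
    "load_reference_proteins",
    "load_curated_motifs",
    "load_prosite_patterns",
    "load_swissprot_composition",
    "curated_motif_matrices",
    "synthetic_carrier_sequences",
]

_DATA = resources.files("tfrmotifs") / "data"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: unique id, free-text description, residues."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-amino-acid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """An ordered, id-unique collection of sequences.

    ``truncated_prefix`` counts residues removed from the N-terminus of every
    record, so positions reported on the truncated set map back to full-protein
    numbering as ``full_pos = pos + truncated_prefix``.
    """

    records: list[SequenceRecord]
    truncated_prefix: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
        self._by_id = {rec.id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self._by_id[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def truncate(self, n_residues: int) -> "SequenceSet":
        """Trim ``n_residues`` from every N-terminus (drops nothing; errors instead)."""
        if n_residues < 0:
            raise ValueError("n_residues must be >= 0")
        too_short = [r.id for r in self.records if len(r) <= n_residues]
        if too_short:
            raise ValueError(
                f"cannot truncate {n_residues} residues: sequences too short: {too_short}"
            )
        recs = [
            SequenceRecord(r.id, r.description, r.residues[n_residues:])
            for r in self.records
        ]
        return SequenceSet(recs, truncated_prefix=self.truncated_prefix + n_residues)


@dataclass
class MotifMatrix:
    """A position probability matrix over the 20 amino acids.

    ``probs`` has shape (width, 20) with rows summing to 1; ``background`` is the
    0th-order model the motif was discovered against; ``nsites`` the number of
    sites the matrix was estimated from.
    """

    motif_id: str
    probs: np.ndarray
    nsites: int = 20
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 1.0 / 20.0)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 20:
            raise ValueError(f"motif {self.motif_id!r}: probs must be width x 20")
        if not 1 <= self.width <= 100:
            raise ValueError(f"motif {self.motif_id!r}: width {self.width} out of [1, 100]")
        if (self.probs < 0).any():
            raise ValueError(f"motif {self.motif_id!r}: negative probabilities")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.motif_id!r}: rows must sum to 1")
        if self.background.shape != (20,) or not np.isclose(
            self.background.sum(), 1.0, atol=1e-9
        ):
            raise ValueError(f"motif {self.motif_id!r}: invalid background")
        if self.nsites <= 0:
            raise ValueError(f"motif {self.motif_id!r}: nsites must be > 0")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        """Most probable residue per column (no ambiguity letters)."""
        return "".join(AMINO_ACIDS[i] for i in self.probs.argmax(axis=1))


class LabelTable:
    """Mapping sequence id -> subfamily code over a finite vocabulary."""

    def __init__(self, mapping: Mapping[str, str]):
        self.mapping: dict[str, str] = dict(mapping)
        self.vocabulary: tuple[str, ...] = tuple(sorted(set(self.mapping.values())))

    def __getitem__(self, seq_id: str) -> str:
        return self.mapping[seq_id]

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.mapping

    def items(self):
        return self.mapping.items()

    def ids_for(self, code: str) -> list[str]:
        return [i for i, c in self.mapping.items() if c == code]

    def missing_from(self, seqs: SequenceSet) -> list[str]:
        """Label ids absent from an accompanying sequence set (warning list)."""
        return [i for i in self.mapping if i not in seqs]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file into a SequenceSet, preserving record order.

    Ids are the first whitespace token of the header; residues are uppercased
    and validated against the amino-acid alphabet (plus X).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, desc, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet | Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in seqs
    ]
    if not bio:
        raise ValueError("refusing to write an empty FASTA file")
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme(path: str | Path) -> list[MotifMatrix]:
    """Parse a MEME minimal motif file of protein motifs.

    Requires ``alength= 20``; rows must sum to 1 within 1e-3 and are then
    renormalized exactly. A file-level background block, if present, is attached
    to every motif; otherwise the background is uniform.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    background = np.full(20, 1.0 / 20.0)
    motifs: list[MotifMatrix] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            tokens: list[str] = []
            i += 1
            while i < n and lines[i].strip() and not lines[i].startswith("MOTIF"):
                tokens.extend(lines[i].split())
                i += 1
            pairs = dict(zip(tokens[0::2], tokens[1::2]))
            missing = [a for a in AMINO_ACIDS if a not in pairs]
            if missing:
                raise ValueError(f"background block missing letters {missing}")
            background = np.array([float(pairs[a]) for a in AMINO_ACIDS])
            background = background / background.sum()
            continue
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"MOTIF line without an id: {line!r}")
            motif_id = parts[1]
            i += 1
            while i < n and "letter-probability matrix" not in lines[i]:
                if lines[i].startswith("MOTIF"):
                    raise ValueError(f"motif {motif_id!r}: no letter-probability matrix")
                i += 1
            if i >= n:
                raise ValueError(f"motif {motif_id!r}: no letter-probability matrix")
            header = lines[i]
            toks = header.split()
            kv: dict[str, str] = {}
            for j, t in enumerate(toks):
                if t.endswith("=") and j + 1 < len(toks):
                    kv[t[:-1]] = toks[j + 1]
            alength = int(kv.get("alength", "20"))
            if alength != 20:
                raise ValueError(
                    f"motif {motif_id!r}: alength= {alength}, protein motifs need 20"
                )
            width = int(kv["w"])
            nsites = int(float(kv.get("nsites", "20")))
            rows = []
            i += 1
            for r in range(width):
                while i < n and not lines[i].strip():
                    i += 1
                if i >= n:
                    raise ValueError(f"motif {motif_id!r}: truncated matrix at row {r}")
                vals = np.array([float(v) for v in lines[i].split()])
                if vals.size != 20:
                    raise ValueError(
                        f"motif {motif_id!r}: row {r} has {vals.size} columns, expected 20"
                    )
                if abs(vals.sum() - 1.0) > 1e-3:
                    raise ValueError(
                        f"motif {motif_id!r}: row {r} sums to {vals.sum():.6f}, not 1"
                    )
                rows.append(vals / vals.sum())
                i += 1
            motifs.append(
                MotifMatrix(motif_id, np.vstack(rows), nsites=nsites, background=background)
            )
            continue
        i += 1
    if not motifs:
        raise ValueError(f"no MOTIF blocks found in {path}")
    return motifs


def write_meme(
    motifs: list[MotifMatrix],
    path: str | Path,
    background: np.ndarray | None = None,
) -> None:
    """Write motifs in MEME minimal format (consumable by MEME-suite tools)."""
    if not motifs:
        raise ValueError("refusing to write an empty motif file")
    if background is None:
        background = motifs[0].background
    background = np.asarray(background, dtype=float)
    buf = _stdio.StringIO()
    buf.write("MEME version 4\n\n")
    buf.write(f"ALPHABET= {AMINO_ACIDS}\n\n")
    buf.write("Background letter frequencies\n")
    buf.write(
        " ".join(f"{a} {f:.6f}" for a, f in zip(AMINO_ACIDS, background)) + "\n\n"
    )
    for m in motifs:
        buf.write(f"MOTIF {m.motif_id}\n")
        buf.write(
            f"letter-probability matrix: alength= 20 w= {m.width} nsites= {m.nsites} E= 0\n"
        )
        for row in m.probs:
            buf.write(" " + " ".join(f"{v:.6g}" for v in row) + "\n")
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# label tables

_HEADER_TOKENS = {"id", "seq_id", "sequence_id", "code", "subfamily", "label", "class"}


def read_label_table(path: str | Path) -> LabelTable:
    """Read a two-column (id, subfamily code) TSV; header row optional.

    Duplicate ids with the same code are deduplicated; conflicting codes are a
    hard error.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            seq_id, code = parts[0].strip(), parts[1].strip()
            if lineno == 1 and {seq_id.lower(), code.lower()} & _HEADER_TOKENS:
                continue
            if seq_id in mapping and mapping[seq_id] != code:
                raise ValueError(
                    f"id {seq_id!r} mapped to both {mapping[seq_id]!r} and {code!r}"
                )
            mapping[seq_id] = code
    if not mapping:
        raise ValueError(f"no label rows found in {path}")
    return LabelTable(mapping)


def write_label_table(labels: LabelTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsubfamily\n")
        for seq_id, code in labels.items():
            fh.write(f"{seq_id}\t{code}\n")


# ---------------------------------------------------------------------------
# packaged fixtures


def _read_data_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_reference_proteins() -> pd.DataFrame:
    """The ten reference TFRs (protein tag, subfamily, UniProt id, organism, role)."""
    return _read_data_tsv("tfr_reference_proteins.tsv")


def load_curated_motifs() -> pd.DataFrame:
    """The 37 curated CTD motifs: consensus, matched sequence, positions, q-value.

    The ``discrepancy`` column flags rows transcribed as printed despite an
    internal inconsistency (tFadR-2: 14-position span vs 15-residue match).
    """
    df = _read_data_tsv("curated_motifs.tsv")
    df["discrepancy"] = df["discrepancy"].fillna("")
    return df


def load_prosite_patterns() -> pd.DataFrame:
    """Published PROSITE patterns with expected-random-match counts and verdicts."""
    df = _read_data_tsv("prosite_patterns.tsv")
    df["erm"] = pd.to_numeric(df["erm"], errors="coerce")  # "n/a" -> NaN
    return df


def load_swissprot_composition() -> np.ndarray:
    """Swiss-Prot residue composition as 20 frequencies in alphabet order."""
    df = _read_data_tsv("swissprot_composition.tsv")
    freq = np.zeros(20)
    for _, row in df.iterrows():
        freq[AA_INDEX[row["residue"]]] = float(row["percent"])
    return freq / freq.sum()


def curated_motif_matrices() -> list[MotifMatrix]:
    """Position probability matrices for the 37 curated motifs.

    The published PWMs themselves are not redistributable, so these are synthetic
    reconstructions from the consensus/matched-sequence pairs: each column puts
    most of its mass on the consensus letter (split across its pair for the
    ambiguity codes B/Z/J), a large share on the letter matched in the reference
    protein, and a flat 5% residue floor. They are sharp enough that the matched
    sequence is the top-scoring window of its reference protein, which is the
    property the pipeline exercises.
    """
    table = load_curated_motifs()
    uniform = np.full(20, 1.0 / 20.0)
    motifs: list[MotifMatrix] = []
    for _, row in table.iterrows():
        cons, matched = row["consensus"], row["matched"]
        if len(cons) != len(matched):
            raise AssertionError(f"{row['motif_id']}: consensus/matched length mismatch")
        probs = np.zeros((len(cons), 20))
        for i, (c, m) in enumerate(zip(cons, matched)):
            w = 0.05 * uniform.copy()
            if c in AA_INDEX:
                if c == m:
                    w[AA_INDEX[c]] += 0.95
                else:
                    w[AA_INDEX[c]] += 0.55
                    w[AA_INDEX[m]] += 0.40
            else:  # ambiguity pair
                from .alphabet import AMBIGUITY

                pair = sorted(AMBIGUITY[c])
                if m in pair:
                    other = pair[0] if pair[1] == m else pair[1]
                    w[AA_INDEX[m]] += 0.60
                    w[AA_INDEX[other]] += 0.35
                else:
                    w[AA_INDEX[pair[0]]] += 0.45
                    w[AA_INDEX[pair[1]]] += 0.30
                    w[AA_INDEX[m]] += 0.20
            probs[i] = w / w.sum()
        motifs.append(
            MotifMatrix(row["motif_id"], probs, nsites=int(row["n_sequences"]))
        )
    return motifs


def synthetic_carrier_sequences(seed: int = 0) -> SequenceSet:
    """Synthetic stand-ins for the ten reference protein sequences.

    The true UniProt sequences are not shipped; each carrier embeds every curated
    matched sequence of its protein at the printed 1-based positions (the flagged
    tFadR-2 row plants its full 15-mer from position 110), with uniform-background
    residues elsewhere. Overlapping motif rows are cross-checked for consistency.
    Record ids are the protein tags; descriptions carry the UniProt accession and
    a ``synthetic carrier`` label.
    """
    table = load_curated_motifs()
    proteins = load_reference_proteins().set_index("protein")
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    for protein, rows in table.groupby("protein", sort=False):
        length = int(max(r["start"] + len(r["matched"]) - 1 for _, r in rows.iterrows())) + 20
        residues = list(rng.choice(list(AMINO_ACIDS), size=length))
        written: dict[int, str] = {}
        for _, r in rows.iterrows():
            for offset, letter in enumerate(r["matched"]):
                pos = int(r["start"]) + offset  # 1-based
                if pos in written and written[pos] != letter:
                    raise AssertionError(
                        f"{protein}: inconsistent overlap at position {pos}"
                    )
                written[pos] = letter
                residues[pos - 1] = letter
        acc = proteins.loc[protein, "uniprot_id"]
        records.append(
            SequenceRecord(
                protein,
                f"UniProt {acc} synthetic carrier (planted curated motifs)",
                "".join(residues),
            )
        )
    return SequenceSet(records)
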