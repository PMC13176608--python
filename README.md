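# tfrmotifs

Conserved C-terminal-domain (CTD) motif analysis for TetR-family regulators
(TFRs).

TFRs are one of the largest families of bacterial transcription factors. Their
N-terminal DNA-binding domain is strongly conserved, but the C-terminal
ligand-binding domain is highly variable — average pairwise identity across the
family is only a few percent — which is exactly why conserved CTD motifs, where
they exist, are informative: they mark subfamily membership and often contain
the residues that contact the effector ligand. This package provides the
computational machinery for discovering, selecting and exploiting such motifs,
together with a curated fixture set of 37 CTD motifs from ten well-characterized
TFRs (TetR, EthR, RamR, EilR, EbrA, TtgR, two FadRs, DesT, KstR2) and the
PROSITE signature patterns proposed for them.

## What it computes

* **PWM scanning** (`tfrmotifs.scanner`) — FIMO-style log-odds scores in bits,
  `s(w) = Σᵢ log₂((pᵢ(wᵢ) + α·bᵢ)/((1+α)·b(wᵢ)))` against a 0th-order
  background; *exact* p-values by dynamic programming on a discretized score
  lattice; Benjamini–Hochberg q-values per motif over all scanned windows; hit
  calling at the stringent q ≤ 10⁻⁴ cutoff used for the curated set.
* **Consensus motif selection** (`tfrmotifs.feature_select`) — the
  machine-learning protocol for finding subfamily-characteristic motifs:
  balanced downsampling (300 per subfamily), per-predictor centering/scaling,
  stratified 3:1 split, 3×3 repeated cross-validation of six classifier
  families, a 60% best-resample accuracy gate, per-class permutation
  importances max-scaled to 100 per model, and selection of motifs that clear a
  cutoff in *all* surviving models. Exposed statsmodels-style:
  `MotifSelectionModel(features, labels).fit(seed)` returns a results object
  with an accuracy table, importance report, per-subfamily selection and
  `summary()`.
* **Conservation** (`tfrmotifs.conservation`) — occurrence stacks (ungapped
  alignments of fixed-width hits), per-column frequencies, entropy and
  information content `IC = log₂20 − H` (so a fully conserved column reaches
  ≈ 4.32 bits), sequence-logo letter heights, consensus strings with the
  ambiguity codes B (D/N), Z (E/Q), J (I/L), and 1–9 conservation grades.
* **PROSITE patterns** (`tfrmotifs.prosite`) — parser/matcher for the pattern
  subset used by the curated signatures, automatic pattern derivation from
  column profiles, and expected-random-match (ERM) estimates: the product of
  per-element residue-class probabilities under a Swiss-Prot composition,
  scaled to 50,000,000 residues (~100,000 sequences).
* **Similarity diagnostics** (`tfrmotifs.simstats`) — global-alignment
  pairwise identity (BLOSUM62, gap −10/−0.5), Wasserstein/KS/Cramér–von Mises
  distances and the rank-biserial Mann–Whitney effect size, a greedy
  longest-first clustering stand-in for CD-HIT, and the 30-draws-of-300
  subsampling-stability control.
* **Synthetic data** (`tfrmotifs.synthetic`) — subfamily-structured datasets
  with planted motifs and a full truth table, including a `paper-small` preset
  (14 subfamilies, 300 sequences each with one of 104) so every stage can be
  validated against known ground truth.

## Worked example

Scan the packaged reference carrier for *Streptomyces lividans* EbrA with the
EbrA-3 motif, then derive a signature-style report for the RamR-2 pattern:

```python
import tfrmotifs as tm
from tfrmotifs.prosite import parse_pattern, expected_random_matches, signature_report

carriers = tm.synthetic_carrier_sequences()          # ten reference proteins
motifs = {m.motif_id: m for m in tm.curated_motif_matrices()}

for h in tm.scan(carriers, [motifs["EbrA-3"]]):
    print(f"{h.motif_id}  {h.seq_id}  {h.start}-{h.stop}  {h.matched}"
          f"  score={h.score:.2f} bits  q={h.q_value:.2e}")

pat = parse_pattern("K-x(3)-[RH]-x-[IV]-W-N-S-Y-[IV]-x-W")   # RamR-2 signature
erm = expected_random_matches(pat)
rep = signature_report(pat, erm)
print(f"RamR-2 signature: {pat.text}  ERM={erm:.3g}  -> {rep.recommendation}")
```

prints

```
EbrA-3  Sli_EbrA  99-107  DRTGVELEY  score=38.14 bits  q=3.30e-09
RamR-2 signature: K-x(3)-[RH]-x-[IV]-W-N-S-Y-[IV]-x-W  ERM=3.54e-05  -> YES
```

The hit sits at positions 99–107 of EbrA (full-protein numbering), exactly the
annotated EbrA-3 occurrence; the signature's expected count of ~3.5 random
matches per hundred million residues marks it as specific enough to use as a
subfamily signature.

From the shell, the same stages are available as `tfrmotifs simulate | scan |
select | logo | pattern | simstats | annotate`; `tfrmotifs annotate --fasta
new.fasta` checks an uncharacterized TFR against the curated motif set and
reports, per hit, the source regulator, its subfamily, and how many distinct
motifs of that regulator were found (more matched motifs means a stronger
functional hint).

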