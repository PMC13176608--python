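"""Log-odds scoring, exact p-values, FDR filtering and feature extraction."""

import itertools
import math

import numpy as np
import pytest

import tfrmotifs as tm
from tfrmotifs.alphabet import AA_INDEX, AMINO_ACIDS
from tfrmotifs.io import MotifMatrix, SequenceRecord, SequenceSet
from tfrmotifs.scanner import (
    BackgroundModel,
    LogOddsMatrix,
    best_scores,
    exact_pvalue_table,
    log_odds,
    scan,
    score_distribution_summary,
    window_score,
)


@pytest.fixture(scope="module")
def random_motif3():
    rng = np.random.default_rng(1)
    return MotifMatrix("w3", rng.dirichlet(np.ones(20), size=3))


@pytest.fixture(scope="module")
def skew_background():
    rng = np.random.default_rng(2)
    return BackgroundModel(rng.dirichlet(np.ones(20) * 5))


class TestLogOdds:
    def test_motif_equal_to_background_scores_zero(self, skew_background):
        m = MotifMatrix("bg", np.tile(skew_background.freqs, (4, 1)))
        lom = log_odds(m, skew_background, pseudocount=0.0)
        assert np.allclose(lom.scores, 0.0, atol=1e-12)

    def test_certain_letter_uniform_background_gives_log2_20(self):
        probs = np.zeros((1, 20))
        probs[0, AA_INDEX["A"]] = 1.0
        lom = log_odds(MotifMatrix("sharp", probs), BackgroundModel.uniform(), 0.0)
        assert lom.scores[0, AA_INDEX["A"]] == pytest.approx(math.log2(20), abs=1e-9)

    def test_matches_direct_recomputation_with_pseudocount(self, skew_background):
        rng = np.random.default_rng(3)
        m = MotifMatrix("w2", rng.dirichlet(np.ones(20), size=2))
        lom = log_odds(m, skew_background, pseudocount=0.01)
        for i in range(2):
            for a in range(20):
                bg = skew_background.freqs[a]
                expected = math.log2((m.probs[i, a] + 0.01 * bg) / (1.01 * bg))
                assert lom.scores[i, a] == pytest.approx(expected, abs=1e-12)


class TestWindowScore:
    def test_zero_matrix_scores_zero(self):
        lom = LogOddsMatrix("z", np.zeros((5, 20)))
        assert window_score(lom, "MKVLW") == 0.0

    def test_width_one_equals_lookup(self, random_motif3, skew_background):
        lom = log_odds(random_motif3, skew_background)
        one = LogOddsMatrix("w1", lom.scores[:1])
        assert window_score(one, "K") == pytest.approx(lom.scores[0, AA_INDEX["K"]])

    def test_equals_brute_force_sum(self, random_motif3, skew_background):
        lom = log_odds(random_motif3, skew_background)
        window = "WKD"
        expected = sum(lom.scores[i, AA_INDEX[c]] for i, c in enumerate(window))
        assert window_score(lom, window) == pytest.approx(expected, abs=1e-12)

    def test_x_contributes_zero(self, random_motif3, skew_background):
        lom = log_odds(random_motif3, skew_background)
        assert window_score(lom, "WXD") == pytest.approx(
            lom.scores[0, AA_INDEX["W"]] + lom.scores[2, AA_INDEX["D"]]
        )

    def test_invalid_residue_rejected(self, random_motif3, skew_background):
        lom = log_odds(random_motif3, skew_background)
        with pytest.raises(ValueError):
            window_score(lom, "WK*")


class TestExactPvalues:
    def test_width_one_best_score_pvalue_is_letter_frequency(self, skew_background):
        probs = np.zeros((1, 20))
        best = int(skew_background.freqs.argmin())  # rarest letter scores highest
        probs[0, best] = 1.0
        m = MotifMatrix("w1", probs)
        sd = exact_pvalue_table(m, skew_background, pseudocount=0.01)
        lom = log_odds(m, skew_background, pseudocount=0.01)
        p = sd.pvalue(float(lom.scores[0, best]))
        assert p == pytest.approx(skew_background.freqs[best], rel=1e-9)

    @pytest.mark.parametrize("width", [1, 2, 3])
    def test_dp_tail_matches_exhaustive_enumeration(self, width, skew_background):
        """The lattice DP reproduces brute-force enumeration over all 20^w
        windows, up to the discretization margin of w bins."""
        rng = np.random.default_rng(width)
        m = MotifMatrix(f"w{width}", rng.dirichlet(np.ones(20), size=width))
        sd = exact_pvalue_table(m, skew_background)
        lom = log_odds(m, skew_background)
        scores = np.zeros(20**width)
        probs = np.ones(20**width)
        for k, combo in enumerate(itertools.product(range(20), repeat=width)):
            for i, a in enumerate(combo):
                scores[k] += lom.scores[i, a]
                probs[k] *= skew_background.freqs[a]
        margin = width / sd.granularity
        for q in [0.999, 0.99, 0.9, 0.5, 0.1, 0.01, 0.001]:
            s = float(np.quantile(scores, q))
            p_dp = sd.pvalue(s)
            upper = probs[scores >= s - margin].sum()
            lower = probs[scores >= s + margin].sum()
            assert lower - 1e-12 <= p_dp <= upper + 1e-12

    def test_pmf_sums_to_one_and_tail_monotone(self, random_motif3, skew_background):
        sd = exact_pvalue_table(random_motif3, skew_background)
        assert sd.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(sd.tail) <= 1e-15).all()

    def test_refining_granularity_changes_little(self, random_motif3, skew_background):
        coarse = exact_pvalue_table(random_motif3, skew_background, granularity=500)
        fine = exact_pvalue_table(random_motif3, skew_background, granularity=1000)
        lom = log_odds(random_motif3, skew_background)
        for s in [0.0, 2.0, 5.0]:
            # refinement moves a p-value by at most the mass near the score's bin
            k = int(np.floor(s * 500)) - coarse.offset
            local = coarse.pmf[max(0, k - 3) : k + 4].sum()
            assert abs(coarse.pvalue(s) - fine.pvalue(s)) <= local + 1e-12

    def test_granularity_floor_enforced(self, random_motif3, skew_background):
        with pytest.raises(ValueError):
            exact_pvalue_table(random_motif3, skew_background, granularity=10)


class TestScan:
    def test_planted_sharp_motif_found_at_planted_start(self):
        rng = np.random.default_rng(5)
        consensus = "WDRTGVELEY"
        motif = tm.make_planted_motif(10, 0.98, consensus, motif_id="sharp")
        records = []
        for k in range(30):
            residues = list(rng.choice(list(AMINO_ACIDS), size=80))
            residues[37:47] = consensus
            records.append(SequenceRecord(f"s{k:02d}", "", "".join(residues)))
        seqs = SequenceSet(records)
        hits = scan(seqs, [motif])
        assert {(h.seq_id, h.start) for h in hits} >= {(f"s{k:02d}", 38) for k in range(30)}
        for h in hits:
            assert h.stop == h.start + 9
            assert h.matched == seqs[h.seq_id].residues[h.start - 1 : h.stop]

    def test_pure_x_sequence_yields_no_hits(self, curated_matrices):
        seqs = SequenceSet([SequenceRecord("nx", "", "X" * 100)])
        assert scan(seqs, curated_matrices[:3]) == []

    def test_published_ebra3_position(self, carriers, curated_matrices):
        ebra3 = [m for m in curated_matrices if m.motif_id == "EbrA-3"]
        hits = scan(carriers, ebra3)
        mine = [h for h in hits if h.seq_id == "Sli_EbrA"]
        assert len(mine) == 1
        assert (mine[0].start, mine[0].stop, mine[0].matched) == (99, 107, "DRTGVELEY")

    def test_empty_motif_list_rejected(self, carriers):
        with pytest.raises(ValueError):
            scan(carriers, [])

    def test_short_sequences_skipped_not_fatal(self, curated_matrices):
        seqs = SequenceSet([SequenceRecord("short", "", "MK")])
        assert scan(seqs, curated_matrices[:1]) == []

    def test_deterministic_and_order_invariant(self, small_planted):
        seqs, _, _, motifs = small_planted
        hits1 = scan(seqs, motifs)
        shuffled = SequenceSet(list(reversed(seqs.records)))
        hits2 = scan(shuffled, motifs)
        key = lambda h: (h.motif_id, h.seq_id, h.start)
        assert sorted(key(h) for h in hits1) == sorted(key(h) for h in hits2)
        s1 = {key(h): h.score for h in hits1}
        s2 = {key(h): h.score for h in hits2}
        assert s1 == s2

    def test_bh_hit_set_monotone_in_threshold(self, small_planted):
        seqs, _, _, motifs = small_planted
        keys = lambda hits: {(h.motif_id, h.seq_id, h.start) for h in hits}
        previous = None
        for alpha in [1e-2, 1e-4, 1e-6]:
            current = keys(scan(seqs, motifs, q_threshold=alpha))
            if previous is not None:
                assert current <= previous
            previous = current


class TestBestScores:
    def test_table_shape_zero_rows_and_max_semantics(self, small_planted):
        seqs, _, truth, motifs = small_planted
        hits = scan(seqs, motifs)
        table = best_scores(hits, seqs, motifs)
        assert table.shape == (len(seqs), len(motifs))
        hit_ids = {h.seq_id for h in hits}
        for sid in seqs.ids:
            if sid not in hit_ids:
                assert (table.loc[sid] == 0).all()
        by_pair = {}
        for h in hits:
            by_pair.setdefault((h.seq_id, h.motif_id), []).append(h.score)
        for (sid, mid), scores in by_pair.items():
            assert table.at[sid, mid] == pytest.approx(max(scores))


class TestScoreSummary:
    def _hit(self, score, i=0):
        return tm.MotifHit("m", f"s{i}", 1, 3, "AAA", score, 1e-9, 1e-9)

    def test_single_hit_all_five_numbers_equal(self):
        df = score_distribution_summary([self._hit(7.5)])
        row = df.iloc[0]
        assert row["min"] == row["q1"] == row["median"] == row["q3"] == row["max"] == 7.5

    def test_five_point_sample_quartiles(self):
        values = [1.0, 2.0, 3.0, 4.0, 10.0]
        df = score_distribution_summary([self._hit(v, i) for i, v in enumerate(values)])
        row = df.iloc[0]
        assert (row["q1"], row["median"], row["q3"]) == (2.0, 3.0, 4.0)

    def test_outlier_beyond_whiskers_excluded(self):
        base = [10.0, 11.0, 12.0, 13.0, 14.0]
        df1 = score_distribution_summary([self._hit(v, i) for i, v in enumerate(base)])
        df2 = score_distribution_summary(
            [self._hit(v, i) for i, v in enumerate(base + [99.0])]
        )
        assert df2.iloc[0]["max"] == df1.iloc[0]["max"] == 14.0
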