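import numpy as np
import pytest

from dctmosaic import (
    ClassifierConfig,
    Interval,
    TransferConfig,
    classify_windows,
    paint_genome,
    score_window_aligned,
    score_window_mapping,
    simulate_transconjugant,
    tile_windows,
)
from dctmosaic.windows import ClassifierError, _aligned_identities

from conftest import hamming_identity, truth_majority_vote


class TestTileWindows:
    def test_exact_tiling(self):
        ivs = tile_windows(2000, 500)
        assert [(iv.start, iv.end) for iv in ivs] == [
            (0, 500), (500, 1000), (1000, 1500), (1500, 2000)
        ]

    def test_tail_at_least_half_window_stands_alone(self):
        ivs = tile_windows(1300, 500)
        assert [(iv.start, iv.end) for iv in ivs] == [
            (0, 500), (500, 1000), (1000, 1300)
        ]

    def test_short_tail_merged_into_last_window(self):
        ivs = tile_windows(1100, 500)
        assert [(iv.start, iv.end) for iv in ivs] == [(0, 500), (500, 1100)]

    def test_genome_shorter_than_window(self):
        with pytest.raises(ClassifierError, match="genome shorter than window"):
            tile_windows(400, 500)

    @pytest.mark.parametrize("length", [5_000, 5_249, 5_250, 5_777])
    def test_tiling_covers_genome_disjointly(self, length):
        ivs = tile_windows(length, 500)
        cursor = 0
        for iv in ivs:
            assert iv.start == cursor
            cursor = iv.end
        assert cursor == length


class TestAlignedScoring:
    def test_identical_to_both(self):
        assert score_window_aligned("ACGT", "ACGT", "ACGT") == (1.0, 1.0)

    def test_arithmetic(self):
        rec = "A" * 500
        win = "C" * 5 + "A" * 495
        assert score_window_aligned(win, rec, win) == (0.99, 1.0)

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ClassifierError, match="frame mismatch"):
            score_window_aligned("ACGT", "ACG", "ACGT")

    def test_n_counts_as_mismatch_to_every_parent(self):
        id_r, id_d = score_window_aligned("NNAA", "NNAA", "AAAA")
        assert id_r == 0.5  # N positions do not match even an N parent
        assert id_d == 0.5

    def test_matches_hamming_oracle_on_seeded_windows(self, small_cross):
        rec, don, tc, _ = small_cross
        ivs = tile_windows(len(tc), 500)
        scored = _aligned_identities(tc, rec, don, ivs)
        rng = np.random.default_rng(0)
        for iv, id_r, id_d in [scored[i] for i in rng.choice(len(scored), 40)]:
            w = tc.sequence[iv.start : iv.end]
            assert id_r == pytest.approx(
                hamming_identity(w, rec.sequence[iv.start : iv.end])
            )
            assert id_d == pytest.approx(
                hamming_identity(w, don.sequence[iv.start : iv.end])
            )

    def test_monotone_in_donor_specific_variants(self):
        """Adding donor-specific variants to a window never raises the
        recipient identity."""
        rng = np.random.default_rng(1)
        bases = "ACGT"
        rec = "".join(bases[i] for i in rng.integers(0, 4, 500))
        win = list(rec)
        prev = 1.0
        for pos in rng.choice(500, 50, replace=False):
            win[pos] = bases[(bases.index(win[pos]) + 1) % 4]
            id_r, _ = score_window_aligned("".join(win), rec, "".join(win))
            assert id_r <= prev
            prev = id_r


class TestMappingScoring:
    def test_verbatim_window_scores_one(self, small_pair):
        rec, _, _ = small_pair
        assert score_window_mapping(rec.sequence[40_000:40_500], rec) == 1.0

    def test_random_window_scores_zero(self, small_pair):
        rec, _, _ = small_pair
        rng = np.random.default_rng(0)
        win = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        assert score_window_mapping(win, rec) == 0.0

    def test_matches_exhaustive_scan_oracle(self, small_pair):
        """Seeded identity equals the best identity over every possible
        placement of the window in the parent."""
        import edlib

        from dctmosaic import Genome

        rec, _, _ = small_pair
        parent = Genome("p", rec.sequence[:5_000])
        win = list(parent.sequence[2_000:2_500])
        for pos in (10, 200, 400):
            win[pos] = "A" if win[pos] != "A" else "C"
        window = "".join(win)
        got = score_window_mapping(window, parent)
        best = min(
            edlib.align(window, parent.sequence[s : s + 500], mode="NW",
                        task="distance")["editDistance"]
            for s in range(0, len(parent) - 500 + 1)
        )
        assert got == pytest.approx(1 - best / 500)
        assert got == pytest.approx(0.994)


class TestClassifyWindows:
    def _scored(self, identities):
        return [
            (Interval(i * 500, (i + 1) * 500), r, d)
            for i, (r, d) in enumerate(identities)
        ]

    def test_perfect_tie_inherits_previous_origin(self):
        calls = classify_windows(
            self._scored([(1.0, 0.99), (1.0, 1.0), (0.99, 1.0)])
        )
        assert [c.origin for c in calls] == ["recipient", "recipient", "donor"]
        assert calls[1].ambiguous_inherited

    def test_first_window_tie_falls_back_to_background(self):
        calls = classify_windows(self._scored([(1.0, 1.0)]), background="recipient")
        assert calls[0].origin == "recipient"
        assert calls[0].ambiguous_inherited
        calls = classify_windows(self._scored([(1.0, 1.0)]), background="donor")
        assert calls[0].origin == "donor"

    def test_imperfect_tie_uses_lookback_and_is_flagged(self):
        calls = classify_windows(
            self._scored([(0.9, 0.99), (0.95, 0.95), (1.0, 0.9)])
        )
        assert [c.origin for c in calls] == ["donor", "donor", "recipient"]
        assert calls[1].ambiguous_inherited

    def test_low_identity_unassigned(self):
        cfg = ClassifierConfig(min_identity=0.9)
        calls = classify_windows(
            self._scored([(1.0, 0.95), (0.3, 0.25), (0.89, 0.89)]), cfg
        )
        assert [c.origin for c in calls] == ["recipient", "unassigned", "unassigned"]

    def test_lookback_skips_unassigned_windows(self):
        calls = classify_windows(
            self._scored([(0.8, 1.0), (0.2, 0.2), (1.0, 1.0)])
        )
        assert [c.origin for c in calls] == ["donor", "unassigned", "donor"]

    def test_unordered_input_rejected(self):
        scored = self._scored([(1.0, 0.9), (1.0, 0.9)])
        with pytest.raises(ClassifierError, match="not tiled"):
            classify_windows([scored[1], scored[0]])


class TestPaintGenome:
    def test_agrees_with_truth_majority_vote(self, small_pair):
        """Window origins match a per-window majority vote over ground-truth
        base origins wherever the vote is decisive (>=5 informative sites)."""
        rec, don, _ = small_pair
        cfg = TransferConfig(
            n_segments=8,
            segment_length_dist=("log-uniform", 2_000, 10_000),
            min_gap_bp=1_000,
            seed=11,
        )
        tc, truth = simulate_transconjugant(rec, don, cfg)
        calls = paint_genome(tc, rec, don)
        checked = 0
        for c in calls:
            vote, n_sites = truth_majority_vote(
                tc.sequence, rec.sequence, don.sequence,
                c.interval.start, c.interval.end,
            )
            if vote is not None and n_sites >= 5:
                assert c.origin == vote
                checked += 1
        assert checked > 100

    def test_marker_windows_unassigned_in_mapping_mode(self, small_pair):
        rec, don, _ = small_pair
        cfg = TransferConfig(n_segments=2, seed=2, marker=(2_000, 30_000),
                             segment_length_dist=("log-uniform", 2_000, 5_000))
        tc, truth = simulate_transconjugant(rec, don, cfg)
        calls = paint_genome(tc, rec, don, ClassifierConfig(mode="mapping"))
        marker_iv = next(iv for iv, o in truth.segments if o == "marker")
        interior = [
            c for c in calls
            if c.interval.start >= marker_iv.start
            and c.interval.end <= marker_iv.end
        ]
        assert interior and all(c.origin == "unassigned" for c in interior)

    def test_aligned_mode_requires_collinear_frame(self, small_pair):
        rec, don, _ = small_pair
        cfg = TransferConfig(n_segments=0, marker=(1_500, None), seed=1)
        tc, _ = simulate_transconjugant(rec, don, cfg)
        with pytest.raises(ClassifierError, match="frame mismatch"):
            paint_genome(tc, rec, don)

    def test_mapping_mode_agrees_with_aligned_on_collinear_input(self, small_cross):
        rec, don, tc, _ = small_cross
        aligned = paint_genome(tc, rec, don)
        mapped = paint_genome(tc, rec, don, ClassifierConfig(mode="mapping"))
        agree = sum(
            a.origin == m.origin for a, m in zip(aligned, mapped)
        )
        assert agree / len(aligned) > 0.95
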