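"""Maximal-scoring-segment semantics, checked against an exhaustive oracle.

The oracle implements recursive best-segment extraction: take the
maximum-scoring interval (ties: shortest, then leftmost), remove it, recurse
on both sides. For the all-maximal-scoring-subsequences problem this
enumeration produces exactly the disjoint maximal segment set, so it is an
independent quadratic-time check of the linear-time implementation.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from h3k4seq.annotations_io import GeneModel, Genome
from h3k4seq.peak_calling import (
    BackgroundModel,
    call_peaks,
    estimate_background,
    maximal_scoring_segments,
    peaks_for_all_samples,
)

from .conftest import make_track


def oracle_maximal_segments(scores):
    """Quadratic brute force: recursive extraction of the best interval."""
    s = np.asarray(scores, dtype=float)

    def best(lo, hi):
        top = None
        for i in range(lo, hi):
            total = 0.0
            for j in range(i, hi):
                total += s[j]
                if total <= 0:
                    continue
                key = (total, -(j + 1 - i), -i)  # max score, then shortest, then leftmost
                if top is None or key > top[0]:
                    top = (key, i, j + 1)
        return top

    out = []

    def recurse(lo, hi):
        found = best(lo, hi)
        if found is None:
            return
        _, i, j = found
        out.append((i, j, float(s[i:j].sum())))
        recurse(lo, i)
        recurse(j, hi)

    recurse(0, len(s))
    return sorted(out)


class TestMaximalScoringSegments:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ([2, -1, 2], [(0, 3, 3.0)]),  # compensated drop -> one segment
            ([2, -3, 2], [(0, 1, 2.0), (2, 3, 2.0)]),  # uncompensated -> two
            ([1, 1, -3, 2, 2], [(0, 2, 2.0), (3, 5, 4.0)]),
            ([-1, -2, 0], []),  # nothing above background
            ([], []),
        ],
    )
    def test_published_drop_rule_examples(self, scores, expected):
        assert maximal_scoring_segments(np.array(scores, dtype=float)) == expected

    def test_matches_oracle_on_500_random_vectors(self):
        rng = np.random.default_rng(2024)
        for _ in range(500):
            n = int(rng.integers(1, 61))
            s = rng.normal(-0.2, 1.0, size=n)
            got = sorted(maximal_scoring_segments(s))
            want = oracle_maximal_segments(s)
            assert [(a, b) for a, b, _ in got] == [(a, b) for a, b, _ in want]
            np.testing.assert_allclose(
                [x for _, _, x in got], [x for _, _, x in want], atol=1e-9
            )

    @given(st.lists(st.integers(-3, 3), min_size=1, max_size=40))
    def test_matches_oracle_on_small_integer_vectors(self, values):
        s = np.array(values, dtype=float)
        got = sorted(maximal_scoring_segments(s))
        want = oracle_maximal_segments(s)
        assert [(a, b) for a, b, _ in got] == [(a, b) for a, b, _ in want]

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=60))
    def test_segments_are_disjoint_and_boundary_positive(self, values):
        s = np.array(values, dtype=float)
        segs = maximal_scoring_segments(s)
        prev_end = -1
        for lo, hi, score in segs:
            assert lo > prev_end
            prev_end = hi - 1
            assert score > 0
            assert s[lo] > 0 and s[hi - 1] > 0

    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=50),
        st.integers(-8, 8),
    )
    def test_shift_invariance_of_background_subtraction(self, values, shift_quarters):
        # adding k to both coverage and background leaves the peaks unchanged
        # (quarter-integer shifts are exactly representable, so the check is exact)
        c = np.array(values, dtype=float)
        b = 1.25
        k = shift_quarters / 4.0
        base = maximal_scoring_segments(c - b)
        shifted = maximal_scoring_segments((c + k) - (b + k))
        assert [(a, z) for a, z, _ in base] == [(a, z) for a, z, _ in shifted]


class TestCallPeaks:
    def _track(self, values):
        genome = Genome({"chr1": len(values)})
        track = make_track(genome)
        track.data["chr1"][:] = values
        return track

    def test_score_and_height_reported(self):
        track = self._track([0, 5, 5, 5, 0, 0])
        peaks = call_peaks(track, BackgroundModel(1.0), min_score=0, min_length=1)
        (p,) = peaks
        assert (p.start, p.end) == (1, 4)
        assert p.score == pytest.approx(12.0)
        assert p.max_height == 5.0

    def test_thresholds_filter(self):
        track = self._track([0, 5, 5, 5, 0, 0])
        assert call_peaks(track, BackgroundModel(1.0), min_score=20, min_length=1) == []
        assert call_peaks(track, BackgroundModel(1.0), min_score=0, min_length=10) == []

    def test_empty_when_nothing_above_background(self):
        track = self._track([1, 1, 1])
        assert call_peaks(track, BackgroundModel(2.0), min_score=0, min_length=1) == []

    def test_raising_background_never_extends_peaks(self):
        rng = np.random.default_rng(9)
        track = self._track(rng.integers(0, 8, size=400).astype(float))
        lo = call_peaks(track, BackgroundModel(2.0), min_score=0, min_length=1)
        hi = call_peaks(track, BackgroundModel(3.0), min_score=0, min_length=1)
        lo_cover = set()
        for p in lo:
            lo_cover.update(range(p.start, p.end))
        for p in hi:
            assert set(range(p.start, p.end)) <= lo_cover

    def test_peaks_do_not_cross_chromosomes(self):
        genome = Genome({"chr1": 10, "chr2": 10})
        track = make_track(genome)
        track.data["chr1"][:] = 5.0
        track.data["chr2"][:] = 5.0
        peaks = call_peaks(track, BackgroundModel(1.0), min_score=0, min_length=1)
        assert [(p.chrom, p.start, p.end) for p in peaks] == [
            ("chr1", 0, 10),
            ("chr2", 0, 10),
        ]


class TestBackground:
    def test_constant_track(self, toy_genome, toy_genes, flat_track):
        assert estimate_background(flat_track, toy_genes, toy_genome).level == 3.0

    def test_masking_arithmetic(self):
        genome = Genome({"chr1": 100})
        genes = [GeneModel("g", "chr1", 0, 50, "+")]
        track = make_track(genome)
        track.data["chr1"][:50] = 10.0
        track.data["chr1"][50:] = 1.0
        assert estimate_background(track, genes, genome).level == 1.0

    def test_matches_per_base_loop(self, toy_genome, toy_genes):
        rng = np.random.default_rng(12)
        track = make_track(toy_genome)
        for c in toy_genome:
            track.data[c][:] = rng.random(toy_genome[c])
        genic = {
            (g.chrom, x) for g in toy_genes for x in range(g.start, g.end)
        }
        values = [
            track.data[c][x]
            for c in toy_genome.names
            for x in range(toy_genome[c])
            if (c, x) not in genic
        ]
        est = estimate_background(track, toy_genes, toy_genome)
        assert est.level == pytest.approx(np.mean(values))

    def test_fully_genic_genome_rejected(self):
        genome = Genome({"chr1": 100})
        genes = [GeneModel("g", "chr1", 0, 100, "+")]
        track = make_track(genome, fill=1.0)
        with pytest.raises(ValueError):
            estimate_background(track, genes, genome)


class TestAllSamples:
    def test_missing_samples_listed(self, toy_genome, toy_genes, flat_track):
        with pytest.raises(ValueError, match="H3K4me2"):
            peaks_for_all_samples({("H3K4me3", "watered"): flat_track}, toy_genes, toy_genome)

    def test_independent_backgrounds_and_isolation(self, toy_genome, toy_genes):
        tracks = {}
        for mark in ("H3", "H3K4me1", "H3K4me2", "H3K4me3"):
            for cond in ("watered", "stressed"):
                t = make_track(toy_genome, fill=1.0, mark=mark, condition=cond)
                tracks[(mark, cond)] = t
        # one sample gets a strong genic peak
        tracks[("H3K4me3", "watered")].data["chr1"][1000:1400] = 30.0
        peak_sets, backgrounds = peaks_for_all_samples(tracks, toy_genes, toy_genome)
        assert len(peak_sets[("H3K4me3", "watered")]) == 1
        assert all(len(v) == 0 for k, v in peak_sets.items() if k != ("H3K4me3", "watered"))
        assert backgrounds[("H3K4me1", "watered")] == pytest.approx(1.0)
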