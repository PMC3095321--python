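"""Quintile assignment, anchored and length-normalized profiles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from h3k4seq.annotations_io import GeneModel, Genome
from h3k4seq.metagene import (
    MetageneProfile,
    anchored_profile,
    assign_quintiles,
    gene_body_matrix,
    length_normalized_profile,
    peak_normalize,
    profile_peak_position,
    resample_body,
)

from .conftest import make_track


class TestQuintiles:
    def test_top_values_land_in_q5(self):
        values = {f"g{i}": float(i) for i in range(1, 11)}
        q = assign_quintiles(values)
        assert q["g9"] == q["g10"] == 5
        assert q["g1"] == q["g2"] == 1

    def test_ties_broken_by_gene_id(self):
        values = {f"g{i:02d}": 1.0 for i in range(10)}
        q = assign_quintiles(values)
        assert [q[f"g{i:02d}"] for i in range(10)] == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    @pytest.mark.parametrize(
        "n, sizes",
        [(12, (3, 3, 2, 2, 2)), (13, (3, 3, 3, 2, 2)), (10, (2, 2, 2, 2, 2))],
    )
    def test_block_sizes_ascending(self, n, sizes):
        values = {f"g{i:02d}": float(i) for i in range(n)}
        q = assign_quintiles(values)
        counts = tuple(sum(1 for v in q.values() if v == k) for k in range(1, 6))
        assert counts == sizes

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            assign_quintiles({"a": 1.0, "b": 2.0})


class TestAnchoredProfile:
    def test_constant_track_gives_flat_profile(self, toy_genome, toy_genes, flat_track):
        for anchor in ("tss", "stop"):
            for aggregate in ("mean", "median"):
                prof = anchored_profile(
                    flat_track, toy_genes, anchor=anchor, window=(-200, 200), aggregate=aggregate
                )
                np.testing.assert_allclose(prof.values, 3.0)
                assert len(prof.axis) == 401

    def test_spike_lands_at_its_offset_on_plus_strand(self, toy_genome):
        gene = GeneModel("g", "chr1", 2000, 4000, "+")
        track = make_track(toy_genome)
        track.data["chr1"][2300] = 9.0
        prof = anchored_profile(track, [gene], anchor="tss")
        assert profile_peak_position(prof) == 300

    def test_minus_strand_spike_equivalent(self, toy_genome):
        # spike 300 bp downstream of a minus-strand TSS appears at +300 too
        gene = GeneModel("g", "chr1", 2000, 4000, "-")
        track = make_track(toy_genome)
        track.data["chr1"][gene.tss() - 300] = 9.0
        prof = anchored_profile(track, [gene], anchor="tss")
        assert profile_peak_position(prof) == 300

    def test_strand_flip_oracle_on_cohort(self):
        # mirroring the genome layout leaves the strand-oriented profile unchanged
        rng = np.random.default_rng(8)
        L = 20_000
        genome = Genome({"chr1": L})
        track = make_track(genome)
        track.data["chr1"][:] = rng.random(L)
        mirrored = make_track(genome)
        mirrored.data["chr1"][:] = track.data["chr1"][::-1]
        genes, flipped = [], []
        for i in range(10):
            start = 1500 + i * 1800
            end = start + 1000
            genes.append(GeneModel(f"g{i}", "chr1", start, end, "+"))
            flipped.append(GeneModel(f"g{i}", "chr1", L - end, L - start, "-"))
        for anchor in ("tss", "stop"):
            a = anchored_profile(track, genes, anchor=anchor, window=(-500, 500))
            b = anchored_profile(mirrored, flipped, anchor=anchor, window=(-500, 500))
            np.testing.assert_allclose(a.values, b.values)

    def test_off_chromosome_offsets_excluded(self, toy_genome):
        gene = GeneModel("g", "chr1", 100, 600, "+")
        track = make_track(toy_genome, fill=2.0)
        prof = anchored_profile(track, [gene], window=(-300, 0))
        assert prof.counts[0] == 0  # offset -300 is off the chromosome
        assert prof.counts[-1] == 1
        assert np.isnan(prof.values[0])

    def test_empty_cohort_rejected(self, flat_track):
        with pytest.raises(ValueError):
            anchored_profile(flat_track, [])


class TestResampling:
    def test_identity_for_std_length_gene(self):
        v = np.arange(1500.0)
        np.testing.assert_allclose(resample_body(v, 1500), v)

    def test_linear_ramp_preserved(self):
        v = np.linspace(0, 10, 1000)
        out = resample_body(v, 1500)
        # a linear function stays linear under linear interpolation (the
        # half-sample at each end is clamped to the outermost base value)
        diffs = np.diff(out[1:-1])
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-9)
        assert out[0] == pytest.approx(0.0, abs=0.02)
        assert out[-1] == pytest.approx(10.0, abs=0.02)

    def test_binmean_conserves_mass(self):
        rng = np.random.default_rng(2)
        v = rng.random(1234)
        out = resample_body(v, 1500, mode="binmean")
        assert out.sum() * 1234 / 1500 == pytest.approx(v.sum())


class TestLengthNormalizedProfile:
    def test_median_of_constant_bodies(self, toy_genome):
        genome = Genome({"chr1": 20_000})
        track = make_track(genome)
        genes = []
        for i, level in enumerate([1.0, 2.0, 9.0]):
            start = 2000 + i * 4000
            end = start + 1500
            track.data["chr1"][start:end] = level
            genes.append(GeneModel(f"g{i}", "chr1", start, end, "+"))
        prof = length_normalized_profile(track, genes)
        body = prof.values[(prof.axis >= 0) & (prof.axis < 1500)]
        np.testing.assert_allclose(body, 2.0)

    def test_flanks_at_native_scale_and_strand(self):
        genome = Genome({"chr1": 10_000}); track = make_track(genome)
        gene = GeneModel("g", "chr1", 3000, 4500, "-")
        track.data["chr1"][4500:5000] = 7.0  # upstream of the minus-strand TSS
        prof = length_normalized_profile(track, [gene])
        upstream = prof.values[prof.axis < 0]
        downstream = prof.values[prof.axis >= 1500]
        np.testing.assert_allclose(upstream, 7.0)
        np.testing.assert_allclose(downstream, 0.0)

    def test_length_filter(self, toy_genome):
        track = make_track(toy_genome, fill=1.0)
        short = GeneModel("s", "chr1", 100, 600, "+")
        ok = GeneModel("ok", "chr1", 2000, 3500, "+")
        prof = length_normalized_profile(track, [short, ok])
        assert prof.cohort == ("ok",)
        with pytest.raises(ValueError):
            length_normalized_profile(track, [short])

    def test_gene_body_matrix_matches_profile_cohort(self, toy_genome):
        track = make_track(toy_genome, fill=2.0)
        genes = [GeneModel("a", "chr1", 0, 1200, "+"), GeneModel("b", "chr1", 2000, 3800, "-")]
        ids, matrix = gene_body_matrix(track, genes)
        assert ids == ["a", "b"]
        assert matrix.shape == (2, 1500)
        np.testing.assert_allclose(matrix, 2.0)


class TestPeakNormalize:
    def test_divides_by_max(self):
        prof = MetageneProfile(
            axis=np.array([0, 1, 2]),
            values=np.array([2.0, 4.0, 8.0]),
            counts=np.ones(3, dtype=int),
            cohort=("g",),
            aggregate_kind="mean",
        )
        out = peak_normalize(prof)
        np.testing.assert_allclose(out.values, [0.25, 0.5, 1.0])
        np.testing.assert_allclose(peak_normalize(out).values, out.values)  # idempotent

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=50))
    def test_argmax_preserved(self, values):
        prof = MetageneProfile(
            axis=np.arange(len(values)),
            values=np.array(values),
            counts=np.ones(len(values), dtype=int),
            cohort=("g",),
            aggregate_kind="mean",
        )
        assert int(np.argmax(peak_normalize(prof).values)) == int(np.argmax(prof.values))

    def test_all_zero_rejected(self):
        prof = MetageneProfile(
            axis=np.arange(3), values=np.zeros(3), counts=np.ones(3, dtype=int),
            cohort=("g",), aggregate_kind="mean",
        )
        with pytest.raises(ValueError):
            peak_normalize(prof)


class TestPeakPosition:
    def test_monotone_decreasing_peaks_at_window_start(self):
        prof = MetageneProfile(
            axis=np.arange(-5, 5), values=np.linspace(9, 0, 10),
            counts=np.ones(10, dtype=int), cohort=("g",), aggregate_kind="mean",
        )
        assert profile_peak_position(prof) == -5

    def test_tie_takes_smallest_offset(self):
        prof = MetageneProfile(
            axis=np.arange(4), values=np.array([0.0, 5.0, 5.0, 1.0]),
            counts=np.ones(4, dtype=int), cohort=("g",), aggregate_kind="mean",
        )
        assert profile_peak_position(prof) == 1

    def test_flat_profile_signalled(self):
        prof = MetageneProfile(
            axis=np.arange(4), values=np.full(4, 2.0),
            counts=np.ones(4, dtype=int), cohort=("g",), aggregate_kind="mean",
        )
        with pytest.raises(ValueError):
            profile_peak_position(prof)
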