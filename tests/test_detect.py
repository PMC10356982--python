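import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rohmap.detect import (
    assemble_runs,
    detect_roh,
    detect_roh_oracle,
    filter_runs,
    snp_hit_proportions,
    window_flags,
)
from rohmap.types import MISSING, GenotypeDataset, ROHParameters

from conftest import make_dataset, random_dataset

P = ROHParameters()


class TestWindowFlags:
    def test_single_all_homozygous_window(self):
        assert window_flags(np.zeros(50, dtype=np.int8), P).tolist() == [True]

    def test_two_heterozygotes_fail_with_het_cap_one(self):
        codes = np.zeros(50, dtype=np.int8)
        codes[[10, 30]] = 1
        assert window_flags(codes, P).tolist() == [False]

    def test_one_heterozygote_tolerated(self):
        codes = np.zeros(50, dtype=np.int8)
        codes[10] = 1
        assert window_flags(codes, P).tolist() == [True]

    def test_51_markers_give_two_windows(self):
        assert window_flags(np.full(51, 2, dtype=np.int8), P).tolist() == [
            True,
            True,
        ]

    def test_short_chromosome_yields_no_windows(self):
        assert len(window_flags(np.zeros(49, dtype=np.int8), P)) == 0


class TestHitProportions:
    def test_all_windows_flagged(self):
        props = snp_hit_proportions(np.ones(11, dtype=bool), 60, P)
        assert np.all(props == 1.0)

    def test_no_windows_flagged(self):
        props = snp_hit_proportions(np.zeros(11, dtype=bool), 60, P)
        assert np.all(props == 0.0)

    def test_hand_counted_coverage(self):
        # 60 markers, 11 complete windows, only the first flagged:
        # marker 1 (index 0) is covered by window 1 alone -> proportion 1;
        # marker 55 (index 54) is covered by windows 6-11, none flagged -> 0.
        flags = np.zeros(11, dtype=bool)
        flags[0] = True
        props = snp_hit_proportions(flags, 60, P)
        assert props[0] == 1.0
        assert props[54] == 0.0
        # marker 50 (index 49) is covered by windows 1-11 -> 1/11
        assert props[49] == pytest.approx(1 / 11)


class TestAssembleRuns:
    def test_single_run_spanning_all_markers(self):
        n = 120
        codes = np.zeros(n, dtype=np.int8)
        positions = np.arange(1, n + 1) * 10_000
        props = np.ones(n)
        assert assemble_runs(codes, positions, props, P) == [(0, n - 1)]

    def test_split_at_gap_above_500kb(self):
        n = 120
        codes = np.zeros(n, dtype=np.int8)
        positions = np.arange(1, n + 1) * 10_000
        positions[60:] += 600_000  # 610 kb gap between markers 59 and 60
        runs = assemble_runs(codes, positions, np.ones(n), P)
        assert runs == [(0, 59), (60, n - 1)]

    def test_gap_of_exactly_500kb_not_split(self):
        n = 120
        codes = np.zeros(n, dtype=np.int8)
        positions = np.arange(1, n + 1) * 10_000
        positions[60:] += 490_000  # exactly 500 kb between 59 and 60
        assert assemble_runs(codes, positions, np.ones(n), P) == [(0, n - 1)]

    def test_heterozygous_start_trimmed(self):
        n = 120
        codes = np.zeros(n, dtype=np.int8)
        codes[0] = 1
        positions = np.arange(1, n + 1) * 10_000
        assert assemble_runs(codes, positions, np.ones(n), P) == [(1, n - 1)]

    def test_missing_end_trimmed(self):
        n = 120
        codes = np.zeros(n, dtype=np.int8)
        codes[-1] = MISSING
        positions = np.arange(1, n + 1) * 10_000
        assert assemble_runs(codes, positions, np.ones(n), P) == [(0, n - 2)]


class TestFilterRuns:
    positions_10kb = np.arange(1, 201) * 10_000

    def _segments(self, lo, hi, positions=None):
        positions = self.positions_10kb if positions is None else positions
        codes = np.zeros(len(positions), dtype=np.int8)
        return filter_runs([(lo, hi)], codes, positions, P, "b", 1)

    def test_run_passing_all_filters_kept(self):
        segs = self._segments(0, 149)  # 150 SNPs, 1,490.001 kb, 9.9 kb/SNP
        assert len(segs) == 1
        assert segs[0].n_snp == 150
        assert segs[0].length_kb == pytest.approx(1490.001)

    def test_run_with_99_markers_dropped(self):
        assert self._segments(0, 98) == []

    def test_run_spanning_900kb_dropped(self):
        positions = np.arange(1, 101) * 9_000  # 100 SNPs over ~891 kb
        assert self._segments(0, 99, positions) == []

    def test_sparse_run_dropped_by_density(self):
        positions = np.arange(1, 121) * 60_000  # 60 kb/SNP > 50
        assert self._segments(0, 119, positions) == []


class TestDetect:
    def test_all_heterozygous_dataset_has_no_segments(self):
        ds = make_dataset(
            {"b1": [1] * 200}, positions=list(np.arange(1, 201) * 10_000)
        )
        assert detect_roh(ds, P).segments == []

    def test_fully_homozygous_chromosome_single_segment(self):
        ds = make_dataset(
            {"b1": [0] * 150}, positions=list(np.arange(1, 151) * 10_000)
        )
        res = detect_roh(ds, P)
        assert len(res.segments) == 1
        seg = res.segments[0]
        assert (seg.start_bp, seg.end_bp) == (10_000, 1_500_000)
        assert seg.n_snp == 150

    def test_every_animal_indexed_even_without_segments(self):
        ds = make_dataset(
            {"b1": [0] * 150, "b2": [1] * 150},
            positions=list(np.arange(1, 151) * 10_000),
        )
        res = detect_roh(ds, P)
        assert set(res.per_animal) == {"b1", "b2"}
        assert res.per_animal["b2"] == []

    def test_planted_tract_recovered(self):
        rng = np.random.default_rng(42)
        ds = random_dataset(
            rng, n_animals=2, n_markers=600, spacing_kb=12.0,
            hom_patch=(200, 400),
        )
        res = detect_roh(ds, P)
        pos = ds.markers.positions_bp
        for animal in ds.animal_ids:
            segs = [
                s
                for s in res.per_animal[animal]
                if s.start_bp <= pos[399] and s.end_bp >= pos[200]
            ]
            assert len(segs) == 1
            # window-edge overshoot: endpoints within a few markers
            assert abs(np.searchsorted(pos, segs[0].start_bp) - 200) <= 25
            assert abs(np.searchsorted(pos, segs[0].end_bp) - 399) <= 25

    def test_segment_invariants_hold_on_random_data(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            ds = random_dataset(
                rng, n_animals=3, n_markers=700, het_rate=0.1,
                hom_patch=(100, 350),
            )
            res = detect_roh(ds, P)
            for seg in res.segments:
                assert seg.n_snp >= P.min_snp
                assert seg.length_kb >= P.min_length_kb
                assert seg.length_kb / seg.n_snp <= P.max_density_kb_per_snp
                sl = ds.markers.chrom_slice(seg.chromosome)
                pos = ds.markers.positions_bp[sl]
                inside = pos[(pos >= seg.start_bp) & (pos <= seg.end_bp)]
                assert np.all(np.diff(inside) <= P.max_gap_kb * 1000)
            # per-animal disjointness
            for animal, segs in res.per_animal.items():
                segs = sorted(segs, key=lambda s: (s.chromosome, s.start_bp))
                for s1, s2 in zip(segs, segs[1:]):
                    if s1.chromosome == s2.chromosome:
                        assert s1.end_bp < s2.start_bp


class TestOracleEquivalence:
    def test_empty_dataset(self):
        ds = make_dataset({"b1": [1] * 60}, positions=list(np.arange(1, 61) * 5000))
        assert detect_roh_oracle(ds, P).segments == detect_roh(ds, P).segments

    @pytest.mark.parametrize("seed", range(8))
    def test_randomized_differential(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(
            rng, n_animals=2, n_markers=400, het_rate=0.08,
            hom_patch=(120, 300),
        )
        params = ROHParameters(min_snp=60, min_length_kb=500)
        assert (
            detect_roh(ds, params).segments
            == detect_roh_oracle(ds, params).segments
        )


class TestProperties:
    def test_allele_swap_symmetry(self):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, n_animals=2, n_markers=500, hom_patch=(100, 350))
        swapped = GenotypeDataset(
            ds.animal_ids,
            ds.markers,
            np.where(ds.genotypes == 0, 2, np.where(ds.genotypes == 2, 0, ds.genotypes)),
        )
        assert detect_roh(ds, P).segments == detect_roh(swapped, P).segments

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_filter_monotonicity(self, seed):
        """Raising min_snp or min_length_kb never adds segments."""
        rng = np.random.default_rng(seed)
        ds = random_dataset(
            rng, n_animals=1, n_markers=400, het_rate=0.05, hom_patch=(50, 300)
        )
        base = ROHParameters(min_snp=50, min_length_kb=400)
        n_base = len(detect_roh(ds, base).segments)
        for stricter in (
            ROHParameters(min_snp=120, min_length_kb=400),
            ROHParameters(min_snp=50, min_length_kb=1500),
        ):
            assert len(detect_roh(ds, stricter).segments) <= n_base

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_in_run_marker_set_shrinks_with_threshold(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n_animals=1, n_markers=300, het_rate=0.1)
        codes = ds.genotypes[0]
        flags = window_flags(codes, P)
        props = snp_hit_proportions(flags, len(codes), P)
        lo = props >= 0.05
        hi = props >= 0.25
        assert np.all(lo | ~hi)  # hi-threshold set is a subset
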