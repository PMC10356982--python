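import numpy as np
import pytest

from rohmap.summary import (
    chromosome_homozygosity,
    correlate_roh_pedigree,
    pedigree_inbreeding,
    regress_scr_on_roh,
    summarize_animals,
)
from rohmap.types import (
    AnimalROHStats,
    Pedigree,
    PhenotypeTable,
    PipelineError,
    ROHParameters,
    ROHResult,
    ROHSegment,
)

from conftest import make_map
from oracles import wright_path_inbreeding


def result_with(segments, animal_ids, positions, chromosome=1, lengths=None):
    markers = make_map(positions, chromosome, chromosome_lengths=lengths)
    return ROHResult(ROHParameters(), segments, animal_ids, markers)


class TestSummarize:
    def test_two_segment_arithmetic(self):
        segs = [
            ROHSegment("b1", 1, 1, 1_000_000, 100, 0, 0),  # 1,000 kb
            ROHSegment("b1", 1, 2_000_001, 5_000_000, 300, 1, 0),  # 3,000 kb
        ]
        res = result_with(segs, ["b1"], positions=[1, 10_000_000])
        (s,) = summarize_animals(res)
        assert s.n_segments == 2
        assert s.total_length_kb == pytest.approx(4000.0)
        assert s.mean_length_kb == pytest.approx(2000.0)
        assert s.max_length_kb == pytest.approx(3000.0)
        assert s.total_length_mb == pytest.approx(4.0)
        # denominator: covered span = 10,000,000 bp
        assert s.f_roh == pytest.approx(4_000_000 / 10_000_000)

    def test_animal_without_segments_all_zeros(self):
        res = result_with([], ["b1", "b2"], positions=[1, 1_000_000])
        stats = {s.animal_id: s for s in summarize_animals(res)}
        assert stats["b2"].n_segments == 0
        assert stats["b2"].total_length_kb == 0.0
        assert stats["b2"].f_roh == 0.0

    def test_totals_invariant_to_segment_order(self):
        segs = [
            ROHSegment("b1", 1, 2_000_001, 5_000_000, 300, 0, 0),
            ROHSegment("b1", 1, 1, 1_000_000, 100, 0, 0),
        ]
        res1 = result_with(segs, ["b1"], positions=[1, 10_000_000])
        res2 = result_with(segs[::-1], ["b1"], positions=[1, 10_000_000])
        assert summarize_animals(res1) == summarize_animals(res2)


class TestChromosomeHomozygosity:
    def test_single_animal_thirty_percent(self):
        segs = [ROHSegment("b1", 1, 1, 30_000_000, 1000, 0, 0)]
        res = result_with(
            segs, ["b1"], positions=[1, 90_000_000], lengths={1: 100_000_000}
        )
        assert chromosome_homozygosity(res)[1] == pytest.approx(30.0)

    def test_no_segments_zero_everywhere(self):
        res = result_with([], ["b1"], positions=[1, 1_000_000])
        assert chromosome_homozygosity(res) == {1: 0.0}

    def test_two_animal_average(self):
        segs = [
            ROHSegment("b1", 1, 1, 10_000_000, 500, 0, 0),
            ROHSegment("b2", 1, 1, 20_000_000, 900, 0, 0),
        ]
        res = result_with(
            segs, ["b1", "b2"], positions=[1, 50_000_000],
            lengths={1: 100_000_000},
        )
        assert chromosome_homozygosity(res)[1] == pytest.approx(15.0)


class TestPedigreeInbreeding:
    def test_outbred_offspring(self):
        ped = Pedigree([("A", None, None), ("B", None, None), ("X", "A", "B")])
        assert pedigree_inbreeding(ped)["X"] == 0.0

    def test_full_sib_mating(self):
        ped = Pedigree(
            [
                ("P", None, None),
                ("Q", None, None),
                ("S", "P", "Q"),
                ("D", "P", "Q"),
                ("X", "S", "D"),
            ]
        )
        assert pedigree_inbreeding(ped)["X"] == pytest.approx(0.25)

    def test_half_sib_mating(self):
        ped = Pedigree(
            [
                ("P", None, None),
                ("M1", None, None),
                ("M2", None, None),
                ("S", "P", "M1"),
                ("D", "P", "M2"),
                ("X", "S", "D"),
            ]
        )
        assert pedigree_inbreeding(ped)["X"] == pytest.approx(0.125)

    def test_parent_offspring_mating(self):
        ped = Pedigree(
            [("A", None, None), ("M", None, None), ("B", "A", "M"), ("X", "A", "B")]
        )
        assert pedigree_inbreeding(ped)["X"] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_path_counting_oracle(self, seed):
        ped = _random_pedigree(np.random.default_rng(seed), n=12)
        f = pedigree_inbreeding(ped)
        for animal in ped.animals:
            assert f[animal] == pytest.approx(
                wright_path_inbreeding(ped, animal), abs=1e-12
            )


def _random_pedigree(rng, n=12):
    """Random acyclic pedigree: each animal's parents come from earlier ids."""
    records = []
    for i in range(n):
        if i < 3 or rng.random() < 0.25:
            records.append((f"x{i}", None, None))
        else:
            s, d = rng.choice(i, size=2, replace=False)
            records.append((f"x{i}", f"x{s}", f"x{d}"))
    return Pedigree(records)


class TestCorrelation:
    def _stats(self, froh):
        return [
            AnimalROHStats(f"b{i}", 1, v * 1e6, v * 1e6, v * 1e6, v)
            for i, v in enumerate(froh)
        ]

    def test_identical_vectors_r_one(self):
        froh = [0.1, 0.2, 0.3, 0.4]
        f_ped = {f"b{i}": v for i, v in enumerate(froh)}
        assert correlate_roh_pedigree(self._stats(froh), f_ped) == pytest.approx(1.0)

    def test_negative_affine_r_minus_one(self):
        froh = [0.1, 0.2, 0.3]
        f_ped = {f"b{i}": 0.5 - v for i, v in enumerate(froh)}
        assert correlate_roh_pedigree(self._stats(froh), f_ped) == pytest.approx(-1.0)

    def test_constant_side_raises(self):
        froh = [0.2, 0.2, 0.2]
        f_ped = {f"b{i}": 0.1 * i for i in range(3)}
        with pytest.raises(PipelineError, match="constant"):
            correlate_roh_pedigree(self._stats(froh), f_ped)


class TestRegression:
    def _pheno(self, ys):
        return PhenotypeTable(
            [f"b{i}" for i in range(len(ys))],
            np.array(ys),
            np.full(len(ys), 100),
        )

    def _stats(self, xs):
        return [
            AnimalROHStats(f"b{i}", int(x), x * 1000, x * 1000, x * 1000, 0.1)
            for i, x in enumerate(xs)
        ]

    def test_collinear_points_exact(self):
        fit = regress_scr_on_roh(self._pheno([2.0, 1.0, 0.0]), self._stats([0, 100, 200]))
        assert fit.beta == pytest.approx(-0.01, abs=1e-15)
        assert fit.intercept == pytest.approx(2.0, abs=1e-12)
        assert fit.n == 3

    def test_matches_reference_least_squares(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 400, 200)
        y = -0.01 * x + rng.normal(0, 2, 200)
        fit = regress_scr_on_roh(self._pheno(y), self._stats(x))
        ref = statsmodels.OLS(y, statsmodels.add_constant(x)).fit()
        assert fit.beta == pytest.approx(ref.params[1], abs=1e-10)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-10)
        assert fit.se_beta == pytest.approx(ref.bse[1], abs=1e-10)
        assert fit.t_value == pytest.approx(ref.tvalues[1], abs=1e-8)
        assert fit.p_value == pytest.approx(ref.pvalues[1], abs=1e-10)

    def test_zero_variance_predictor_raises(self):
        with pytest.raises(PipelineError, match="variance"):
            regress_scr_on_roh(self._pheno([1.0, 2.0, 3.0]), self._stats([5, 5, 5]))

    def test_study_realizes_negative_association(self, default_study, default_roh):
        stats = summarize_animals(default_roh)
        fit = regress_scr_on_roh(default_study.phenotypes, stats)
        assert fit.beta < 0
        assert fit.p_value < 0.01
        fit2 = regress_scr_on_roh(default_study.phenotypes, stats, "n_segments")
        assert fit2.beta < 0


class TestStudyCorrelation:
    def test_froh_tracks_pedigree_inbreeding(self, default_study, default_roh):
        stats = summarize_animals(default_roh)
        r = correlate_roh_pedigree(stats, default_study.truth.f_ped)
        # realized correlation from the generator's own ground truth
        ids = [s.animal_id for s in stats]
        true_mb = np.array([default_study.truth.true_total_mb[a] for a in ids])
        fped = np.array([default_study.truth.f_ped[a] for a in ids])
        realized = np.corrcoef(true_mb, fped)[0, 1]
        assert abs(r - realized) <= 0.1
        assert r > 0.4
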