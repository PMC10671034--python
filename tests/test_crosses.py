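import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qtlallele.crosses import (
    GeneticMap,
    cross_percentiles,
    haldane_r,
    optimal_crosses,
    physical_to_genetic,
    predict_all_crosses,
    recombination_potential,
    ril_recomb_fraction,
    simulate_cross,
)


def make_map(positions, chroms=None):
    n = len(positions)
    df = pd.DataFrame(
        {
            "locus": [f"L{i}" for i in range(n)],
            "chrom": chroms or [1] * n,
            "pos": positions,
        }
    ).set_index("locus")
    return GeneticMap.from_positions(df)


class TestMapArithmetic:
    @pytest.mark.parametrize(
        "bp, cm", [(1_000_000, 1.0), (0, 0.0), (24_526_775, 24.526775)]
    )
    def test_physical_to_genetic(self, bp, cm):
        assert physical_to_genetic([bp])[0] == pytest.approx(cm)

    def test_rate_must_be_positive(self):
        with pytest.raises(ValueError):
            physical_to_genetic([1], rate_cm_per_mb=0)

    @pytest.mark.parametrize("r, R", [(0.0, 0.0), (0.5, 0.5), (0.25, 1 / 3)])
    def test_ril_recomb_fraction(self, r, R):
        assert ril_recomb_fraction(r) == pytest.approx(R)

    def test_r_out_of_range(self):
        with pytest.raises(ValueError):
            ril_recomb_fraction(0.7)

    def test_haldane_limits(self):
        assert haldane_r(0.0) == 0.0
        assert haldane_r(1e9) == pytest.approx(0.5)


class TestSimulateCross:
    def test_identical_parents_zero_variance(self):
        gmap = make_map([1000, 2000, 500_000])
        effects = {"L0": np.array([1.0, -1.0]), "L1": np.array([2.0, -2.0]),
                   "L2": np.array([0.5, -0.5])}
        calls = np.array([0, 1, 0])
        vals = simulate_cross(calls, calls, gmap, effects, mu=40.0, n_progeny=500,
                              rng=np.random.default_rng(0))
        assert vals.std() == 0.0
        assert vals[0] == pytest.approx(40.0 + 1.0 - 2.0 + 0.5)

    def test_two_unlinked_loci_give_quarter_classes(self):
        gmap = make_map([1000, 1000], chroms=[1, 2])
        a, b = 3.0, 7.0
        effects = {"L0": np.array([a, -a]), "L1": np.array([b, -b])}
        p1 = np.array([0, 1])  # repulsion: +a with -b
        p2 = np.array([1, 0])
        n = 2000
        vals = simulate_cross(p1, p2, gmap, effects, mu=0.0, n_progeny=n,
                              model="linkage", rng=np.random.default_rng(1))
        classes, counts = np.unique(np.round(vals, 9), return_counts=True)
        expected = sorted([a + b, a - b, -a + b, -a - b])
        np.testing.assert_allclose(sorted(classes), expected)
        sigma = np.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(counts - n / 4) < 3 * sigma)

    def test_complete_linkage_keeps_parental_classes(self):
        gmap = make_map([1000, 1001])  # ~0 cM apart -> r ~ 0
        effects = {"L0": np.array([2.0, -2.0]), "L1": np.array([3.0, -3.0])}
        p1 = np.array([0, 0])
        p2 = np.array([1, 1])
        vals = simulate_cross(p1, p2, gmap, effects, mu=0.0, n_progeny=1000,
                              rng=np.random.default_rng(2))
        assert set(np.round(vals, 6)) <= {5.0, -5.0}

    def test_locus_count_mismatch(self):
        gmap = make_map([1000, 2000])
        with pytest.raises(ValueError):
            simulate_cross(np.array([0]), np.array([0, 1]), gmap,
                           {"L0": np.zeros(2), "L1": np.zeros(2)}, 0.0)

    def test_linkage_at_half_matches_independent(self):
        # loci on distinct chromosomes: linkage chain switches at 1/2 anyway
        gmap = make_map([1000] * 6, chroms=list(range(1, 7)))
        rng = np.random.default_rng(3)
        effects = {f"L{i}": rng.normal(0, 3, 2) for i in range(6)}
        p1 = np.zeros(6, dtype=int)
        p2 = np.ones(6, dtype=int)
        v1 = simulate_cross(p1, p2, gmap, effects, 40.0, 2000, "linkage",
                            np.random.default_rng(10))
        v2 = simulate_cross(p1, p2, gmap, effects, 40.0, 2000, "independent",
                            np.random.default_rng(11))
        assert stats.ks_2samp(v1, v2).pvalue > 0.01

    def test_progeny_allele_frequency_balanced(self):
        gmap = make_map([1000], chroms=[1])
        effects = {"L0": np.array([1.0, -1.0])}
        vals = simulate_cross(np.array([0]), np.array([1]), gmap, effects, 0.0,
                              2000, rng=np.random.default_rng(4))
        share = (vals > 0).mean()
        assert abs(share - 0.5) < 3 * np.sqrt(0.25 / 2000)

    def test_mean_near_midparent_for_unlinked_loci(self):
        rng = np.random.default_rng(5)
        k = 8
        gmap = make_map([1000] * k, chroms=list(range(1, k + 1)))
        effects = {f"L{i}": rng.normal(0, 3, 3) for i in range(k)}
        p1 = rng.integers(0, 3, k)
        p2 = rng.integers(0, 3, k)
        vals = simulate_cross(p1, p2, gmap, effects, 40.0, 4000, "independent",
                              np.random.default_rng(6))
        midparent = 40.0 + np.mean(
            [effects[f"L{i}"][p1[i]] + effects[f"L{i}"][p2[i]] for i in range(k)],
            axis=0,
        ).sum() / 1  # per-locus mean of the two parental effects, summed
        midparent = 40.0 + sum(
            (effects[f"L{i}"][p1[i]] + effects[f"L{i}"][p2[i]]) / 2 for i in range(k)
        )
        assert vals.mean() == pytest.approx(midparent, abs=4 * vals.std() / np.sqrt(4000))


class TestPercentiles:
    def test_constant_sample(self):
        out = cross_percentiles(np.full(10, 7.0))
        assert {out["p20"], out["p25"], out["p50"], out["p75"], out["mean"]} == {7.0}

    def test_type7_interpolation(self):
        out = cross_percentiles(np.arange(1, 101))
        assert out["p25"] == pytest.approx(25.75)

    def test_ordering(self):
        rng = np.random.default_rng(0)
        out = cross_percentiles(rng.normal(size=500))
        assert out["p20"] <= out["p25"] <= out["p50"] <= out["p75"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cross_percentiles([])


@pytest.fixture(scope="module")
def small_matrix(small_scan):
    from qtlallele.allele_matrix import build_matrix

    res, markers, filtered = small_scan
    return build_matrix(
        res.qtls, {m.id: m for m in markers}, filtered.accessions, res.intercept
    )


class TestPredictAllCrosses:
    def test_pair_count(self, small_matrix):
        from qtlallele.allele_matrix import submatrix

        sub = submatrix(small_matrix, small_matrix.accessions[:3])
        out = predict_all_crosses(sub, n_progeny=50, master_seed=1)
        assert len(out) == 3

    def test_deterministic_and_order_independent(self, small_matrix):
        from qtlallele.allele_matrix import submatrix

        sub = submatrix(small_matrix, small_matrix.accessions[:4])
        out1 = predict_all_crosses(sub, n_progeny=100, master_seed=5)
        out2 = predict_all_crosses(sub, n_progeny=100, master_seed=5)
        assert out1.equals(out2)
        rev = submatrix(small_matrix, list(reversed(small_matrix.accessions[:4])))
        out3 = predict_all_crosses(rev, n_progeny=100, master_seed=5)
        key = lambda df: df.assign(
            pair=[tuple(sorted(t)) for t in zip(df.parent1, df.parent2)]
        ).set_index("pair")["p25"].sort_index()
        pd.testing.assert_series_equal(key(out1), key(out3))

    def test_single_accession_rejected(self, small_matrix):
        from qtlallele.allele_matrix import submatrix

        with pytest.raises(ValueError):
            predict_all_crosses(submatrix(small_matrix, small_matrix.accessions[:1]))

    def test_percentile_invariants(self, small_matrix):
        from qtlallele.allele_matrix import submatrix

        sub = submatrix(small_matrix, small_matrix.accessions[:6])
        out = predict_all_crosses(sub, n_progeny=200, master_seed=2)
        assert (out["p20"] <= out["p25"]).all()
        assert (out["p25"] <= out["p50"]).all()
        assert (out["p50"] <= out["p75"]).all()
        # best-recombinant bound on P25
        for _, row in out.iterrows():
            lo = sub.mu + sum(
                min(sub.effects.loc[l, row["parent1"]], sub.effects.loc[l, row["parent2"]])
                for l in sub.loci
            )
            assert row["p25"] >= lo - 1e-9


class TestOptimalCrosses:
    def test_threshold_extremes(self, small_matrix):
        from qtlallele.allele_matrix import submatrix

        sub = submatrix(small_matrix, small_matrix.accessions[:4])
        out = predict_all_crosses(sub, n_progeny=100, master_seed=3)
        assert optimal_crosses(out, float("-inf")).empty
        assert len(optimal_crosses(out, float("inf"))) == len(out)

    def test_planted_complementary_pair_ranks_first(self):
        from qtlallele.allele_matrix import QtlAlleleMatrix

        loci = ["q1", "q2"]
        accs = ["comp_a", "comp_b", "mid_c"]
        effects_by_locus = {"q1": np.array([-6.0, 6.0]), "q2": np.array([-4.0, 4.0])}
        calls = pd.DataFrame(
            [["h0", "h1", "h1"], ["h1", "h0", "h1"]], index=loci, columns=accs
        )
        eff = pd.DataFrame(
            [[-6.0, 6.0, 6.0], [4.0, -4.0, 4.0]], index=loci, columns=accs
        )
        m = QtlAlleleMatrix(
            effects=eff, allele_calls=calls,
            effects_by_locus=effects_by_locus,
            alleles_by_locus={"q1": ["h0", "h1"], "q2": ["h0", "h1"]},
            positions=pd.DataFrame(
                {"chrom": [1, 2], "pos": [1000, 1000]}, index=pd.Index(loci, name="locus")
            ),
            mu=40.0,
        )
        out = predict_all_crosses(m, n_progeny=2000, master_seed=7)
        best = optimal_crosses(out, float("inf")).iloc[0]
        assert {best["parent1"], best["parent2"]} == {"comp_a", "comp_b"}


class TestRecombinationPotential:
    def test_printed_arithmetic(self):
        out = recombination_potential(44.5, 17.2, p25_mean=37.0, p25_min=3.0)
        assert out["average"] == pytest.approx(7.5)
        assert out["max_improvement"] == pytest.approx(41.5)
        assert out["max_transgression"] == pytest.approx(14.2)

    def test_zero_transgression_at_population_minimum(self):
        out = recombination_potential(40.0, 10.0, p25=[10.0, 20.0])
        assert out["max_transgression"] == 0.0

    def test_array_input(self):
        out = recombination_potential(40.0, 15.0, p25=[10.0, 20.0, 30.0])
        assert out["average"] == pytest.approx(20.0)
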