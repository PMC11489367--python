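import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

import oracles
from conftest import make_matrix
from ripopgen.differentiation import (
    PairwiseMatrix,
    evanno_delta_k,
    jost_d_matrix,
    jost_d_pair,
    pair_table,
    pairwise_distance_km,
    permutation_glm_d,
)
from ripopgen.genotype_io import PopulationMeta, PopulationSet
from ripopgen.synthetic_data import SimulationConfig, simulate_island_metapopulation


def calls_of(gm):
    return [[tuple(gm.calls[i, j]) for i in range(gm.n_individuals)]
            for j in range(gm.n_loci)]


class TestJostD:
    def test_identical_frequencies_zero(self):
        gm = make_matrix([[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)]])
        assert jost_d_pair(gm, gm) == 0.0

    def test_fixed_different_alleles_near_one(self):
        a = make_matrix(np.full((30, 2, 2), 1))
        b = make_matrix(np.full((30, 2, 2), 2))
        assert jost_d_pair(a, b) > 0.95

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(9)
        a = make_matrix(rng.integers(1, 5, size=(6, 2, 2)))
        b = make_matrix(rng.integers(2, 7, size=(5, 2, 2)))
        expected = oracles.jost_d_two_pops(calls_of(a), calls_of(b))
        assert jost_d_pair(a, b) == pytest.approx(expected, abs=1e-12)

    def test_identical_monomorphic_locus_inert(self):
        rng = np.random.default_rng(10)
        base_a = rng.integers(1, 5, size=(8, 2, 2))
        base_b = rng.integers(1, 5, size=(8, 2, 2))
        a, b = make_matrix(base_a), make_matrix(base_b)
        with_mono_a = make_matrix(np.concatenate(
            [base_a, np.full((8, 1, 2), 7)], axis=1))
        with_mono_b = make_matrix(np.concatenate(
            [base_b, np.full((8, 1, 2), 7)], axis=1))
        # identical fixed locus contributes D=0 to the arithmetic mean:
        d_with = jost_d_pair(with_mono_a, with_mono_b)
        d_without = jost_d_pair(a, b)
        assert d_with == pytest.approx(d_without * 2 / 3, abs=1e-12)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(11)
        a = make_matrix(rng.integers(1, 6, size=(10, 4, 2)))
        b = make_matrix(rng.integers(1, 6, size=(12, 4, 2)))
        d1, d2 = jost_d_pair(a, b), jost_d_pair(b, a)
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0

    def test_harmonic_option(self):
        rng = np.random.default_rng(12)
        a = make_matrix(rng.integers(1, 6, size=(10, 4, 2)))
        b = make_matrix(rng.integers(3, 9, size=(10, 4, 2)))
        arith = jost_d_pair(a, b, "arithmetic")
        harm = jost_d_pair(a, b, "harmonic")
        assert harm <= arith + 1e-12

    def test_locus_mismatch_rejected(self):
        a = make_matrix([[(1, 2)]], locus_ids=["L1"])
        b = make_matrix([[(1, 2)]], locus_ids=["L2"])
        with pytest.raises(ValueError, match="share loci"):
            jost_d_pair(a, b)


class TestPairwiseDistance:
    def test_known_distances(self, two_pop_set):
        m = pairwise_distance_km(two_pop_set)
        assert m.values[0, 1] == pytest.approx(5.0)
        assert m.values[0, 0] == 0.0

    def test_missing_coordinates_named(self):
        ps = PopulationSet({"X": make_matrix([[(1, 1)]])},
                           {"X": PopulationMeta(type="sympatric")})
        with pytest.raises(ValueError, match="X"):
            pairwise_distance_km(ps)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 100, size=(3, 2))
        ps = PopulationSet(
            {f"P{i}": make_matrix([[(1, 2)]]) for i in range(3)},
            {f"P{i}": PopulationMeta(type="sympatric", x_km=float(coords[i, 0]),
                                     y_km=float(coords[i, 1]))
             for i in range(3)},
        )
        m = pairwise_distance_km(ps).values
        assert m[0, 2] <= m[0, 1] + m[1, 2] + 1e-9

    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            PairwiseMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            PairwiseMatrix(["a", "b"], np.array([[1.0, 2.0], [2.0, 0.0]]))


@pytest.fixture(scope="module")
def labelled_landscape():
    return simulate_island_metapopulation(
        SimulationConfig(n_pops=8, N=100, s=0.3, m=0.05, L=6, k=6, mu=1e-3,
                         G=20, seed=21, sample_size=15))


class TestPairTable:
    def test_pair_types(self, labelled_landscape):
        ps = labelled_landscape
        d = jost_d_matrix(ps)
        dist = pairwise_distance_km(ps)
        pairs = pair_table(ps, d, dist)
        assert len(pairs) == 8 * 7 // 2
        assert set(pairs["pair_type"]) == {"sym-sym", "allo-sym", "allo-allo"}
        # 4 sympatric, 4 allopatric -> 6 + 16 + 6
        counts = pairs["pair_type"].value_counts()
        assert counts["allo-sym"] == 16


class TestPermutationGlm:
    def _pairs(self, y, dist, types=None):
        n = len(y)
        return pd.DataFrame({
            "pop_a": [f"a{i}" for i in range(n)],
            "pop_b": [f"b{i}" for i in range(n)],
            "pair_type": types or (["sym-sym", "allo-sym", "allo-allo"] * n)[:n],
            "distance_km": dist,
            "D": y,
        })

    def test_constant_response(self):
        pairs = self._pairs([0.5] * 30, np.linspace(0, 10, 30))
        res = permutation_glm_d(pairs, n_perm=999, seed=0)
        coefs = res.to_frame()["coefficient"]
        assert abs(coefs["distance_km"]) < 1e-12
        assert res.to_frame().loc["distance_km", "perm_p"] == 1.0

    def test_exact_linear_response_floor_p(self):
        rng = np.random.default_rng(3)
        dist = rng.uniform(0, 100, size=40)
        pairs = self._pairs(0.001 * dist, dist,
                            types=["sym-sym"] * 40)
        res = permutation_glm_d(pairs, n_perm=999, seed=1)
        df = res.to_frame()
        assert df.loc["distance_km", "coefficient"] == pytest.approx(0.001)
        assert df.loc["distance_km", "perm_p"] == pytest.approx(1 / 1000)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(7)
        dist = rng.uniform(0, 50, size=45)
        pvals = []
        for r in range(200):
            pairs = self._pairs(rng.normal(size=45), dist)
            res = permutation_glm_d(pairs, n_perm=999, seed=1000 + r)
            pvals.append(res.to_frame().loc["distance_km", "perm_p"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_isolation_by_distance_power(self):
        # pre-registered scenario: D increases with distance; permutation GLM
        # must detect the positive distance coefficient in >80% of replicates
        rng = np.random.default_rng(8)
        hits = 0
        reps = 25
        for r in range(reps):
            dist = rng.uniform(0, 100, size=45)
            y = 0.3 + 0.003 * dist + rng.normal(0, 0.05, size=45)
            pairs = self._pairs(y, dist)
            res = permutation_glm_d(pairs, n_perm=999, seed=r)
            df = res.to_frame()
            if (df.loc["distance_km", "perm_p"] < 0.05
                    and df.loc["distance_km", "coefficient"] > 0):
                hits += 1
        assert hits / reps > 0.8

    def test_rank_deficiency_flagged(self):
        pairs = self._pairs([0.1] * 10, [5.0] * 10, types=["sym-sym"] * 10)
        pairs["pair_type"] = ["sym-sym"] * 5 + ["allo-allo"] * 5
        pairs.loc[:4, "distance_km"] = 1.0
        pairs.loc[5:, "distance_km"] = 2.0  # distance collinear with type
        res = permutation_glm_d(pairs, n_perm=999, seed=0)
        assert res.flags

    def test_n_perm_minimum(self):
        pairs = self._pairs([0.1] * 10, np.arange(10))
        with pytest.raises(ValueError, match="999"):
            permutation_glm_d(pairs, n_perm=10)


class TestEvanno:
    def _table(self, lnp_by_k, jitter=0.0, reps=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for k, lnp in lnp_by_k.items():
            for rep in range(reps):
                rows.append({"K": k, "replicate": rep,
                             "lnP": lnp + (rng.normal(0, jitter) if jitter else
                                           0.1 * (rep - 1.5))})
        return pd.DataFrame(rows)

    def test_linear_lnp_gives_zero_delta(self):
        table = self._table({k: -1000.0 + 50.0 * k for k in range(1, 6)})
        stats, _ = evanno_delta_k(table)
        interior = stats["deltaK"].iloc[1:-1]
        assert np.allclose(interior, 0.0)

    def test_kink_at_three(self):
        lnp = {1: -2000.0, 2: -1500.0, 3: -1000.0, 4: -990.0, 5: -980.0}
        stats, best = evanno_delta_k(self._table(lnp))
        assert best == 3

    def test_matches_spreadsheet_oracle(self):
        lnp = {1: -900.0, 2: -700.0, 3: -650.0, 4: -500.0, 5: -480.0}
        table = self._table(lnp, jitter=5.0, reps=4, seed=3)
        stats, _ = evanno_delta_k(table)
        means = table.groupby("K")["lnP"].mean().to_dict()
        sds = table.groupby("K")["lnP"].std(ddof=1).to_dict()
        expected = oracles.evanno_delta_k_table(means, sds)
        for k, dk in expected.items():
            assert stats.loc[k, "deltaK"] == pytest.approx(dk, abs=1e-12)

    def test_zero_sd_excluded(self, caplog):
        rows = []
        for k in (1, 2, 3):
            for rep in range(3):
                noise = 0.0 if k == 2 else 0.1 * rep
                rows.append({"K": k, "replicate": rep, "lnP": -100.0 * k + noise})
        with caplog.at_level("WARNING", logger="ripopgen"):
            with pytest.raises(ValueError, match="undefined at every"):
                evanno_delta_k(pd.DataFrame(rows))
        assert "zero sd" in caplog.text

    def test_needs_three_consecutive_k(self):
        table = self._table({1: -100.0, 3: -90.0, 5: -80.0})
        with pytest.raises(ValueError, match="consecutive"):
            evanno_delta_k(table)
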