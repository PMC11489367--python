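import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import make_matrix
from ripopgen.diversity import f_is
from ripopgen.genotype_io import PlotSurvey, SeedFamily
from ripopgen.mating_system import (
    classify_seed,
    fit_outcrossing_glmm,
    g2_estimate,
    g2_forward,
    g2_invert,
    ml_selfing_fit,
    ml_selfing_loglik,
    plot_outcrossing_rate,
    selfing_estimates,
    selfing_from_fis,
)
from ripopgen.synthetic_data import (
    SimulationConfig,
    simulate_mixed_mating_population,
    simulate_plot_survey,
    simulate_seed_families,
)


class TestSelfingFromFis:
    @pytest.mark.parametrize("F,expected", [(0.0, 0.0), (1.0, 1.0), (1 / 3, 0.5)])
    def test_wright_transform(self, F, expected):
        s, flags = selfing_from_fis(F)
        assert s == pytest.approx(expected)
        assert not flags

    def test_negative_f_clamped_with_flag(self):
        s, flags = selfing_from_fis(-0.2)
        assert s == 0.0 and flags

    def test_f_minus_one_undefined(self):
        with pytest.raises(ValueError):
            selfing_from_fis(-1.0)


class TestG2:
    def test_zero_gives_zero(self):
        assert g2_invert(0.0) == 0.0

    def test_known_inversion(self):
        # forward formula at s=0.5: 0.5 / (0.5 * 3.5) = 0.2857142857...
        assert g2_forward(0.5) == pytest.approx(0.2857142857, abs=1e-9)
        assert g2_invert(0.2857142857) == pytest.approx(0.5, abs=1e-8)

    @settings(max_examples=50, deadline=None)
    @given(s=st.floats(0.0, 0.99))
    def test_roundtrip_property(self, s):
        assert g2_invert(g2_forward(s)) == pytest.approx(s, abs=1e-9)

    def test_requires_two_het_loci(self):
        gm = make_matrix([[(1, 1), (1, 2)], [(2, 2), (1, 1)]])
        with pytest.raises(ValueError, match="2 loci"):
            g2_estimate(gm)

    def test_negative_g2_undetermined(self):
        # perfectly anti-correlated heterozygosity across two loci
        gm = make_matrix([[(1, 2), (3, 3)], [(1, 1), (3, 4)]] * 4)
        res = g2_estimate(gm)
        assert res.g2 < 0
        assert res.s_hat is None
        assert any("undetermined" in f for f in res.flags)

    def test_parameter_recovery(self):
        vals = []
        for r in range(20):
            pop = simulate_mixed_mating_population(
                SimulationConfig(N=500, s=0.8, L=10, k=8, mu=1e-3, G=60,
                                 seed=200 + r, sample_size=100))
            res = g2_estimate(pop)
            if res.s_hat is not None:
                vals.append(res.s_hat)
        assert abs(np.mean(vals) - 0.8) < 0.1


class TestMlSelfing:
    def test_all_heterozygous_boundary_zero(self):
        gm = make_matrix([[(1, 2), (3, 4)]] * 6)
        res = ml_selfing_fit(gm)
        assert res.s_hat < 0.01

    def test_all_homozygous_upper_boundary(self):
        gm = make_matrix([[(1, 1), (3, 3)], [(2, 2), (4, 4)]] * 3)
        res = ml_selfing_fit(gm)
        assert res.s_hat > 0.99
        assert any("upper boundary" in f for f in res.flags)

    def test_loglik_matches_loop_oracle(self):
        het = [[1, 0], [0, 0], [1, 1], [None, 1], [0, None]]
        het_arr = np.array([[x == 1 for x in row] for row in het])
        obs_arr = np.array([[x is not None for x in row] for row in het])
        for s, h in [(0.0, [0.5, 0.6]), (0.3, [0.7, 0.2]), (0.9, [0.9, 0.8])]:
            expected = oracles.ml_loglik_loops(s, h, het)
            got = ml_selfing_loglik(s, np.array(h), het_arr, obs_arr)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_fit_beats_grid_oracle(self):
        # 2-locus, 5-individual instance: fitted logL >= best grid point
        gm = make_matrix([
            [(1, 2), (3, 3)], [(1, 1), (3, 4)], [(1, 2), (3, 4)],
            [(2, 2), (4, 4)], [(1, 1), (3, 3)],
        ])
        res = ml_selfing_fit(gm)
        het = [[1 if gm.het_mask()[i, j] else 0 for j in range(2)]
               for i in range(5)]
        grid = np.linspace(0.01, 0.99, 15)
        best = max(
            oracles.ml_loglik_loops(s, [h1, h2], het)
            for s in grid for h1 in grid for h2 in grid
        )
        assert res.loglik >= best - 1e-6

    def test_parameter_recovery(self):
        vals = []
        for r in range(20):
            pop = simulate_mixed_mating_population(
                SimulationConfig(N=500, s=0.8, L=10, k=8, mu=1e-3, G=60,
                                 seed=300 + r, sample_size=30))
            vals.append(ml_selfing_fit(pop).s_hat)
        assert abs(np.mean(vals) - 0.8) < 0.1


class TestEstimatorConcordance:
    @pytest.mark.parametrize("s", [0.2, 0.5, 0.9])
    def test_three_routes_agree(self, s):
        sf_vals, g2_vals, ml_vals = [], [], []
        for r in range(8):
            pop = simulate_mixed_mating_population(
                SimulationConfig(N=500, s=s, L=10, k=8, mu=1e-3, G=60,
                                 seed=1000 + r, sample_size=60))
            F = f_is(pop).f
            sf_vals.append(selfing_from_fis(max(F, 0.0))[0])
            res = g2_estimate(pop)
            if res.s_hat is not None:
                g2_vals.append(res.s_hat)
            ml_vals.append(ml_selfing_fit(pop).s_hat)
        means = [np.mean(sf_vals), np.mean(g2_vals), np.mean(ml_vals)]
        for a in means:
            for b in means:
                assert abs(a - b) < 0.1


class TestClassifier:
    def _family(self, mother_calls, embryo_calls):
        mom = make_matrix([mother_calls], individual_ids=["M"])
        emb = make_matrix(embryo_calls,
                          individual_ids=[f"e{k}" for k in range(len(embryo_calls))])
        return SeedFamily("plot1", "S01", mom, emb)

    def test_compatible_embryo_is_selfed(self):
        fam = self._family([(1, 2), (3, 3)], [[(1, 1), (3, 3)]])
        calls = classify_seed(fam)
        assert calls[0].label == "selfed"
        assert calls[0].evidence_loci == []

    def test_foreign_allele_is_outcrossed(self):
        fam = self._family([(1, 2), (3, 3)], [[(2, 4), (3, 3)]])
        calls = classify_seed(fam)
        assert calls[0].label == "outcrossed"
        assert calls[0].evidence_loci == ["L0"]

    def test_missing_loci_skipped(self):
        fam = self._family([(0, 0), (3, 3)], [[(9, 9), (3, 3)]])
        assert classify_seed(fam)[0].label == "selfed"

    def test_no_comparable_locus_undetermined(self):
        fam = self._family([(0, 0), (3, 3)], [[(9, 9), (0, 0)], [(1, 1), (3, 3)]])
        calls = classify_seed(fam)
        assert calls[0].label == "undetermined"

    def test_truly_selfed_never_outcrossed(self):
        mothers = simulate_mixed_mating_population(
            SimulationConfig(N=200, s=0.5, L=10, k=8, mu=1e-3, G=40, seed=2,
                             sample_size=50))
        fams = simulate_seed_families(mothers, 1.0, mothers, 20, seed=3)
        labels = [c.label for f in fams for c in classify_seed(f)]
        assert "outcrossed" not in labels

    def test_conservative_rate_below_truth(self):
        mothers = simulate_mixed_mating_population(
            SimulationConfig(N=100, s=0.5, L=10, k=8, mu=1e-3, G=40, seed=4,
                             sample_size=30))
        est_rates, true_rates = [], []
        for r in range(50):
            fams = simulate_seed_families(mothers, 0.5, mothers, 5, seed=50 + r)
            calls = [c for f in fams for c in classify_seed(f)]
            labels = [l for f in fams for l in f.true_labels]
            est_rates.append(np.mean([c.label == "outcrossed" for c in calls]))
            true_rates.append(np.mean([l == "outcrossed" for l in labels]))
        assert np.mean(est_rates) <= np.mean(true_rates)


class TestPlotRates:
    def test_simple_rates(self):
        plots = [PlotSurvey("a", "p", "d", 1, 1, 0.0, 5, 0),
                 PlotSurvey("b", "p", "d", 1, 1, 0.0, 4, 2)]
        rates = plot_outcrossing_rate(plots)
        assert rates["a"] == 0.0 and rates["b"] == 0.5

    def test_zero_seed_plot_excluded(self, caplog):
        plots = [PlotSurvey("a", "p", "d", 1, 1, 0.0, 0, 0),
                 PlotSurvey("b", "p", "d", 1, 1, 0.0, 2, 1)]
        with caplog.at_level("WARNING", logger="ripopgen"):
            rates = plot_outcrossing_rate(plots)
        assert list(rates.index) == ["b"]
        assert "excluded" in caplog.text

    def test_consistency_with_classifier(self):
        mothers = simulate_mixed_mating_population(
            SimulationConfig(N=80, s=0.2, L=8, k=8, G=30, seed=6, sample_size=10))
        fams = simulate_seed_families(mothers, 0.3, mothers, 6, seed=8)
        calls = [c for f in fams for c in classify_seed(f)]
        determined = [c for c in calls if c.label != "undetermined"]
        n_out = sum(c.label == "outcrossed" for c in determined)
        plot = PlotSurvey("plot1", "pop1", "d", 1, 1, 0.0, len(determined), n_out)
        assert plot_outcrossing_rate([plot])["plot1"] == pytest.approx(
            n_out / len(determined))


class TestGlmm:
    def test_glm_limit_recovers_truth(self):
        plots = simulate_plot_survey(1.0, -2.0, 0.5, 0.0, sd_date=0.0,
                                     sd_pop=0.0, n_plots=400, seeds_per_plot=50,
                                     seed=10)
        res = fit_outcrossing_glmm(plots)
        truth = [1.0, -2.0, 0.5, 0.0]
        for b, se, t in zip(res.beta, res.se, truth):
            assert abs(b - t) < max(3 * se, 0.15)

    def test_recovery_within_2se(self):
        truth = np.array([1.0, -2.0, 0.5, 0.0])
        hits = []
        for r in range(20):
            plots = simulate_plot_survey(*truth, sd_date=0.3, sd_pop=0.3,
                                         n_plots=200, seeds_per_plot=20,
                                         seed=600 + r)
            res = fit_outcrossing_glmm(plots)
            hits.append(np.abs(res.beta - truth) <= 2 * res.se)
        # ~95% coverage per coefficient over 20 replicates
        assert np.mean(hits) >= 0.85

    def test_null_calibration(self):
        rej = []
        for r in range(100):
            plots = simulate_plot_survey(0.0, 0.0, 0.0, 0.0, sd_date=0.3,
                                         sd_pop=0.3, n_plots=60,
                                         seeds_per_plot=15, seed=r)
            res = fit_outcrossing_glmm(plots)
            rej.extend(np.abs(res.zvalues[1:]) > 1.96)
        assert np.mean(rej) <= 0.10

    def test_degenerate_random_term_flagged(self):
        plots = [PlotSurvey(f"p{k}", "onlypop", "sameday", 5, 5, 1.0, 10, 5)
                 for k in range(10)]
        res = fit_outcrossing_glmm(plots)
        assert any("<2 levels" in f for f in res.flags)

    def test_too_few_plots_rejected(self):
        with pytest.raises(ValueError, match="2 plots"):
            fit_outcrossing_glmm([PlotSurvey("a", "p", "d", 1, 1, 0.0, 5, 1)])


class TestSelfingTable:
    def test_table_shape_and_bounds(self):
        from ripopgen.genotype_io import PopulationSet
        pops = {}
        for i, s in enumerate((0.2, 0.8)):
            pops[f"P{i}"] = simulate_mixed_mating_population(
                SimulationConfig(N=200, s=s, L=8, k=8, mu=1e-3, G=40,
                                 seed=20 + i, sample_size=25))
        df = selfing_estimates(PopulationSet(pops))
        assert set(["S_F", "g2", "S_g2", "S_ML"]).issubset(df.columns)
        for col in ("S_F", "S_ML"):
            assert ((df[col] >= 0) & (df[col] <= 1)).all()
        assert df.loc["P1", "S_F"] > df.loc["P0", "S_F"]
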