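"""Grid-search fitting, KS goodness of fit, AIC, and the batch comparison."""

import numpy as np
import pytest
from scipy import stats

from efdcomp import (
    CompetitionParams,
    EFDHistogram,
    FitGrid,
    HistogramSpec,
    aic,
    build_histogram,
    compare_models,
    competition_pmf,
    empirical_peak_time,
    fit_competition,
    fit_exgaussian,
    ks_binned,
    multinomial_loglik,
    sample_efd,
)
from efdcomp.simulate import SimulationDesign, generate_mdtm


def _hist_from_probs(probs, spec, n=100_000):
    counts = np.round(np.asarray(probs) * n).astype(int)
    return EFDHistogram(spec, counts[:-1], int(counts[-1]))


class TestFitGrid:
    def test_default_shape(self):
        g = FitGrid()
        assert g.shape == (100, 99)
        assert g.A_values[0] == 0.05 and g.A_values[-1] == 5.0
        assert g.ps_values[0] == 0.01 and g.ps_values[-1] == 0.99

    def test_rejects_empty_or_unordered(self):
        with pytest.raises(ValueError):
            FitGrid(A_values=(), ps_values=(0.5,))
        with pytest.raises(ValueError):
            FitGrid(A_values=(1.0, 0.5), ps_values=(0.5,))
        with pytest.raises(ValueError):
            FitGrid(A_values=(1.0,), ps_values=(0.0, 0.5))


class TestFitCompetition:
    def test_self_fit_fixed_point(self, spec50):
        truth = CompetitionParams(A=1.5, ps=0.25)
        pmf = competition_pmf(truth, collapse_index=15)
        hist = _hist_from_probs(pmf.binned(), spec50)
        res = fit_competition(hist)
        assert res.params.A == pytest.approx(1.5, abs=0.05)
        assert res.params.ps == pytest.approx(0.25, abs=0.01)
        assert res.correlation > 0.999

    def test_simulation_recovery(self, spec50, mid_params):
        d = sample_efd(mid_params, 5000, rng=np.random.default_rng(1))
        res = fit_competition(build_histogram(d, spec50))
        assert abs(res.params.A - 1.5) <= 2 * 0.05
        assert abs(res.params.ps - 0.25) <= 2 * 0.01

    def test_exhaustive_argmax_is_deterministic(self, spec50, mid_params):
        d = sample_efd(mid_params, 2000, rng=np.random.default_rng(3))
        hist = build_histogram(d, spec50)
        a = fit_competition(hist)
        b = fit_competition(hist)
        assert (a.params.A, a.params.ps) == (b.params.A, b.params.ps)
        assert a.correlation == b.correlation

    def test_constant_histogram_rejected(self, spec50):
        hist = EFDHistogram(spec50, [5] * 15, 5)
        with pytest.raises(ValueError, match="constant"):
            fit_competition(hist)

    def test_result_is_consistent(self, spec50, mid_params):
        d = sample_efd(mid_params, 3000, rng=np.random.default_rng(4))
        res = fit_competition(build_histogram(d, spec50))
        assert res.aic == pytest.approx(2 * res.k - 2 * res.loglik, abs=1e-9)
        assert 0 <= res.ks_D <= 1
        assert res.k == 2 and res.model_name == "competition"


class TestKsBinned:
    def test_identical_distributions(self, spec50, rng):
        h = build_histogram(rng.uniform(1, 1400, 400), spec50)
        from efdcomp.histogram import histogram_probabilities
        D, p = ks_binned(h, histogram_probabilities(h))
        assert D == 0.0 and p == 1.0

    def test_two_bin_interior_edge(self):
        spec = HistogramSpec(50, 100, 1500)
        h = EFDHistogram(spec, [60, 40], 0)
        D, p = ks_binned(h, np.array([0.5, 0.5, 0.0]))
        assert D == pytest.approx(0.1, abs=1e-12)

    def test_asymptotic_kolmogorov_pvalue(self):
        # oracle: Kolmogorov series P(sqrt(n) D > x) = 2 sum (-1)^(k-1) e^(-2 k^2 x^2)
        spec = HistogramSpec(50, 100, 1500)
        h = EFDHistogram(spec, [60, 40], 0)  # n = 100, D = 0.1
        _, p = ks_binned(h, np.array([0.5, 0.5, 0.0]))
        lam = np.sqrt(100) * 0.1
        series = 2 * sum((-1) ** (k - 1) * np.exp(-2 * k ** 2 * lam ** 2)
                         for k in range(1, 101))
        assert p == pytest.approx(series, abs=1e-6)
        assert p == pytest.approx(0.270, abs=5e-4)

    def test_misaligned_vector_rejected(self, spec50, rng):
        h = build_histogram(rng.uniform(1, 700, 100), spec50)
        with pytest.raises(ValueError, match="shape"):
            ks_binned(h, np.ones(5) / 5)

    def test_ks_calibration_against_true_params(self, spec50, mid_params):
        # data simulated from the model, tested against the true PMF:
        # rejection rate at alpha = 0.05 stays near (in fact below) nominal
        probs = competition_pmf(mid_params, collapse_index=15).binned()
        rejections = 0
        n_rep = 200
        for i in range(n_rep):
            d = sample_efd(mid_params, 200, rng=np.random.default_rng(1000 + i))
            h = build_histogram(d, spec50)
            _, p = ks_binned(h, probs)
            rejections += p < 0.05
        assert rejections / n_rep <= 0.07


class TestLoglikAndAic:
    def test_hand_computed_loglik(self):
        spec = HistogramSpec(50, 100, 1500)
        h = EFDHistogram(spec, [6, 4], 0)
        ll = multinomial_loglik(h, np.array([0.5, 0.5, 0.0]))
        assert ll == pytest.approx(10 * np.log(0.5), abs=1e-9)

    def test_perfect_prediction_gives_zero(self):
        spec = HistogramSpec(50, 100, 1500)
        h = EFDHistogram(spec, [10, 0], 0)
        assert multinomial_loglik(h, np.array([1.0, 0.0, 0.0])) == 0.0

    def test_mle_at_own_proportions(self):
        spec = HistogramSpec(50, 100, 1500)
        h = EFDHistogram(spec, [6, 4], 0)
        best = multinomial_loglik(h, np.array([0.6, 0.4, 0.0]))
        for q in (0.3, 0.5, 0.7, 0.9):
            assert multinomial_loglik(h, np.array([q, 1 - q, 0.0])) <= best

    def test_aic_arithmetic(self):
        assert aic(-6.9315, 1) == pytest.approx(15.863, abs=1e-3)
        assert aic(-10.0, 3) - aic(-10.0, 2) == pytest.approx(2.0)
        assert aic(-5.0, 2) < aic(-6.0, 2)


@pytest.fixture(scope="module")
def small_batch():
    design = SimulationDesign(n_subjects=3, blocks=(1, 2),
                              image_types=(7, 11),
                              fixations_per_condition=300, seed=42)
    mdtm = generate_mdtm(design)
    return mdtm, compare_models(mdtm)


class TestCompareModels:
    def test_one_row_per_condition(self, small_batch):
        _, comp = small_batch
        assert comp.n_total == 3 * 2 * 2
        assert len(comp.table) == comp.n_total
        assert comp.failures == []

    def test_competition_wins_on_its_own_data(self, small_batch):
        _, comp = small_batch
        assert comp.win_fraction > 50.0

    def test_win_fraction_accounting(self, small_batch):
        _, comp = small_batch
        wins = (comp.table["winner"] == "competition").sum()
        assert wins == comp.n_competition_wins
        assert comp.win_fraction == pytest.approx(100 * wins / comp.n_total)

    def test_single_condition_table(self, spec50, mid_params):
        import pandas as pd
        from efdcomp import MDTMTable
        d = sample_efd(mid_params, 400, rng=np.random.default_rng(9))
        df = pd.DataFrame({"duration_ms": d, "subject": 1,
                           "image_order": np.arange(len(d)), "block": 1,
                           "image_type": 7})
        comp = compare_models(MDTMTable(df))
        assert comp.n_total == 1

    def test_peak_time_alignment_across_conditions(self):
        # model vs empirical peak times correlate strongly over varied params
        rng = np.random.default_rng(5)
        spec = HistogramSpec()
        model_peaks, emp_peaks = [], []
        for _ in range(100):
            p = CompetitionParams(A=rng.uniform(0.5, 3.0),
                                  ps=rng.uniform(0.08, 0.5))
            d = sample_efd(p, 2000, rng=rng)
            hist = build_histogram(d, spec)
            res = fit_competition(hist)
            model_peaks.append(res.peak_time_model)
            emp_peaks.append(res.peak_time_empirical)
        r = np.corrcoef(model_peaks, emp_peaks)[0, 1]
        assert r > 0.9

    def test_fitted_params_track_generating_anticorrelation(self):
        # conditions generated with A and ps negatively correlated should
        # yield negatively correlated fitted parameters
        rng = np.random.default_rng(6)
        spec = HistogramSpec()
        fitted = []
        for _ in range(60):
            u = rng.uniform()
            p = CompetitionParams(A=0.6 + 2.2 * u,
                                  ps=0.45 - 0.35 * u + rng.normal(0, 0.02))
            d = sample_efd(p, 2000, rng=rng)
            res = fit_competition(build_histogram(d, spec))
            fitted.append((res.params.A, res.params.ps))
        A, ps = np.array(fitted).T
        assert np.corrcoef(A, ps)[0, 1] < -0.5


class TestEmpiricalPeak:
    def test_modal_bin_midpoint(self, spec50):
        counts = np.zeros(15, dtype=int)
        counts[4] = 50
        counts[5] = 20
        h = EFDHistogram(spec50, counts, 0)
        assert empirical_peak_time(h) == 225.0

    def test_tie_goes_to_earliest_bin(self, spec50):
        counts = np.zeros(15, dtype=int)
        counts[3] = counts[7] = 50
        h = EFDHistogram(spec50, counts, 0)
        assert empirical_peak_time(h) == 175.0
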