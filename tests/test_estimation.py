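"""pKa estimation and trajectory analytics on synthetic constant-pH data."""

import numpy as np
import pandas as pd
import pytest

from phlinkage import (
    KineticParams,
    PkaEstimate,
    ThermoCycle,
    TitrationSeries,
    Trajectory,
    bootstrap_ci,
    conditional_pka,
    detect_transition,
    fit_titration,
    pka_from_counts,
    running_average,
    running_pka,
    simulate,
    summarize_observable,
)


def hh_fraction(ph, pka, hill=1.0):
    """Protonated fraction under the Henderson-Hasselbalch law."""
    return 1.0 / (1.0 + 10.0 ** (hill * (np.asarray(ph) - pka)))


def exact_hh_series(pka: float, n_total: int = 1000) -> TitrationSeries:
    """Counts that are exact HH fractions: pH offsets log10(r) give f = 1/(1+r)."""
    ratios = np.array([1 / 9, 1 / 3, 1.0, 3.0, 9.0])
    ph = pka + np.log10(ratios)
    k = (n_total / (1.0 + ratios)).round().astype(int)
    assert np.allclose(k, n_total * hh_fraction(ph, pka))  # oracle self-check
    return TitrationSeries(ph=ph, n_protonated=k, n_total=np.full(5, n_total))


def make_trajectory(protonated, conformation=None, ph=7.5, **kwargs):
    protonated = np.asarray(protonated, dtype=int)
    n = protonated.size
    if conformation is None:
        conformation = ["closed"] * n
    frames = pd.DataFrame(
        {
            "time_ns": np.arange(n, dtype=float) * 1e-4,
            "conformation": conformation,
            "protonated": protonated,
            "d_asp30_leu130": np.full(n, 3.5),
            "d_asp35_asp129": np.full(n, 5.0),
            "sasa": np.full(n, 9.0),
        }
    )
    return Trajectory(frames=frames, ph=ph, **kwargs)


class TestPkaFromCounts:
    def test_half_protonated_returns_the_ph(self):
        assert pka_from_counts(5.5, 500, 1000).pka == pytest.approx(5.5)

    def test_ten_to_one_odds(self):
        est = pka_from_counts(7.5, 909, 1000)
        assert est.pka == pytest.approx(7.5 + np.log10(909 / 91), abs=1e-12)
        assert est.pka == pytest.approx(8.50, abs=0.01)

    def test_stderr_matches_binomial_propagation(self):
        est = pka_from_counts(7.5, 909, 1000)
        f = 0.909
        expected = 1.0 / (np.log(10) * np.sqrt(1000 * f * (1 - f)))
        assert est.stderr == pytest.approx(expected)
        assert est.ci[0] < est.pka < est.ci[1]

    @pytest.mark.parametrize(
        "k, direction", [(1000, ">"), (0, "<")], ids=["all_protonated", "none_protonated"]
    )
    def test_extreme_fractions_are_censored_not_infinite(self, k, direction):
        est = pka_from_counts(7.5, k, 1000)
        assert est.is_censored and est.censored == direction
        assert est.bound == 7.5
        assert not np.isinf(est.bound)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            pka_from_counts(7.5, 11, 10)
        with pytest.raises(ValueError):
            pka_from_counts(7.5, 0, 0)


class TestFitTitration:
    @pytest.mark.parametrize("pka_true", [8.5, 4.3])
    def test_noiseless_recovery(self, pka_true):
        est = fit_titration(exact_hh_series(pka_true))
        assert est.pka == pytest.approx(pka_true, abs=1e-6)
        assert est.hill == 1.0

    @pytest.mark.parametrize("pka_true", [8.5, 4.3])
    def test_free_hill_recovers_unit_slope(self, pka_true):
        est = fit_titration(exact_hh_series(pka_true), fix_hill=False)
        assert est.pka == pytest.approx(pka_true, abs=1e-4)
        assert est.hill == pytest.approx(1.0, abs=1e-3)

    def test_consistent_with_single_point_inversions(self):
        # on noiseless HH data every single-point inversion and the pooled
        # fit must land on the same pKa
        series = exact_hh_series(8.5)
        est = fit_titration(series)
        for ph, k, n in zip(series.ph, series.n_protonated, series.n_total):
            inv = pka_from_counts(ph, int(k), int(n))
            assert est.pka == pytest.approx(inv.pka, abs=1e-6)

    def test_calibration_of_stated_errors(self):
        # binomial noise at the true curve: +-2 SE covers the truth at the
        # nominal ~95.4% rate; 500 replicates resolve that to ~+-2.8% (3 sigma)
        rng = np.random.default_rng(812)
        ph = np.linspace(6.0, 11.0, 6)
        f = hh_fraction(ph, 8.5)
        hits = 0
        for _ in range(500):
            k = rng.binomial(2000, f)
            est = fit_titration(
                TitrationSeries(ph=ph, n_protonated=k, n_total=np.full(6, 2000))
            )
            hits += abs(est.pka - 8.5) <= 2 * est.stderr
        assert 0.93 <= hits / 500 <= 0.99

    def test_insufficient_informative_points_rejected(self):
        series = TitrationSeries(
            ph=np.array([3.0, 12.0]),
            n_protonated=np.array([1000, 0]),
            n_total=np.array([1000, 1000]),
        )
        with pytest.raises(ValueError, match="bound the pKa"):
            fit_titration(series)


class TestConditionalPka:
    def test_recovers_both_microscopic_values(self, equilibrated_trajectory):
        closed_est, open_est = conditional_pka(equilibrated_trajectory)
        assert closed_est.pka == pytest.approx(8.5, abs=0.1)
        assert open_est.pka == pytest.approx(4.3, abs=0.1)

    def test_single_conformation_all_protonated_is_censored(self):
        traj = make_trajectory(np.ones(1000))
        closed_est, open_est = conditional_pka(traj)
        assert closed_est.censored == ">"
        assert open_est.is_censored and open_est.n_samples == 0

    def test_pooling_doubles_samples_and_shrinks_stderr_by_sqrt2(self):
        # two trajectories with identical per-frame statistics: pooling must
        # double the counts and shrink the binomial stderr by exactly sqrt(2)
        rng = np.random.default_rng(13)
        prot = (rng.random(10_000) < 0.8).astype(int)
        t1 = make_trajectory(prot, ph=7.5)
        t2 = make_trajectory(prot, ph=7.5)
        single, _ = conditional_pka(t1, burn_in=0.0)
        pooled, _ = conditional_pka([t1, t2], burn_in=0.0)
        assert pooled.n_samples == 2 * single.n_samples
        assert pooled.pka == pytest.approx(single.pka)
        assert pooled.stderr == pytest.approx(single.stderr / np.sqrt(2), rel=1e-9)

    def test_mixed_ph_trajectories_rejected(self, reference_cycle):
        t1 = make_trajectory(np.ones(100), ph=6.5)
        t2 = make_trajectory(np.ones(100), ph=7.5)
        with pytest.raises(ValueError, match="share one pH"):
            conditional_pka([t1, t2])


class TestRunningAverage:
    def test_constant_series_maps_to_itself(self):
        smoothed, filled = running_average(np.full(500, 3.5), 100)
        assert np.allclose(smoothed, 3.5)
        assert filled.sum() == 99 and filled[:99].all()

    def test_alternating_series_settles_at_half(self):
        smoothed, _ = running_average(np.tile([0.0, 1.0], 50), 2)
        assert np.allclose(smoothed[1:], 0.5)

    def test_white_noise_variance_reduction(self):
        rng = np.random.default_rng(55)
        x = rng.normal(3.5, 0.3, size=100_000)
        smoothed, filled = running_average(x, 100)
        sd = np.std(smoothed[~filled])
        assert sd == pytest.approx(0.3 / np.sqrt(100), rel=0.15)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            running_average([], 10)


class TestRunningPka:
    def test_fully_protonated_trace_is_censored_above_ph(self):
        traj = make_trajectory(np.ones(200), ph=7.5)
        trace = running_pka(traj, window=50)
        assert trace["pka"].isna().all()
        assert (trace["censored"].iloc[49:] == ">").all()

    def test_full_window_matches_global_inversion(self):
        rng = np.random.default_rng(7)
        prot = rng.random(500) < 0.8
        traj = make_trajectory(prot.astype(int), ph=7.5)
        trace = running_pka(traj, window=500)
        global_est = pka_from_counts(7.5, int(prot.sum()), 500)
        assert trace["pka"].iloc[-1] == pytest.approx(global_est.pka)
        assert trace["pka"].iloc[:-1].isna().all()

    def test_trace_drifts_from_closed_to_open_regime_after_opening(self, reference_cycle):
        # closed-protonated start at pH 7.5: deprotonation then opening; the
        # windowed pKa starts in the closed regime (high values, ~8.5-like
        # protonation odds) and ends open-dominated, where windows read low
        # values or are censored below the solvent pH
        traj = simulate(reference_cycle, 7.5, KineticParams(n_steps=60_000, seed=21))
        window = 100
        trace = running_pka(traj, window=window)
        open_frac = (
            pd.Series((traj.frames["conformation"] == "open").to_numpy(float))
            .rolling(window)
            .mean()
            .to_numpy()
        )
        pka = trace["pka"].to_numpy()
        cens = trace["censored"].to_numpy()
        closed_windows = open_frac == 0.0
        open_windows = open_frac == 1.0
        assert closed_windows.sum() > 50 and open_windows.sum() > 1000
        # fully closed windows read high (toward 8.5) or are censored above
        high = (cens == ">") | (pka > 6.5)
        assert high[closed_windows].mean() > 0.9
        # fully open windows read low (toward 4.3) or are censored below
        low = (cens == "<") | (pka < 5.6)
        assert low[open_windows].mean() > 0.9
        # and the opening happened: closed windows precede the open bulk
        assert np.nonzero(closed_windows)[0][0] < np.nonzero(open_windows)[0][0]

    def test_window_bounds_enforced(self):
        traj = make_trajectory(np.ones(100))
        with pytest.raises(ValueError):
            running_pka(traj, window=5)
        with pytest.raises(ValueError):
            running_pka(traj, window=101)


class TestSummarizeObservable:
    def test_recovers_generator_parameters(self):
        rng = np.random.default_rng(100)
        mean, sd = summarize_observable(rng.normal(3.5, 0.3, size=20_000))
        assert mean == pytest.approx(3.5, abs=3 * 0.3 / np.sqrt(20_000))
        assert sd == pytest.approx(0.3, rel=0.05)

    def test_identical_values_have_zero_sd(self):
        assert summarize_observable([4.2, 4.2]) == (4.2, 0.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            summarize_observable([1.0])


class TestDetectTransition:
    REF_CLOSED = (3.5, 0.3)
    REF_OPEN = (8.0, 1.0)

    def test_step_series_located_exactly_without_smoothing(self):
        series = np.r_[np.full(5000, 3.5), np.full(5000, 8.0)]
        assert detect_transition(series, self.REF_CLOSED, self.REF_OPEN, 50) == 5000

    def test_smoothing_delays_by_at_most_the_window(self):
        series = np.r_[np.full(5000, 3.5), np.full(5000, 8.0)]
        idx = detect_transition(series, self.REF_CLOSED, self.REF_OPEN, 50, window=100)
        assert 5000 <= idx <= 5100

    def test_constant_series_has_no_transition(self):
        assert detect_transition(np.full(2000, 3.5), self.REF_CLOSED, self.REF_OPEN, 50) is None

    def test_brief_excursion_filtered_by_persistence(self):
        series = np.full(2000, 3.5)
        series[1000] = 8.0
        assert detect_transition(series, self.REF_CLOSED, self.REF_OPEN, 50) is None

    def test_overlapping_references_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            detect_transition(np.zeros(100), (3.5, 2.0), (5.0, 2.0), 10)


class TestBootstrapCi:
    def test_constant_series_zero_width(self):
        lo, hi = bootstrap_ci(np.full(1000, 2.5), "mean", 200, 10, seed=0)
        assert lo == hi == 2.5

    def test_iid_bernoulli_interval(self):
        rng = np.random.default_rng(42)
        x = (rng.random(10_000) < 0.5).astype(float)
        lo, hi = bootstrap_ci(x, "mean", 1000, 1, seed=1)
        assert lo < 0.5 < hi
        assert lo == pytest.approx(0.49, abs=0.005)
        assert hi == pytest.approx(0.51, abs=0.005)

    def test_same_seed_reproduces_interval(self):
        x = np.random.default_rng(9).normal(size=2000)
        assert bootstrap_ci(x, "mean", 200, 50, seed=7) == bootstrap_ci(x, "mean", 200, 50, seed=7)

    def test_coverage_on_binomial_titration_fractions(self):
        # 95% intervals for the protonated fraction should cover the truth in
        # 90-99% of replicates
        rng = np.random.default_rng(2024)
        f_true = 1.0 / (1.0 + 10.0 ** (6.5 - 8.5))  # protonated fraction at pH 6.5
        hits = 0
        for _ in range(200):
            x = (rng.random(1000) < f_true).astype(float)
            lo, hi = bootstrap_ci(x, "mean", 200, 1, seed=int(rng.integers(2**31)))
            hits += lo <= f_true <= hi
        assert 0.90 <= hits / 200 <= 0.99

    def test_parameter_validation(self):
        x = np.zeros(100)
        with pytest.raises(ValueError):
            bootstrap_ci(x, "mean", 50, 10)
        with pytest.raises(ValueError):
            bootstrap_ci(x, "mean", 200, 101)


class TestPkaEstimateContract:
    def test_ci_must_contain_point_estimate(self):
        with pytest.raises(ValueError):
            PkaEstimate(pka=5.0, ci=(5.5, 6.0))

    def test_uncensored_estimate_must_be_finite(self):
        with pytest.raises(ValueError):
            PkaEstimate(pka=np.inf)
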