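"""Decay-constant fitting, peak finding, and the summary-table builder."""

import numpy as np
import pytest

import camkii_spine as ck
from camkii_spine import analysis
from camkii_spine.params import ParameterError


def _trace(tau, A=200.0, floor=0.0, dt=0.01, t_end=30.0, rng=None, poisson=False):
    t = np.arange(0.0, t_end + dt / 2, dt)
    y = A * np.exp(-t / tau) + floor
    if poisson:
        y = rng.poisson(np.clip(y, 0, None)).astype(float)
    return t, y


class TestTauFit:
    def test_noiseless_recovery(self):
        t, y = _trace(tau=2.0)
        fit = ck.fit_exponential_tau(t, y, (0.0, 10.0))
        assert fit.ok and fit.tau == pytest.approx(2.0, abs=0.01)
        assert fit.amplitude == pytest.approx(200.0, rel=0.01)

    def test_two_point_closed_form(self):
        t = np.array([4.0, 4.5, 5.0])
        y = np.array([100.0, 80.0, 60.0])
        fit = ck.fit_exponential_tau(t, y, (4.0, 5.0), method="two_point")
        assert fit.tau == pytest.approx(1.0 / np.log(100 / 60), rel=1e-9)
        assert fit.tau == pytest.approx(1.9576, abs=1e-3)

    def test_floor_is_recovered(self):
        t, y = _trace(tau=3.0, floor=40.0)
        fit = ck.fit_exponential_tau(t, y, (0.0, 20.0), with_floor=True)
        assert fit.tau == pytest.approx(3.0, rel=0.01)
        assert fit.floor == pytest.approx(40.0, rel=0.02)

    def test_noisy_average_recovery_within_ten_percent(self):
        rng = np.random.default_rng(1)
        traces = [_trace(tau=2.0, poisson=True, rng=rng)[1] for _ in range(20)]
        t = _trace(tau=2.0)[0]
        fit = ck.fit_exponential_tau(t, np.mean(traces, axis=0), (0.0, 8.0))
        assert fit.ok and fit.tau == pytest.approx(2.0, rel=0.10)

    @pytest.mark.parametrize("tau", [0.3, 2.0, 60.0])
    def test_unbiased_across_timescales(self, tau):
        """Monte-Carlo bias of the mean-trace fit stays within the noise."""
        rng = np.random.default_rng(7)
        t_end = min(max(6 * tau, 2.0), 40.0)
        t = np.arange(0.0, t_end, 0.01)
        taus = []
        for _ in range(10):
            y = 200.0 * np.exp(-t / tau)
            y = rng.poisson(y).astype(float)
            fit = ck.fit_exponential_tau(t, y, (0.0, t[-1]), with_floor=False)
            taus.append(fit.tau)
        mean = np.mean(taus)
        se = np.std(taus, ddof=1) / np.sqrt(len(taus))
        assert abs(mean - tau) <= max(3 * se, 0.05 * tau)

    def test_non_decaying_window_reports_failure_not_exception(self):
        t = np.arange(0.0, 5.0, 0.01)
        y = np.full_like(t, 10.0)
        fit = ck.fit_exponential_tau(t, y, (0.0, 4.0))
        assert not fit.ok and fit.tau is None
        fit2 = ck.fit_exponential_tau(t, y, (0.0, 4.0), method="two_point")
        assert not fit2.ok

    def test_window_outside_span_rejected(self):
        t, y = _trace(tau=1.0, t_end=5.0)
        with pytest.raises(ParameterError):
            ck.fit_exponential_tau(t, y, (2.0, 50.0))


class TestFindPeak:
    def test_monotone_rising_peaks_at_end(self):
        t = np.arange(0.0, 2.0, 0.01)
        tp, vp = ck.find_peak(t, t ** 2, (0.0, 1.99), smooth_s=0.0)
        assert tp == pytest.approx(t[-1])

    def test_interior_maximum(self):
        t = np.arange(0.0, 10.0, 0.01)
        y = np.exp(-((t - 4.0) ** 2))
        tp, vp = ck.find_peak(t, y, smooth_s=0.0)
        assert tp == pytest.approx(4.0, abs=0.02)
        assert vp == pytest.approx(1.0, rel=1e-3)

    def test_tie_break_earliest(self):
        t = np.arange(0.0, 1.0, 0.1)
        y = np.zeros_like(t)
        y[[3, 7]] = 5.0
        tp, _ = ck.find_peak(t, y, smooth_s=0.0)
        assert tp == pytest.approx(t[3])

    def test_empty_interval_rejected(self):
        t = np.arange(0.0, 1.0, 0.1)
        with pytest.raises(ParameterError):
            ck.find_peak(t, t, (0.5, 0.4))


class TestNeighborProbability:
    @pytest.mark.parametrize("m,expected", [
        (1.5, 1.0 / 3.0),
        (0.75, 0.75 / 5.25),
        (0.0, 0.0),
        (5.9, 1.0),  # capped
    ])
    def test_heuristic(self, m, expected):
        assert ck.neighbor_probability(m) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            ck.neighbor_probability(6.0)
        with pytest.raises(ParameterError):
            ck.neighbor_probability(-0.1)


class _StubEnsemble:
    """Duck-typed stand-in for an engine Ensemble (synthetic mean trace)."""

    def __init__(self, times, trace):
        self.times = times
        self._trace = trace

    def mean_observable(self, name):
        assert name == "pT286"
        return self._trace


class TestMakeTable1:
    def _stub(self, tau1, tau2, t_end=11.0):
        t = np.arange(0.0, t_end + 0.005, 0.01)
        y = np.where(t < 2.0, 200.0 * t / 2.0,
                     200.0 * np.exp(-(t - 2.0) / tau1))
        y = y + np.where(t >= 6.0, 150.0 * np.exp(-(t - 6.0) / tau2), 0.0)
        return _StubEnsemble(t, y)

    def test_identical_ensembles_identical_tau(self):
        ens = {(1.25, False, False): self._stub(1.9, 1.7),
               (2.5, False, False): self._stub(1.9, 1.7)}
        table = ck.make_table1(ens)
        t1 = table[(table.pp1_uM == 1.25) & (table.epoch == "epoch1")].tau_s.iloc[0]
        t2 = table[(table.pp1_uM == 2.5) & (table.epoch == "epoch1")].tau_s.iloc[0]
        assert t1 == pytest.approx(t2, rel=1e-9)

    def test_recovers_programmed_taus(self):
        table = ck.make_table1({(1.25, False, False): self._stub(2.0, 1.5)})
        e1 = table[table.epoch == "epoch1"].tau_s.iloc[0]
        assert e1 == pytest.approx(2.0, rel=0.05)

    def test_extended_window_for_slow_condition_missing_data_is_nan(self):
        # trapping+competition uses the 21 s window; an 11 s trace can't fill it
        table = ck.make_table1({(1.25, True, True): self._stub(2.0, 60.0)})
        assert np.isnan(table[table.epoch == "epoch2"].tau_s.iloc[0])

    def test_compartment_concentration_partition(self, params):
        counts = np.array([100.0, 50.0])
        c_psd = analysis.compartment_concentration(counts, params.V_psd)
        c_all = analysis.compartment_concentration(counts, params.V_spine)
        assert c_psd[0] / c_all[0] == pytest.approx(params.V_spine / params.V_psd)
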