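"""Post-processing: exponential decay constants, peaks, and summary tables.

The headline readout of the model is the single-exponential decay constant
tau of the ensemble-mean pCaMKII trace after each stimulus epoch, fit either
by least squares (A * exp(-t/tau), optionally plus a floor) or from two
anchor points as tau = (t2 - t1) / ln(y1 / y2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .params import ParameterError


@dataclass
class TauFit:
    tau: float | None
    amplitude: float | None
    floor: float
    window: tuple[float, float]
    method: str
    ok: bool
    rmse: float | None = None
    message: str = ""


def _window_slice(times: np.ndarray, window: tuple[float, float]):
    t1, t2 = window
    if t2 <= t1:
        raise ParameterError("fit window must have t2 > t1")
    if t1 < times[0] - 1e-9 or t2 > times[-1] + 1e-9:
        raise ParameterError("fit window lies outside the trajectory span")
    m = (times >= t1 - 1e-9) & (times <= t2 + 1e-9)
    return times[m], m


def fit_exponential_tau(times: np.ndarray, values: np.ndarray,
                        window: tuple[float, float], method: str = "least_squares",
                        with_floor: bool = True) -> TauFit:
    """Fit a single exponential decay to ``values`` inside ``window``.

    ``two_point`` uses the first and last samples of the window and requires
    y1 > y2 > 0; a non-decaying window returns a failed fit (``ok=False``),
    not an exception.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    tw, m = _window_slice(times, window)
    yw = values[m]

    if method == "two_point":
        if len(tw) < 2:
            raise ParameterError("two_point needs at least two samples in the window")
        y1, y2 = yw[0], yw[-1]
        if not (y1 > y2 > 0):
            return TauFit(None, None, 0.0, window, method, ok=False,
                          message="window is not decaying")
        tau = (tw[-1] - tw[0]) / np.log(y1 / y2)
        return TauFit(tau, y1, 0.0, window, method, ok=True)

    if method != "least_squares":
        raise ParameterError(f"unknown fit method: {method!r}")
    if len(tw) < 10:
        raise ParameterError("least_squares needs at least 10 samples in the window")
    if yw[0] <= yw[-1]:
        return TauFit(None, None, 0.0, window, method, ok=False,
                      message="window is not decaying")

    t0 = tw[0]
    span = yw[0] - yw[-1]
    tau0 = max((tw[-1] - tw[0]) / max(np.log(max(yw[0], 1e-12) /
                                             max(yw[-1], 1e-12)), 0.1), 1e-3)
    try:
        if with_floor:
            def f(t, A, tau, c):
                return A * np.exp(-(t - t0) / tau) + c
            p0 = [span, tau0, max(yw[-1], 0.0)]
            bounds = ([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf])
        else:
            def f(t, A, tau):
                return A * np.exp(-(t - t0) / tau)
            p0 = [yw[0], tau0]
            bounds = ([0.0, 1e-6], [np.inf, np.inf])
        popt, _ = curve_fit(f, tw, yw, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as e:
        return TauFit(None, None, 0.0, window, method, ok=False, message=str(e))
    resid = yw - f(tw, *popt)
    floor = popt[2] if with_floor else 0.0
    return TauFit(float(popt[1]), float(popt[0]), float(floor), window, method,
                  ok=True, rmse=float(np.sqrt(np.mean(resid ** 2))))


def effective_decay_constant(times: np.ndarray, values: np.ndarray,
                             window: tuple[float, float],
                             anchor_halfwidth: float = 0.25) -> float:
    """Two-point single-exponential decay constant over ``window``.

    The anchor values are means over +/- ``anchor_halfwidth`` seconds around
    the window edges, which suppresses bin noise on slowly varying traces.
    Returns (t2 - t1)/ln(y1/y2); a non-positive or very large magnitude
    signals a trace that does not decay over the window.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    t1, t2 = window
    _window_slice(times, window)  # validates the span

    def anchor(t):
        m = np.abs(times - t) <= anchor_halfwidth
        return float(values[m].mean())

    y1, y2 = anchor(t1), anchor(t2)
    if y1 <= 0 or y2 <= 0 or y1 == y2:
        return float("inf")
    return float((t2 - t1) / np.log(y1 / y2))


def find_peak(times: np.ndarray, values: np.ndarray,
              interval: tuple[float, float] | None = None,
              smooth_s: float = 0.05) -> tuple[float, float]:
    """(t_peak, value) of the boxcar-smoothed trace; earliest wins on ties."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if interval is None:
        interval = (times[0], times[-1])
    tw, m = _window_slice(times, interval)
    if len(tw) == 0:
        raise ParameterError("empty peak-search interval")
    yw = values[m]
    if smooth_s > 0 and len(tw) > 2:
        dt = np.median(np.diff(times))
        w = max(int(round(smooth_s / dt)), 1)
        kernel = np.ones(w) / w
        yw = np.convolve(yw, kernel, mode="same")
    k = int(np.argmax(yw))  # argmax returns the first (earliest) maximum
    return float(tw[k]), float(yw[k])


def neighbor_probability(mean_p_per_ring: float) -> float:
    """Chance that a newly CaM-bound subunit sits clockwise of an active one.

    With m phosphorylated subunits in a 6-ring, the heuristic is m/(6 - m),
    capped at 1.
    """
    m = float(mean_p_per_ring)
    if not 0 <= m < 6:
        raise ParameterError("mean phosphorylated subunits per ring must be in [0, 6)")
    return min(m / (6.0 - m), 1.0)


#: default fit windows (s): epoch-1 decay, epoch-2 decay, and the extended
#: epoch-2 window used for the slow trapping+competition condition
EPOCH1_WINDOW = (2.2, 5.0)
EPOCH2_WINDOW = (7.7, 8.7)
EPOCH2_EXTENDED_WINDOW = (8.7, 21.0)


def make_table1(ensembles: dict[tuple[float, bool, bool], "object"],
                extended_conditions: set | None = None) -> pd.DataFrame:
    """Tau table over (PP1 uM, trapping, competition) conditions.

    ``ensembles`` maps condition keys to :class:`camkii_spine.engine.Ensemble`
    objects.  The slow trapping+competition condition uses the extended
    post-stimulus window; missing cells are reported empty, never fabricated.
    """
    if extended_conditions is None:
        extended_conditions = {k for k in ensembles if k[1] and k[2]}
    rows = []
    for (pp1_uM, trapping, competition), ens in sorted(ensembles.items()):
        mean_p = ens.mean_observable("pT286")
        for epoch, window in (("epoch1", EPOCH1_WINDOW),
                              ("epoch2", EPOCH2_EXTENDED_WINDOW
                               if (pp1_uM, trapping, competition) in extended_conditions
                               else EPOCH2_WINDOW)):
            if window[1] > ens.times[-1] + 1e-9:
                rows.append({"pp1_uM": pp1_uM, "trapping": trapping,
                             "competition": competition, "epoch": epoch,
                             "tau_s": np.nan, "fit_method": "least_squares",
                             "window_lo": window[0], "window_hi": window[1]})
                continue
            fit = fit_exponential_tau(ens.times, mean_p, window,
                                      method="least_squares", with_floor=True)
            rows.append({"pp1_uM": pp1_uM, "trapping": trapping,
                         "competition": competition, "epoch": epoch,
                         "tau_s": fit.tau if fit.ok else np.nan,
                         "fit_method": fit.method,
                         "window_lo": window[0], "window_hi": window[1]})
    return pd.DataFrame(rows)


def per_seed_taus(ens, observable: str, window, method="least_squares",
                  with_floor=True) -> np.ndarray:
    """Tau fitted per seed (uncertainty companion to the mean-trace fit)."""
    traces = ens.per_seed_observable(observable)
    taus = []
    for y in traces:
        fit = fit_exponential_tau(ens.times, y, window, method, with_floor)
        taus.append(fit.tau if fit.ok else np.nan)
    return np.asarray(taus)


def compartment_concentration(count: np.ndarray, volume_L: float) -> np.ndarray:
    """Concentration trace (M) from a count trace in a compartment."""
    from .params import AVOGADRO
    return np.asarray(count, float) / (AVOGADRO * volume_L)


def plot_mean_with_bands(ens, observable: str, path, title: str | None = None):
    """Mean trace with +/- s.e.m. (dark) and +/- s.d. (light) bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = ens.mean_observable(observable)
    traces = ens.per_seed_observable(observable)
    sd = traces.std(axis=0, ddof=1)
    sem = sd / np.sqrt(ens.n_seeds)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.fill_between(ens.times, m - sd, m + sd, color="0.85", label="±s.d.")
    ax.fill_between(ens.times, m - sem, m + sem, color="0.6", label="±s.e.m.")
    ax.plot(ens.times, m, color="m", lw=1.2, label=observable)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("count")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
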