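"""Synthetic two-epoch presynaptic drive and the resulting Ca2+ influx schedule.

The stimulus is two epochs of five bursts (5 Hz) of five action potentials
(50 Hz), i.e. 50 APs in all, starting at 1 s with the second epoch at 5 s.
Vesicle release is stochastic from a small pool of docked sites with slow
redocking, two-parameter facilitation, and depression through pool depletion.
A back-propagating action potential (bAP) follows each AP after a fixed
delay; Ca2+ enters only when a glutamate release coincides with a bAP
(temporal gate standing in for the Mg2+-block relief of NMDA receptors).

Membrane voltage, cleft glutamate diffusion, and NMDAR channel kinetics are
deliberately not modelled: they are collapsed into a per-receptor opening
probability and a calibrated number of ions per opening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ParameterError, ParameterSet, StimulusParams


# ---------------------------------------------------------------------------
# AP train
# ---------------------------------------------------------------------------

def build_ap_train(epochs: int = 2, bursts_per_epoch: int = 5, aps_per_burst: int = 5,
                   burst_rate_hz: float = 5.0, ap_rate_hz: float = 50.0,
                   t_start_s: float = 1.0, epoch2_onset_s: float = 5.0) -> np.ndarray:
    """Deterministic nested grid of AP times (s), strictly increasing."""
    if min(epochs, bursts_per_epoch, aps_per_burst) < 0:
        raise ParameterError("counts must be non-negative")
    if burst_rate_hz <= 0 or ap_rate_hz <= 0:
        raise ParameterError("rates must be positive")
    epoch_len = bursts_per_epoch / burst_rate_hz
    onsets = [t_start_s, epoch2_onset_s][:max(epochs, 0)]
    if epochs > 2:
        # further epochs repeat at the epoch-2 spacing
        gap = epoch2_onset_s - t_start_s
        onsets += [epoch2_onset_s + gap * (k + 1) for k in range(epochs - 2)]
    if epochs >= 2 and epoch2_onset_s < t_start_s + epoch_len:
        raise ParameterError("epochs overlap: epoch2_onset precedes the end of epoch 1")
    times = []
    for onset in onsets:
        for b in range(bursts_per_epoch):
            for a in range(aps_per_burst):
                times.append(onset + b / burst_rate_hz + a / ap_rate_hz)
    return np.asarray(times, dtype=float)


def ap_train_from_params(stim: StimulusParams) -> np.ndarray:
    return build_ap_train(stim.epochs, stim.bursts_per_epoch, stim.aps_per_burst,
                          stim.burst_rate_hz, stim.ap_rate_hz,
                          stim.t_start_s, stim.epoch2_onset_s)


# ---------------------------------------------------------------------------
# vesicle release
# ---------------------------------------------------------------------------

@dataclass
class ReleaseSchedule:
    """Vesicle-release events: (time, site) pairs plus per-AP docked counts."""

    times: np.ndarray                    # release times, s
    sites: np.ndarray                    # releasing site index per event
    docked_at_ap: np.ndarray = field(default=None)  # docked count seen by each AP

    def __len__(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "event_type": "release",
                             "count": 1, "site": self.sites})


def simulate_release(ap_train: np.ndarray, n_sites: int = 7, p_init: float = 0.2,
                     redock_rate: float = 0.2, facilitation_increment: float = 0.0,
                     facilitation_tau_s: float = 0.25, seed: int = 0) -> ReleaseSchedule:
    """Stochastic vesicle release over the AP train.

    Each docked site releases independently at each AP with per-site
    probability ``1 - (1 - p_init)**(1/n_sites)`` scaled by a facilitation
    factor that increments after every AP and decays back to 1 between APs.
    Released sites redock as independent exponential events at
    ``redock_rate`` (s^-1).  Fully reproducible from ``seed``.
    """
    if not 0.0 <= p_init <= 1.0:
        raise ParameterError("p_init must lie in [0, 1]")
    if n_sites <= 0:
        raise ParameterError("need at least one docked site")
    rng = np.random.default_rng(seed)
    p_site0 = 1.0 - (1.0 - p_init) ** (1.0 / n_sites)

    redock_time = np.zeros(n_sites)  # site docked when redock_time <= t
    fac = 1.0
    t_prev = None
    times, sites, docked_trace = [], [], []
    for t in np.sort(np.asarray(ap_train, dtype=float)):
        if t_prev is not None and facilitation_tau_s > 0:
            fac = 1.0 + (fac - 1.0) * np.exp(-(t - t_prev) / facilitation_tau_s)
        docked = np.flatnonzero(redock_time <= t)
        docked_trace.append(len(docked))
        p = min(p_site0 * fac, 1.0)
        for s in docked:
            if rng.random() < p:
                times.append(t)
                sites.append(s)
                redock_time[s] = t + rng.exponential(1.0 / redock_rate) if redock_rate > 0 else np.inf
        fac += facilitation_increment
        t_prev = t
    return ReleaseSchedule(times=np.asarray(times, dtype=float),
                           sites=np.asarray(sites, dtype=int),
                           docked_at_ap=np.asarray(docked_trace, dtype=int))


# ---------------------------------------------------------------------------
# Ca2+ influx
# ---------------------------------------------------------------------------

@dataclass
class CaInfluxSchedule:
    """Ca2+ delivery events: each contributes ``n_ions`` with an exponential pulse."""

    times: np.ndarray
    n_ions: np.ndarray
    pulse_tau: float

    def __len__(self) -> int:
        return len(self.times)

    @property
    def total_ions(self) -> int:
        return int(self.n_ions.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "event_type": "ca_influx",
                             "count": self.n_ions})


def schedule_ca_influx(releases: ReleaseSchedule, ap_train: np.ndarray,
                       bap_delay_s: float = 0.010, window_s: float = 0.020,
                       n_nmdar: int = 15, p_open: float = 0.5,
                       n_ca_per_opening: int = 95, pulse_tau_s: float = 0.005,
                       refractory_s: float = 0.0, seed: int = 0) -> CaInfluxSchedule:
    """Convert coincident release/bAP pairs into Ca2+ influx events.

    For each release, every receptor becomes glutamate-bound; if a bAP falls
    within ``window_s`` after the release, each bound receptor opens with
    probability ``p_open`` and contributes one event of ``n_ca_per_opening``
    ions at the bAP time.  A release with no bAP in the window contributes
    nothing.  ``refractory_s`` > 0 keeps a receptor shut for that long after
    an opening (a one-parameter stand-in for desensitisation, off by default).
    """
    if window_s <= 0:
        raise ParameterError("coincidence window must be positive")
    if not 0.0 <= p_open <= 1.0:
        raise ParameterError("p_open must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bap_times = np.sort(np.asarray(ap_train, dtype=float)) + bap_delay_s
    ready_at = np.zeros(n_nmdar)
    ev_t, ev_n = [], []
    for t_rel in np.sort(np.asarray(releases.times, dtype=float)):
        k = np.searchsorted(bap_times, t_rel, side="left")
        if k == len(bap_times) or bap_times[k] - t_rel > window_s:
            continue
        t_bap = bap_times[k]
        for r in range(n_nmdar):
            if t_bap < ready_at[r]:
                continue
            if rng.random() < p_open:
                ev_t.append(t_bap)
                ev_n.append(n_ca_per_opening)
                if refractory_s > 0:
                    ready_at[r] = t_bap + refractory_s
    return CaInfluxSchedule(times=np.asarray(ev_t, dtype=float),
                            n_ions=np.asarray(ev_n, dtype=int),
                            pulse_tau=pulse_tau_s)


def make_stimulus(params: ParameterSet, seed: int) -> CaInfluxSchedule:
    """Full pipeline: AP train -> stochastic releases -> Ca2+ influx events."""
    stim = params.stimulus
    aps = ap_train_from_params(stim)
    rel = simulate_release(aps, n_sites=stim.n_docked_init, p_init=stim.p_release_init,
                           redock_rate=stim.redock_rate,
                           facilitation_increment=stim.facilitation_increment,
                           facilitation_tau_s=stim.facilitation_tau_s,
                           seed=seed)
    return schedule_ca_influx(rel, aps, bap_delay_s=stim.bap_delay_s,
                              window_s=stim.coincidence_window_s,
                              n_nmdar=stim.n_nmdar, p_open=stim.p_open,
                              n_ca_per_opening=stim.n_ca_per_opening,
                              pulse_tau_s=stim.pulse_tau_s,
                              refractory_s=stim.refractory_s,
                              seed=seed + 1_000_003)
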