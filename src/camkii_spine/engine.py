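"""Coupled stochastic simulation of Ca2+, CaM, CaMKII holoenzymes, and PP1.

Two engine modes share one reaction rule set:

``hybrid`` (default)
    The fast, abundant pools — free Ca2+ and the nine free-CaM species — are
    advanced by mean-field integration, while every CaMKII subunit and PP1
    molecule remains a discrete stochastic agent sampled against
    time-varying propensities on an adaptive time step.  This is the
    production mode used for all headline runs.

``exact_ssa``
    A Gillespie direct-method reference in which every molecule, including
    each Ca2+ ion and free CaM, is discrete.  Exact but slow; used as the
    in-package oracle on reduced systems.

Compartments are well-mixed: the spine (0.016 fL) optionally nests a PSD
capsule (0.002915 fL) that confines CaMKII (and PP1 when requested) while
Ca2+ and CaM remain spine-wide shared pools.  The dendritic shaft is an
infinite bath: free CaM relaxes toward the bath composition and free Ca2+
toward baseline, first order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from . import cam, holoenzyme as holo, stimulus as stim_mod
from .params import AVOGADRO, CTX_FREE, LOBE_C, LOBE_N, ParameterError, ParameterSet
from .phosphatase import micro_rates_from_params

_MODE_LA, _MODE_HA = 0, 1


@dataclass
class RunConfig:
    seed: int = 0
    t_end: float = 11.0
    record_dt: float = 0.01
    engine: str = "hybrid"          # hybrid | exact_ssa
    ca_clamp: float | None = None   # clamp free Ca2+ (M); disables influx/clearance
    cam_init_zero: bool = False     # start with an empty spine CaM pool


@dataclass
class CompartmentLayout:
    V_spine: float
    V_psd: float | None = None

    def __post_init__(self):
        if self.V_psd is not None and not self.V_psd < self.V_spine:
            raise ParameterError("capsule volume must be smaller than the spine")

    @property
    def V_outside(self) -> float:
        return self.V_spine if self.V_psd is None else self.V_spine - self.V_psd


#: observable column names (fixed record layout)
def _columns() -> list[str]:
    cols = ["ca_free", "cam_free_total"]
    cols += [f"cam_free_{n}" for n in cam.SPECIES_NAMES]
    cols += ["pT286", "pT286_psd", "pT286_cyt", "pp1_bound", "ha_subunits",
             "cam_bound_total"]
    cols += [f"cam_on_pcamkii_{n}" for n in cam.SPECIES_NAMES]
    cols += ["cam_on_npcamkii"]
    return cols


class Trajectory:
    """Time-binned observables of a single run."""

    def __init__(self, times: np.ndarray, values: np.ndarray, meta: dict):
        self.times = times
        self.data = pd.DataFrame(values, columns=_columns())
        self.data.insert(0, "time_s", times)
        self.meta = meta

    def observable(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def to_tidy(self) -> pd.DataFrame:
        long = self.data.melt(id_vars="time_s", var_name="observable", value_name="count")
        long["compartment"] = np.where(long["observable"].str.endswith("_psd"), "psd",
                                       np.where(long["observable"].str.endswith("_cyt"),
                                                "cytosol", "spine"))
        return long


class Ensemble:
    """A set of trajectories on a common record grid, with cross-seed summaries."""

    def __init__(self, trajectories: list[Trajectory]):
        if len(trajectories) < 2:
            raise ParameterError("an ensemble needs at least two seeds")
        t0 = trajectories[0].times
        for tr in trajectories[1:]:
            if len(tr.times) != len(t0) or not np.allclose(tr.times, t0):
                raise ParameterError("trajectories have mismatched record grids")
        self.trajectories = trajectories
        self.times = t0
        self._stack = np.stack([tr.data.iloc[:, 1:].to_numpy() for tr in trajectories])

    @property
    def n_seeds(self) -> int:
        return len(self.trajectories)

    def _frame(self, arr: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(arr, columns=_columns())
        df.insert(0, "time_s", self.times)
        return df

    def mean(self) -> pd.DataFrame:
        return self._frame(self._stack.mean(axis=0))

    def sd(self) -> pd.DataFrame:
        return self._frame(self._stack.std(axis=0, ddof=1))

    def sem(self) -> pd.DataFrame:
        return self._frame(self._stack.std(axis=0, ddof=1) / np.sqrt(self.n_seeds))

    def mean_observable(self, name: str) -> np.ndarray:
        j = _columns().index(name)
        return self._stack[:, :, j].mean(axis=0)

    def per_seed_observable(self, name: str) -> np.ndarray:
        j = _columns().index(name)
        return self._stack[:, :, j]

    def to_hdf5(self, path) -> None:
        """Write times, per-seed values, and summaries to an HDF5 container."""
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("time_s", data=self.times)
            f.create_dataset("values", data=self._stack)
            f.create_dataset("mean", data=self._stack.mean(axis=0))
            f.create_dataset("sd", data=self._stack.std(axis=0, ddof=1))
            f.attrs["observables"] = _columns()
            f.attrs["n_seeds"] = self.n_seeds


# ---------------------------------------------------------------------------
# shared setup
# ---------------------------------------------------------------------------

class _Setup:
    """Arrays and constants shared by both engine modes."""

    def __init__(self, params: ParameterSet, config: RunConfig):
        params.validate()
        self.params = params
        self.config = config
        self.tables = cam.build_rate_tables(params)
        self.pp1_rates = micro_rates_from_params(params)

        n_holo = params.n_holoenzymes
        self.n_sub = n_holo * holo.SUBUNITS_PER_HOLO
        self.kin = holo.kinase_index_map(n_holo)

        # compartments: 0 = spine cytosol (outside capsule), 1 = PSD capsule
        self.localized = params.psd_localization != "off"
        self.layout = CompartmentLayout(params.V_spine,
                                        params.V_psd if self.localized else None)
        self.comp = np.zeros(self.n_sub, dtype=np.int64)
        if self.localized:
            n_in = n_holo // 2
            self.comp[: n_in * holo.SUBUNITS_PER_HOLO] = 1

        # PP1 pools and their mixing volumes
        pp1_total = params.pp1_count()
        if params.psd_localization == "camkii_and_pp1":
            n_caps = pp1_total // 2
            self.pp1_total = np.array([pp1_total - n_caps, n_caps], dtype=np.int64)
            self.pp1_vol = np.array([self.layout.V_outside, params.V_psd])
            self.sub_pool = self.comp
        else:
            self.pp1_total = np.array([pp1_total, 0], dtype=np.int64)
            self.pp1_vol = np.array([params.V_spine, params.V_psd])
            self.sub_pool = np.zeros(self.n_sub, dtype=np.int64)

        # CaM pool (spine-wide, shared) and bath composition
        self.cam_total = params.conc_CaM_total * AVOGADRO * params.V_spine
        self.res_dist = cam.equilibrium_cam_distribution(params.ca_baseline, params)
        self.res_vec = self.res_dist * self.cam_total
        self.ca_base_count = params.ca_baseline * AVOGADRO * params.V_spine

        # per-count bimolecular conversions
        self.inv_nav_spine = 1.0 / (AVOGADRO * params.V_spine)
        self.kon_bind_eff = self.tables.kon_bind * self.inv_nav_spine
        self.koff_bind = np.stack([self.tables.koff_bind_la, self.tables.koff_bind_ha])

        # per-species lobe transition rates by context (index 1 = la, 2 = ha)
        nC = np.array([s[0] for s in cam.SPECIES])
        nN = np.array([s[1] for s in cam.SPECIES])
        self.cup_C = np.zeros((3, 9))
        self.cup_N = np.zeros((3, 9))
        self.cdn_C = np.zeros((3, 9))
        self.cdn_N = np.zeros((3, 9))
        for ctx in range(3):
            for i in range(9):
                if nC[i] < 2:
                    self.cup_C[ctx, i] = params.ca_on[ctx, LOBE_C, nC[i]]
                if nN[i] < 2:
                    self.cup_N[ctx, i] = params.ca_on[ctx, LOBE_N, nN[i]]
                if nC[i] > 0:
                    self.cdn_C[ctx, i] = params.ca_off[ctx, LOBE_C, nC[i] - 1]
                if nN[i] > 0:
                    self.cdn_N[ctx, i] = params.ca_off[ctx, LOBE_N, nN[i] - 1]

        # free-context generator split: Q(ca) = A0 + ca_conc * A1
        self.A0 = np.zeros((9, 9))
        self.A1 = np.zeros((9, 9))
        for i in range(9):
            for (j, on_coeff) in ((i + 3, self.cup_C[CTX_FREE, i]),
                                  (i + 1, self.cup_N[CTX_FREE, i])):
                if on_coeff > 0:
                    self.A1[j, i] += on_coeff
                    self.A1[i, i] -= on_coeff
            for (j, off) in ((i - 3, self.cdn_C[CTX_FREE, i]),
                             (i - 1, self.cdn_N[CTX_FREE, i])):
                if off > 0:
                    self.A0[j, i] += off
                    self.A0[i, i] -= off
        self.b_on = -np.diag(self.A1)   # total association coefficient per species
        self.b_off = -np.diag(self.A0)  # total dissociation rate per species

    def initial_camfree(self) -> np.ndarray:
        return self.res_vec.copy()


def _record_row(out: np.ndarray, row: int, ca: float, camfree: np.ndarray,
                sp: np.ndarray, mode: np.ndarray, pT: np.ndarray,
                pp1b: np.ndarray, comp: np.ndarray) -> None:
    bound = sp >= 0
    on_p = bound & pT
    per_p = np.bincount(sp[on_p], minlength=9) if on_p.any() else np.zeros(9)
    k = 0
    out[row, k] = ca; k += 1
    out[row, k] = camfree.sum(); k += 1
    out[row, k:k + 9] = camfree; k += 9
    out[row, k] = pT.sum(); k += 1
    out[row, k] = (pT & (comp == 1)).sum(); k += 1
    out[row, k] = (pT & (comp == 0)).sum(); k += 1
    out[row, k] = pp1b.sum(); k += 1
    out[row, k] = (mode == _MODE_HA).sum(); k += 1
    out[row, k] = bound.sum(); k += 1
    out[row, k:k + 9] = per_p; k += 9
    out[row, k] = bound.sum() - on_p.sum()


# ---------------------------------------------------------------------------
# hybrid engine
# ---------------------------------------------------------------------------

@njit(cache=True)
def _hybrid_core(seed32, t_end, record_dt,
                 # state
                 sp, mode, pT, pp1b, pp1_free, camfree, ca0, clamped,
                 # structure
                 kin, sub_pool, comp,
                 # rate tables
                 koff_bind, kon_bind_eff, cup_C, cup_N, cdn_C, cdn_N,
                 A0, A1, b_on, b_off, res_vec,
                 # scalars
                 kp4, kpp, kon_pp1_eff, k_resolve, p_cat,
                 competition, comp_block, trapping, ha_revert, ha_rebind,
                 k_ex, tau_clear, ca_base_count, inv_nav,
                 # stimulus
                 ev_times, ev_ions, pulse_tau,
                 # output
                 out):
    np.random.seed(seed32)
    n_sub = sp.shape[0]
    n_rec = out.shape[0]
    ca = ca0
    pulse = 0.0
    t = 0.0
    next_ev = 0
    next_rec = 0
    max_rtot_prev = 10.0
    kon_max_bound = 0.0
    for c in range(1, 3):
        for lo in range(9):
            v = cup_C[c, lo] + cup_N[c, lo]
            if v > kon_max_bound:
                kon_max_bound = v
    dt_min, dt_max = 2e-5, 1e-3

    while t < t_end - 1e-12:
        ca_conc = ca * inv_nav
        guess = 300.0 + kon_max_bound * ca_conc
        if max_rtot_prev > guess:
            guess = max_rtot_prev
        dt = 0.15 / guess
        if dt < dt_min:
            dt = dt_min
        if dt > dt_max:
            dt = dt_max
        if next_ev < ev_times.shape[0]:
            gap = ev_times[next_ev] - t
            if gap < dt:
                dt = gap if gap > 1e-9 else 1e-9
        if next_rec < n_rec:
            gap = next_rec * record_dt - t
            if 1e-9 < gap < dt:
                dt = gap
        if t + dt > t_end:
            dt = t_end - t

        # ---- deterministic pools (substepped explicit Euler) ----
        maxdiag = k_ex
        for s in range(9):
            v = b_off[s] + ca_conc * b_on[s]
            if v > maxdiag - k_ex:
                maxdiag = v + k_ex
        nss = int(np.ceil(dt * maxdiag / 0.2))
        if nss < 1:
            nss = 1
        dt_ss = dt / nss
        decay = np.exp(-dt_ss / pulse_tau)
        dcam = np.empty(9)
        for _ in range(nss):
            ca_conc = ca * inv_nav
            uptake = 0.0
            for i in range(9):
                acc = k_ex * (res_vec[i] - camfree[i])
                for j in range(9):
                    acc += (A0[i, j] + ca_conc * A1[i, j]) * camfree[j]
                dcam[i] = acc
                uptake += (ca_conc * b_on[i] - 0.0) * camfree[i]
                uptake -= b_off[i] * camfree[i]
            if not clamped:
                released = pulse * (1.0 - decay)
                ca += released - (ca - ca_base_count) * dt_ss / tau_clear \
                    - uptake * dt_ss
                pulse *= decay
                if ca < 0.0:
                    ca = 0.0
            for i in range(9):
                camfree[i] += dcam[i] * dt_ss
                if camfree[i] < 0.0:
                    camfree[i] = 0.0

        # ---- discrete subunit events ----
        ca_conc = ca * inv_nav
        bind_tot = 0.0
        for s in range(9):
            bind_tot += kon_bind_eff[s] * camfree[s]
        max_rtot = 0.0
        for i in range(n_sub):
            s_i = sp[i]
            if s_i >= 0:
                c = 1 + mode[i]
                r1 = koff_bind[mode[i], s_i]
                r2 = cup_C[c, s_i] * ca_conc
                r3 = cup_N[c, s_i] * ca_conc
                r4 = cdn_C[c, s_i]
                r5 = cdn_N[c, s_i]
                r6 = 0.0
            else:
                r1 = r2 = r3 = r4 = r5 = 0.0
                r6 = bind_tot
            r7 = 0.0
            if s_i >= 0 and not pT[i]:
                k = kin[i]
                if pT[k] or sp[k] >= 0:
                    if s_i == 8 and (pT[k] or sp[k] == 8):
                        r7 = kp4
                    else:
                        r7 = kpp
            r8 = 0.0
            if pT[i] and not pp1b[i]:
                pool = sub_pool[i]
                r8 = kon_pp1_eff[pool] * pp1_free[pool]
                if competition and s_i >= 0:
                    r8 *= comp_block
            r9 = k_resolve if pp1b[i] else 0.0
            r10 = 0.0
            if trapping and s_i >= 0 and pT[i] and mode[i] == 0:
                r10 = koff_bind[0, s_i]
            rtot = r1 + r2 + r3 + r4 + r5 + r6 + r7 + r8 + r9 + r10
            if rtot > max_rtot:
                max_rtot = rtot
            if rtot <= 0.0:
                continue
            if np.random.random() >= -np.expm1(-rtot * dt):
                continue
            u = np.random.random() * rtot
            if u < r1:                       # CaM unbinds
                camfree[s_i] += 1.0
                sp[i] = -1
                mode[i] = 1 if (trapping and ha_rebind and pT[i]) else 0
                continue
            u -= r1
            if u < r2:                       # Ca on, C lobe
                sp[i] = s_i + 3
                if not clamped and ca >= 1.0:
                    ca -= 1.0
                continue
            u -= r2
            if u < r3:                       # Ca on, N lobe
                sp[i] = s_i + 1
                if not clamped and ca >= 1.0:
                    ca -= 1.0
                continue
            u -= r3
            if u < r4:                       # Ca off, C lobe
                sp[i] = s_i - 3
                if not clamped:
                    ca += 1.0
                continue
            u -= r4
            if u < r5:                       # Ca off, N lobe
                sp[i] = s_i - 1
                if not clamped:
                    ca += 1.0
                continue
            u -= r5
            if u < r6:                       # CaM binds; pick species
                v = np.random.random() * bind_tot
                s_pick = 8
                acc = 0.0
                for s in range(9):
                    acc += kon_bind_eff[s] * camfree[s]
                    if v < acc:
                        s_pick = s
                        break
                if camfree[s_pick] >= 1.0:
                    camfree[s_pick] -= 1.0
                    sp[i] = s_pick
                    mode[i] = 1 if (trapping and ha_rebind and pT[i]) else 0
                continue
            u -= r6
            if u < r7:                       # autophosphorylation
                pT[i] = True
                continue
            u -= r7
            if u < r8:                       # PP1 binds
                pool = sub_pool[i]
                if pp1_free[pool] >= 1:
                    pp1_free[pool] -= 1
                    pp1b[i] = True
                continue
            u -= r8
            if u < r9:                       # PP1 resolves: catalysis or unbind
                pool = sub_pool[i]
                pp1b[i] = False
                pp1_free[pool] += 1
                if np.random.random() < p_cat:
                    pT[i] = False
                    if ha_revert and mode[i] == 1:
                        mode[i] = 0
                continue
            mode[i] = 1                      # la -> ha conversion
        max_rtot_prev = max_rtot if max_rtot > 1.0 else 1.0

        t += dt
        while next_ev < ev_times.shape[0] and t >= ev_times[next_ev] - 1e-9:
            pulse += ev_ions[next_ev]
            next_ev += 1
        while next_rec < n_rec and t >= next_rec * record_dt - 1e-9:
            _record_row_nb(out, next_rec, ca, camfree, sp, mode, pT, pp1b, comp)
            next_rec += 1
        if ca < 0.0:
            return -1
    while next_rec < n_rec:
        _record_row_nb(out, next_rec, ca, camfree, sp, mode, pT, pp1b, comp)
        next_rec += 1
    return 0


@njit(cache=True)
def _record_row_nb(out, row, ca, camfree, sp, mode, pT, pp1b, comp):
    n_sub = sp.shape[0]
    out[row, 0] = ca
    tot = 0.0
    for s in range(9):
        out[row, 2 + s] = camfree[s]
        tot += camfree[s]
    out[row, 1] = tot
    n_pT = 0; n_psd = 0; n_cyt = 0; n_pp1 = 0; n_ha = 0; n_bound = 0; n_onp = 0
    for s in range(9):
        out[row, 17 + s] = 0.0
    for i in range(n_sub):
        if pT[i]:
            n_pT += 1
            if comp[i] == 1:
                n_psd += 1
            else:
                n_cyt += 1
        if pp1b[i]:
            n_pp1 += 1
        if mode[i] == 1:
            n_ha += 1
        if sp[i] >= 0:
            n_bound += 1
            if pT[i]:
                n_onp += 1
                out[row, 17 + sp[i]] += 1.0
    out[row, 11] = n_pT
    out[row, 12] = n_psd
    out[row, 13] = n_cyt
    out[row, 14] = n_pp1
    out[row, 15] = n_ha
    out[row, 16] = n_bound
    out[row, 26] = n_bound - n_onp


def _run_hybrid(setup: _Setup, influx: stim_mod.CaInfluxSchedule,
                rng: np.random.Generator) -> np.ndarray:
    """Prepare arrays, call the compiled core, and return the record matrix."""
    p = setup.params
    cfg = setup.config
    clamped = cfg.ca_clamp is not None

    sp = np.full(setup.n_sub, -1, dtype=np.int64)
    mode = np.zeros(setup.n_sub, dtype=np.int64)
    pT = np.zeros(setup.n_sub, dtype=np.bool_)
    pp1b = np.zeros(setup.n_sub, dtype=np.bool_)
    pp1_free = setup.pp1_total.astype(np.int64).copy()
    camfree = np.zeros(9) if cfg.cam_init_zero else setup.initial_camfree()
    ca0 = cfg.ca_clamp * AVOGADRO * p.V_spine if clamped else setup.ca_base_count

    pulse_tau = influx.pulse_tau if len(influx) else p.stimulus.pulse_tau_s
    rec_times = np.arange(0.0, cfg.t_end + 0.5 * cfg.record_dt, cfg.record_dt)
    out = np.zeros((len(rec_times), len(_columns())))

    pp1r = setup.pp1_rates
    seed32 = int(rng.integers(0, 2 ** 31 - 1))
    status = _hybrid_core(
        seed32, cfg.t_end, cfg.record_dt,
        sp, mode, pT, pp1b, pp1_free, camfree, float(ca0), clamped,
        setup.kin, setup.sub_pool, setup.comp,
        setup.koff_bind, setup.kon_bind_eff,
        setup.cup_C, setup.cup_N, setup.cdn_C, setup.cdn_N,
        setup.A0, setup.A1, setup.b_on, setup.b_off, setup.res_vec,
        p.k_pCaM4, p.k_pCaMpartial,
        pp1r.kon_pp1 / (AVOGADRO * setup.pp1_vol),
        pp1r.kcat_pp1 + pp1r.koff_pp1, pp1r.p_catalysis,
        p.competition, 1.0 - p.competition_scale if p.competition else 1.0,
        p.trapping, p.ha_revert_on_dephos, p.trapped_rebind == "ha",
        p.k_cam_exchange, p.tau_ca_clear, setup.ca_base_count,
        setup.inv_nav_spine,
        influx.times.astype(np.float64), influx.n_ions.astype(np.float64),
        pulse_tau, out)
    if status != 0:
        raise RuntimeError("negative count encountered during hybrid run")
    if np.any(pp1_free < 0) or np.any(camfree < -1e-9):
        raise RuntimeError("negative pool count after hybrid run")
    return out


# ---------------------------------------------------------------------------
# exact SSA engine
# ---------------------------------------------------------------------------

def _run_exact_ssa(setup: _Setup, influx: stim_mod.CaInfluxSchedule,
                   rng: np.random.Generator) -> np.ndarray:
    p = setup.params
    cfg = setup.config
    n_sub = setup.n_sub
    clamped = cfg.ca_clamp is not None

    sp = np.full(n_sub, -1, dtype=np.int64)
    mode = np.zeros(n_sub, dtype=np.int64)
    pT = np.zeros(n_sub, dtype=bool)
    pp1b = np.zeros(n_sub, dtype=bool)
    pp1_free = setup.pp1_total.astype(np.int64).copy()

    camfree = np.floor(setup.initial_camfree()).astype(np.int64)
    # put the rounding remainder in the modal species so the total is exact
    deficit = int(round(setup.cam_total)) - camfree.sum()
    camfree[np.argmax(setup.res_vec)] += max(deficit, 0)
    if cfg.cam_init_zero:
        camfree[:] = 0
    ca = int(round(cfg.ca_clamp * AVOGADRO * p.V_spine)) if clamped \
        else int(round(setup.ca_base_count))
    pulse = 0

    ev_times = influx.times
    ev_ions = influx.n_ions
    pulse_tau = influx.pulse_tau if len(influx) else p.stimulus.pulse_tau_s
    next_ev = 0

    rec_times = np.arange(0.0, cfg.t_end + 0.5 * cfg.record_dt, cfg.record_dt)
    out = np.zeros((len(rec_times), len(_columns())))
    next_rec = 0

    pp1r = setup.pp1_rates
    kon_pp1_eff = pp1r.kon_pp1 / (AVOGADRO * setup.pp1_vol)
    kp4, kpp = p.k_pCaM4, p.k_pCaMpartial
    comp_block = 1.0 - p.competition_scale if p.competition else 1.0
    trapping = p.trapping
    ha_rebind = p.trapped_rebind == "ha"
    k_ex = p.k_cam_exchange
    base_birth = setup.ca_base_count / p.tau_ca_clear

    t = 0.0
    while t < cfg.t_end - 1e-12:
        ca_conc = ca * setup.inv_nav_spine
        # pool channels -----------------------------------------------------
        a_pulse = pulse / pulse_tau
        a_clear = 0.0 if clamped else ca / p.tau_ca_clear
        a_birth = 0.0 if clamped else base_birth
        # free CaM: 4 directed channels per species
        a_fupC = camfree * setup.cup_C[CTX_FREE] * ca_conc
        a_fupN = camfree * setup.cup_N[CTX_FREE] * ca_conc
        a_fdnC = camfree * setup.cdn_C[CTX_FREE]
        a_fdnN = camfree * setup.cdn_N[CTX_FREE]
        a_ex_out = k_ex * camfree
        a_ex_in = k_ex * setup.res_vec
        # subunit channels --------------------------------------------------
        bound = sp >= 0
        spc = np.where(bound, sp, 0)
        ctx = 1 + mode
        r_unbind = np.where(bound, setup.koff_bind[mode, spc], 0.0)
        r_cupC = np.where(bound, setup.cup_C[ctx, spc] * ca_conc, 0.0)
        r_cupN = np.where(bound, setup.cup_N[ctx, spc] * ca_conc, 0.0)
        r_cdnC = np.where(bound, setup.cdn_C[ctx, spc], 0.0)
        r_cdnN = np.where(bound, setup.cdn_N[ctx, spc], 0.0)
        bind_w = setup.kon_bind_eff * camfree
        bind_tot = bind_w.sum()
        r_bind = np.where(bound, 0.0, bind_tot)
        kin_active = pT[setup.kin] | (sp[setup.kin] >= 0)
        eligible = bound & ~pT & kin_active
        fast = (sp == cam.CAM4) & (pT[setup.kin] | (sp[setup.kin] == cam.CAM4))
        r_phos = np.where(eligible, np.where(fast, kp4, kpp), 0.0)
        r_pp1on = np.where(pT & ~pp1b,
                           kon_pp1_eff[setup.sub_pool] * pp1_free[setup.sub_pool], 0.0)
        if p.competition:
            r_pp1on = np.where(bound, r_pp1on * comp_block, r_pp1on)
        r_pp1ev = np.where(pp1b, pp1r.kcat_pp1 + pp1r.koff_pp1, 0.0)
        if trapping:
            r_trap = np.where(bound & pT & (mode == _MODE_LA),
                              setup.koff_bind[_MODE_LA, spc], 0.0)
        else:
            r_trap = np.zeros(n_sub)

        sub_stack = np.concatenate([r_unbind, r_cupC, r_cupN, r_cdnC, r_cdnN,
                                    r_bind, r_phos, r_pp1on, r_pp1ev, r_trap])
        props = np.concatenate([[a_pulse, a_clear, a_birth],
                                a_fupC, a_fupN, a_fdnC, a_fdnN,
                                a_ex_out, a_ex_in, sub_stack])
        A = props.sum()
        if A <= 0:
            t_next = ev_times[next_ev] if next_ev < len(ev_times) else cfg.t_end
            t = min(t_next, cfg.t_end)
        else:
            t_cand = t + rng.exponential(1.0 / A)
            if next_ev < len(ev_times) and t_cand >= ev_times[next_ev]:
                t = ev_times[next_ev]
                pulse += int(ev_ions[next_ev])
                next_ev += 1
                while next_rec < len(rec_times) and t > rec_times[next_rec]:
                    _record_row(out, next_rec, ca, camfree.astype(float), sp, mode,
                                pT, pp1b, setup.comp)
                    next_rec += 1
                continue
            t = t_cand
            k = int(np.searchsorted(np.cumsum(props), rng.random() * A))
            k = min(k, len(props) - 1)
            if k == 0:
                pulse -= 1; ca += 1
            elif k == 1:
                ca -= 1
            elif k == 2:
                ca += 1
            elif k < 3 + 4 * 9:
                j = k - 3
                block, s = divmod(j, 9)
                if block == 0:
                    camfree[s] -= 1; camfree[s + 3] += 1; ca -= 0 if clamped else 1
                elif block == 1:
                    camfree[s] -= 1; camfree[s + 1] += 1; ca -= 0 if clamped else 1
                elif block == 2:
                    camfree[s] -= 1; camfree[s - 3] += 1; ca += 0 if clamped else 1
                else:
                    camfree[s] -= 1; camfree[s - 1] += 1; ca += 0 if clamped else 1
            elif k < 3 + 4 * 9 + 9:
                camfree[k - 3 - 36] -= 1          # exchange out
            elif k < 3 + 4 * 9 + 18:
                camfree[k - 3 - 45] += 1          # exchange in
            else:
                j = k - (3 + 4 * 9 + 18)
                chan, i = divmod(j, n_sub)
                if chan == 0:
                    camfree[sp[i]] += 1
                    sp[i] = -1
                    mode[i] = _MODE_HA if (trapping and ha_rebind and pT[i]) else _MODE_LA
                elif chan == 1:
                    sp[i] += 3; ca -= 0 if clamped else 1
                elif chan == 2:
                    sp[i] += 1; ca -= 0 if clamped else 1
                elif chan == 3:
                    sp[i] -= 3; ca += 0 if clamped else 1
                elif chan == 4:
                    sp[i] -= 1; ca += 0 if clamped else 1
                elif chan == 5:
                    s = int(np.searchsorted(np.cumsum(bind_w), rng.random() * bind_tot))
                    s = min(s, 8)
                    if camfree[s] >= 1:
                        camfree[s] -= 1
                        sp[i] = s
                        mode[i] = _MODE_HA if (trapping and ha_rebind and pT[i]) else _MODE_LA
                elif chan == 6:
                    pT[i] = True
                elif chan == 7:
                    pool = setup.sub_pool[i]
                    if pp1_free[pool] >= 1:
                        pp1_free[pool] -= 1
                        pp1b[i] = True
                elif chan == 8:
                    pool = setup.sub_pool[i]
                    pp1b[i] = False
                    pp1_free[pool] += 1
                    if rng.random() < pp1r.p_catalysis:
                        pT[i] = False
                        if p.ha_revert_on_dephos and mode[i] == _MODE_HA:
                            mode[i] = _MODE_LA
                else:
                    mode[i] = _MODE_HA
            if ca < 0 or pulse < 0 or np.any(camfree < 0) or np.any(pp1_free < 0):
                raise RuntimeError(f"negative count at t={t:.5f} (channel {k})")

        while next_rec < len(rec_times) and t >= rec_times[next_rec] - 1e-12:
            _record_row(out, next_rec, ca, camfree.astype(float), sp, mode,
                        pT, pp1b, setup.comp)
            next_rec += 1
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def run_simulation(params: ParameterSet, config: RunConfig,
                   stimulus: stim_mod.CaInfluxSchedule | None = None) -> Trajectory:
    """Advance the full coupled system for one seed.

    ``stimulus=None`` generates the default two-epoch schedule from the seed;
    an explicit (possibly empty) schedule overrides it.  Identical seed,
    parameters, and engine mode give bit-identical trajectories.
    """
    setup = _Setup(params, config)
    if stimulus is None:
        stimulus = stim_mod.make_stimulus(params, config.seed)
    if len(stimulus) and stimulus.times.max() > config.t_end:
        stimulus = stim_mod.CaInfluxSchedule(
            times=stimulus.times[stimulus.times <= config.t_end],
            n_ions=stimulus.n_ions[stimulus.times <= config.t_end],
            pulse_tau=stimulus.pulse_tau)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2_000_003]))
    if config.engine == "hybrid":
        values = _run_hybrid(setup, stimulus, rng)
    elif config.engine == "exact_ssa":
        values = _run_exact_ssa(setup, stimulus, rng)
    else:
        raise ParameterError(f"unknown engine mode: {config.engine!r}")
    rec_times = np.arange(0.0, config.t_end + 0.5 * config.record_dt, config.record_dt)
    meta = {"seed": config.seed, "engine": config.engine,
            "t_end": config.t_end, "n_influx_events": len(stimulus),
            "flags": {"trapping": params.trapping, "competition": params.competition,
                      "psd_localization": params.psd_localization},
            "resolved_params": params.to_dict()}
    return Trajectory(rec_times, values, meta)


def run_ensemble(params: ParameterSet, seeds, t_end: float = 11.0,
                 record_dt: float = 0.01, engine: str = "hybrid",
                 ca_clamp: float | None = None) -> Ensemble:
    """Run one trajectory per seed and wrap them with cross-seed summaries."""
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ParameterError("an ensemble needs at least two seeds")
    trajs = [run_simulation(params, RunConfig(seed=s, t_end=t_end,
                                              record_dt=record_dt, engine=engine,
                                              ca_clamp=ca_clamp))
             for s in seeds]
    return Ensemble(trajs)
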