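"""Model constants, unit conversions, and thermodynamic validation.

All quantities are stored internally in SI units (mol/L for concentrations,
litres for volumes, seconds for times).  The shipped defaults live in
``data/defaults.yaml``; every entry can be overridden from a user config file
or keyword overrides, and the fully resolved set can be exported as JSON so
each run logs exactly the constants it used.

Provenance (literature source and measurement temperature, where known) is
carried per parameter in :data:`PROVENANCE`.  No temperature rescaling (Q10)
is applied: the underlying measurements span roughly 22-34 C and are used
as published.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import yaml

AVOGADRO = 6.02214076e23  # mol^-1

#: Context indices for the Ca2+/CaM rate tables.
CTX_FREE, CTX_LA, CTX_HA = 0, 1, 2
CONTEXT_NAMES = ("free", "camkii_la", "camkii_ha")
LOBE_C, LOBE_N = 0, 1


class ParameterError(ValueError):
    """Raised for invalid, missing, or thermodynamically inconsistent input."""


# ---------------------------------------------------------------------------
# count <-> concentration conversions
# ---------------------------------------------------------------------------

def count_from_concentration(conc: float, volume: float, rounding: str = "nearest") -> int:
    """Number of molecules at concentration ``conc`` (M) in ``volume`` (L).

    ``rounding`` is ``"nearest"`` or ``"floor"``.
    """
    if conc < 0:
        raise ParameterError(f"negative concentration: {conc}")
    if volume <= 0:
        raise ParameterError(f"non-positive volume: {volume}")
    x = conc * AVOGADRO * volume
    if rounding == "nearest":
        return int(round(x))
    if rounding == "floor":
        return int(math.floor(x))
    raise ParameterError(f"unknown rounding mode: {rounding!r}")


def concentration_from_count(count: float, volume: float) -> float:
    """Concentration (M) of ``count`` molecules in ``volume`` (L)."""
    if count < 0:
        raise ParameterError(f"negative count: {count}")
    if volume <= 0:
        raise ParameterError(f"non-positive volume: {volume}")
    return count / (AVOGADRO * volume)


# ---------------------------------------------------------------------------
# provenance metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Provenance:
    source: str
    reference: str = ""
    temperature_C: float | None = None


PROVENANCE: dict[str, Provenance] = {
    "k_pCaM4": Provenance("measured", "quench-flow autophosphorylation turnover", 30),
    "k_pCaMpartial": Provenance("coarse-grained", "single rate for all partially loaded permutations", 30),
    "kcat_pp1": Provenance("measured", "PP1 turnover on pT286", 30),
    "KM_pp1": Provenance("measured", "PP1 Michaelis constant for pCaMKII", 0),
    "koff_CaM4_la": Provenance("measured", "CaM4 off-rate, initial binding state", 30),
    "koff_CaM4_ha": Provenance("measured", "CaM4 off-rate, trapped state", 22),
    "KD_CaM4_la": Provenance("measured", "initial CaM4-CaMKII dissociation constant", 30),
    "cam_ca_rates": Provenance("source model (transcribed)", "two-step lobe scheme of Ca2+ binding to CaM", 30),
    "cam_binding_kon_anchors": Provenance("source model (ratios only)", "species on-rate anchors for geometric interpolation", 30),
    "n_ca_per_opening": Provenance("calibrated, not measured", "anchored to reference peak pCaMKII"),
    "tau_ca_clear": Provenance("calibrated, not measured", "effective first-order spine Ca2+ clearance"),
    "k_cam_exchange": Provenance("estimated", "spine-shaft CaM exchange through the neck"),
    "facilitation": Provenance("stand-in", "two-parameter facilitation, not a measured value"),
}


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class StimulusParams:
    epochs: int = 2
    bursts_per_epoch: int = 5
    aps_per_burst: int = 5
    burst_rate_hz: float = 5.0
    ap_rate_hz: float = 50.0
    t_start_s: float = 1.0
    epoch2_onset_s: float = 5.0
    p_release_init: float = 0.2
    n_docked_init: int = 7
    redock_rate: float = 0.2
    facilitation_increment: float = 0.25
    facilitation_tau_s: float = 0.25
    n_nmdar: int = 15
    bap_delay_s: float = 0.010
    coincidence_window_s: float = 0.020
    p_open: float = 0.5
    n_ca_per_opening: int = 250
    pulse_tau_s: float = 0.005
    refractory_s: float = 0.0


@dataclass
class ParameterSet:
    """Fully resolved model constants in SI units."""

    # kinase rates
    k_pCaM4: float
    k_pCaMpartial: float
    # PP1 Michaelis-Menten
    kcat_pp1: float
    KM_pp1: float          # M
    pp1_koff_policy: str   # "kcat" | "zero" | numeric multiple of kcat
    # CaM4-CaMKII binding anchors
    koff_CaM4_la: float
    koff_CaM4_ha: float
    KD_CaM4_la: float      # M
    # Ca2+/CaM rate tables: shape (3 contexts, 2 lobes, 2 steps)
    ca_on: np.ndarray
    ca_off: np.ndarray
    # per-species kon interpolation anchors (M^-1 s^-1), keyed by species name
    kon_anchors: dict[str, float]
    # pools
    conc_CaM_total: float  # M
    n_holoenzymes: int
    conc_PP1: float        # M
    ca_baseline: float     # M
    # geometry
    V_spine: float         # L
    V_psd: float           # L
    V_reservoir: float     # L
    # effective transport
    tau_ca_clear: float
    k_cam_exchange: float
    # stimulus
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    # model variant flags
    trapping: bool = False
    competition: bool = False
    psd_localization: str = "off"   # off | camkii_only | camkii_and_pp1
    ha_revert_on_dephos: bool = True
    trapped_rebind: str = "la"     # la | ha: mode of an emptied trapped site
    competition_scale: float = 1.0  # 1.0 = full steric block when CaM bound

    # -- derived ------------------------------------------------------------
    @property
    def kon_CaM4(self) -> float:
        """Association rate of CaM4 to the la site, from KD_la and koff_la."""
        return self.koff_CaM4_la / self.KD_CaM4_la

    def pp1_count(self, volume: float | None = None) -> int:
        return count_from_concentration(self.conc_PP1, volume or self.V_spine)

    def cam_count(self, volume: float | None = None) -> int:
        return count_from_concentration(self.conc_CaM_total, volume or self.V_spine)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        pos = {
            "k_pCaM4": self.k_pCaM4, "k_pCaMpartial": self.k_pCaMpartial,
            "kcat_pp1": self.kcat_pp1, "KM_pp1": self.KM_pp1,
            "koff_CaM4_la": self.koff_CaM4_la, "koff_CaM4_ha": self.koff_CaM4_ha,
            "KD_CaM4_la": self.KD_CaM4_la, "V_spine": self.V_spine,
            "V_psd": self.V_psd, "V_reservoir": self.V_reservoir,
            "tau_ca_clear": self.tau_ca_clear,
        }
        for name, v in pos.items():
            if not v > 0:
                raise ParameterError(f"{name} must be strictly positive, got {v}")
        for name, v in (("conc_CaM_total", self.conc_CaM_total),
                        ("conc_PP1", self.conc_PP1),
                        ("ca_baseline", self.ca_baseline),
                        ("k_cam_exchange", self.k_cam_exchange)):
            if v < 0:
                raise ParameterError(f"{name} must be non-negative, got {v}")
        if self.n_holoenzymes < 0 or int(self.n_holoenzymes) != self.n_holoenzymes:
            raise ParameterError("n_holoenzymes must be a non-negative integer")
        if not self.koff_CaM4_ha < self.koff_CaM4_la:
            raise ParameterError("trapping must slow dissociation: koff_ha < koff_la")
        if abs(self.kon_CaM4 * self.KD_CaM4_la - self.koff_CaM4_la) > 1e-9 * self.koff_CaM4_la:
            raise ParameterError("kon_CaM4 * KD_la does not reproduce koff_la")
        if not self.V_psd < self.V_spine:
            raise ParameterError("V_psd must be smaller than V_spine")
        if self.psd_localization not in ("off", "camkii_only", "camkii_and_pp1"):
            raise ParameterError(f"unknown psd_localization: {self.psd_localization!r}")
        if self.trapped_rebind not in ("la", "ha"):
            raise ParameterError(f"unknown trapped_rebind mode: {self.trapped_rebind!r}")
        if np.any(self.ca_on <= 0) or np.any(self.ca_off <= 0):
            raise ParameterError("all Ca2+/CaM rates must be strictly positive")
        if not 0 <= self.stimulus.p_release_init <= 1:
            raise ParameterError("p_release_init must lie in [0, 1]")
        if not 0 <= self.stimulus.p_open <= 1:
            raise ParameterError("p_open must lie in [0, 1]")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["ca_on"] = self.ca_on.tolist()
        d["ca_off"] = self.ca_off.tolist()
        d["kon_CaM4"] = self.kon_CaM4
        return d

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        s = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    def replace(self, **kw) -> "ParameterSet":
        stim_kw = kw.pop("stimulus", None)
        new = dataclasses.replace(self, **kw)
        if stim_kw is not None:
            if isinstance(stim_kw, StimulusParams):
                new.stimulus = stim_kw
            else:
                new.stimulus = dataclasses.replace(self.stimulus, **stim_kw)
        new.validate()
        return new


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------

def _deep_update(base: dict, extra: dict) -> dict:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def _ca_tables(raw: dict) -> tuple[np.ndarray, np.ndarray]:
    on = np.zeros((3, 2, 2))
    off = np.zeros((3, 2, 2))
    ha = raw.get("camkii_ha") or raw["camkii_la"]  # null -> copy of la
    for ci, block in ((CTX_FREE, raw["free"]), (CTX_LA, raw["camkii_la"]), (CTX_HA, ha)):
        for li, lobe in ((LOBE_C, "C"), (LOBE_N, "N")):
            on[ci, li, 0] = float(block[lobe]["kon1"])
            on[ci, li, 1] = float(block[lobe]["kon2"])
            off[ci, li, 0] = float(block[lobe]["koff1"])
            off[ci, li, 1] = float(block[lobe]["koff2"])
    return on, off


def default_config() -> dict:
    with resources.files("camkii_spine.data").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_params(config: str | Path | dict | None = None, **overrides) -> ParameterSet:
    """Build a validated :class:`ParameterSet`.

    ``config`` may be a YAML path or a (possibly partial) dict; entries merge
    over the shipped defaults.  ``overrides`` are applied last as top-level
    section dicts, e.g. ``load_params(flags={"trapping": True})``.
    """
    cfg = default_config()
    if config is not None:
        if isinstance(config, (str, Path)):
            user = yaml.safe_load(Path(config).read_text())
        else:
            user = copy.deepcopy(config)
        _deep_update(cfg, user or {})
    _deep_update(cfg, overrides)

    vols = cfg["volumes"]
    r = float(vols["reservoir_diameter_um"]) / 2.0
    length = float(vols["reservoir_length_um"])
    v_res_fL = math.pi * r * r * length  # um^3 == fL

    ca_on, ca_off = _ca_tables(cfg["cam_ca_rates"])
    stim = StimulusParams(**cfg["stimulus"])
    flags = cfg["flags"]

    ps = ParameterSet(
        k_pCaM4=float(cfg["kinase"]["k_pCaM4"]),
        k_pCaMpartial=float(cfg["kinase"]["k_pCaMpartial"]),
        kcat_pp1=float(cfg["pp1"]["kcat"]),
        KM_pp1=float(cfg["pp1"]["KM_uM"]) * 1e-6,
        pp1_koff_policy=str(cfg["pp1"]["koff_policy"]),
        koff_CaM4_la=float(cfg["kinase"]["koff_CaM4_la"]),
        koff_CaM4_ha=float(cfg["kinase"]["koff_CaM4_ha"]),
        KD_CaM4_la=float(cfg["kinase"]["KD_CaM4_la_nM"]) * 1e-9,
        ca_on=ca_on,
        ca_off=ca_off,
        kon_anchors={k: float(v) for k, v in cfg["cam_binding_kon_anchors_M_s"].items()},
        conc_CaM_total=float(cfg["concentrations"]["conc_CaM_total_uM"]) * 1e-6,
        n_holoenzymes=int(cfg["counts"]["n_holoenzymes"]),
        conc_PP1=float(cfg["concentrations"]["conc_PP1_uM"]) * 1e-6,
        ca_baseline=float(cfg["concentrations"]["ca_baseline_nM"]) * 1e-9,
        V_spine=float(vols["V_spine_fL"]) * 1e-15,
        V_psd=float(vols["V_psd_fL"]) * 1e-15,
        V_reservoir=v_res_fL * 1e-15,
        tau_ca_clear=float(cfg["calcium"]["tau_ca_clear_s"]),
        k_cam_exchange=float(cfg["exchange"]["k_cam_exchange"]),
        stimulus=stim,
        trapping=bool(flags["trapping"]),
        competition=bool(flags["competition"]),
        psd_localization=str(flags["psd_localization"]),
        ha_revert_on_dephos=bool(flags.get("ha_revert_on_dephos", True)),
        trapped_rebind=str(flags.get("trapped_rebind", "la")),
        competition_scale=float(flags.get("competition_scale", 1.0)),
    )
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# thermodynamic consistency
# ---------------------------------------------------------------------------

def validate_thermodynamics(tables, tol: float = 1e-6):
    """Check detailed balance around every CaM-binding/Ca-binding cycle.

    For each lattice edge (species X -> X+Ca at one site) and each bound
    context (la, ha), the four-state cycle

        CaMKII + X  ->  K.X  ->  K.X'  ->  CaMKII + X'  ->  CaMKII + X

    must have zero net free-energy change, i.e. the product of equilibrium
    constants around the loop must be 1.  Returns a pandas DataFrame with one
    row per cycle and a boolean ``flagged`` column for residuals above
    ``tol``; ``tables`` is a :class:`camkii_spine.cam.RateTables`.
    """
    import pandas as pd
    from . import cam

    required = ("kon_bind", "koff_bind_la", "koff_bind_ha", "ca_on", "ca_off")
    for attr in required:
        if getattr(tables, attr, None) is None:
            raise ParameterError(f"rate table is missing entry {attr!r}")

    rows = []
    for ctx, koff_bind in ((CTX_LA, tables.koff_bind_la), (CTX_HA, tables.koff_bind_ha)):
        for i, (nC, nN) in enumerate(cam.SPECIES):
            for lobe, dn in ((LOBE_C, (1, 0)), (LOBE_N, (0, 1))):
                n_lobe = nC if lobe == LOBE_C else nN
                if n_lobe >= 2:
                    continue
                j = cam.species_index(nC + dn[0], nN + dn[1])
                with np.errstate(divide="raise"):
                    k_bind_x = tables.kon_bind[i] / koff_bind[i]
                    k_ca_bound = tables.ca_on[ctx, lobe, n_lobe] / tables.ca_off[ctx, lobe, n_lobe]
                    k_unbind_xp = koff_bind[j] / tables.kon_bind[j]
                    k_ca_free_rev = tables.ca_off[CTX_FREE, lobe, n_lobe] / tables.ca_on[CTX_FREE, lobe, n_lobe]
                residual = abs(math.log(k_bind_x * k_ca_bound * k_unbind_xp * k_ca_free_rev))
                rows.append({
                    "context": CONTEXT_NAMES[ctx],
                    "species": cam.SPECIES_NAMES[i],
                    "lobe": "C" if lobe == LOBE_C else "N",
                    "residual": residual,
                    "flagged": residual > tol,
                })
    return pd.DataFrame(rows)
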