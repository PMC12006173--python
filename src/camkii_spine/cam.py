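"""Nine-species calmodulin Ca2+-binding scheme and detailed-balance derivations.

Calmodulin carries two sequential Ca2+ sites on each lobe (C and N), giving
nine occupancy species on a 3x3 lattice with no diagonal moves.  Each species
is interpreted in one of three contexts: free in solution, bound to an
unphosphorylated-affinity (la) CaMKII site, or bound to a trapped (ha) site.

The shipped config specifies Ca2+ on/off rates per lobe site in the free and
bound contexts, plus the measured CaM4 binding anchors (KD = 65 nM,
koff = 6.6 /s initial; koff = 9e-5 /s trapped).  Everything else — the
CaM-CaMKII dissociation constant of every partially loaded species, and the
full table of trapped off-rates — is derived here from the requirement that
every closed binding cycle has zero net free energy (detailed balance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    AVOGADRO, CTX_FREE, CTX_HA, CTX_LA, LOBE_C, LOBE_N,
    ParameterError, ParameterSet,
)

#: lattice order: index = 3*nC + nN
SPECIES: tuple[tuple[int, int], ...] = tuple((nC, nN) for nC in range(3) for nN in range(3))

SPECIES_NAMES: tuple[str, ...] = (
    "CaM0", "CaM1N", "CaM2N",
    "CaM1C", "CaM1C1N", "CaM1C2N",
    "CaM2C", "CaM2C1N", "CaM4",
)

N_SPECIES = 9
CAM0 = 0
CAM4 = 8

CONTEXTS = ("free", "camkii_la", "camkii_ha")
_CTX_INDEX = {"free": CTX_FREE, "camkii_la": CTX_LA, "camkii_ha": CTX_HA}


def species_index(nC: int, nN: int) -> int:
    if not (0 <= nC <= 2 and 0 <= nN <= 2):
        raise ParameterError(f"lobe occupancy out of range: ({nC}, {nN})")
    return 3 * nC + nN


def n_ca(i: int) -> int:
    nC, nN = SPECIES[i]
    return nC + nN


@dataclass
class RateTables:
    """All per-species rate constants used by the simulator.

    ``ca_on``/``ca_off`` have shape (context, lobe, step); binding arrays are
    indexed by species.  ``kon_bind`` is in M^-1 s^-1 and applies to both the
    la and ha site (rebinding to a trapped site uses the same on-rate, only
    the off-rate differs).
    """

    ca_on: np.ndarray
    ca_off: np.ndarray
    kon_bind: np.ndarray       # (9,)
    koff_bind_la: np.ndarray   # (9,)
    koff_bind_ha: np.ndarray   # (9,)
    kd_la: np.ndarray          # (9,) M
    kd_ha: np.ndarray          # (9,) M

    def koff_bind(self, mode: str) -> np.ndarray:
        return self.koff_bind_la if mode == "la" else self.koff_bind_ha


def _kd_ladder(params: ParameterSet, ctx: int, kd_cam4: float) -> np.ndarray:
    """Species-wise CaM-CaMKII KD from detailed balance, anchored at CaM4.

    Adding one Ca2+ at lobe site ``s`` multiplies the binding KD by
    r_s = KD_Ca(bound)/KD_Ca(free) for that site, so removing Ca2+ from CaM4
    divides by r_s step by step.
    """
    kd_ca = params.ca_off / params.ca_on  # (ctx, lobe, step)
    r = kd_ca[ctx] / kd_ca[CTX_FREE]      # (lobe, step)
    kd = np.empty(N_SPECIES)
    for i, (nC, nN) in enumerate(SPECIES):
        factor = 1.0
        for s in range(nC, 2):
            factor /= r[LOBE_C, s]
        for s in range(nN, 2):
            factor /= r[LOBE_N, s]
        kd[i] = kd_cam4 * factor
    return kd


def _kon_interpolated(params: ParameterSet) -> np.ndarray:
    """Per-species association rates to the CaMKII cam site.

    Geometric interpolation in lobe occupancy, using the measured on-rate
    ratios of CaM0/CaM2C/CaM2N/CaM4 as shape anchors and renormalised so
    kon(CaM4) equals koff_CaM4_la / KD_CaM4_la exactly.
    """
    a = params.kon_anchors
    try:
        aC = np.sqrt(a["CaM2C"] / a["CaM0"])
        aN = np.sqrt(a["CaM2N"] / a["CaM0"])
    except KeyError as e:
        raise ParameterError(f"missing kon anchor: {e}") from e
    w = np.array([aC ** nC * aN ** nN for nC, nN in SPECIES])
    return params.kon_CaM4 * w / w[CAM4]


def build_rate_tables(params: ParameterSet) -> RateTables:
    """Assemble the full rate table; passes ``validate_thermodynamics``."""
    kon_bind = _kon_interpolated(params)
    kd_la = _kd_ladder(params, CTX_LA, params.KD_CaM4_la)
    kd_ha = _kd_ladder(params, CTX_HA, params.koff_CaM4_ha / params.kon_CaM4)
    return RateTables(
        ca_on=params.ca_on.copy(),
        ca_off=params.ca_off.copy(),
        kon_bind=kon_bind,
        koff_bind_la=kon_bind * kd_la,
        koff_bind_ha=kon_bind * kd_ha,
        kd_la=kd_la,
        kd_ha=kd_ha,
    )


def derive_ha_offrates(params: ParameterSet) -> dict[str, float]:
    """Trapped-state off-rate of every CaM species, keyed by species name.

    Anchored at koff_ha(CaM4) = ``params.koff_CaM4_ha``; all other entries
    follow from the zero-free-energy loop rule.  When the ha-context Ca2+
    table equals the la-context table (the default), the entire column is the
    la column scaled by koff_ha(CaM4)/koff_la(CaM4).
    """
    t = build_rate_tables(params)
    return dict(zip(SPECIES_NAMES, t.koff_bind_ha.tolist()))


# ---------------------------------------------------------------------------
# transitions and equilibrium
# ---------------------------------------------------------------------------

def ca_transition_rates(species: int | str, context: str, ca_conc: float,
                        params: ParameterSet) -> list[tuple[int, float]]:
    """Legal +/-1 Ca2+ moves from ``species`` with their propensity rates.

    Association entries are pseudo-first-order (kon * [Ca2+]); at most four
    transitions are returned (one per lobe and direction where legal).
    """
    if context not in _CTX_INDEX:
        raise ParameterError(f"unknown binding context: {context!r}")
    ctx = _CTX_INDEX[context]
    i = SPECIES_NAMES.index(species) if isinstance(species, str) else int(species)
    nC, nN = SPECIES[i]
    out: list[tuple[int, float]] = []
    for lobe, n_lobe, dn in ((LOBE_C, nC, 3), (LOBE_N, nN, 1)):
        if n_lobe < 2:
            out.append((i + dn, params.ca_on[ctx, lobe, n_lobe] * ca_conc))
        if n_lobe > 0:
            out.append((i - dn, params.ca_off[ctx, lobe, n_lobe - 1]))
    return out


def generator_matrix(context: str, ca_conc: float, params: ParameterSet) -> np.ndarray:
    """Column-based generator Q of the 9-state chain at clamped [Ca2+].

    dq/dt = Q @ p with p the species-probability vector.
    """
    Q = np.zeros((N_SPECIES, N_SPECIES))
    for i in range(N_SPECIES):
        for j, rate in ca_transition_rates(i, context, ca_conc, params):
            Q[j, i] += rate
            Q[i, i] -= rate
    return Q


def equilibrium_cam_distribution(ca_clamp: float, params: ParameterSet,
                                 context: str = "free") -> np.ndarray:
    """Equilibrium proportions of the 9 species at clamped [Ca2+] (M).

    Solves the linear balance equations (null space of the generator); the
    result sums to one.
    """
    if ca_clamp < 0:
        raise ParameterError("ca_clamp must be non-negative")
    if ca_clamp == 0.0:
        p = np.zeros(N_SPECIES)
        p[CAM0] = 1.0
        return p
    # The lattice is reversible (each lobe is a birth-death chain), so the
    # balance equations have an exact product-form solution; this is far
    # better conditioned than a numerical null-space solve on a chain whose
    # rates span seven orders of magnitude.
    ctx = _CTX_INDEX[context]
    w = np.empty(N_SPECIES)
    for i, (nC, nN) in enumerate(SPECIES):
        x = 1.0
        for s in range(nC):
            x *= params.ca_on[ctx, LOBE_C, s] * ca_clamp / params.ca_off[ctx, LOBE_C, s]
        for s in range(nN):
            x *= params.ca_on[ctx, LOBE_N, s] * ca_clamp / params.ca_off[ctx, LOBE_N, s]
        w[i] = x
    if not np.all(np.isfinite(w)) or w.sum() == 0:
        raise ParameterError("singular balance system at this Ca2+ clamp")
    return w / w.sum()


def cam_affinity_increases_on_binding(params: ParameterSet) -> bool:
    """True when every lobe site binds Ca2+ tighter in the bound context."""
    kd = params.ca_off / params.ca_on
    return bool(np.all(kd[CTX_LA] < kd[CTX_FREE]))
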