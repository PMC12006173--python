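"""Stochastic PP1 binding and catalysis (Michaelis-Menten), with CaM-block.

Dephosphorylation of pT286 is an explicit two-step process: PP1 binds a
phosphorylated subunit, then either catalyses (releasing dephosphorylated
subunit and enzyme) or unbinds unproductively.  The split of K_M into
kon/koff is not an observable of the model, only (koff+kcat)/kon = K_M is
constrained; the default policy sets koff = kcat.

The optional competition rule implements steric hindrance by bound CaM:
PP1 can bind a pCaMKII subunit only while its cam site is free.  The default
is the all-or-none block; ``competition_scale`` < 1 exposes a partial block.
"""

from __future__ import annotations

from dataclasses import dataclass

from .holoenzyme import SubunitState
from .params import AVOGADRO, ParameterError, ParameterSet


@dataclass(frozen=True)
class PP1MicroRates:
    kon_pp1: float   # M^-1 s^-1
    koff_pp1: float  # s^-1
    kcat_pp1: float  # s^-1

    @property
    def KM(self) -> float:
        return (self.koff_pp1 + self.kcat_pp1) / self.kon_pp1

    @property
    def p_catalysis(self) -> float:
        """Branching probability that a bound complex ends in dephosphorylation."""
        return self.kcat_pp1 / (self.kcat_pp1 + self.koff_pp1)

    @property
    def mean_dwell(self) -> float:
        """Mean lifetime of the bound complex (exponential race)."""
        return 1.0 / (self.kcat_pp1 + self.koff_pp1)


def derive_pp1_micro_rates(KM: float, kcat: float,
                           koff_policy: str | float = "kcat") -> PP1MicroRates:
    """Split K_M (M) and kcat (s^-1) into micro-rates.

    ``koff_policy``: "kcat" (koff = kcat, default), "zero" (koff = 0), or a
    numeric multiple of kcat.
    """
    if KM <= 0 or kcat <= 0:
        raise ParameterError("KM and kcat must be strictly positive")
    if koff_policy == "kcat":
        koff = kcat
    elif koff_policy == "zero":
        koff = 0.0
    else:
        koff = float(koff_policy) * kcat
        if koff < 0:
            raise ParameterError("koff multiple must be non-negative")
    return PP1MicroRates(kon_pp1=(koff + kcat) / KM, koff_pp1=koff, kcat_pp1=kcat)


def micro_rates_from_params(params: ParameterSet) -> PP1MicroRates:
    return derive_pp1_micro_rates(params.KM_pp1, params.kcat_pp1, params.pp1_koff_policy)


def pp1_binding_propensity(subunit: SubunitState, pp1_free: float, volume: float,
                           rates: PP1MicroRates, competition: bool = False,
                           competition_scale: float = 1.0) -> float:
    """Binding propensity (s^-1) of free PP1 to one subunit.

    Zero unless the subunit is phosphorylated and PP1-free; with competition
    on, bound CaM blocks binding entirely (or scales it by
    ``1 - competition_scale`` for a partial block).
    """
    if not subunit.pT286 or subunit.pp1_bound:
        return 0.0
    rate = rates.kon_pp1 * pp1_free / (AVOGADRO * volume)
    if competition and subunit.cam_occupant is not None:
        rate *= max(0.0, 1.0 - competition_scale)
    return rate


def pp1_catalysis_step(rates: PP1MicroRates, rng) -> tuple[str, float]:
    """Resolve a bound complex: ('catalysis'|'unbind', dwell time).

    The two exits compete as exponential clocks; catalysis clears pT286 and
    releases PP1, unbinding releases PP1 with the state unchanged.
    """
    dwell = rng.exponential(rates.mean_dwell)
    outcome = "catalysis" if rng.random() < rates.p_catalysis else "unbind"
    return outcome, dwell
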