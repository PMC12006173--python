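"""Dodecameric CaMKII holoenzyme: topology, CaM binding, autophosphorylation.

A holoenzyme is 12 subunits in two stacked 6-rings.  Autophosphorylation of
Thr286 is strictly intra-ring and directional: the clockwise ("right-hand")
neighbour acts as kinase and phosphorylates its left-hand neighbour when the
substrate has CaM bound and the kinase is active (CaM-bound or already
phosphorylated).  The inter-ring contact is structural only — no reaction
crosses rings.  Thr306 is carried as a state but never phosphorylated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cam
from .params import AVOGADRO, ParameterError, ParameterSet

SUBUNITS_PER_RING = 6
RINGS = 2
SUBUNITS_PER_HOLO = SUBUNITS_PER_RING * RINGS


@dataclass
class SubunitState:
    """One catalytic subunit.

    ``cam_occupant`` is a species index (0-8) or None; ``affinity_mode`` is
    "la" or "ha" and may only be "ha" when trapping is enabled.
    """

    cam_occupant: int | None = None
    affinity_mode: str = "la"
    pT286: bool = False
    pp1_bound: bool = False
    pT306: bool = False  # always False in this model
    compartment: str = "spine"

    def check(self) -> None:
        if self.pp1_bound and not self.pT286:
            raise ParameterError("PP1 may only be bound to a phosphorylated subunit")
        if self.pT306:
            raise ParameterError("T306 remains unphosphorylated in this model")

    @property
    def active(self) -> bool:
        return self.pT286 or self.cam_occupant is not None


@dataclass
class Holoenzyme:
    id: int = 0
    compartment: str = "spine"
    subunits: list[SubunitState] = field(default_factory=list)

    def __post_init__(self):
        if not self.subunits:
            self.subunits = [SubunitState(compartment=self.compartment)
                             for _ in range(SUBUNITS_PER_HOLO)]

    def ring_position(self, idx: int) -> tuple[int, int]:
        return divmod(idx, SUBUNITS_PER_RING)

    def neighbor(self, idx: int, side: str) -> int:
        """Index of the ring neighbour on ``side`` ("left" or "right")."""
        ring, pos = self.ring_position(idx)
        step = 1 if side == "right" else -1
        return ring * SUBUNITS_PER_RING + (pos + step) % SUBUNITS_PER_RING
    def kinase_of(self, idx: int) -> int:
        """The subunit that phosphorylates ``idx`` (its right-hand neighbour)."""
        return self.neighbor(idx, "right")

    @property
    def n_phospho(self) -> int:
        return sum(s.pT286 for s in self.subunits)

    def to_table(self):
        import pandas as pd
        rows = []
        for i, s in enumerate(self.subunits):
            ring, pos = self.ring_position(i)
            rows.append({"holo_id": self.id, "ring": ring, "position": pos,
                         "cam_species": None if s.cam_occupant is None
                         else cam.SPECIES_NAMES[s.cam_occupant],
                         "mode": s.affinity_mode, "pT286": s.pT286,
                         "pp1_bound": s.pp1_bound})
        return pd.DataFrame(rows)


def build_holoenzyme(holo_id: int = 0, compartment: str = "spine") -> Holoenzyme:
    """A fresh holoenzyme: nothing phosphorylated, all cam sites la, no CaM."""
    return Holoenzyme(id=holo_id, compartment=compartment)


def kinase_index_map(n_holo: int) -> np.ndarray:
    """Flat kinase-neighbour index for ``n_holo`` holoenzymes' subunits.

    Subunit ``i`` is phosphorylated by subunit ``out[i]`` (same ring).
    """
    out = np.empty(n_holo * SUBUNITS_PER_HOLO, dtype=np.int64)
    for h in range(n_holo):
        base = h * SUBUNITS_PER_HOLO
        for r in range(RINGS):
            for p in range(SUBUNITS_PER_RING):
                i = base + r * SUBUNITS_PER_RING + p
                out[i] = base + r * SUBUNITS_PER_RING + (p + 1) % SUBUNITS_PER_RING
    return out


# ---------------------------------------------------------------------------
# reaction rules
# ---------------------------------------------------------------------------

def cam_binding_propensity(subunit: SubunitState, species: int, free_count: float,
                           volume: float, tables: cam.RateTables,
                           direction: str = "bind") -> float:
    """Association or dissociation propensity (s^-1) for one subunit.

    Association is kon(species) * [free CaMx]; dissociation uses the off-rate
    of the subunit's current affinity mode.  Zero when the site is occupied
    (binding) or empty (unbinding).
    """
    if direction == "bind":
        if subunit.cam_occupant is not None:
            return 0.0
        return tables.kon_bind[species] * free_count / (AVOGADRO * volume)
    if subunit.cam_occupant is None:
        return 0.0
    return float(tables.koff_bind(subunit.affinity_mode)[subunit.cam_occupant])


def autophosphorylation_rate(left: SubunitState, right: SubunitState,
                             params: ParameterSet) -> float:
    """Rate of phosphorylation of ``left`` by its kinase-side neighbour ``right``.

    Zero unless the substrate has CaM bound, is not yet phosphorylated, and
    the kinase is active.  Both-CaM4 pairs (or a CaM4 substrate under an
    already-phosphorylated kinase) proceed at k_pCaM4; every other active
    permutation is coarse-grained to k_pCaMpartial.
    """
    if left.pT286 or left.cam_occupant is None:
        return 0.0
    if not right.active:
        return 0.0
    if left.cam_occupant == cam.CAM4 and (right.pT286 or right.cam_occupant == cam.CAM4):
        return params.k_pCaM4
    return params.k_pCaMpartial


def apply_phosphorylation(holo: Holoenzyme, idx: int, params: ParameterSet,
                          tables: cam.RateTables) -> float | None:
    """Set pT286 on subunit ``idx``; returns the la->ha conversion rate.

    With trapping on and CaM bound, a first-order la->ha conversion is
    enabled at the la off-rate of the bound species (the caller schedules
    it); returns None when no conversion applies.
    """
    sub = holo.subunits[idx]
    kin = holo.subunits[holo.kinase_of(idx)]
    if autophosphorylation_rate(sub, kin, params) <= 0.0:
        raise ParameterError("phosphorylation fired on an ineligible subunit")
    sub.pT286 = True
    if params.trapping and sub.cam_occupant is not None and sub.affinity_mode == "la":
        return float(tables.koff_bind_la[sub.cam_occupant])
    return None
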