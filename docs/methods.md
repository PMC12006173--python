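# Methods

## The model

`camkii-spine` simulates the first tens of seconds of CaMKII activation in a
median-sized dendritic spine (0.016 fL) driven by a two-epoch presynaptic
burst stimulus. The chemistry comprises four coupled layers:

1. **Ca²⁺ pool.** Free Ca²⁺ is a single spine-wide pool with a 100 nM
   baseline. Stimulus events inject ions as exponentially decaying pulses
   (time constant `pulse_tau_s`); the pool relaxes back to baseline first
   order with `tau_ca_clear_s`. Pumps, exchangers, voltage-gated channels,
   and explicit buffers are not modelled — their combined effect is absorbed
   into the calibrated clearance (see *Calibration*).

2. **Calmodulin.** CaM carries two sequential Ca²⁺ sites on each lobe
   (C and N), giving nine occupancy species on a 3×3 lattice. Ca²⁺ on/off
   rates are specified per lobe site in two measured contexts — free CaM and
   CaM bound to a CaMKII subunit — using the two-step lobe scheme of the
   published Ca²⁺/CaM/CaMKII source model (rates measured near 30 °C).
   Binding CaM to the kinase tightens every Ca²⁺ site, as thermodynamics
   requires.

3. **CaMKII holoenzymes.** Sixty dodecamers (720 subunits, 80 µM) are
   represented subunit-by-subunit as two 6-rings with directional topology.
   Autophosphorylation of Thr286 is intra-ring: the right-hand neighbour is
   the kinase, the left-hand neighbour the substrate. The substrate must
   have CaM bound (any species) and the kinase must be active (CaM-bound or
   already phosphorylated). Both-CaM4 pairs — or a CaM4 substrate under a
   phosphorylated kinase — fire at k_pCaM4 = 0.96 s⁻¹; every other active
   permutation is coarse-grained to k_pCaMpartial = 0.1 s⁻¹. Thr306 is
   carried as a state but never phosphorylated.

4. **PP1.** Dephosphorylation is an explicit two-step Michaelis–Menten
   process: binding of a free PP1 (12 copies at 1.25 µM baseline) to a
   phosphorylated subunit, then a race between catalysis (k_cat = 11.5 s⁻¹)
   and unbinding. Only (k_off + k_cat)/k_on = K_M = 11 µM is observable; the
   split defaults to k_off = k_cat and is configurable (`pp1.koff_policy`);
   the fitted decay constants are insensitive to the split at the substrate
   scales reached here because the bound-state dwell (≲ 90 ms) is short
   against every measured τ.

### CaM-trapping

Autophosphorylation exposes residues that let Ca²⁺/CaM wrap the extended
CaM-binding domain, dropping the CaM4 off-rate from 6.6 s⁻¹ (K_D = 65 nM)
to 9×10⁻⁵ s⁻¹. We model this as a low-affinity (la) versus high-affinity
(ha) state of the cam site. Following a phosphorylation event with CaM
bound, the la→ha conversion proceeds first order at the la off-rate of the
bound species (so conversion and escape race 50/50 per binding episode).
Off-rates of every partially loaded species from the ha site are derived
from the ΔG = 0 loop rule (below). When a trapped occupant finally leaves,
the site reverts to la: the package deliberately does **not** let freshly
binding CaM enter the trapped state on an already-phosphorylated subunit,
because with the default trapped-context Ca²⁺ table the thermodynamically
implied apo-CaM trapped affinity (~260 nM) would let Ca²⁺-free CaM occupy
every phosphorylated subunit permanently at 30 µM CaM. The alternative
semantics is available as `flags.trapped_rebind: "ha"`.

### Detailed-balance completions

Only the CaM4 anchors of CaM–kinase binding are measured. The remaining 17
binding constants are derived, not imposed:

* **K_D ladder.** Around the cycle (bind CaM, load Ca²⁺ on the kinase, vs.
  load Ca²⁺ free, then bind), adding one Ca²⁺ at lobe site *s* multiplies
  the CaM–kinase K_D by r_s = K_D^Ca(bound)/K_D^Ca(free). Anchoring at
  K_D(CaM4) = 65 nM yields every species' la-state K_D; the ha ladder is
  anchored at K_D = 9×10⁻⁵/k_on(CaM4) ≈ 0.9 pM.
* **On-rates.** Species association rates are interpolated geometrically in
  lobe occupancy using the source model's measured CaM0/CaM2C/CaM2N/CaM4
  on-rate ratios, renormalised so k_on(CaM4) = k_off,la/K_D,la. Off-rates
  then follow as k_on × K_D. `validate_thermodynamics` checks every
  4-state cycle (24 cycles: 12 lattice edges × 2 bound contexts) and the
  shipped table closes all of them to < 10⁻⁹ in log-space.
* **Trapped-context Ca²⁺ rates** default to the bound-context values, so the
  whole trapping effect rides on the CaM off-rate. This is the main
  unconstrained choice in the model (the original supplementary table is a
  three-context table we could not transcribe) and it controls the lifetime
  of the trapped state; see *Known limitations*.

### Stimulus

Two epochs (onsets 1 s and 5 s) of five bursts at 5 Hz, each of five APs at
50 Hz — 50 APs in all. Per AP, each of 7 docked sites releases independently
with per-site probability 1−(1−0.2)^(1/7), scaled by a two-parameter
facilitation factor (increment 0.25 per AP, decay 0.25 s — a stand-in, not a
measured pair); emptied sites redock at 0.2 s⁻¹, which produces synaptic
depression in epoch 2. A bAP follows each AP by 10 ms; a release gates Ca²⁺
entry only if a bAP falls within a 20 ms window after it, in which case each
of 15 receptors opens with probability 0.5 and delivers `n_ca_per_opening`
ions. Voltage, cleft glutamate, and receptor state kinetics are abstracted
into this temporal coincidence gate.

### Calibration

`n_ca_per_opening` and `tau_ca_clear_s` are the model's only calibrated
constants, marked "calibrated, not measured" in the config. The clearance
was fixed at 15 ms (the physiological scale of spine Ca²⁺ decay) and the
ions-per-opening count set once (250) so that the trapping-on,
competition-off model at 1.25 µM PP1 peaks near the ~200 phosphorylated
subunits of the reference condition. Nothing downstream was adjusted after
this single anchoring.

## Engines

* **hybrid** (production): free Ca²⁺ and the nine free-CaM pools advance by
  mean-field integration (explicit Euler with stability-controlled
  substeps); every subunit and PP1 molecule is discrete, sampled per step
  against its total propensity with the step bounded so max(R·dt) ≲ 0.15.
  The core is numba-compiled; an 11 s run of the full spine takes on the
  order of a second.
* **exact_ssa** (reference): Gillespie direct method with every molecule
  discrete, including per-ion Ca²⁺ birth/death for the clearance and bath
  exchange. Used on reduced systems (6 holoenzymes, 29 CaM, 2 PP1) to
  cross-check the hybrid integrator; ensemble means agree within
  3 pooled s.e. under a clamped-Ca drive, where both engines see an
  identical input.

Compartments are well mixed. With PSD localization on, a 0.002915 fL capsule
confines half the holoenzymes (and, in the `camkii_and_pp1` mode, half the
PP1, which then mixes in capsule/remainder volumes separately); Ca²⁺ and CaM
remain spine-wide pools, so the deliberately omitted spatial effect is the
small autophosphorylation enhancement from NMDAR proximity. The dendritic
shaft is an infinite bath: spine free CaM relaxes toward the bath
composition at `k_cam_exchange` = 10 s⁻¹ (an estimate of neck exchange for
a small protein), and Ca²⁺ toward 100 nM.

Reproducibility: one generator per seed; channel order is fixed; identical
seed, parameters, and engine mode give bit-identical trajectories.

## Analysis

Decay constants are fitted to the ensemble-mean pCaMKII trace (per-seed τ
distributions are available separately) as A·e^(−t/τ), optionally with an
additive floor, or from two anchor points as (t₂−t₁)/ln(y₁/y₂). The epoch-1
window is [2.2, 5.0] s — the stimulus epoch ends at 1.98 s and the fastest
conditions reach baseline before 4 s, so a window starting at 4 s would fit
noise. Epoch-2 windows are [7.7, 8.7] s, or [8.7, 21] s for the slow
trapping-plus-competition condition run to 21 s. Peaks are read from a
50 ms boxcar-smoothed trace, earliest bin winning ties.

Ensembles default to 10 seeds. This is a desk-scale choice: cross-seed
s.e.m. of the fitted τ is a few percent of the stochastic tolerances used
in the checks, and the mean of 10 seeds is statistically indistinguishable
from larger ensembles for every fitted quantity we examined.

## What the synthetic stimulus does and does not emulate

It reproduces the burst structure, the stochastic release statistics
(compound p ≈ 0.2, facilitation then depression), the bAP coincidence gate,
and release-to-release variability across seeds. It does not reproduce
voltage waveforms, glutamate diffusion, receptor desensitisation kinetics
(only an optional refractory period), or the spatial position of release
sites. Consequently, passing checks demonstrate the network's kinetic
logic — phosphatase sensitivity, trapping, steric competition — under a
realistic event statistics, not a quantitative reconstruction of NMDAR
currents.

## Known limitations

* The trapped-state off-rates of partially loaded CaM species are derived,
  not measured. With the default completion the trapped pool at baseline
  Ca²⁺ retains sub-nanomolar affinity, so when PP1 binding is sterically
  blocked by bound CaM the model predicts a quasi-stable pCaMKII plateau
  over the 21 s horizon rather than a ~60 s decay: an even stronger
  steric-hindrance effect than the reference prediction. The plateau's
  lifetime is controlled entirely by the trapped-context Ca²⁺ table
  (`cam_ca_rates.camkii_ha`), which users can override.
* No Q10 temperature rescaling: constants measured at 22–34 °C are used as
  published.
* Interholoenzyme autophosphorylation, Thr305/306 chemistry, α/β mixed
  holoenzymes, CaM buffers (neurogranin), and PP1 regulation are out of
  scope.
* Mean-field free pools ignore Ca²⁺ shot noise at the ~1-ion baseline; the
  exact engine retains it, and the cross-checks bound the effect on
  ensemble means.
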