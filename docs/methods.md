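# Methods

## Model and assumptions

The lung is a single well-mixed alveolar gas compartment exchanging only
oxygen.  Its gas volume is `V_A(t) = V_A,EELV + V(t)`, where `V(t)` is the
ventilator waveform above end-expiratory lung volume and
`V_A,EELV = (EELV/kg − V_D/kg) · mass` — end-expiratory lung volume minus
series dead space.  EELV is defined at 5 cmH₂O PEEP, so no additional
PEEP-volume correction is applied.  Oxygen uptake V̇O₂ (ml/s BTPS) is
constant through the cycle; shunt, when enabled, is likewise constant —
the model deliberately contains no cyclical atelectasis, recruitment, or
within-breath perfusion redistribution, because its point is that
oscillations appear without them.

The state variable is the O₂ partial volume `n = F_A · V_A`:

- inspiration: `dn/dt = F_insp(t)·V̇(t) − V̇O₂`, where the first `V_D` ml
  of each inspiration re-enter at the end-expiratory alveolar composition
  (series, first-in-last-out dead space) and the remainder at FIO₂;
- expiration: `dn/dt = −F_A·|V̇(t)| − V̇O₂` (gas leaves at alveolar
  composition);
- breath hold: `dn/dt = −V̇O₂` with `V_A` frozen (airway-open,
  constant-pressure hold).

Alveolar PO₂ is `F_A·(P_B − P_H₂O)`.  During expiration and holds the
dilution term cancels, giving the closed form
`dP_A/dt = −V̇O₂·(P_B − P_H₂O)/V_A` that the breath-hold analysis uses.

Only O₂ is tracked: CO₂/N₂ exchange and respiratory-quotient-driven
volume shrinkage are ignored, and uptake is treated as removal of O₂
partial volume at BTPS.  A helper converts STPD uptakes to BTPS
(`× 760/(P_B − P_H₂O) × 310/273`).

## Parameters, units, defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| body mass | 29 | kg | the studied animals (~29 ± 2 kg) |
| EELV | 22.3 | ml/kg | measured end-expiratory volume at 5 cmH₂O PEEP |
| dead space | 3 | ml/kg | the estimate used for alveolar volume |
| V̇O₂ | 5.416 | ml/s BTPS | calibrated so the closed-form end-expiratory decline is 6.9 mmHg/s at 559.7 ml (no direct uptake measurement exists) |
| P_B / P_H₂O | 760 / 47 | mmHg | sea level, body temperature |
| shunt | 0 | – | uninjured lung; constant within breath when set |
| Hb / P̄vO₂ | 10 g/dl / 40 mmHg | – | used only for shunt mixing; venous PO₂ fixed because no cardiac-output model exists |
| transit delay | 2 | s | lung→carotid sensor transport |
| sensor τ | 0.8 | s | first-order smoothing; gain ≈ 0.70 at a 5-s breath period, matching the ~30% by which closed-form alveolar predictions overestimate measured arterial declines |
| compliance / resistance | 45 ml/cmH₂O / 0.012 cmH₂O·s/ml | τ = 0.54 s | chosen so a 10 ml/kg breath at PEEP 5 peaks below the observed 13.6 cmH₂O; no direct mechanics measurements exist |
| PC rise time | 0.1 | s | near-square pressure targets |
| integration step | 0.01 | s | ≥ 50 samples in the shortest phase (Te = 1 s at RR 12, 4:1) |

A note on the sensor time constant: a first-order filter with τ = 2 s at a
5-s period would attenuate the fundamental by ~63%, far more than the
~30% arterial-vs-alveolar discrepancy it is meant to represent; τ = 0.8 s
gives the intended attenuation, so that is the default (the transport
delay does not affect amplitude and stays at 2 s).

## Ventilator waveforms

Volume control delivers `V_T` at constant flow `V_T/Ti`; pressure control
applies `p_insp` above PEEP (ramped over the rise time) and volume follows
exact first-order RC charging, stepped with the exponential propagator for
piecewise-constant pressure.  Expiration is passive and exponential toward
EELV in both modes.  Breaths are chained until the end-expiratory volume
is periodic (flagged if it still drifts by >0.5% of V_T between the last
two breaths).  `pc_pressure_for_vt` inverts the charging curve; given the
expiratory time it solves for the *periodic steady state*, because at
inverse I:E ratios expiration is incomplete and a single-breath inversion
would under-deliver the tidal volume that the protocol matches across
conditions.

## Numerical choices

The O₂ balance is integrated with explicit Euler on exact volume
increments `ΔV_k = V_{k+1} − V_k`, with expired gas leaving at the
start-of-step composition.  That choice makes two discrete identities
exact rather than approximate: (i) per-breath inspired/expired O₂ volumes
telescope consistently with the waveform, so the steady-state O₂ budget
balances to the steady-state residual (<0.01%); (ii) the expiratory step
reduces to `P_{k+1} − P_k = −(P_B − P_H₂O)·V̇O₂·Δt/V_{k+1}`, reproducing
the inverse-volume law to machine precision.  The alveolar fraction is
range-checked each step; leaving (0, 1) raises a model-validity error.
The initial fraction is `0.9·FIO₂` and at least ten breath periods of
transient are discarded before analysis (alveolar washout time constant is
~15–20 s at RR 12, so 60 s of transient is ample; at RR 6 the transient is
ten 10-s periods).

FIO₂ calibration bisects on (0.21, 1.0] until the 2-min steady-state mean
arterial PO₂ is within 1 mmHg of target (the mean responds monotonically,
and nearly linearly, to FIO₂).

## Trace statistics

Breaths are segmented at airway-pressure troughs (end-expiration) when a
pressure channel exists, else at PaO₂ troughs with ≥1 mmHg prominence;
minimum cut spacing is half the expected period.  Oscillation amplitude is
the within-breath max − min, reported as mean and max across the 2-min
window.  The steepest decline is the largest-magnitude negative ordinary
least-squares slope over every sliding 5-s window (OLS rather than a
two-point difference, for noise robustness); any window containing a
sample below 100 mmHg is excluded, because below that the haemoglobin
dissociation curve, not the alveolar store, shapes the decline.  Steady
state means consecutive non-overlapping 60-s means differing by
≤5 mmHg/min.  Bland–Altman limits use 1.96·SD with t-based CIs
(`SD/√n` for the bias, the standard `SD·√(3/n)` approximation for each
limit).  Body-mass normalisation of decline rates is configurable (linear
in mass, or none) since no published formula exists.

## Quantitative CT

Voxels mix gas and tissue linearly on the HU scale: gas fraction
`−HU/1000` over the quantitation range [−1000, +100], tissue density
1.0 g/ml (configurable to 1.04).  Aeration bands follow the standard
convention (overinflated −1000…−901, normal −900…−501, poor −500…−101,
atelectatic −100…+100) and are configurable, since the study's exact
thresholds are not public.  Masked voxels outside the quantitation range
are clamped into the nearest band and counted, never dropped.
Single-slice 2-D inputs are first-class, matching dynamic-CT practice.
Whether reported lung "volume" means gas-only or gas+tissue is ambiguous
in such tables, so both are returned.

## Synthetic data: what it emulates, what it does not

Generators emulate the study's inputs: breath-synchronous arterial traces
(model output plus i.i.d. Gaussian sensor noise, default sd 1 mmHg —
the real sensor's noise figure is unpublished), 18-hold breath-hold
datasets (three volumes × six repeats, sequenced by a doubled de Bruijn
cycle so all nine ordered volume pairs occur — the original sequence
table is not public), and CT phantoms with HU drawn uniformly within each
band at voxel counts chosen to hit prescribed tissue-mass fractions.

The tidal CT series is a stylized construction: at fixed voxel volume,
tissue mass is a bijection of HU, so "aeration changes with mass
conserved" is impossible voxel-by-voxel.  Inflation therefore (a) recruits
poor-band voxels into the normal band by an HU shift exactly compensated
by an opposite shift in partner voxels that stay within the poor band
(conserving total tissue mass and within-lung gas to round-off), and
(b) adds inspired gas as pure-gas (−1000 HU, zero-mass) rim voxels
appended to the mask.  An optional mode oscillates the atelectatic
fraction by a set number of points for contrast experiments.

None of the generators models real-sensor drift or nonlinearity, cardiac
or pulsatile modulation of PaO₂, CT texture, beam hardening, or
reconstruction artefacts.  Passing the recovery tests therefore shows the
*pipeline* is correct under the model's assumptions, not that the model
captures every feature of in-vivo traces — in particular the in-vivo
mean±SD tables across animals cannot be reproduced without the animals'
raw data.

## Problem sizes

Tidal simulations run at 10-ms steps for ten transient breath periods (or
60 s, whichever is longer) plus a 2-min analysis window; CT phantoms
default to 64×64 voxels with a 3-voxel air border.  These sizes keep a
full 16-condition study under a few seconds while leaving >50 integration
steps in the shortest ventilator phase and <0.5% sampling error in
phantom class fractions.

## Known limitations

Single compartment, single gas: no V/Q heterogeneity, no CO₂ or N₂
dynamics, no recruitment, no zone-1 perfusion effects, no
haemoglobin-limited decline below 100 mmHg (traces are truncated at the
physical floor instead).  Mechanics are linear with passive expiration;
no spontaneous effort.  The arterial transform is a fixed
delay-plus-first-order filter — a phenomenological stand-in for
circulatory dispersion, not a transport model.  The constant-shunt mixing
uses a fixed mixed-venous PO₂ rather than a closed O₂ transport loop.
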