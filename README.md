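# tidalox

Within-breath alveolar and arterial oxygen dynamics of the mechanically
ventilated lung, for respiratory physiologists and researchers working on
continuous intra-arterial PO₂ sensing.

Arterial PO₂ is usually treated as constant within a respiratory cycle in
the healthy lung; when fast sensors show it oscillating, the oscillations
are commonly read as a sign of cyclical atelectasis (within-breath shunt
variation) in the injured lung.  `tidalox` implements the alternative,
injury-free explanation: a **single well-mixed alveolar compartment with a
constant oxygen uptake** already produces substantial respiratory PaO₂
oscillations, because oxygen enters the alveoli only during inspiration
while the pulmonary circulation removes it continuously.

## The model

The alveolar O₂ partial volume `F_A·V_A` obeys a mass balance

```
d(F_A·V_A)/dt =  F_insp(t)·V̇(t) − V̇O₂        (inspiration)
d(F_A·V_A)/dt = −F_A·|V̇(t)|     − V̇O₂        (expiration)
```

with `V_A(t) = V_A,EELV + V(t)`, where `V_A,EELV = (EELV − V_D)` is the
end-expiratory alveolar gas volume, the first `V_D` ml of each inspiration
re-enter at end-expiratory alveolar composition (series dead space), and
`P_AO₂ = F_A·(P_B − P_H₂O)`.  During expiration (or an apnoeic hold) the
dilution term cancels and alveolar PO₂ falls at exactly

```
dP_A/dt = −V̇O₂·(P_B − P_H₂O) / V_A
```

— inversely proportional to lung volume, which is what breath-hold
manoeuvres at different inflation levels measure.  V̇O₂ is calibrated so
this closed form reproduces a 6.9 mmHg/s decline at the end-expiratory
volume of a 29 kg pig (EELV 22.3 ml/kg, dead space 3 ml/kg).  The arterial
channel is the alveolar signal after a transport delay, first-order
smoothing, and optional constant-shunt venous admixture in O₂-content
units (Severinghaus dissociation curve).

Around the gas-exchange core the package provides:

- `ventilation` — volume-control and pressure-control waveforms from a
  linear resistance–compliance lung (any RR, I:E ratio, PEEP);
- `trace_statistics` — per-breath oscillation mean/amplitude over 2-min
  steady-state windows, the steepest 5-s decline with exclusion of samples
  below 100 mmHg, steady-state detection, Bland–Altman agreement;
- `ct_aeration` — quantitative-CT lung aeration: linear HU gas/tissue
  mixing, the four standard aeration bands, per-class tissue mass and gas
  volume, cycle-resolved mass fractions;
- `synthetic` — seeded generators for noisy PO₂ traces, breath-hold
  datasets, CT phantoms with prescribed composition, and the full
  experimental design (16 tidal conditions, 18-hold sequence);
- `study` / a `tidalox` CLI — end-to-end simulated protocol runs.

## Worked example

```python
from tidalox import (
    GasExchangeParams, RespiratoryMechanics, VentilatorSettings,
    SampledTrace, alveolar_volume_at_eelv, predict_breath_hold_decline,
    calibrate_fio2, oscillation_stats,
)

params = GasExchangeParams()          # 29 kg pig, EELV 22.3 ml/kg, VD 3 ml/kg
va0 = alveolar_volume_at_eelv(params)
print(f"alveolar volume at EELV: {va0:.1f} ml")
print(f"calibrated VO2: {params.vo2:.3f} ml/s")
for label, dv in [("Ve", 0), ("VT10", 10), ("VT20", 20)]:
    r = predict_breath_hold_decline(params, va0 + dv * params.mass)
    print(f"breath-hold decline at {label}: {r:.2f} mmHg/s")

mech = RespiratoryMechanics()
settings = VentilatorSettings(mode="VC", rr=12, ie_ratio=1.0, vt=290, peep=5)
cal = calibrate_fio2(settings, mech, params, target_mean=130.0)
stats = oscillation_stats(SampledTrace.from_po2trace(cal.trace), rr_hint=12)
print(f"FIO2 for mean PaO2 130 mmHg: {cal.fio2:.3f}")
print(f"arterial oscillation amplitude: {stats.amplitude_mean:.1f} mmHg "
      f"over {stats.n_breaths} breaths (mean {stats.mean_pao2:.1f} mmHg)")
```

prints

```
alveolar volume at EELV: 559.7 ml
calibrated VO2: 5.416 ml/s
breath-hold decline at Ve: 6.90 mmHg/s
breath-hold decline at VT10: 4.55 mmHg/s
breath-hold decline at VT20: 3.39 mmHg/s
FIO2 for mean PaO2 130 mmHg: 0.333
arterial oscillation amplitude: 12.2 mmHg over 22 breaths (mean 130.8 mmHg)
```

The three decline rates are the inverse-volume law evaluated at the three
breath-hold volumes (end-expiration, after a 10 ml/kg and after a 20 ml/kg
inflation): higher lung volume means a larger oxygen store and a slower
fall.  The last two lines simulate the reference ventilation condition
(volume control, RR 12, I:E 1:1, 10 ml/kg, PEEP 5 cmH₂O) with the inspired
fraction calibrated so the 2-min mean arterial PO₂ sits at 130 mmHg; the
arterial signal oscillates breath-synchronously with a ~12 mmHg mean
peak-to-trough amplitude.  Inverse-ratio ventilation (I:E 4:1) raises the
mean and shrinks the amplitude; RR 6 with 20 ml/kg produces alveolar
swings beyond 50 mmHg — run `tidalox study --out-dir out/` for the full
16-condition table.

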