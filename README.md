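# powerstrain

Energy-system-specific training load and adaptation modelling for cycling
power data.

Classic training load metrics collapse every ride into one number: TSS
scores an hour at threshold as 100 regardless of how the watts were
distributed, and a single Banister fitness–fatigue model then assumes all
training drives the same adaptation. `powerstrain` keeps the three energy
systems apart. It converts second-by-second power into three strain
scores — one each for the aerobic (CP), glycolytic (W′) and alactic
(Pmax) systems — and feeds them through three parallel impulse-response
models so that aerobic endurance, anaerobic capacity and sprint power can
each follow their own trajectory.

## The model

An athlete is described by the 3-parameter critical-power model:

- **CP** [W] — critical power, the highest metabolically steady power;
- **W′** [J] — the finite work capacity above CP;
- **Pmax** [W] — maximal fatigue-free instantaneous power.

Power-duration curve and its inverse:

    t_lim(P) = W′/(P − CP) − W′/(Pmax − CP)
    P(t)     = CP + (Pmax − CP)·W′ / (W′ + (Pmax − CP)·t)

Riding above CP spends W′; the *maximum power available* falls with it,

    MPA = Pmax − (Pmax − CP)·(W′exp / W′)            (linear variant)

reaching CP when W′ is gone. Task failure in a constant effort occurs
when P meets MPA. Power is attributed to the three systems by

    P_CP   = min(P, CP)
    P_Pmax = (P − CP)² / (Pmax − CP)        for P > CP
    P_W′   = P − CP − P_Pmax

and each second is weighted by proximity to the current ceiling,

    k_strain = (Pmax − MPA + CP) / (Pmax − P + CP),   SR = k_strain·P
    SS = Σ SR·dt · (Pmax/CP²) · (100/3600)

so a fresh hour at CP scores exactly 100 SS, and the same watts score
more as W′ drains. Splitting SR by the power attribution yields SS_CP,
SS_W′ and SS_Pmax. Daily per-system loads w(t) then drive three
independent fitness–fatigue models

    g(t) = g(t−1)·e^(−1/τ1) + w(t),   h(t) = h(t−1)·e^(−1/τ2) + w(t)
    p(t) = k1·g(t) − k2·h(t)

(with an EWMA/CTL variant available), whose parameters can be fitted to
observed performance per system.

## Worked example

```python
from powerstrain import AthleteProfile, gen_intervals, gen_steady, session_report

athlete = AthleteProfile(cp=300.0, w_prime=20000.0, pmax=1200.0)
for name, ride in {
    "continuous": gen_steady(350, 1200),                 # 20 min @ 350 W
    "intervals": gen_intervals(350, 60, 0, 60, 20),      # 20 x 1 min on/off
}.items():
    rep = session_report(athlete, ride, recovery="skiba_differential")
    print(name, round(rep.strain.ss_total, 1), round(rep.legacy.tss, 1))
```

prints

    continuous 137.4 45.4
    intervals 60.9 53.8

Both rides contain 420 kJ of work. The continuous effort empties W′ and
spends its last 13+ minutes at the task-failure ceiling, so its strain
score (137.4) far exceeds the interval session's (60.9); TSS ranks them
the other way (45.4 vs 53.8) because normalized power rewards the on/off
structure while ignoring how close to failure the rider was. The
`examples/` directory has one narrative script per capability:
power-duration basics, session strain, the three-system performance
management chart, and parameter fitting.

A thin CLI wraps the same functions:

```sh
powerstrain synth --kind steady --power 300 --duration 3600 --out ride.csv
powerstrain analyze --profile athlete.yaml --input ride.csv --out report.json
powerstrain pmc --loads loads.csv --out pmc.csv
```

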