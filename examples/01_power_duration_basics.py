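"""Power-duration basics: exhaustion times, MPA, and the energy-system split.

Builds the worked-example athlete (CP 300 W, W' 20 kJ, Pmax 1200 W) and
asks the 3-parameter critical-power model three questions: how long can a
given power be held, what power is sustainable for a given time, and which
energy system supplies which share of the watts.
"""

from powerstrain import AthleteProfile, mpa, split_power, sustainable_power, time_to_exhaustion

athlete = AthleteProfile(cp=300.0, w_prime=20000.0, pmax=1200.0)

print(f"Athlete: CP={athlete.cp:.0f} W, W'={athlete.w_prime/1000:.0f} kJ, Pmax={athlete.pmax:.0f} W")
print()

for p in (400, 600, 900):
    t = time_to_exhaustion(athlete, p)
    print(f"{p} W is sustainable for {t:6.1f} s")
# and the inverse: best power for a 5-minute effort
print(f"best 5-min power: {sustainable_power(athlete, 300):.0f} W")
print()

# MPA falls from Pmax toward CP as W' is spent
for frac in (0.0, 0.5, 1.0):
    m = mpa(athlete, frac * athlete.w_prime)
    print(f"W' {frac:3.0%} spent -> maximum power available {m:6.1f} W")
print()

# watts attributed to the aerobic (CP), glycolytic (W') and alactic (Pmax) systems
for p in (250, 400, 1000):
    s = split_power(athlete, p)
    print(f"at {p:4d} W: CP {s.p_cp:5.0f} W | W' {s.p_w:5.0f} W | Pmax {s.p_pmax:5.0f} W")
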