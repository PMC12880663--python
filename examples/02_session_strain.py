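"""Strain score vs TSS for two equal-work sessions.

Compares a 20-min continuous 350 W effort with a 20x1-min 350 W interval
session (1-min passive rest) for the same athlete. Both contain exactly
the same mechanical work, but the continuous effort drives the athlete
much closer to task failure: the strain score ranks it harder, while TSS
ranks the interval session higher because normalized power rewards its
on/off structure. The per-system scores show where the strain lands.
"""

from powerstrain import AthleteProfile, gen_intervals, gen_steady, session_report

athlete = AthleteProfile(cp=300.0, w_prime=20000.0, pmax=1200.0)

sessions = {
    "20-min continuous @ 350 W": gen_steady(350, 1200),
    "20 x (1 min @ 350 W / 1 min rest)": gen_intervals(350, 60, 0, 60, 20),
}

for name, series in sessions.items():
    rep = session_report(athlete, series, recovery="skiba_differential")
    s = rep.strain
    print(name)
    print(f"  work {s.work_kj:.0f} kJ over {s.duration_s/60:.0f} min")
    print(f"  strain score {s.ss_total:6.1f}  (CP {s.ss_cp:.1f} | W' {s.ss_w:.1f} | Pmax {s.ss_pmax:.1f})")
    print(f"  NP {rep.legacy.np:.0f} W  IF {rep.legacy.intensity_factor:.2f}  TSS {rep.legacy.tss:.1f}")
    print(f"  peak W' expended {rep.peak_w_exp/1000:.1f} kJ; samples past task failure: {rep.overdraw_samples}")
    print()
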