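# Methods

This note records the model assumptions, the numerical choices, and the
design decisions behind `powerstrain`, in the order the data flows:
power recording → W′/MPA trace → strain scores → daily loads →
fitness–fatigue trajectories → fitted parameters.

## Power-duration core

The athlete model is the 3-parameter critical-power model (CP, W′,
Pmax). Its assumptions, inherited knowingly: aerobic power is available
instantly and at a constant maximal rate CP; each system's contribution
at a given power is constant over time; efficiency and the three
parameters themselves do not drift within a session. No oxygen-kinetics
correction is applied.

**W′ bookkeeping.** Above CP, expended work grows by (P − CP)·dt per
sample; at or below CP it either stays (recovery `none`, the classic
integral model) or recovers along the differential model
dW′bal/dt = (CP − P)·(W′ − W′bal)/W′ (`skiba_differential`), an
exponential approach to full whose rate scales with the gap below CP.
The integrator is forward Euler per sample. At 1 Hz the per-step
recovery factor (CP − P)·dt/W′ is ≪ 1 for realistic parameters, so
Euler error is negligible; `dt` is configurable and a dt = 0.01 s
simulation reproduces the analytic time-to-exhaustion to better than
0.5 % (tested). Power exactly at CP neither depletes nor recovers.

**MPA.** Two variants: `linear` (the default, used for all reference
grids) and `squared`, which raises the depletion fraction to the second
power so that MPA stays high until W′ is nearly spent — a better match
to intermittent efforts, offered as an opt-in flag. Both pin
MPA(0) = Pmax and MPA(W′) = CP.

**Overdraw.** Real recordings contain spikes above the current MPA, and
a constant effort can be traced past its failure point. A per-sample
overdraw flag is raised whenever demanded power exceeds the MPA
*entering* the sample; W′exp clamps at W′; downstream strain uses
k_strain = 1, its value at P = MPA. Recorded power above Pmax is
clamped to Pmax for the contribution split (it is already at k = 1).
The public `split_power` stays strict and rejects P > Pmax.

**Sessions are independent.** Every trace starts fresh (W′exp = 0);
recovery applies within a session only. Carrying residual W′ depletion
across sessions would need a model of between-session recovery the
package does not claim.

## Strain metrics

Each sample is scored with the MPA entering that sample, so a 1-s
fresh sprint at Pmax is scored against MPA = Pmax. The normalisation
Pmax/CP² · 100/3600 makes a fresh hour at CP worth exactly 100 for
*every* profile (property-tested), because at P = CP, MPA = Pmax the
strain rate is CP²/Pmax identically. The sum in the score is an
integral, SR·dt per sample, which coincides with a per-second sum at
1 Hz. Per-system scores apply the sample's k_strain to each system's
watts, so they add up to the total by construction.

Reference-grid validation holds MPA fixed per cell: the published grid
tabulates instantaneous rates (per second and scaled to an hour) at
given MPA levels, not full-session traces. Full-session scores use the
evolving MPA trace. One prose example elsewhere quotes k_strain ≈ 0.27
for a fresh athlete at CP; that athlete's parameters are not printed,
and the CP = 300 W / Pmax = 1200 W grid value 0.25 is treated as the
authoritative anchor.

**Legacy comparators.** Normalized power uses a simple (unweighted)
trailing 30-s moving average over full windows, then the fourth-power
mean — the standard dialect of the algorithm, adopted because only the
name of the weighting is public. TSS = t·NP·IF/FTP·100/3600 with
IF = NP/FTP; FTP defaults to CP when a profile omits it. Sessions
shorter than the rolling window report zero legacy metrics rather than
an extrapolated NP.

## Fitness–fatigue models

Fitness g and fatigue h are first-order filters of the daily load, with
the stimulus interval fixed at one day; multiple sessions on a day are
summed first and missing days are zero-load days. Two recursions are
implemented as named variants: `impulse` adds w(t) raw; `ewma` scales
it by (1 − e^(−1/τ)), the chronic-training-load convention whose fixed
point under constant load is the load itself. Reference block-then-rest
simulations here use the impulse variant. Initial conditions default to
g0 = h0 = 0. Default constants, absent an individual fit, are the
platform-conventional τ1 = 42 d, τ2 = 7 d with k1 = 1, k2 = 1.5.

The three-system model runs three such filters independently — no
cross-system coupling, by design — on the per-system strain scores, and
maps each performance trace to physical units through an affine scaling
(gain × p + offset; W for CP and Pmax, kJ for W′). The scaling's form
is deliberately user-configurable with an identity default, since no
canonical conversion exists; calibrating gain/offset against measured
CP tests is the user's responsibility.

**Fitting.** Parameters (k1, k2, τ1, τ2) are estimated by least squares
against sparse observed performance: a grid at 1-day resolution over
(τ1, τ2) ∈ [1, 100]² with the optimal non-negative (k1, k2) solved at
each node (NNLS on [g, −h]), then Nelder–Mead refinement of the time
constants with the grid optimum as fallback. The procedure is
seedless and deterministic. Non-negativity of k also removes the
(k1, τ1) ↔ (−k2, τ2) relabelling ambiguity. At least four observations
are required; constant observations under constant load are flagged
unidentifiable rather than fitted. Weight bounds extend to 10⁴ to admit
the order-of-magnitude spread real per-system fits can produce.

## Synthetic data

The generators emulate the *structure* the model consumes, not
physiology: constant efforts, on/off intervals, optional truncated-
Gaussian jitter (floor 0 W), and daily load histories. The `variable`
schedule — used to show that blocked loading out-peaks constant loading
at equal total — is 14-day blocks of 11 build days (seeded ±20 %
uniform jitter) and 3 recovery days at 25 % of build, aligned so the
program ends on a recovery phase, then rescaled so the total equals the
constant schedule's exactly. The `periodized` schedule drifts the
per-system split from 95 % aerobic at the start to 65 % at the end with
the remainder split 9:1 between W′ and Pmax. A total daily load is
otherwise split 80/18/2 across CP/W′/Pmax, the daily ratio used in the
reference three-system simulation. All generators are bit-reproducible
under a fixed seed.

Because the synthetic data share the model's own structure, passing
recovery tests demonstrate internal consistency (the fitter can invert
the simulator; the strain pipeline reproduces its anchors), not
real-data validity: real rides have autocorrelated power, pauses,
sensor dropouts and day-to-day parameter drift that these fixtures do
not emulate.

## Problem sizes and tolerances

Exhaustion-oracle checks simulate 50 random athletes × 5 powers at
dt = 0.01 s with target powers drawn from 30–90 % of the CP–Pmax span
(keeping individual simulations in the seconds-to-minutes range);
closed-form recursion checks use 100 random parameter draws at 1e−9
relative tolerance; parameter recovery uses a 100-day loading / 100-day
detraining protocol observed every 10 days, noise-free (exact recovery
expected) and at 5 % of the performance range over 20 seeded
replicates (mean recovered τ1 within ±20 %). Conservation and
normalisation identities are asserted at 1e−9 relative; published grid
cells at their printed precision.

## Known limitations

- The contribution split is a crude energetic attribution, not an ATP
  flux measurement; it inherits every assumption listed above.
- Strain of supra-MPA samples saturates at k = 1; genuinely impossible
  data (long stretches above MPA) are flagged, not rejected.
- The a.u.→physical scaling of the three-system model is uncalibrated
  by default; absolute CP/W′/Pmax projections require user-supplied
  gain and offset.
- Only uniformly sampled CSV power recordings are read (FIT/TCX files
  must be converted externally); gaps are zero-filled with a warning,
  which under-counts strain if the gap was actually a recording dropout
  mid-effort.
- HR-based TRIMP comparators are out of scope.
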