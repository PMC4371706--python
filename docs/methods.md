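# Methods

`neurofp` simulates networks of discrete-time binary units that communicate
by exchanging short serial bit patterns ("neural fingerprints") and that
decide their output by *recognizing* such patterns in the recent history of
each input channel. This note records the model as implemented, the
parameters that matter, the reconstruction and calibration choices that were
genuinely open, and the known limitations.

## The unit model

Each unit has 8 recurrent input channels (one per presynaptic unit) plus one
external channel, and keeps one **local informational context** per channel:
a shift register holding the last `n` bits received on that channel, where
`n` is the fingerprint length of the simulation (4–11 bits; 5 by default,
a single `n` per simulation). Signals are binary: 1 is a spike, 0 silence.
Synapses are pure transmission lines; a unit reads, at step `t`, the bits
its presynaptic units emitted at step `t − 1`, plus the external bit of
step `t`.

Per step, a *listening* unit (see lifecycle below):

1. shifts every register by one incoming bit;
2. checks for a **recognition**: the external channel first (external input
   has priority), then the recurrent channels in a freshly randomized
   order; the first channel whose register equals one of the unit's known
   fingerprints is this step's single recognition event. Because register
   length equals fingerprint length, "contains" reduces to equality.
3. rolls Bernoulli(`p_r`) on that event: success commits the unit to
   re-emitting the recognized fingerprint; failure means the unit continues
   as if nothing had been recognized;
4. if free and without a successful recognition, rolls Bernoulli(`p_e`)
   to emit its predefined **spontaneous pattern** (all-ones by default),
   otherwise stays silent this step.

`p_r` is the unit's permeability to stimuli, `p_e` its level of background
activity; the explored regimes satisfy `p_e ≪ p_r`.

## Lifecycle and activity accounting

A commit at step `t` produces output 0 at `t`, the pattern's `n` bits at
`t+1 … t+n`, and a refractory pause; the next decision opportunity is at
`t + n + R + 2` with `R = 10`. The unit is **counted active** on its
committed pattern for `n + 1` steps (`t+1 … t+n+1`). This accounting is
calibrated so that an isolated unit's stationary active fraction is

    f(p_e) = (n + 1) / (n + R + 1 + 1/p_e),

which reproduces the published autonomous levels for all six `p_e` values
to better than 0.1 neurons in 2500 (the naive reading — `n` active steps
and a decision at `t + n + R + 1`, level `n/(n+R+1/p_e)` — contradicts all
of them and remains available via `accounting="naive"`). Autonomous
networks perform no recognitions, so this closed form holds per unit
regardless of topology, and serves as the engine's analytic oracle.

Two further lifecycle rules were reconstructed by fitting the published
stimulated-network statistics, because the verbal rules underdetermine
them:

* **Gated listening.** Registers are updated only while the unit is
  listening; bits arriving while it is emitting or refractory are
  discarded, and the registers are cleared when the unit returns to the
  free state. A fingerprint must therefore be received *in full* while the
  unit listens before it can trigger. The alternative (registers always
  shifting) roughly doubles every stimulus-following level and raises the
  detection thresholds far above the published ones; gating reproduces the
  regular-lattice threshold column exactly (±0.01 on the 0.01 grid) and
  the slow regular-lattice propagation velocity.
* **Interruptible spontaneous emissions.** A unit emitting its spontaneous
  pattern keeps listening during the first `n − 2` emission steps; a
  recognition in that window aborts the background babble and commits the
  fingerprint, provided it passes an additional override roll. The total
  interruption probability is `p_r^1.5` (recognition roll `p_r` × override
  roll `√p_r`). Without interruption, background commits continually break
  the relay chains and detection dies at `p_e ≈ 0.10` even at `p_r = 0.8`,
  where the published thresholds are 0.15–0.21; with unconditional
  interruption the network saturates at its minimal relay period and
  overshoots every published level. The window length and the exponent 1.5
  (between the single-roll and double-roll readings of the recognition
  rule) are the two calibrated constants of the reconstruction.
  Recognized-fingerprint emissions are never interruptible.

## Network substrate

A 50×50 grid (2500 units) with periodic boundaries; each unit receives
input from its 8 Moore neighbours. Watts–Strogatz-style disorder: each
in-edge is independently rewired with probability `p` to a uniformly chosen
source (no self-edges, no duplicates). Rewiring redraws the *source* of an
in-edge, preserving in-degree 8 — required because the unit model owns
exactly 8 recurrent channels — so out-degree becomes variable. Presets:
Regular (`p=0`), SW(10), SW(25), Random (`p=1`).

## Stimulation protocols

An external stimulus is a pattern delivered on the external channel of its
target units, repeated back-to-back with no gaps for the whole episode.
Canonical designs: **single** (one pattern, one uniformly chosen unit, free
evolution to step 5000 then 10,000 stimulation steps), **series** (two
patterns alternating in 10,000-step episodes separated by 5000 silent
steps, eight episodes ending at step 120,000, delivered to one 2×5
cluster), and **parallel** (several distinct patterns delivered
simultaneously to disjoint 2×5 clusters; 20,000-step episode by default).
Unless overridden, the recognizable fingerprint set of a run is exactly its
set of stimulus patterns.

## Trace analyses

* **Steady level**: time-mean count of units active on a label over the
  second half of a phase; dispersion is the across-seed standard error.
* **Detection**: a stimulus propagates when its steady level exceeds
  θ_detect = 50 units (2% of the network) — far above the non-propagating
  baseline, far below the smallest propagating level (~200).
* **Velocity**: steady level ÷ rise time, where the rise time is the first
  step at which the centred 100-step moving average reaches 75% of the
  steady level. The fraction and smoothing width are calibration knobs set
  so the regular-lattice velocity lands on the published scale; even so,
  rewired networks come out a factor ~2 slower than published (the
  collective level needs several emission cycles to build up, whereas the
  published rise times are close to the bare front-propagation latency).
* **Memory**: long-term iff the mean over the final 5000 steps of a run
  extending ≥ 20,000 steps past stimulation exceeds θ_detect; short-term
  iff the count reaches zero (or ends essentially dead, below θ_detect/2);
  anything still visibly decaying is flagged undetermined.
* **Competition**: NC when two stimuli never exceed θ_detect concurrently;
  WLC when ≥ 2 stimuli stay concurrently above θ_detect for ≥ 2·n·100
  steps without the contested pattern going extinct; WTA otherwise.
* **Survival**: steps from a new episode's onset until the previously
  encoded pattern's count first reaches zero; absent-at-onset episodes are
  skipped and never-disappearing ones censored.
* **Coexistence**: mean number of stimuli with ≥ θ_coexist = 18 actively
  emitting units per step, θ calibrated on the regular-lattice nine-stimulus
  design (~7.8 of 9 encoded).

## Reproducibility and numerics

State lives in flat per-unit arrays with registers bit-packed into
integers; a 2500-unit, 100k-step run takes a few seconds. The default
backend is a numba-compiled scalar loop consuming random draws in a fixed
documented order (step, then unit index; within a unit: recognition roll,
override roll, channel pick, spontaneous roll); a vectorized numpy loop is
the fallback. Each backend is bitwise reproducible for a fixed seed; the
two are cross-validated statistically and agree exactly on deterministic
configurations, and both are validated against the literal per-unit
reference implementation (`neurofp.neuron`). The winning channel of the
randomized scan is drawn as a uniform pick over the matching channels,
which is distributionally identical to materializing the permutation.
Updates are fully synchronous from a standard initial state (all units
free, all registers zero). Stationary statistics discard a 2000-step
burn-in.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run the full 2500-unit networks
at the published protocol lengths, with 5 replicate seeds for level and
survival estimates, 2–3 seeds per grid point for threshold and phase
scans, and bisection over the 0.01 `p_e` grid (propagation is monotone in
`p_e`, so bisection finds the same boundary as an ascending scan at a
fraction of the cost).

## Known limitations

* The gating/interruption lifecycle is a reconstruction. It reproduces the
  autonomous levels exactly, the detection-threshold table's regular
  column exactly and its monotone structure everywhere, and most
  stimulus-following levels to a few percent — but rewired topologies
  propagate slightly too well (thresholds high by 0.02–0.06, following
  levels by up to ~15–20% in the worst cell at `p_r = 0.5`), and the
  regular `p_r = 0.5` following level sits ~13% low.
* Short-term memory in this implementation is narrower than published:
  near the detection boundary, evoked activity either fails to ignite or
  persists indefinitely, so the finite-lifetime reverberation regime
  (detected during stimulation, decaying within thousands of steps after
  it) is largely absent, and several published short-term design points
  classify long-term here.
* In the in-series design, the first displacement of an encoded pattern by
  a newly driven one occurs on the published time scale for random
  topologies, but an established pattern can subsequently resist
  re-invasion, leaving censored survival episodes; regular-lattice
  survival times are correspondingly short of the published mean.
* The decline of parallel-stimulus coexistence with network randomness is
  weaker than published: the regular lattice is calibrated (~7.8 of 9),
  random networks retain ~6 rather than ~4.3.
* Synchronous updating phase-locks relay chains more strongly than the
  published statistics suggest; this is the likely common cause of the
  residuals above.
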