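"""Quantitative analyses of simulation traces.

Steady activity levels, stimulus-detection and propagation-velocity
estimates, short-/long-term memory classification, competition regimes
(winner-take-all vs winnerless), survival times of displaced stimuli,
coexistence counts for parallel stimulation, and the analytic stationary
level of an isolated unit.

Operational thresholds
----------------------
``THETA_DETECT``
    A stimulus counts as propagating network-wide when its steady
    following level exceeds 50 neurons (2% of the standard 2500-unit
    network) — far above the near-zero non-propagating baseline and far
    below the smallest propagating steady level (~200-300 neurons).
``THETA_COEXIST``
    A stimulus counts as *encoded* at a time step when at least 18 neurons
    are actively emitting it; calibrated so that a regular long-term
    network driven by nine parallel 9-bit stimuli encodes ~7.8 of them per
    step.
``RISE_FRACTION`` / ``RISE_SMOOTH``
    The rise time underlying the propagation velocity is the first step at
    which the centred 100-step moving average of the stimulus count reaches
    75% of its steady level; both constants are calibration knobs set so
    the regular-lattice velocity lands on the published scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np

from .engine import SimulationTrace

THETA_DETECT = 50
THETA_COEXIST = 18
RISE_FRACTION = 0.75
RISE_SMOOTH = 100
#: relative tolerance for calling the total activity "constant"
CONSTANT_TOTAL_TOL = 0.05
#: final window, in steps, over which persistence is judged
MEMORY_FINAL_WINDOW = 5000

DETECTED = "detected"
NOT_DETECTED = "not-detected"
SHORT_TERM = "short-term"
LONG_TERM = "long-term"
UNDETERMINED = "undetermined"
NC, WTA, WLC = "NC", "WTA", "WLC"


@dataclass(frozen=True)
class SteadyEstimate:
    """Time-mean activity of one label over a stationary window."""

    mean: float                 # neurons per step
    se: Optional[float]         # across-run standard error (None: single run)
    window: Tuple[int, int]
    temporal_sd: float          # within-run SD over the window

    def __str__(self):  # pragma: no cover - cosmetic
        pm = f" ± {self.se:.2f}" if self.se is not None else ""
        return f"{self.mean:.2f}{pm} (window {self.window})"


def _traces(trace_or_traces) -> list:
    if isinstance(trace_or_traces, SimulationTrace):
        return [trace_or_traces]
    return list(trace_or_traces)


def steady_level(trace_or_traces, label: str,
                 window: Tuple[int, int]) -> SteadyEstimate:
    """Mean count of neurons active on ``label`` over ``window``.

    With several traces (replicate seeds) the across-run standard error of
    the per-run means is reported as the dispersion.
    """
    a, b = window
    if a >= b:
        raise ValueError("empty steady window")
    traces = _traces(trace_or_traces)
    means = [tr.series(label)[a:b].mean() for tr in traces]
    sds = [tr.series(label)[a:b].std() for tr in traces]
    se = (np.std(means, ddof=1) / np.sqrt(len(means))
          if len(means) > 1 else None)
    return SteadyEstimate(float(np.mean(means)), se, (a, b),
                          float(np.mean(sds)))


def detect_propagation(trace_or_traces, label: str,
                       stim_window: Tuple[int, int],
                       theta: float = THETA_DETECT) -> str:
    """Did the stimulus spread network-wide?

    Detected iff the steady following level over the second half of the
    stimulation window exceeds ``theta``.
    """
    a, b = stim_window
    est = steady_level(trace_or_traces, label, ((a + b) // 2, b))
    return DETECTED if est.mean > theta else NOT_DETECTED


def propagation_velocity(trace: SimulationTrace, label: str,
                         stim_window: Tuple[int, int],
                         theta: float = THETA_DETECT) -> float:
    """Steady following level divided by the rise time (neurons/step).

    The rise time is measured from stimulation onset to the first step at
    which the centred ``RISE_SMOOTH``-step moving average of the stimulus
    count reaches ``RISE_FRACTION`` of the steady level.
    """
    a, b = stim_window
    if detect_propagation(trace, label, stim_window, theta) != DETECTED:
        raise ValueError("velocity undefined: stimulus not detected")
    steady = steady_level(trace, label, ((a + b) // 2, b)).mean
    sig = trace.series(label)[a:b].astype(float)
    kernel = np.ones(RISE_SMOOTH) / RISE_SMOOTH
    smooth = np.convolve(sig, kernel, mode="same")
    hits = np.flatnonzero(smooth >= RISE_FRACTION * steady)
    if not hits.size:
        raise ValueError("steady level never reached within stimulation")
    t_rise = int(hits[0]) + 1
    return steady / t_rise


def classify_memory(trace: SimulationTrace, label: str, stim_end: int,
                    theta: float = THETA_DETECT) -> str:
    """Transient (short-term) vs persistent (long-term) stimulus memory.

    Long-term iff the stimulus count's mean over the final
    ``MEMORY_FINAL_WINDOW`` steps exceeds ``theta``; short-term iff the
    count reaches 0 after stimulation or its final mean has fallen below
    ``theta``; a trace still visibly decaying at the end is flagged
    undetermined (the caller should extend the run).
    """
    sig = trace.series(label)
    if trace.total_steps < stim_end + MEMORY_FINAL_WINDOW:
        raise ValueError("trace too short beyond stimulation end")
    final = sig[-MEMORY_FINAL_WINDOW:].mean()
    if final > theta:
        return LONG_TERM
    post = sig[stim_end:]
    if (post == 0).any():
        return SHORT_TERM
    # never extinct and below threshold on average: dead if the trace ends
    # near zero, otherwise the decay has not resolved yet
    if sig[-500:].mean() <= theta / 2:
        return SHORT_TERM
    return UNDETERMINED


def _episode_starts(protocol) -> list:
    return [(e.t_start, e.pattern.label or e.pattern.to_string())
            for e in protocol.episodes]


def survival_time(trace: SimulationTrace, old_label: str,
                  episode_start: int) -> Optional[int]:
    """Steps from a new episode's onset until the previously encoded
    pattern completely disappears; None if it never does (censored)."""
    sig = trace.series(old_label)[episode_start:]
    if sig.size == 0:
        raise ValueError("episode start beyond trace end")
    if sig[0] == 0:
        return 0
    zeros = np.flatnonzero(sig == 0)
    return int(zeros[0]) if zeros.size else None


def classify_competition(trace: SimulationTrace, labels: Sequence[str],
                         protocol=None, theta: float = THETA_DETECT,
                         wlc_window: Optional[int] = None) -> str:
    """Competition regime between >= 2 stimuli: NC, WTA or WLC.

    * NC — at no step do two stimuli exceed ``theta`` concurrently
      (nothing to compete, or only one stimulus ever propagates).
    * WLC — at least two stimuli are concurrently above ``theta`` for a
      sustained total duration (``wlc_window``, default ``2 n 100`` steps)
      without the contested pattern going extinct.
    * WTA — competition occurs but each contested window resolves by the
      extinction of the displaced pattern.
    """
    if len(labels) < 2:
        return NC
    n = trace.meta.get("fingerprint_length", 5)
    if wlc_window is None:
        wlc_window = 2 * n * 100
    sig = np.stack([trace.series(l) for l in labels], axis=1)
    above = sig > theta
    concurrent = above.sum(axis=1) >= 2
    if not concurrent.any():
        return NC
    if protocol is not None and protocol.design == "series":
        wlc = contested = False
        eps = protocol.episodes
        for k in range(1, len(eps)):
            start = eps[k].t_start
            end = eps[k + 1].t_start if k + 1 < len(eps) else trace.total_steps
            old = eps[k - 1].pattern.label or eps[k - 1].pattern.to_string()
            if trace.series(old)[start] == 0:
                continue
            contested = True
            surv = survival_time(trace, old, start)
            sustained = concurrent[start:end].sum()
            if (surv is None or surv > end - start) and sustained >= wlc_window:
                wlc = True
        if not contested:
            return NC
        return WLC if wlc else WTA
    # parallel / generic: sustained concurrency = winnerless
    if concurrent.sum() >= wlc_window:
        return WLC
    # resolved: exactly one survivor above theta at the end
    final_above = above[-500:].any(axis=0)
    extinct = (sig == 0).any(axis=0)
    if final_above.sum() <= 1 and extinct.sum() >= len(labels) - 1:
        return WTA
    return WTA


def coexistence_count(trace_or_traces, labels: Sequence[str],
                      window: Tuple[int, int],
                      theta: float = THETA_COEXIST) -> float:
    """Mean number of stimuli encoded per step over ``window`` (a stimulus
    counts when at least ``theta`` neurons are actively emitting it)."""
    a, b = window
    vals = []
    for tr in _traces(trace_or_traces):
        sig = np.stack([tr.series(l) for l in labels], axis=1)[a:b]
        vals.append((sig >= theta).sum(axis=1).mean())
    return float(np.mean(vals))


def total_activity_mode(trace: SimulationTrace,
                        pre_window: Tuple[int, int],
                        stim_window: Tuple[int, int],
                        tol: float = CONSTANT_TOTAL_TOL) -> str:
    """Compare total active counts before vs during stimulation.

    "constant" when the phase means agree within relative tolerance
    ``tol``, "increased" otherwise.
    """
    tot = trace.total_active()
    pre = tot[pre_window[0]:pre_window[1]].mean()
    a, b = stim_window
    dur = tot[(a + b) // 2:b].mean()
    if pre == 0:
        return "constant" if dur == 0 else "increased"
    return "constant" if (dur - pre) / pre < tol else "increased"


def closed_form_spontaneous(n: int, p_e: float, R: int = 10) -> float:
    """Stationary fraction of steps an isolated unit spends active on its
    spontaneous pattern: (n+1) / (n + R + 1 + 1/p_e).

    The renewal cycle is 1/p_e free steps (geometric wait including the
    commit step), n emission steps, one active tail step and R refractory
    steps, of which n+1 count as active.
    """
    if p_e <= 0:
        raise ValueError("closed form requires p_e > 0")
    return (n + 1) / (n + R + 1 + 1.0 / p_e)
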