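"""Single-unit model: gated local contexts, recognition, emission.

Each neuron receives binary streams on 9 channels (1 external + 8 recurrent)
and keeps one *local informational context* per channel — a shift register
holding the last ``n`` bits received on that channel, where ``n`` is the
fingerprint length of the simulation.  The processing rules:

* While the unit is *listening* it shifts every register by one incoming bit
  per step and checks whether some register equals one of its known
  fingerprints.  The external channel is checked first (external stimuli
  have priority); the recurrent channels are scanned in a freshly randomized
  order.  The first match found constitutes this step's recognition event: a
  single Bernoulli(``p_r``) roll decides whether the unit starts re-emitting
  that fingerprint.  On failure the unit continues as if no recognition had
  happened.
* A free unit with no successful recognition emits its predefined
  *spontaneous* pattern with probability ``p_e``, else stays silent.
* A commit at step ``t`` writes the pattern bits on steps ``t+1 .. t+n``,
  followed by a refractory period (``R = 10`` by default).  A committed
  fingerprint emission cannot be overridden.  A *spontaneous* emission,
  however, remains open to recognition during its first ``n - 2`` emission
  steps: a recognition that additionally passes an override roll
  (Bernoulli(``sqrt(p_r)``)) aborts the background babble and the unit
  starts the recognized fingerprint instead.
* Outside the listening states (fingerprint emission, the tail of a
  spontaneous emission, any refractory) incoming bits are not processed;
  the registers are cleared when the unit next returns to the free state,
  so a fingerprint must again be received in full before it can trigger.

Activity accounting
-------------------
A unit counts as *active* on its committed pattern for ``n + 1`` consecutive
steps per emission event, and the next decision opportunity comes ``R + 1``
steps after the last emitted bit, i.e. ``n + R + 2`` steps after the commit.
This calibrated accounting reproduces the analytic stationary level
``(n+1)/(n+R+1+1/p_e)`` of an isolated unit; the naive alternative (``n``
active steps, next decision ``n + R + 1`` steps after commit, level
``n/(n+R+1/p_e)``) remains available via ``accounting="naive"`` for
sensitivity analysis.

This module is the *reference* implementation: a literal, per-neuron
transcription of the rules, used for hand-checked fixtures and as the oracle
the compiled engine is validated against.  Production simulations run
through :mod:`neurofp.engine`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .patterns import BinaryPattern, common_length

#: default refractory length, in time steps
DEFAULT_REFRACTORY = 10

#: number of recurrent input channels per neuron
N_RECURRENT = 8


class Mode(Enum):
    FREE = "free"
    COMMITTED = "committed"      # commit step: output 0, emission starts next step
    EMITTING = "emitting"
    REFRACTORY = "refractory"


@dataclass(frozen=True)
class NeuronParams:
    """Intraunit parameters shared by all neurons of a simulation.

    ``p_e`` controls the level of spontaneous activity, ``p_r`` the
    permeability of the neuron to (recognized) stimuli; the explored regimes
    satisfy ``p_e << p_r``.
    """

    p_e: float
    p_r: float
    spontaneous: BinaryPattern
    known_fingerprints: tuple = ()
    refractory: int = DEFAULT_REFRACTORY
    spontaneous_is_fingerprint: bool = False
    #: emission steps of a spontaneous pattern that stay open to recognition;
    #: None selects the default n - 2
    interrupt_window: Optional[int] = None
    accounting: str = "calibrated"   # or "naive", see module docstring

    def __post_init__(self):
        if not 0.0 <= self.p_e <= 1.0:
            raise ValueError(f"p_e must be in [0,1], got {self.p_e}")
        if not 0.0 <= self.p_r <= 1.0:
            raise ValueError(f"p_r must be in [0,1], got {self.p_r}")
        if self.refractory < 0:
            raise ValueError("refractory period must be >= 0")
        if self.accounting not in ("calibrated", "naive"):
            raise ValueError(f"unknown accounting {self.accounting!r}")
        fps = tuple(self.known_fingerprints)
        object.__setattr__(self, "known_fingerprints", fps)
        common_length([self.spontaneous, *fps])
        if not self.spontaneous_is_fingerprint:
            if any(f.bits == self.spontaneous.bits for f in fps):
                raise ValueError(
                    "spontaneous pattern is in the fingerprint set but "
                    "spontaneous_is_fingerprint is False")
        if self.interrupt_window is not None and self.interrupt_window < 0:
            raise ValueError("interrupt_window must be >= 0")

    @property
    def n(self) -> int:
        return self.spontaneous.n

    @property
    def window(self) -> int:
        """Resolved length of the interruptible spontaneous-emission window."""
        if self.interrupt_window is None:
            return max(0, self.n - 2)
        return self.interrupt_window

    @property
    def p_override(self) -> float:
        """Probability that a successful recognition also overrides an
        ongoing spontaneous emission (sqrt(p_r): the combined interruption
        probability is p_r**1.5, between the single-roll and double-roll
        readings of the recognition rule; calibrated against the published
        steady levels and detection thresholds)."""
        return self.p_r ** 0.5

    @property
    def recognizable(self) -> tuple:
        """Patterns whose recognition can trigger emission."""
        if self.spontaneous_is_fingerprint:
            return (self.spontaneous,) + self.known_fingerprints
        return self.known_fingerprints

    # lifecycle geometry -------------------------------------------------
    @property
    def active_window(self) -> int:
        """Steps per emission event during which the unit counts as active."""
        return self.n + 1 if self.accounting == "calibrated" else self.n

    @property
    def cycle_after_commit(self) -> int:
        """Non-decision steps after a commit; the unit is free again on the
        step after these have elapsed."""
        base = self.n + self.refractory
        return base + 1 if self.accounting == "calibrated" else base


@dataclass
class ChannelContext:
    """Shift register holding the last ``n`` bits received on one channel."""

    register: tuple

    @classmethod
    def zeros(cls, n: int) -> "ChannelContext":
        return cls((0,) * n)


def shift_context(ctx: ChannelContext, bit: int) -> ChannelContext:
    """Drop the oldest bit, append ``bit`` as the newest; length unchanged."""
    if bit not in (0, 1):
        raise ValueError(f"channel received non-binary input {bit!r}")
    return ChannelContext(ctx.register[1:] + (bit,))


def match_fingerprint(ctx: ChannelContext,
                      known: Sequence[BinaryPattern]) -> Optional[BinaryPattern]:
    """Return the known pattern equal to the register, or None.

    Because the register length equals the fingerprint length, "the context
    contains a fingerprint" reduces to exact equality.
    """
    for pat in known:
        if ctx.register == pat.bits:
            return pat
    return None


@dataclass
class NeuronState:
    """Full per-neuron state: one context per channel plus the emission
    state machine, tracked as steps-since-commit (None while free)."""

    contexts: list                      # [external, recurrent 0..C-1]
    committed: Optional[BinaryPattern] = None
    since_commit: Optional[int] = None  # None <=> FREE

    @classmethod
    def initial(cls, n: int, n_channels: int = N_RECURRENT + 1) -> "NeuronState":
        return cls([ChannelContext.zeros(n) for _ in range(n_channels)])

    def mode(self, params: NeuronParams) -> Mode:
        s = self.since_commit
        if s is None:
            return Mode.FREE
        if s == 0:
            return Mode.COMMITTED
        if s <= params.n:
            return Mode.EMITTING
        return Mode.REFRACTORY

    def is_free(self) -> bool:
        return self.since_commit is None

    def is_listening(self, params: NeuronParams) -> bool:
        """Free, or within the interruptible window of a spontaneous
        emission."""
        s = self.since_commit
        if s is None:
            return True
        return (self.committed is not None
                and self.committed.bits == params.spontaneous.bits
                and 1 <= s <= params.window)


@dataclass(frozen=True)
class Decision:
    commit: Optional[BinaryPattern]
    source_channel: Optional[int]   # 0 = external, 1..C recurrent, None = p_e


def decide(state: NeuronState, params: NeuronParams,
           rng: np.random.Generator) -> Decision:
    """Recognition/emission decision of a listening neuron for one step.

    The external channel (index 0) is checked first; the recurrent channels
    follow in a freshly randomized order.  The first matching channel is
    this step's single recognition event: one Bernoulli(p_r) roll commits
    its fingerprint or leaves the neuron processing as if nothing had been
    recognized.  A neuron interrupting its own spontaneous emission must
    additionally pass an override roll (Bernoulli(sqrt(p_r))).  A *free*
    neuron without a successful recognition then commits the spontaneous
    pattern with probability p_e.
    """
    if not state.is_listening(params):
        raise RuntimeError("decide() called on a non-listening neuron")
    known = params.recognizable
    order = [0] + list(1 + rng.permutation(len(state.contexts) - 1))
    for ch in order:
        pat = match_fingerprint(state.contexts[ch], known)
        if pat is not None:
            if rng.random() < params.p_r and (
                    state.is_free() or rng.random() < params.p_override):
                return Decision(pat, ch)
            break       # single recognition event per step
    if state.is_free() and rng.random() < params.p_e:
        return Decision(params.spontaneous, None)
    return Decision(None, None)


def advance_neuron(state: NeuronState, decision: Optional[Decision],
                   params: NeuronParams):
    """Apply one step of the emission/refractory lifecycle in place.

    Returns ``(output_bit, active_label)`` for the current step.  On the
    commit step the output is 0; the committed pattern's bits appear on the
    following ``n`` steps, and the unit reports itself active on that pattern
    for ``params.active_window`` steps starting the step after the commit.
    """
    if decision is not None and decision.commit is not None:
        state.committed = decision.commit
        state.since_commit = 0
    s = state.since_commit
    if s is None or s == 0:
        return 0, None
    out = state.committed.bits[s - 1] if s <= params.n else 0
    label = state.committed.label if s <= params.active_window else None
    return out, label


class ReferenceNeuron:
    """Literal step-by-step simulator for a single unit; the oracle against
    which the compiled engine is tested."""

    def __init__(self, params: NeuronParams, rng: np.random.Generator,
                 n_channels: int = N_RECURRENT + 1):
        self.params = params
        self.rng = rng
        self.state = NeuronState.initial(params.n, n_channels)

    def step(self, inputs: Sequence[int]):
        """Advance one time step given this step's input bit per channel
        (inputs[0] is the external channel).  Returns (output, active_label).
        """
        st, p = self.state, self.params
        if len(inputs) != len(st.contexts):
            raise ValueError("one input bit per channel required")
        # lifecycle advance; contexts are cleared on the return to free
        if st.since_commit is not None:
            st.since_commit += 1
            if st.since_commit > p.cycle_after_commit:
                st.since_commit = None
                n = p.n
                st.contexts = [ChannelContext.zeros(n) for _ in st.contexts]
        decision = None
        if st.is_listening(p):
            st.contexts = [shift_context(c, b)
                           for c, b in zip(st.contexts, inputs)]
            decision = decide(st, p, self.rng)
        return advance_neuron(st, decision, p)
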