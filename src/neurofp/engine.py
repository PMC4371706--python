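"""Synchronous time-stepping engine.

Each global step proceeds identically for every neuron, using only the
previous step's outputs (no within-step ordering effects between units):

1. every *listening* neuron shifts its 9 local contexts with the bits its
   presynaptic neurons emitted on the previous step plus this step's
   external bit (a unit listens while free and during the interruptible
   window of its own spontaneous emission; registers are cleared when a
   busy unit returns to the free state);
2. every listening neuron runs the recognition decision (one recognition
   event per step, external channel first), and free neurons additionally
   the spontaneous-emission roll;
3. every neuron advances its emission/refractory state machine, producing
   this step's output bit and (possibly) an active-pattern label.

State is held in flat per-neuron arrays with contexts bit-packed into
integers; the observable contract is the trace, not the representation.
Two interchangeable backends exist: a numba-compiled scalar loop (default
when numba is importable, :mod:`neurofp._kernel`) and a vectorized numpy
loop.  Both draw the winning recurrent channel of the randomized scan as a
uniform pick over the matching channels, which is distributionally
identical to the literal permutation scan of :mod:`neurofp.neuron`; the
test suite cross-validates the three implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import _kernel
from .neuron import NeuronParams
from .patterns import BinaryPattern, common_length
from .stimulation import StimulationProtocol
from .topology import NetworkTopology

SILENT = "silent"
SPONTANEOUS = "spontaneous"


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one run bit-for-bit (per backend)."""

    topology: Union[NetworkTopology, np.ndarray]
    params: NeuronParams
    total_steps: int
    seed: int
    protocol: Optional[StimulationProtocol] = None
    record_states: bool = False
    state_interval: int = 20
    #: when True and the parameter set lists no fingerprints, the recognizable
    #: set is built from the protocol's stimulus patterns
    auto_fingerprints: bool = True
    backend: str = "auto"      # auto | numba | numpy

    def resolved_params(self) -> NeuronParams:
        p = self.params
        if (self.auto_fingerprints and not p.known_fingerprints
                and self.protocol is not None and self.protocol.episodes):
            p = replace(p, known_fingerprints=self.protocol.patterns)
        return p


@dataclass
class SimulationTrace:
    """Per-step counts of actively emitting neurons, by pattern label.

    ``counts[t, k]`` is the number of neurons active on label ``labels[k]``
    at step ``t`` (label 0 is the spontaneous pattern).  Silent neurons are
    ``n_neurons - counts.sum(axis=1)`` — conservation holds every step.
    """

    counts: np.ndarray          # (T, 1 + n_fingerprints) int32
    labels: list                # label strings, index-aligned with counts
    n_neurons: int
    meta: dict = field(default_factory=dict)
    states: Optional[np.ndarray] = None        # (frames, N) int8, -1 = silent
    state_steps: Optional[np.ndarray] = None   # step index of each frame

    @property
    def total_steps(self) -> int:
        return self.counts.shape[0]

    def silent(self) -> np.ndarray:
        return self.n_neurons - self.counts.sum(axis=1)

    def series(self, label: str) -> np.ndarray:
        """Per-step count for one label; absent labels are all-zero."""
        if label == SILENT:
            return self.silent()
        if label in self.labels:
            return self.counts[:, self.labels.index(label)]
        return np.zeros(self.total_steps, dtype=self.counts.dtype)

    def total_active(self) -> np.ndarray:
        """Overall number of active neurons, whatever the pattern."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: one row per (step, label), silent included."""
        T = self.total_steps
        frames = []
        for k, lab in enumerate(self.labels + [SILENT]):
            cnt = self.silent() if lab == SILENT else self.counts[:, k]
            frames.append(pd.DataFrame(
                {"step": np.arange(T), "label": lab, "count": cnt}))
        return pd.concat(frames, ignore_index=True)


def _label_table(params: NeuronParams):
    """Pattern table and recognition lookup.

    Returns (labels, pattern-bit matrix, lut) where row/label 0 is the
    spontaneous pattern and rows 1..K the known fingerprints; ``lut`` maps a
    packed context register to the label it triggers (or -1).
    """
    pats = [params.spontaneous, *params.known_fingerprints]
    n = common_length(pats)
    labels = [SPONTANEOUS] + [
        fp.label or fp.to_string() for fp in params.known_fingerprints]
    if len(set(labels)) != len(labels):
        raise ValueError("fingerprint labels must be unique")
    if len({p.bits for p in pats}) != len(pats):
        raise ValueError("patterns must be pairwise distinct")
    pat_bits = np.array([p.bits for p in pats], dtype=np.int64)
    lut = np.full(1 << n, -1, dtype=np.int64)
    for k, p in enumerate(pats):
        if k > 0 or params.spontaneous_is_fingerprint:
            lut[p.code] = k
    return labels, pat_bits, lut


def _episode_arrays(protocol: Optional[StimulationProtocol], n: int):
    """Flatten the protocol into plain arrays for the compiled kernel."""
    if protocol is None or not protocol.episodes:
        return (np.zeros((0, n), np.int64), np.zeros(0, np.int64),
                np.zeros(0, np.int64), np.zeros(0, np.int64),
                np.zeros(1, np.int64))
    eps = protocol.episodes
    ep_bits = np.array([e.pattern.bits for e in eps], dtype=np.int64)
    ep_start = np.array([e.t_start for e in eps], dtype=np.int64)
    ep_end = np.array([e.t_end for e in eps], dtype=np.int64)
    ep_tgt = np.concatenate([np.asarray(e.targets, np.int64) for e in eps])
    ep_off = np.zeros(len(eps) + 1, np.int64)
    ep_off[1:] = np.cumsum([len(e.targets) for e in eps])
    return ep_bits, ep_start, ep_end, ep_tgt, ep_off


def run_simulation(config: SimulationConfig) -> SimulationTrace:
    """Execute ``total_steps`` synchronous steps from the standard initial
    state (all neurons free, all contexts zero) and return the trace.

    Bitwise reproducible for a fixed seed (per backend).
    """
    params = config.resolved_params()
    topo = config.topology
    in_edges = topo.in_edges if isinstance(topo, NetworkTopology) \
        else np.asarray(topo)
    N, C = in_edges.shape
    n = params.n
    labels, pat_bits, lut = _label_table(params)
    K = len(labels) - 1

    protocol = config.protocol
    if protocol is not None and protocol.episodes:
        if common_length([e.pattern for e in protocol.episodes]) != n:
            raise ValueError("stimulus length differs from fingerprint length")
        if config.total_steps < protocol.t_end:
            raise ValueError("total_steps must cover the whole protocol")
        for p in protocol.patterns:
            if lut[p.code] < 0:
                raise ValueError(
                    f"stimulus pattern {p} is not recognizable by the neurons")

    aw = params.active_window
    free_s = params.cycle_after_commit + 1   # s value meaning "free"
    window = params.window

    # lifecycle lookup tables indexed by steps-since-commit s in [0, free_s]:
    # output bit per (label, s) and whether s counts as active
    pat_tab = np.zeros((K + 1, free_s + 1), dtype=np.int64)
    pat_tab[:, 1:n + 1] = pat_bits
    act_tab = np.zeros(free_s + 1, dtype=np.bool_)
    act_tab[1:aw + 1] = True

    # -1 entries in in_edges are permanently silent channels (fixture use);
    # they read from a virtual always-0 unit at index N.
    pre = np.where(in_edges < 0, N, in_edges).astype(np.int64)

    T = config.total_steps
    counts = np.zeros((T, K + 1), dtype=np.int64)
    if config.record_states:
        frames = np.arange(0, T, config.state_interval)
        states = np.full((len(frames), N), -1, dtype=np.int8)
        state_interval = config.state_interval
    else:
        frames = None
        states = np.zeros((0, 0), dtype=np.int8)
        state_interval = 0

    rng = np.random.default_rng(config.seed)
    ep = _episode_arrays(protocol, n)

    backend = config.backend
    if backend == "auto":
        backend = "numba" if _kernel.HAVE_NUMBA else "numpy"
    if backend == "numba" and not _kernel.HAVE_NUMBA:
        raise RuntimeError("numba backend requested but numba is unavailable")

    if backend == "numba":
        _kernel.simulate_kernel(T, pre, lut, pat_tab, act_tab, n, free_s,
                                window, params.p_r, params.p_e,
                                params.p_override,
                                *ep, counts, states, state_interval, rng)
    else:
        _run_numpy(T, pre, lut, pat_tab, act_tab, n, free_s, window,
                   params.p_r, params.p_e, params.p_override, protocol,
                   counts, states, state_interval, rng, N, C, K)

    meta = {
        "seed": config.seed, "n_neurons": N, "fingerprint_length": n,
        "p_e": params.p_e, "p_r": params.p_r, "refractory": params.refractory,
        "interrupt_window": window,
        "accounting": params.accounting, "backend": backend,
        "rewiring_p": getattr(topo, "rewiring_p", None),
        "design": protocol.design if protocol is not None else "none",
    }
    return SimulationTrace(counts.astype(np.int32), labels, N, meta,
                           states if state_interval else None, frames)


def _run_numpy(T, pre, lut, pat_tab, act_tab, n, free_s, window, p_r, p_e,
               p_override, protocol, counts, states, state_interval,
               rng, N, C, K):
    """Vectorized fallback loop; same observable semantics as the kernel."""
    mask = np.int64((1 << n) - 1)

    ctx = np.zeros((N, C + 1), dtype=np.int64)
    s = np.full(N, free_s, dtype=np.int64)
    committed = np.zeros(N, dtype=np.int64)
    prev_out = np.zeros(N + 1, dtype=np.int64)
    ext = np.zeros(N, dtype=np.int64)

    for t in range(T):
        # lifecycle advance; clear contexts of units returning to free
        busy = s < free_s
        s[busy] += 1
        ctx[busy & (s == free_s)] = 0

        free = s == free_s
        listening = free | ((committed == 0) & (s >= 1) & (s <= window))
        idx = np.flatnonzero(listening)
        if idx.size:
            # phase 1: inputs and context shift for listening units
            ext.fill(0)
            if protocol is not None:
                protocol.fill_external_bits(t, ext)
            bits = np.empty((idx.size, C + 1), dtype=np.int64)
            bits[:, 0] = ext[idx]
            bits[:, 1:] = prev_out[pre[idx]]
            ctx[idx] = ((ctx[idx] << 1) | bits) & mask

            # phase 2: one recognition event per unit, external first; an
            # override of an ongoing spontaneous emission needs a second roll
            ml = lut[ctx[idx]]                       # (F, C+1)
            ext_match = ml[:, 0] >= 0
            rec_match = ml[:, 1:] >= 0
            m_r = rec_match.sum(axis=1)
            u = rng.random((idx.size, 4))
            event = ext_match | (m_r > 0)
            success = event & (u[:, 0] < p_r) & (free[idx] | (u[:, 3] < p_override))
            pick = (u[:, 1] * m_r).astype(np.int64)
            cs = np.cumsum(rec_match, axis=1)
            pos = (cs > pick[:, None]).argmax(axis=1)
            rec_label = ml[np.arange(idx.size), pos + 1]
            label = np.where(success,
                             np.where(ext_match, ml[:, 0], rec_label), -1)
            spont = (label < 0) & free[idx] & (u[:, 2] < p_e)
            label = np.where(spont, 0, label)
            commit = label >= 0
            ci = idx[commit]
            s[ci] = 0
            committed[ci] = label[commit]

        # phase 3: outputs and activity accounting
        out = pat_tab[committed, s]
        active = act_tab[s]
        counts[t] = np.bincount(committed[active], minlength=K + 1)
        prev_out[:N] = out

        if state_interval and t % state_interval == 0:
            fr = states[t // state_interval]
            fr[active] = committed[active].astype(np.int8)
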