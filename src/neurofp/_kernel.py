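"""Compiled inner loop of the simulation engine.

A straight scalar transcription of the per-neuron rules (gated contexts,
recognition, emission lifecycle) executed for all neurons and all time steps
inside one jitted function.  Random draws are consumed in a fixed documented
order — time step ascending, neuron index ascending, and within a listening
neuron: recognition roll (at most one per step), override roll (only while
interrupting a spontaneous emission), channel pick, spontaneous roll — so
trajectories are bitwise reproducible for a fixed seed.

The winning recurrent channel under "first matching channel in a freshly
randomized scan order" is uniform over the matching channels, which is how
it is drawn here (one uniform pick instead of materializing the
permutation).  The literal permutation scan lives in :mod:`neurofp.neuron`
and the two are cross-validated in the test suite.

If numba is unavailable the engine falls back to the vectorized numpy path.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco


@njit(cache=True, nogil=True)
def simulate_kernel(T, pre, lut, pat_tab, act_tab, n_bits, free_s, window,
                    p_r, p_e, p_override, ep_bits, ep_start, ep_end,
                    ep_tgt, ep_off, counts, states, state_interval, rng):
    N, C = pre.shape
    E = ep_start.shape[0]
    mask = (1 << n_bits) - 1

    ctx = np.zeros((N, C + 1), dtype=np.int64)
    s = np.full(N, free_s, dtype=np.int64)
    committed = np.zeros(N, dtype=np.int64)
    prev = np.zeros(N + 1, dtype=np.int64)   # index N: virtual silent unit
    out = np.zeros(N, dtype=np.int64)
    ext = np.zeros(N, dtype=np.int64)
    match_buf = np.empty(C, dtype=np.int64)

    for t in range(T):
        # external stimulus bits for this step
        for i in range(N):
            ext[i] = 0
        for e in range(E):
            if ep_start[e] <= t < ep_end[e]:
                b = ep_bits[e, (t - ep_start[e]) % n_bits]
                for k in range(ep_off[e], ep_off[e + 1]):
                    ext[ep_tgt[k]] = b

        for i in range(N):
            # advance the emission/refractory state machine; clear the
            # contexts when the unit returns to the free (listening) state
            si = s[i]
            if si < free_s:
                si += 1
                s[i] = si
                if si == free_s:
                    for c in range(C + 1):
                        ctx[i, c] = 0

            free = si == free_s
            # a unit listens while free, and during the first `window`
            # emission steps of its own spontaneous pattern
            listening = free or (committed[i] == 0 and 1 <= si <= window)

            if listening:
                # shift all contexts with the presynaptic outputs of the
                # previous step plus this step's external bit
                ctx[i, 0] = ((ctx[i, 0] << 1) | ext[i]) & mask
                for c in range(C):
                    ctx[i, c + 1] = ((ctx[i, c + 1] << 1)
                                     | prev[pre[i, c]]) & mask
                # at most one recognition event per step: external channel
                # first, else the first matching recurrent channel of a
                # randomized scan (uniform over the matches)
                lab = -1
                l0 = lut[ctx[i, 0]]
                if l0 >= 0:
                    if rng.random() < p_r and (free or rng.random() < p_override):
                        lab = l0
                else:
                    m = 0
                    for c in range(C):
                        lc = lut[ctx[i, c + 1]]
                        if lc >= 0:
                            match_buf[m] = lc
                            m += 1
                    if m > 0 and rng.random() < p_r \
                            and (free or rng.random() < p_override):
                        lab = match_buf[rng.integers(0, m)]
                # a failed roll leaves the unit processing as if no
                # recognition had happened: the spontaneous stage still runs
                if lab < 0 and free and rng.random() < p_e:
                    lab = 0           # spontaneous pattern
                if lab >= 0:
                    s[i] = 0
                    committed[i] = lab
                    si = 0

            # output bit and activity accounting
            out[i] = pat_tab[committed[i], si]
            if act_tab[si]:
                counts[t, committed[i]] += 1

        if state_interval > 0 and t % state_interval == 0:
            fr = t // state_interval
            for i in range(N):
                states[fr, i] = committed[i] if act_tab[s[i]] else -1

        for i in range(N):
            prev[i] = out[i]
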