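"""Trace serialization, activity-movie rendering, and scripted fixtures.

Traces round-trip through a tidy CSV (step, label, count).  Recorded state
grids render to RGB frames with the standard colour convention: yellow for
silent units, blue for the spontaneous pattern, red for the first stimulus,
green for the second, and a fixed palette for further stimuli.  Rendering
is a pure function of the trace.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .engine import SILENT, SimulationConfig, SimulationTrace, run_simulation
from .neuron import NeuronParams
from .patterns import BinaryPattern

#: label-index -> RGB; -1 (silent) handled separately
SILENT_COLOR = (255, 221, 0)          # yellow
PALETTE = [
    (30, 80, 220),                    # 0: spontaneous, blue
    (220, 30, 30),                    # 1: first stimulus, red
    (30, 160, 50),                    # 2: second stimulus, green
    (240, 130, 20),                   # orange
    (150, 60, 190),                   # purple
    (90, 200, 220),                   # cyan
    (240, 80, 160),                   # pink
    (130, 100, 40),                   # brown
    (170, 210, 60),                   # lime
    (100, 100, 100),                  # grey
]


# ------------------------------------------------------------------ traces

def trace_to_csv(trace: SimulationTrace, path) -> None:
    """Write the per-step counts as tidy CSV (step, label, count)."""
    trace.to_frame().to_csv(path, index=False)


def trace_from_csv(path) -> SimulationTrace:
    """Rebuild a counts-only trace from :func:`trace_to_csv` output."""
    df = pd.read_csv(path)
    labels = [l for l in df["label"].unique() if l != SILENT]
    # preserve spontaneous-first ordering
    labels.sort(key=lambda l: 0 if l == "spontaneous" else 1)
    wide = df.pivot(index="step", columns="label", values="count")
    counts = wide[labels].to_numpy(dtype=np.int32)
    n_neurons = int(df[df["step"] == 0]["count"].sum())
    return SimulationTrace(counts, labels, n_neurons)


def save_states(trace: SimulationTrace, array_path, legend_path) -> None:
    """Persist recorded state grids (.npy) plus a JSON legend."""
    if trace.states is None:
        raise ValueError("trace was recorded without states")
    np.save(array_path, trace.states)
    legend = {"labels": trace.labels, "silent": -1,
              "steps": [int(t) for t in trace.state_steps],
              "n_neurons": trace.n_neurons}
    Path(legend_path).write_text(json.dumps(legend))


# ------------------------------------------------------------------ movies

def render_frames(trace: SimulationTrace,
                  merge_spontaneous: bool = False) -> np.ndarray:
    """Render recorded state grids to RGB frames (frames, L, L, 3).

    ``merge_spontaneous`` paints spontaneous emitters in the silent colour,
    the convention used when many stimuli share the palette.
    """
    if trace.states is None:
        raise ValueError("trace was recorded without states "
                         "(set record_states=True)")
    side = int(round(np.sqrt(trace.n_neurons)))
    if side * side != trace.n_neurons:
        raise ValueError("state rendering expects a square network")
    colors = np.array([SILENT_COLOR] + [
        PALETTE[min(k, len(PALETTE) - 1)] for k in range(len(trace.labels))],
        dtype=np.uint8)
    if merge_spontaneous:
        colors[1] = SILENT_COLOR
    idx = trace.states + 1          # -1 silent -> 0
    frames = colors[idx]            # (F, N, 3)
    return frames.reshape(-1, side, side, 3)


def render_movie(trace: SimulationTrace, out_dir,
                 merge_spontaneous: bool = False,
                 gif_path=None, upscale: int = 6) -> list:
    """Write one PNG per recorded frame (optionally an animated GIF).

    Returns the list of written PNG paths.
    """
    frames = render_frames(trace, merge_spontaneous)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    big = frames.repeat(upscale, axis=1).repeat(upscale, axis=2)
    paths = []
    for i, (t, frame) in enumerate(zip(trace.state_steps, big)):
        p = out_dir / f"frame_{i:05d}_t{int(t):07d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    if gif_path is not None:
        iio.imwrite(gif_path, list(big), duration=80, loop=0)
    return paths


# ----------------------------------------------------------------- fixture

def make_figure1_fixture(steps: int = 60):
    """Deterministic two-neuron chain scenario for hand-checked testing.

    Unit 0 is driven externally with the fingerprint F = (1,0,1,0,1)
    repeated without gaps; unit 1 receives unit 0's output on one recurrent
    channel (all other channels silent).  With p_r = 1 and p_e = 0 the
    trajectory is fully deterministic: unit 0 recognizes F once its
    external register fills, re-emits it over the following five steps, and
    unit 1 commits once that emission has filled its own register.

    Returns (config, trace).
    """
    F = BinaryPattern((1, 0, 1, 0, 1), "F")
    spont = BinaryPattern((1, 1, 1, 1, 1), "spontaneous")
    in_edges = np.full((2, 8), -1, dtype=np.int64)
    in_edges[1, 0] = 0                      # unit 1 listens to unit 0
    from .stimulation import StimulationProtocol, StimulusEpisode
    proto = StimulationProtocol(
        (StimulusEpisode(F, (0,), 0, steps),), "single")
    params = NeuronParams(p_e=0.0, p_r=1.0, spontaneous=spont,
                          known_fingerprints=(F,))
    cfg = SimulationConfig(in_edges, params, steps, seed=0, protocol=proto)
    return cfg, run_simulation(cfg)
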