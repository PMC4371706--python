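"""Scripted experiments: canonical run designs, parameter sweeps, and
reproduction of the published summary tables.

The builders here encode the standard study conditions:

* autonomous runs — 50x50 network evolving freely (spontaneous levels);
* single-stimulus runs — free evolution to step 5000, then one 5-bit
  pattern delivered without gaps to one randomly chosen neuron for 10,000
  steps (detection, steady following levels, velocity, memory);
* in-series runs — eight alternating A/B episodes of 10,000 steps on a
  2x5 target cluster, separated by 5000 silent steps, ending at 120,000
  (competition regimes, survival times);
* in-parallel runs — several distinct patterns delivered simultaneously
  to disjoint 2x5 clusters (coexistence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationConfig, SimulationTrace, run_simulation
from .metrics import (LONG_TERM, SHORT_TERM, THETA_COEXIST, THETA_DETECT,
                      classify_competition, classify_memory,
                      closed_form_spontaneous, coexistence_count,
                      detect_propagation, propagation_velocity, steady_level,
                      survival_time)
from .neuron import NeuronParams
from .patterns import BinaryPattern, distinct_patterns
from .stimulation import (cluster_targets, make_parallel_protocol,
                          make_series_protocol, make_single_protocol,
                          random_target, scattered_clusters)
from .topology import PRESETS, make_topology

FIVE_BIT_STIMULUS = BinaryPattern((1, 0, 1, 0, 1), "A")
SERIES_B = BinaryPattern((1, 1, 0, 1, 1), "B")
SPONTANEOUS_5 = BinaryPattern((1, 1, 1, 1, 1), "spontaneous")

#: published reference values, used only in comparison reports
PUBLISHED = {
    "T1": {  # autonomous spontaneous levels by p_e (topology-independent)
        0.05: 416.64, 0.10: 576.96, 0.15: 661.72,
        0.50: 833.34, 0.80: 869.57, 1.00: 882.42,
    },
    "T2": {  # max p_e allowing detection, by (p_r, rewiring p)
        (0.30, 0.0): 0.01, (0.30, 0.1): 0.03, (0.30, 0.25): 0.04, (0.30, 1.0): 0.04,
        (0.50, 0.0): 0.07, (0.50, 0.1): 0.09, (0.50, 0.25): 0.10, (0.50, 1.0): 0.11,
        (0.80, 0.0): 0.15, (0.80, 0.1): 0.18, (0.80, 0.25): 0.20, (0.80, 1.0): 0.21,
        (1.00, 0.0): 0.20, (1.00, 0.1): 0.25, (1.00, 0.25): 0.26, (1.00, 1.0): 0.28,
    },
    "T3": {  # stimulus-following steady levels at p_e=0.05, by (p_r, p)
        (0.50, 0.0): 275.37, (0.50, 0.1): 318.54, (0.50, 0.25): 334.93, (0.50, 1.0): 350.62,
        (0.80, 0.0): 531.94, (0.80, 0.1): 540.17, (0.80, 0.25): 545.52, (0.80, 1.0): 553.52,
        (1.00, 0.0): 622.73, (1.00, 0.1): 628.85, (1.00, 0.25): 634.07, (1.00, 1.0): 638.02,
    },
    "T4": {  # propagation velocity (neurons/step) at p_e=0.05, p_r=0.80
        0.0: 3.82, 0.1: 13.15, 0.25: 16.88, 1.0: 17.80,
    },
    "T5": {  # (p_e, p_r) design points: short-term / long-term examples
        ("Regular", SHORT_TERM): (0.05, 0.42), ("Regular", LONG_TERM): (0.05, 0.80),
        ("SW(10)", SHORT_TERM): (0.05, 0.34), ("SW(10)", LONG_TERM): (0.05, 0.80),
        ("SW(25)", SHORT_TERM): (0.05, 0.32), ("SW(25)", LONG_TERM): (0.05, 0.80),
        ("Random", SHORT_TERM): (0.05, 0.31), ("Random", LONG_TERM): (0.05, 0.80),
    },
    "T6": {  # mean survival of the displaced stimulus (long-term networks)
        0.0: (10477.75, 4500.46), 0.1: (5759.95, 4376.25),
        0.25: (3391.66, 1650.48), 1.0: (3226.42, 1167.10),
    },
    "T7": {  # mean coexisting stimuli, nine parallel 9-bit stimuli
        0.0: (7.77, 0.95), 0.1: (6.68, 1.18), 0.25: (4.51, 1.19), 1.0: (4.29, 1.11),
    },
}


# --------------------------------------------------------------- builders

def autonomous_config(p_e: float, p: float = 0.0, seed: int = 0,
                      side: int = 50, total_steps: int = 20_000,
                      p_r: float = 0.5) -> SimulationConfig:
    """Free-running network with no recognizable fingerprints."""
    topo = make_topology(side, p, seed=seed + 10_000)
    params = NeuronParams(p_e=p_e, p_r=p_r, spontaneous=SPONTANEOUS_5)
    return SimulationConfig(topo, params, total_steps, seed)


def single_stimulus_config(p_e: float, p_r: float, p: float, seed: int,
                           side: int = 50, t_on: int = 5000,
                           duration: int = 10_000, post: int = 0,
                           n_targets: int = 1,
                           pattern: BinaryPattern = FIVE_BIT_STIMULUS,
                           ) -> SimulationConfig:
    """One pattern into one (or a 2xw cluster of) randomly placed neuron(s)."""
    topo = make_topology(side, p, seed=seed + 10_000)
    rng = np.random.default_rng(seed + 20_000)
    if n_targets == 1:
        targets = random_target(side * side, rng)
    else:
        targets = cluster_targets(side, (n_targets + 1) // 2, rng=rng)[:n_targets]
    spont = BinaryPattern((1,) * pattern.n, "spontaneous")
    proto = make_single_protocol(pattern, targets, t_on, duration)
    params = NeuronParams(p_e=p_e, p_r=p_r, spontaneous=spont)
    return SimulationConfig(topo, params, t_on + duration + post, seed,
                            protocol=proto)


def series_config(p_e: float, p_r: float, p: float, seed: int,
                  side: int = 50, t0: int = 5000, on: int = 10_000,
                  off: int = 5000, repeats: int = 8, post: int = 0,
                  cluster_width: int = 5) -> SimulationConfig:
    """Alternating A/B episodes on one randomly placed 2xw cluster."""
    topo = make_topology(side, p, seed=seed + 10_000)
    rng = np.random.default_rng(seed + 20_000)
    targets = cluster_targets(side, cluster_width, rng=rng)
    proto = make_series_protocol(FIVE_BIT_STIMULUS, SERIES_B, targets,
                                 t0, on, off, repeats)
    params = NeuronParams(p_e=p_e, p_r=p_r, spontaneous=SPONTANEOUS_5)
    return SimulationConfig(topo, params, proto.t_end + off + post, seed,
                            protocol=proto)


def parallel_config(p_e: float, p_r: float, p: float, seed: int,
                    n_stimuli: int = 9, n_bits: int = 9, side: int = 50,
                    t_start: int = 5000, duration: int = 20_000,
                    post: int = 0, cluster_width: int = 5) -> SimulationConfig:
    """Several distinct patterns into disjoint 2xw clusters simultaneously."""
    topo = make_topology(side, p, seed=seed + 10_000)
    rng = np.random.default_rng(seed + 20_000)
    pats = distinct_patterns(n_stimuli, n_bits)
    groups = scattered_clusters(side, n_stimuli, cluster_width, rng)
    proto = make_parallel_protocol(pats, groups, t_start, t_start + duration)
    spont = BinaryPattern((1,) * n_bits, "spontaneous")
    params = NeuronParams(p_e=p_e, p_r=p_r, spontaneous=spont)
    return SimulationConfig(topo, params, t_start + duration + post, seed,
                            protocol=proto)


def run_replicates(make_config, seeds: Iterable[int]) -> list:
    """Run ``make_config(seed)`` for every seed and collect the traces."""
    return [run_simulation(make_config(s)) for s in seeds]


# ------------------------------------------------------------- detection

def detection_threshold(p_r: float, p: float, seeds: Sequence[int] = (0, 1, 2),
                        pe_grid: Optional[Sequence[float]] = None,
                        t_on: int = 5000, duration: int = 10_000,
                        theta: float = THETA_DETECT,
                        scan: str = "ascending") -> float:
    """Largest p_e (0.01 grid) at which a single-neuron 5-bit stimulus
    still propagates network-wide; 0.0 if it never does.

    Propagation is monotone in p_e.  ``scan="ascending"`` walks the grid
    upward and stops at the first non-propagating point; ``scan="bisect"``
    finds the same boundary by bisection over the grid (fewer runs).
    """
    if pe_grid is None:
        pe_grid = np.round(np.arange(0.01, 0.41, 0.01), 2)
    pe_grid = list(pe_grid)

    def detected(pe):
        traces = run_replicates(
            lambda s: single_stimulus_config(pe, p_r, p, s, t_on=t_on,
                                             duration=duration), seeds)
        return detect_propagation(traces, "A", (t_on, t_on + duration),
                                  theta) == "detected"

    if scan == "ascending":
        last = 0.0
        for pe in pe_grid:
            if detected(pe):
                last = float(pe)
            else:
                break
        return last
    if scan != "bisect":
        raise ValueError(f"unknown scan mode {scan!r}")
    if not detected(pe_grid[0]):
        return 0.0
    lo, hi = 0, len(pe_grid) - 1          # invariant: grid[lo] detected
    if detected(pe_grid[hi]):
        return float(pe_grid[hi])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if detected(pe_grid[mid]):
            lo = mid
        else:
            hi = mid
    return float(pe_grid[lo])


# ---------------------------------------------------------------- sweeps

@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for phase-diagram sweeps."""

    p_e_values: tuple = (0.05,)
    p_r_values: tuple = tuple(np.round(np.arange(0.30, 1.001, 0.05), 2))
    p_values: tuple = (0.0, 0.1, 0.25, 1.0)
    seeds: tuple = (0, 1, 2, 3, 4)
    side: int = 50
    t_on: int = 5000
    duration: int = 10_000
    post: int = 20_000

    def __post_init__(self):
        if not (self.p_e_values and self.p_r_values and self.p_values):
            raise ValueError("sweep grids must be nonempty")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("replicate seeds must be distinct")


def sweep_memory_phase(spec: SweepSpec) -> pd.DataFrame:
    """Classify each grid point as none / short-term / long-term memory.

    Per point, the majority classification across seeds; points that the
    detection criterion rejects are labelled "none".
    """
    rows = []
    for pe in spec.p_e_values:
        for p in spec.p_values:
            for pr in spec.p_r_values:
                votes = []
                for s in spec.seeds:
                    cfg = single_stimulus_config(
                        pe, pr, p, s, side=spec.side, t_on=spec.t_on,
                        duration=spec.duration, post=spec.post)
                    tr = run_simulation(cfg)
                    win = (spec.t_on, spec.t_on + spec.duration)
                    if detect_propagation(tr, "A", win) != "detected":
                        votes.append("none")
                    else:
                        votes.append(classify_memory(
                            tr, "A", spec.t_on + spec.duration))
                label = max(set(votes), key=votes.count)
                rows.append({"p_e": pe, "p_r": pr, "p": p, "label": label,
                             "votes": ",".join(votes)})
    return pd.DataFrame(rows)


def sweep_competition(spec: SweepSpec) -> pd.DataFrame:
    """Classify each (p_r, p) point of the in-series design as NC/WTA/WLC."""
    rows = []
    pe = spec.p_e_values[0]
    for p in spec.p_values:
        for pr in spec.p_r_values:
            votes = []
            for s in spec.seeds:
                cfg = series_config(pe, pr, p, s, side=spec.side)
                tr = run_simulation(cfg)
                votes.append(classify_competition(tr, ["A", "B"],
                                                  cfg.protocol))
            label = max(set(votes), key=votes.count)
            rows.append({"p_e": pe, "p_r": pr, "p": p, "regime": label,
                         "votes": ",".join(votes)})
    return pd.DataFrame(rows)


# ------------------------------------------------------- table reproduction

def reproduce_table(table_id: str, seeds: Sequence[int] = (0, 1, 2, 3, 4),
                    scale: float = 1.0) -> pd.DataFrame:
    """Re-run the protocol behind a published table and report measured
    vs published values with z-scores.

    ``scale`` < 1 shortens the simulated windows proportionally (for quick
    smoke runs); published values are reported unchanged.
    """
    if table_id == "T1":
        return _table1(seeds, scale)
    if table_id == "T2":
        return _table2(seeds)
    if table_id == "T3":
        return _table3(seeds, scale)
    if table_id == "T4":
        return _table4(seeds, scale)
    if table_id == "T6":
        return _table6(seeds)
    if table_id == "T7":
        return _table7(seeds, scale)
    raise ValueError(f"unknown table id {table_id!r} "
                     "(supported: T1, T2, T3, T4, T6, T7)")


def _zrow(measured, se, published):
    z = (measured - published) / se if se else np.nan
    return {"measured": measured, "se": se, "published": published, "z": z}


def _table1(seeds, scale):
    steps = max(int(20_000 * scale), 4000)
    burn = max(int(2000 * scale), 500)
    rows = []
    for pe, published in PUBLISHED["T1"].items():
        for name, p in PRESETS.items():
            traces = run_replicates(
                lambda s: autonomous_config(pe, p, s, total_steps=steps),
                seeds)
            est = steady_level(traces, "spontaneous", (burn, steps))
            rows.append({"p_e": pe, "topology": name,
                         "closed_form": 2500 * closed_form_spontaneous(5, pe),
                         **_zrow(est.mean, est.se, published)})
    return pd.DataFrame(rows)


def _table2(seeds):
    rows = []
    for (pr, p), published in PUBLISHED["T2"].items():
        thr = detection_threshold(pr, p, seeds=seeds)
        rows.append({"p_r": pr, "p": p, "measured": thr, "published": published,
                     "error": thr - published})
    return pd.DataFrame(rows)


def _table3(seeds, scale):
    dur = max(int(10_000 * scale), 4000)
    t_on = max(int(5000 * scale), 2000)
    rows = []
    for (pr, p), published in PUBLISHED["T3"].items():
        traces = run_replicates(
            lambda s: single_stimulus_config(0.05, pr, p, s, t_on=t_on,
                                             duration=dur), seeds)
        est = steady_level(traces, "A", (t_on + dur // 2, t_on + dur))
        rows.append({"p_r": pr, "p": p, **_zrow(est.mean, est.se, published)})
    return pd.DataFrame(rows)


def _table4(seeds, scale):
    dur = max(int(10_000 * scale), 4000)
    t_on = max(int(5000 * scale), 2000)
    rows = []
    for p, published in PUBLISHED["T4"].items():
        vels = []
        for s in seeds:
            tr = run_simulation(single_stimulus_config(
                0.05, 0.80, p, s, t_on=t_on, duration=dur))
            vels.append(propagation_velocity(tr, "A", (t_on, t_on + dur)))
        se = np.std(vels, ddof=1) / np.sqrt(len(vels)) if len(vels) > 1 else 0
        rows.append({"p": p, **_zrow(float(np.mean(vels)), se, published)})
    return pd.DataFrame(rows)


def _table6(seeds):
    rows = []
    for p, (pub_mean, pub_sd) in PUBLISHED["T6"].items():
        surv = []
        for s in seeds:
            cfg = series_config(0.05, 0.80, p, s)
            tr = run_simulation(cfg)
            for k, ep in enumerate(cfg.protocol.episodes):
                if k == 0:
                    continue
                old = cfg.protocol.episodes[k - 1].pattern.label
                if tr.series(old)[ep.t_start] == 0:
                    continue
                t = survival_time(tr, old, ep.t_start)
                if t is not None:
                    surv.append(t)
        mean = float(np.mean(surv)) if surv else np.nan
        sd = float(np.std(surv, ddof=1)) if len(surv) > 1 else np.nan
        rows.append({"p": p, "measured": mean, "sd": sd, "n_episodes":
                     len(surv), "published": published_mean, "published_sd": pub_sd})
    return pd.DataFrame(rows)


def _table7(seeds, scale):
    dur = max(int(20_000 * scale), 5000)
    rows = []
    for p, (pub_mean, pub_sd) in PUBLISHED["T7"].items():
        vals = []
        for s in seeds:
            cfg = parallel_config(0.05, 0.80, p, s, duration=dur)
            tr = run_simulation(cfg)
            labels = [pt.label for pt in cfg.protocol.patterns]
            vals.append(coexistence_count(tr, labels, (5000, 5000 + dur)))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0
        rows.append({"p": p, **_zrow(float(np.mean(vals)), se, pub_mean),
                     "published_sd": pub_sd})
    return pd.DataFrame(rows)
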