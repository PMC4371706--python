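"""External-stimulus protocols: single, in-series and in-parallel designs.

A stimulus is a binary pattern delivered on the external channel of a set of
target neurons, repeated back-to-back (no silent gaps between presentations)
for the duration of a stimulation episode.  Protocols are ordered lists of
episodes; the canonical designs are

* ``single`` — one pattern into one (or a few) neurons for one episode;
* ``series`` — two patterns A/B alternating in successive episodes separated
  by stimulus-free intervals, delivered to the same targets;
* ``parallel`` — several patterns delivered simultaneously to disjoint
  neuron groups during a single shared episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .patterns import BinaryPattern, common_length


@dataclass(frozen=True)
class StimulusEpisode:
    """One pattern delivered to ``targets`` during ``[t_start, t_end)``."""

    pattern: BinaryPattern
    targets: tuple
    t_start: int
    t_end: int

    def __post_init__(self):
        object.__setattr__(self, "targets", tuple(int(t) for t in self.targets))
        if self.t_start >= self.t_end:
            raise ValueError("episode must satisfy t_start < t_end")
        if not self.targets:
            raise ValueError("episode needs at least one target neuron")

    def external_bit(self, t: int) -> Optional[int]:
        """Bit on the external channel at step ``t``: the pattern repeated
        without silent periods inside the episode, None outside it."""
        if self.t_start <= t < self.t_end:
            return self.pattern.bit_at(t - self.t_start)
        return None


@dataclass(frozen=True)
class StimulationProtocol:
    episodes: tuple = ()
    design: str = "none"        # none | single | series | parallel

    def __post_init__(self):
        eps = tuple(self.episodes)
        object.__setattr__(self, "episodes", eps)
        for a in range(len(eps)):
            for b in range(a + 1, len(eps)):
                ea, eb = eps[a], eps[b]
                if (ea.t_start < eb.t_end and eb.t_start < ea.t_end
                        and set(ea.targets) & set(eb.targets)):
                    raise ValueError(
                        "episodes overlap in time on shared targets")
        if eps:
            common_length([e.pattern for e in eps])

    @property
    def patterns(self) -> tuple:
        """Distinct stimulus patterns in first-appearance order."""
        seen, out = set(), []
        for e in self.episodes:
            if e.pattern.bits not in seen:
                seen.add(e.pattern.bits)
                out.append(e.pattern)
        return tuple(out)

    @property
    def t_end(self) -> int:
        return max((e.t_end for e in self.episodes), default=0)

    def fill_external_bits(self, t: int, out: np.ndarray) -> None:
        """Write this step's external bit into ``out`` for every stimulated
        neuron (all other entries are left untouched)."""
        for e in self.episodes:
            bit = e.external_bit(t)
            if bit is not None:
                out[list(e.targets)] = bit

    # ------------------------------------------------------------ config io
    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "episodes": [
                {"pattern": e.pattern.to_string(), "label": e.pattern.label,
                 "targets": list(e.targets),
                 "t_start": e.t_start, "t_end": e.t_end}
                for e in self.episodes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationProtocol":
        eps = [StimulusEpisode(
            BinaryPattern.from_string(e["pattern"], e.get("label", "")),
            e["targets"], e["t_start"], e["t_end"]) for e in d["episodes"]]
        return cls(tuple(eps), d.get("design", "none"))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "StimulationProtocol":
        return cls.from_dict(yaml.safe_load(text))


def make_single_protocol(pattern: BinaryPattern, targets: Sequence[int],
                         t_start: int = 5000,
                         duration: int = 10_000) -> StimulationProtocol:
    """One stimulus delivered continuously for ``duration`` steps."""
    ep = StimulusEpisode(pattern, tuple(targets), t_start, t_start + duration)
    return StimulationProtocol((ep,), "single")


def make_series_protocol(A: BinaryPattern, B: BinaryPattern,
                         targets: Sequence[int], t0: int = 5000,
                         on: int = 10_000, off: int = 5000,
                         repeats: int = 8) -> StimulationProtocol:
    """Alternating A/B episodes: episode ``k`` occupies
    ``[t0 + k(on+off), t0 + k(on+off) + on)``; with the defaults the eighth
    episode ends at step 120,000 and no stimulus follows."""
    if A.bits == B.bits:
        raise ValueError("series design requires two distinct patterns")
    common_length([A, B])
    episodes = []
    for k in range(repeats):
        if on <= 0:
            break
        start = t0 + k * (on + off)
        episodes.append(StimulusEpisode(A if k % 2 == 0 else B,
                                        tuple(targets), start, start + on))
    return StimulationProtocol(tuple(episodes), "series")


def make_parallel_protocol(patterns: Sequence[BinaryPattern],
                           target_groups: Sequence[Sequence[int]],
                           t_start: int = 5000,
                           t_end: int = 25_000) -> StimulationProtocol:
    """All patterns delivered simultaneously to disjoint neuron groups
    during one shared episode ``[t_start, t_end)``."""
    if len(patterns) != len(target_groups):
        raise ValueError("one target group per pattern required")
    if len({p.bits for p in patterns}) != len(patterns):
        raise ValueError("parallel patterns must be pairwise distinct")
    seen = set()
    for g in target_groups:
        gs = set(int(i) for i in g)
        if gs & seen:
            raise ValueError("target groups must be disjoint")
        seen |= gs
    eps = tuple(StimulusEpisode(p, tuple(g), t_start, t_end)
                for p, g in zip(patterns, target_groups))
    return StimulationProtocol(eps, "parallel")


# ------------------------------------------------------------------ targets

def random_target(n_neurons: int, rng: np.random.Generator) -> tuple:
    """The default single-stimulus target: one uniformly chosen neuron."""
    return (int(rng.integers(n_neurons)),)


def cluster_targets(side: int, width: int,
                    origin: Optional[tuple] = None,
                    rng: Optional[np.random.Generator] = None) -> tuple:
    """A contiguous 2 x ``width`` rectangle of neuron ids on the torus
    (the default multi-neuron stimulation geometry)."""
    if origin is None:
        if rng is None:
            raise ValueError("need an origin or an rng")
        origin = (int(rng.integers(side)), int(rng.integers(side)))
    r0, c0 = origin
    ids = [((r0 + dr) % side) * side + (c0 + dc) % side
           for dr in range(2) for dc in range(width)]
    return tuple(ids)


def scattered_clusters(side: int, count: int, width: int,
                       rng: np.random.Generator,
                       max_tries: int = 1000) -> list:
    """``count`` disjoint 2 x ``width`` clusters placed at random, rejecting
    overlaps; used for in-parallel multi-stimulus designs."""
    groups, used = [], set()
    tries = 0
    while len(groups) < count:
        g = cluster_targets(side, width, rng=rng)
        if not set(g) & used:
            groups.append(g)
            used |= set(g)
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place disjoint clusters")
    return groups
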