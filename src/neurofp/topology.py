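"""Network substrate: periodic 2-D lattice with Watts-Strogatz rewiring.

Networks are built on an ``L x L`` grid (default 50, i.e. 2500 units) with
periodic boundary conditions where every unit receives input from its eight
nearest (Moore) neighbours.  Each lattice in-edge is then independently
broken with probability ``p`` and replaced by an edge from a uniformly chosen
other unit.  ``p = 0`` gives the regular lattice, ``p = 1`` a random graph,
and intermediate values the small-world regime.

Because every neuron owns exactly 8 recurrent input channels, rewiring
redraws the *source* of each in-edge: in-degree stays exactly 8 for every
``p`` while out-degree becomes variable.  Redraws that would create a
self-edge or a duplicate presynaptic neighbour are re-sampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: named presets used throughout the experiments
PRESETS = {"Regular": 0.0, "SW(10)": 0.1, "SW(25)": 0.25, "Random": 1.0}

# Moore neighbourhood offsets (row, col), fixed channel order
_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class NetworkTopology:
    """Directed wiring: for each neuron an ordered list of 8 presynaptic ids.

    ``in_edges[i, c]`` is the neuron whose output feeds recurrent channel
    ``c`` of neuron ``i``.
    """

    side: int
    rewiring_p: float
    in_edges: np.ndarray        # (N, 8) int32
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return self.side * self.side

    def validate(self) -> None:
        N = self.n_neurons
        e = self.in_edges
        if e.shape != (N, 8):
            raise ValueError(f"in_edges must be (N, 8), got {e.shape}")
        if (e < 0).any() or (e >= N).any():
            raise ValueError("presynaptic ids out of range")
        if (e == np.arange(N)[:, None]).any():
            raise ValueError("self-edges are not allowed")
        for i in range(N):
            if len(set(e[i])) != 8:
                raise ValueError(f"duplicate presynaptic ids for neuron {i}")

    # ---------------------------------------------------------------- io
    def to_csv(self, edge_path, meta_path=None) -> None:
        """Edge list CSV (post_id, channel_index, pre_id) + JSON metadata."""
        N = self.n_neurons
        post = np.repeat(np.arange(N), 8)
        chan = np.tile(np.arange(8), N)
        arr = np.column_stack([post, chan, self.in_edges.ravel()])
        header = "post_id,channel_index,pre_id"
        np.savetxt(edge_path, arr, fmt="%d", delimiter=",", header=header,
                   comments="")
        if meta_path is not None:
            meta = {"side": self.side, "rewiring_p": self.rewiring_p,
                    "seed": self.seed}
            Path(meta_path).write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, edge_path, meta_path) -> "NetworkTopology":
        meta = json.loads(Path(meta_path).read_text())
        arr = np.loadtxt(edge_path, delimiter=",", skiprows=1, dtype=np.int64)
        N = meta["side"] ** 2
        in_edges = np.empty((N, 8), dtype=np.int32)
        in_edges[arr[:, 0], arr[:, 1]] = arr[:, 2]
        topo = cls(meta["side"], meta["rewiring_p"], in_edges, meta.get("seed"))
        topo.validate()
        return topo


def build_lattice(side: int) -> NetworkTopology:
    """Regular torus: every unit's in-edges are its 8 Moore neighbours."""
    if side < 3:
        raise ValueError("side must be >= 3 (Moore neighbourhood would "
                         "self-overlap)")
    rows, cols = np.divmod(np.arange(side * side), side)
    in_edges = np.empty((side * side, 8), dtype=np.int32)
    for c, (dr, dc) in enumerate(_MOORE):
        in_edges[:, c] = ((rows + dr) % side) * side + (cols + dc) % side
    return NetworkTopology(side, 0.0, in_edges)


def rewire(topo: NetworkTopology, p: float,
           rng: np.random.Generator) -> NetworkTopology:
    """Independently replace each in-edge with probability ``p`` by an edge
    from a uniformly chosen unit (no self-edges, no duplicates)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"rewiring probability must be in [0,1], got {p}")
    N = topo.n_neurons
    edges = topo.in_edges.copy()
    if p > 0.0:
        break_mask = rng.random(edges.shape) < p
        for i in np.flatnonzero(break_mask.any(axis=1)):
            current = set(edges[i])
            for c in np.flatnonzero(break_mask[i]):
                current.discard(int(edges[i, c]))
                while True:
                    new = int(rng.integers(N))
                    if new != i and new not in current:
                        break
                current.add(new)
                edges[i, c] = new
    return NetworkTopology(topo.side, p, edges, topo.seed)


def make_topology(side: int = 50, p: float = 0.0,
                  seed: int | None = None) -> NetworkTopology:
    """Build a lattice and rewire it; ``p`` may be a preset name."""
    if isinstance(p, str):
        p = PRESETS[p]
    topo = build_lattice(side)
    if p > 0.0:
        topo = rewire(topo, p, np.random.default_rng(seed))
    return NetworkTopology(topo.side, p, topo.in_edges, seed)
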