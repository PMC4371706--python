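"""Serial binary patterns (neural fingerprints, spontaneous patterns, stimuli).

A *neural fingerprint* is a fixed, ordered sequence of binary symbols: 1 marks
an action potential in a time step, 0 its absence.  Neurons identify the
source or meaning of an incoming signal by matching the recent history of a
channel against a set of such patterns, so the pattern itself is the atomic
unit of information everywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True)
class BinaryPattern:
    """An ordered bit sequence with a short identifying label.

    Parameters
    ----------
    bits
        Sequence of 0/1 integers, oldest-emitted bit first.  Length must be
        at least 1; the simulations explored here use 4-11 bits (default 5).
    label
        Short identifier used in traces and plots (e.g. ``"A"``,
        ``"spontaneous"``).
    """

    bits: tuple
    label: str = ""

    def __post_init__(self):
        bits = tuple(int(b) for b in self.bits)
        if len(bits) < 1:
            raise ValueError("pattern must contain at least one bit")
        if any(b not in (0, 1) for b in bits):
            raise ValueError(f"pattern bits must be 0/1, got {self.bits!r}")
        object.__setattr__(self, "bits", bits)

    @classmethod
    def from_string(cls, s: str, label: str = "") -> "BinaryPattern":
        """Build a pattern from a string such as ``"10101"``."""
        return cls(tuple(int(c) for c in s.strip()), label or s.strip())

    @property
    def n(self) -> int:
        """Pattern length (the fingerprint length of a simulation)."""
        return len(self.bits)

    @property
    def code(self) -> int:
        """Integer encoding with the oldest bit in the most significant
        position — identical to the value a shift register holds after the
        whole pattern has been shifted in (newest bit at bit 0)."""
        code = 0
        for b in self.bits:
            code = (code << 1) | b
        return code

    def bit_at(self, i: int) -> int:
        """Bit at position ``i mod n`` (the repeated-stimulus stream)."""
        return self.bits[i % self.n]

    def to_string(self) -> str:
        return "".join(str(b) for b in self.bits)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.label or 'pattern'}({self.to_string()})"


def common_length(patterns: Iterable[BinaryPattern]) -> int:
    """Return the shared length of ``patterns``; raise if lengths are mixed.

    A simulation uses a single fingerprint length ``n``: every local
    informational context is a shift register of exactly ``n`` bits, so
    patterns of mixed length cannot coexist.
    """
    lengths = {p.n for p in patterns}
    if not lengths:
        raise ValueError("no patterns given")
    if len(lengths) > 1:
        raise ValueError(f"patterns of mixed lengths {sorted(lengths)}; "
                         "a simulation requires a single fingerprint length")
    return lengths.pop()


def distinct_patterns(count: int, n: int, prefix: str = "S") -> list:
    """Generate ``count`` distinct ``n``-bit patterns for stimulation designs.

    Patterns start and end with 1 (so they are never confused with trailing
    silence) and differ in their interior bits.  Used for multi-stimulus
    experiments where the exact bit content is irrelevant by construction
    (network behaviour is independent of which distinct patterns are used).
    """
    if n < 2:
        raise ValueError("need n >= 2 for framed patterns")
    interior = n - 2
    if count > 2 ** interior:
        raise ValueError(f"cannot build {count} distinct framed {n}-bit patterns")
    pats = []
    for k in range(count):
        mid = tuple((k >> (interior - 1 - i)) & 1 for i in range(interior))
        pats.append(BinaryPattern((1,) + mid + (1,), f"{prefix}{k + 1}"))
    return pats
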