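"""Portable seeded random number generation.

The generator is SplitMix64 (Steele, Lea & Flood 2014): a 64-bit counter
advanced by the odd constant 0x9E3779B97F4A7C15 (the golden-ratio
increment), with a two-round xor-shift-multiply finaliser.  It is fully
specified here so that seeded tree simulation is bit-reproducible across
platforms and Python versions, which the platform RNG does not guarantee.
"""

from __future__ import annotations

import math

_MASK64 = (1 << 64) - 1
_GOLDEN = 0x9E3779B97F4A7C15


class SplitMix64:
    """Deterministic 64-bit RNG with a tiny, explicit state."""

    __slots__ = ("_state",)

    def __init__(self, seed: int) -> None:
        self._state = seed & _MASK64

    def next_uint64(self) -> int:
        self._state = (self._state + _GOLDEN) & _MASK64
        z = self._state
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
        return z ^ (z >> 31)

    def random(self) -> float:
        """Uniform float in [0, 1) with 53 bits of precision."""
        return (self.next_uint64() >> 11) * (2.0 ** -53)

    def exponential(self, mean: float = 1.0) -> float:
        """Exponential variate with the given mean (inverse-CDF method)."""
        return -mean * math.log1p(-self.random())

    def randrange(self, n: int) -> int:
        """Integer in [0, n).  Modulo bias is negligible for n << 2**64."""
        if n <= 0:
            raise ValueError("randrange() requires n >= 1")
        return self.next_uint64() % n

    def spawn(self) -> "SplitMix64":
        """Child generator seeded from this one's stream."""
        return SplitMix64(self.next_uint64())
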