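"""Parsing of the N:d(n-j)cis chain nomenclature.

A chain is CH3-(CH2)a-(CH=CH-CH2)d-(CH2)b-CH3 with N = a + 3d + b + 2
backbone carbons and d methylene-interrupted cis double bonds, the first of
which starts at carbon j counted from the methyl terminus C1.  Double bond
i (1-based) joins carbons (j + 3(i-1), j + 3(i-1) + 1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass


class ChainSpecError(ValueError):
    pass


_NAME_RE = re.compile(
    r"^(?:alk-)?(?P<N>\d+):(?P<d>\d+)"
    r"(?:\((?:n-)?(?P<j>\d+)\)(?P<geom>cis)?)?$"
)


@dataclass(frozen=True)
class ChainSpec:
    """Structural parameters of one hydrocarbon chain."""

    N: int
    d: int
    j: int | None  # first double-bond carbon from the methyl end; None if d == 0
    a: int
    b: int

    @property
    def name(self) -> str:
        if self.d == 0:
            return f"{self.N}:0"
        return f"{self.N}:{self.d}(n-{self.j})cis"

    @property
    def double_bond_positions(self) -> tuple[int, ...]:
        """1-based backbone bond indices p such that Cp=C(p+1) is a double bond."""
        if self.d == 0:
            return ()
        return tuple(self.j + 3 * i for i in range(self.d))

    def __post_init__(self):
        if self.N != self.a + 3 * self.d + self.b + 2:
            raise ChainSpecError(
                f"{self.N}:{self.d}: N = a + 3d + b + 2 violated "
                f"(a={self.a}, b={self.b})")
        if self.a < 0 or self.b < 0 or self.d < 0:
            raise ChainSpecError("a, b, d must be non-negative")
        if self.d > 0:
            if self.j is None:
                raise ChainSpecError("unsaturated chain requires (n-j)")
            if self.a != self.j - 2:
                raise ChainSpecError(f"a must equal j-2, got a={self.a}, j={self.j}")


def parse_chain_spec(name: str) -> ChainSpec:
    """Parse ``"18:1(n-9)cis"``-style names (an ``alk-`` prefix is accepted).

    Saturated chains are written ``"16:0"``.  Raises :class:`ChainSpecError`
    for malformed names or double-bond placements that do not fit the
    methylene-interrupted scheme.
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ChainSpecError(f"malformed chain name {name!r}")
    N, d = int(m.group("N")), int(m.group("d"))
    j = m.group("j")
    if d == 0:
        if j is not None:
            raise ChainSpecError(f"{name!r}: saturated chain must not carry (n-j)")
        if N < 2:
            raise ChainSpecError(f"{name!r}: need at least 2 carbons")
        # split the CH2 run arbitrarily; only a+b is defined for d=0
        return ChainSpec(N=N, d=d, j=None, a=N - 2, b=0)
    if j is None:
        raise ChainSpecError(f"{name!r}: unsaturated chain requires (n-j)")
    j = int(j)
    a = j - 2
    b = N - a - 3 * d - 2
    if a < 0:
        raise ChainSpecError(f"{name!r}: first double bond too close to the methyl end")
    if b < 0:
        raise ChainSpecError(f"{name!r}: {d} double bonds starting at n-{j} "
                             f"do not fit into {N} carbons")
    return ChainSpec(N=N, d=d, j=j, a=a, b=b)


#: The ten chains studied at T = 303 K.
STUDY_CHAINS = (
    "16:0", "18:0", "18:1(n-9)cis", "18:2(n-6)cis", "18:3(n-3)cis",
    "18:4(n-3)cis", "18:5(n-3)cis", "20:4(n-6)cis", "20:5(n-3)cis",
    "22:6(n-3)cis",
)
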