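"""Static three-point bending: the reference modulus-of-elasticity formula.

MOE is computed from a bending test as ``23 P l^3 / (108 b h^3 f)`` with the
load difference ``P`` in newtons and all lengths in millimetres, which yields
N/mm^2 (MPa); the result is reported in GPa.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BendingTest", "moe_static_bending"]


@dataclass(frozen=True)
class BendingTest:
    """One static bending measurement.

    Attributes
    ----------
    P : float
        Difference of upper and lower limit load, N.
    l : float
        Span between loading points, mm.
    b : float
        Breadth of the specimen, mm.
    h : float
        Height of the specimen, mm.
    f : float
        Mid-span deformation over the load interval, mm.
    """

    P: float
    l: float
    b: float
    h: float
    f: float

    def __post_init__(self) -> None:
        for name in ("P", "l", "b", "h", "f"):
            if not getattr(self, name) > 0:
                raise ValueError(f"BendingTest.{name} must be strictly positive")


def moe_static_bending(test: BendingTest) -> float:
    """Modulus of elasticity in static bending, GPa.

    ``MOE = 23 P l^3 / (108 b h^3 f)`` evaluates in MPa for N/mm inputs and is
    divided by 1000 to give GPa.
    """
    mpa = 23.0 * test.P * test.l**3 / (108.0 * test.b * test.h**3 * test.f)
    return mpa / 1000.0
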