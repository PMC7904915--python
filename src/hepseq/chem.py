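"""Elemental formulas and mass arithmetic for glycan chains.

A :class:`MolecularFormula` is an immutable CHNOS count vector with
monoisotopic and average masses derived from a single fixed atomic-mass
table.  All chain/fragment masses in the package are sums over these
formulas; glucuronic and iduronic acid are C5 epimers and therefore share
one formula, which is what makes composition-level mass reporting possible
for epimer-erased chains.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MolecularFormula",
    "MONOISOTOPIC_MASS",
    "AVERAGE_MASS",
    "PROTON_MASS",
    "WATER",
    "SULFATE",
    "OME_DELTA",
    "TWO_AB_DELTA",
    "mz",
]

# Fixed atomic-mass table (Da).  Monoisotopic: lightest stable isotope;
# average: IUPAC standard atomic weights.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}
AVERAGE_MASS = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}
PROTON_MASS = 1.00727646688


@dataclass(frozen=True)
class MolecularFormula:
    """CHNOS elemental composition with derived masses."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in ("C", "H", "N", "O", "S"):
            n = getattr(self, el)
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"element count {el}={n!r} must be a nonnegative integer")

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        return MolecularFormula(
            self.C + other.C, self.H + other.H, self.N + other.N,
            self.O + other.O, self.S + other.S,
        )

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        return MolecularFormula(
            self.C - other.C, self.H - other.H, self.N - other.N,
            self.O - other.O, self.S - other.S,
        )

    def __mul__(self, n: int) -> "MolecularFormula":
        return MolecularFormula(self.C * n, self.H * n, self.N * n, self.O * n, self.S * n)

    __rmul__ = __mul__

    def counts(self) -> dict[str, int]:
        return {"C": self.C, "H": self.H, "N": self.N, "O": self.O, "S": self.S}

    @property
    def monoisotopic_mass(self) -> float:
        return sum(n * MONOISOTOPIC_MASS[el] for el, n in self.counts().items())

    @property
    def average_mass(self) -> float:
        return sum(n * AVERAGE_MASS[el] for el, n in self.counts().items())

    def __str__(self) -> str:
        return "".join(
            f"{el}{n}" for el, n in self.counts().items() if n
        ) or "(empty)"


WATER = MolecularFormula(H=2, O=1)
#: net increment of one sulfate ester or N-sulfo group (-H + HSO3 = +SO3)
SULFATE = MolecularFormula(S=1, O=3)
#: reducing-end methyl ester (anomeric OH -> OMe): +CH2
OME_DELTA = MolecularFormula(C=1, H=2)
#: 2-aminobenzamide by reductive amination: +C7H8N2O (2-AB) - H2O + H2 = +C7H8N2
TWO_AB_DELTA = MolecularFormula(C=7, H=8, N=2)


def mz(mass: float, z: int) -> float:
    """m/z of the [M - zH]^z- ion observed in negative-mode ESI.

    Parameters
    ----------
    mass : neutral (mono- or average) mass in Da.
    z : number of deprotonations, >= 1.
    """
    if not isinstance(z, int) or z < 1:
        raise ValueError(f"charge z must be a positive integer, got {z!r}")
    return (mass - z * PROTON_MASS) / z
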