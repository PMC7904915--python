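"""Symbolic model of heparin/heparan-sulfate chains.

A chain is an ordered list of residues read from the nonreducing end (NRE,
position 1) to the reducing end (RE, position L), alternating between
uronate (GlcA/IdoA, or the 4,5-unsaturated dUA left by lyase cleavage, or
the epimer-erased HexUA used in sequence calls) and hexosamine (GlcN with an
N-acetyl, N-sulfo or free-amine substituent) residues.  All linkages are
1->4.  The text notation is::

    chain    := residue ("-" residue)* [re_mod]
    uronate  := ("GlcA" | "IdoA" | "dUA" | "HexUA") ["2S"]
    hexosamine := "GlcN" ("Ac" | "S" | "H") ["3S"] ["6S"]
    re_mod   := "(OMe)" | "(2AB)"

e.g. ``dUA2S-GlcNS6S-GlcA-GlcNS6S`` or ``GlcNS6S-GlcA-GlcNS3S6S-IdoA2S-GlcNS6S(OMe)``.

Disaccharide units pair a uronate with the hexosamine on its RE side and
carry one of the eight standard short codes (0S ... 2SNS6S) classifying the
unit by uronate 2-O-sulfation, N-substituent and 6-O-sulfation; units with
3-O-sulfation or a free amine fall outside the standard set and code as
``"other"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .chem import (
    OME_DELTA,
    SULFATE,
    TWO_AB_DELTA,
    WATER,
    MolecularFormula,
)

__all__ = [
    "Residue",
    "GlycanChain",
    "DisaccharideUnit",
    "CompositionVector",
    "GlycosidicFragment",
    "ChainParseError",
    "UnknownTokenError",
    "AlternationError",
    "MisplacedDeltaError",
    "IllegalSulfationError",
    "EpimerErasedError",
    "uronate",
    "hexosamine",
    "parse_chain",
    "format_chain",
    "disaccharide_units",
    "unit_code",
    "composition_of",
    "formula_of",
    "residue_formula",
    "fragment_ladder",
    "STANDARD_CODES",
    "CODE_PARTS",
]

URONATE_EPIMERS = ("GlcA", "IdoA", "dUA", "HexUA")
N_SUBSTITUENTS = ("NAc", "NS", "NH2")
RE_MODIFICATIONS = ("none", "OMe", "2AB")

#: the eight standard unsaturated-disaccharide codes, as
#: (uronate 2S, N-substituent, hexosamine 6S) -> code
CODE_TABLE = {
    (False, "NAc", False): "0S",
    (False, "NAc", True): "6S",
    (True, "NAc", False): "2S",
    (False, "NS", False): "NS",
    (True, "NAc", True): "2S6S",
    (False, "NS", True): "NS6S",
    (True, "NS", False): "2SNS",
    (True, "NS", True): "2SNS6S",
}
CODE_PARTS = {code: parts for parts, code in CODE_TABLE.items()}
STANDARD_CODES = tuple(CODE_TABLE.values())


class ChainParseError(ValueError):
    """Base class for chain-notation parse errors."""

    def __init__(self, message: str, token: str = "", position: int = 0):
        super().__init__(message)
        self.token = token
        self.position = position


class UnknownTokenError(ChainParseError):
    pass


class AlternationError(ChainParseError):
    pass


class MisplacedDeltaError(ChainParseError):
    pass


class IllegalSulfationError(ChainParseError):
    pass


class EpimerErasedError(ValueError):
    """Raised when a formula is requested for an epimer-erased (HexUA) chain."""


@dataclass(frozen=True)
class Residue:
    """One sugar residue.

    ``kind`` is ``"uronate"`` or ``"hexosamine"``.  Uronates carry an epimer
    label (``dUA`` = 4,5-unsaturated, ``HexUA`` = saturated with the epimer
    erased) and at most a 2-O-sulfate.  Hexosamines carry an N-substituent
    and any subset of {3S, 6S}.
    """

    kind: str
    epimer: str | None = None
    n_substituent: str | None = None
    sulfation: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sulfation", frozenset(self.sulfation))
        if self.kind == "uronate":
            if self.epimer not in URONATE_EPIMERS:
                raise ValueError(f"unknown uronate epimer {self.epimer!r}")
            if self.n_substituent is not None:
                raise ValueError("n_substituent is a hexosamine-only field")
            if not self.sulfation <= {"2S"}:
                raise ValueError(f"uronate sulfation must be a subset of {{2S}}, got {set(self.sulfation)}")
        elif self.kind == "hexosamine":
            if self.epimer is not None:
                raise ValueError("epimer is a uronate-only field")
            if self.n_substituent not in N_SUBSTITUENTS:
                raise ValueError(f"unknown N-substituent {self.n_substituent!r}")
            if not self.sulfation <= {"3S", "6S"}:
                raise ValueError(f"hexosamine sulfation must be a subset of {{3S, 6S}}, got {set(self.sulfation)}")
        else:
            raise ValueError(f"unknown residue kind {self.kind!r}")

    @property
    def is_uronate(self) -> bool:
        return self.kind == "uronate"

    @property
    def is_hexosamine(self) -> bool:
        return self.kind == "hexosamine"

    @property
    def is_unsaturated(self) -> bool:
        return self.epimer == "dUA"

    @property
    def descriptor(self) -> str:
        """Short label: e.g. ``IdoA2S``, ``GlcA``, ``NS6S``, ``NAc``."""
        if self.is_uronate:
            return self.epimer + ("2S" if "2S" in self.sulfation else "")
        sub = {"NAc": "NAc", "NS": "NS", "NH2": "NH2"}[self.n_substituent]
        return sub + ("3S" if "3S" in self.sulfation else "") + ("6S" if "6S" in self.sulfation else "")

    def token(self) -> str:
        if self.is_uronate:
            return self.descriptor
        return (
            "GlcN"
            + {"NAc": "Ac", "NS": "S", "NH2": "H"}[self.n_substituent]
            + ("3S" if "3S" in self.sulfation else "")
            + ("6S" if "6S" in self.sulfation else "")
        )


def uronate(epimer: str, s2: bool = False) -> Residue:
    return Residue("uronate", epimer=epimer, sulfation=frozenset({"2S"} if s2 else set()))


def hexosamine(n_substituent: str, s3: bool = False, s6: bool = False) -> Residue:
    sulf = set()
    if s3:
        sulf.add("3S")
    if s6:
        sulf.add("6S")
    return Residue("hexosamine", n_substituent=n_substituent, sulfation=frozenset(sulf))


@dataclass(frozen=True)
class GlycanChain:
    """Ordered residues, position 1 = nonreducing end."""

    residues: tuple[Residue, ...]
    re_modification: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(self.residues))
        if not self.residues:
            raise ValueError("a chain needs at least one residue")
        if self.re_modification not in RE_MODIFICATIONS:
            raise ValueError(f"unknown reducing-end modification {self.re_modification!r}")
        for i in range(1, len(self.residues)):
            if self.residues[i].kind == self.residues[i - 1].kind:
                raise AlternationError(
                    f"residues {i} and {i + 1} are both {self.residues[i].kind}s",
                    token=self.residues[i].token(),
                    position=i + 1,
                )
        for i, res in enumerate(self.residues, start=1):
            if res.is_unsaturated and i != 1:
                raise MisplacedDeltaError(
                    f"dUA allowed only at the nonreducing end, found at position {i}",
                    token=res.token(),
                    position=i,
                )

    @property
    def dp(self) -> int:
        """Degree of polymerization (residue count)."""
        return len(self.residues)

    @property
    def is_unsaturated(self) -> bool:
        """True when a 4,5-unsaturated uronate (the 232-nm chromophore) sits at the NRE."""
        return self.residues[0].is_unsaturated

    @property
    def has_concrete_epimers(self) -> bool:
        return all(r.epimer != "HexUA" for r in self.residues if r.is_uronate)

    def __str__(self) -> str:
        return format_chain(self)

    def with_re_modification(self, mod: str) -> "GlycanChain":
        return replace(self, re_modification=mod)


@dataclass(frozen=True)
class DisaccharideUnit:
    """(uronate, hexosamine) pair, uronate on the NRE side."""

    uronate: Residue
    hexosamine: Residue

    def __post_init__(self) -> None:
        if not (self.uronate.is_uronate and self.hexosamine.is_hexosamine):
            raise ValueError("a unit is a (uronate, hexosamine) pair")

    @property
    def code(self) -> str:
        if "3S" in self.hexosamine.sulfation or self.hexosamine.n_substituent == "NH2":
            return "other"
        return CODE_TABLE[(
            "2S" in self.uronate.sulfation,
            self.hexosamine.n_substituent,
            "6S" in self.hexosamine.sulfation,
        )]


TOKEN_URONATE = re.compile(r"^(GlcA|IdoA|dUA|HexUA)(2S)?$")
TOKEN_HEXOSAMINE = re.compile(r"^GlcN(Ac|S|H)(3S)?(6S)?$")
RE_MOD_SUFFIX = re.compile(r"\((OMe|2AB)\)$")


def _parse_token(token: str, position: int) -> Residue:
    m = TOKEN_URONATE.match(token)
    if m:
        return uronate(m.group(1), s2=m.group(2) is not None)
    m = TOKEN_HEXOSAMINE.match(token)
    if m:
        return hexosamine(
            {"Ac": "NAc", "S": "NS", "H": "NH2"}[m.group(1)],
            s3=m.group(2) is not None,
            s6=m.group(3) is not None,
        )
    # classify the failure for a precise error
    for base in URONATE_EPIMERS:
        if token.startswith(base):
            rest = token[len(base):]
            if rest and re.fullmatch(r"(2S|3S|6S)+", rest):
                raise IllegalSulfationError(
                    f"sulfation {rest!r} not allowed on uronate {base!r} (position {position})",
                    token=token, position=position,
                )
    if token.startswith("GlcN"):
        rest = token[4:]
        if "2S" in rest:
            raise IllegalSulfationError(
                f"2S not allowed on a hexosamine: {token!r} (position {position})",
                token=token, position=position,
            )
    raise UnknownTokenError(f"unknown residue token {token!r} at position {position}", token=token, position=position)


def parse_chain(text: str) -> GlycanChain:
    """Parse one chain from its text notation (see module docstring)."""
    s = text.split("#", 1)[0].strip()
    if not s:
        raise UnknownTokenError("empty chain string", token=text)
    re_mod = "none"
    m = RE_MOD_SUFFIX.search(s)
    if m:
        re_mod = m.group(1)
        s = s[: m.start()]
    tokens = s.split("-")
    residues = [_parse_token(tok, i) for i, tok in enumerate(tokens, start=1)]
    return GlycanChain(tuple(residues), re_modification=re_mod)


def format_chain(chain: GlycanChain) -> str:
    """Canonical text notation; inverse of :func:`parse_chain`."""
    s = "-".join(res.token() for res in chain.residues)
    if chain.re_modification != "none":
        s += f"({chain.re_modification})"
    return s


def disaccharide_units(chain: GlycanChain) -> tuple[list[DisaccharideUnit], list[Residue]]:
    """Decompose a chain into disaccharide units, pairing from the reducing end.

    Pairing steps back from the RE two residues at a time so that every unit
    is (uronate, hexosamine) — the unit the exolytic enzyme releases.
    Residues that cannot join a unit (the unpaired NRE residue of an
    odd-length chain, or an RE-terminal uronate) are returned separately,
    NRE-to-RE ordered.

    Returns ``(units NRE->RE, unpaired residues)``.
    """
    res = chain.residues
    units_rev: list[DisaccharideUnit] = []
    unpaired: list[Residue] = []
    i = len(res) - 1
    if i >= 0 and res[i].is_uronate:
        unpaired.append(res[i])
        i -= 1
    while i >= 1:
        units_rev.append(DisaccharideUnit(uronate=res[i - 1], hexosamine=res[i]))
        i -= 2
    if i == 0:
        unpaired.insert(0, res[0])
    return list(reversed(units_rev)), unpaired


def unit_code(chain: GlycanChain) -> str:
    """Code of a single-unit (DP2) chain."""
    units, unpaired = disaccharide_units(chain)
    if len(units) != 1 or unpaired:
        raise ValueError(f"chain {format_chain(chain)} is not a single disaccharide unit")
    return units[0].code


@dataclass
class CompositionVector:
    """Molar amounts per disaccharide code — the HPLC measurement abstraction."""

    amounts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, a in self.amounts.items():
            if a < 0:
                raise ValueError(f"negative molar amount for {code}: {a}")

    def total(self) -> float:
        return float(sum(self.amounts.values()))

    def fractions(self) -> dict[str, float]:
        t = self.total()
        if t == 0:
            return {c: 0.0 for c in self.amounts}
        return {c: a / t for c, a in self.amounts.items()}

    def codes(self) -> set[str]:
        return {c for c, a in self.amounts.items() if a > 0}

    def scaled(self, factor: float) -> "CompositionVector":
        return CompositionVector({c: a * factor for c, a in self.amounts.items()})

    def get(self, code: str, default: float = 0.0) -> float:
        return self.amounts.get(code, default)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompositionVector):
            return NotImplemented
        codes = set(self.amounts) | set(other.amounts)
        return all(self.get(c) == other.get(c) for c in codes)


def composition_of(
    fragments, *, with_leftovers: bool = False
):
    """Count DP2 fragments by disaccharide code.

    Only disaccharide (DP2) fragments enter the composition — as in the HPLC
    disaccharide analysis, where mono- and oligosaccharide peaks elute apart
    from the disaccharide standards.  Non-DP2 fragments go to a side channel,
    returned when ``with_leftovers`` is set.
    """
    amounts: dict[str, float] = {}
    leftovers: list[GlycanChain] = []
    for frag in fragments:
        if frag.dp == 2:
            units, unpaired = disaccharide_units(frag)
            if len(units) == 1 and not unpaired:
                code = units[0].code
                amounts[code] = amounts.get(code, 0.0) + 1.0
                continue
        leftovers.append(frag)
    vec = CompositionVector(amounts)
    if with_leftovers:
        return vec, leftovers
    return vec


# --- elemental formulas ---------------------------------------------------

_URONATE_RESIDUE = MolecularFormula(C=6, H=8, O=6)        # GlcA/IdoA/HexUA in-chain
_DELTA_RESIDUE = MolecularFormula(C=6, H=6, O=5)          # 4,5-unsaturated (= saturated - H2O)
_HEXOSAMINE_RESIDUE = MolecularFormula(C=6, H=11, N=1, O=4)  # GlcN in-chain, free amine
_ACETYL = MolecularFormula(C=2, H=2, O=1)

RE_MOD_DELTAS = {"none": MolecularFormula(), "OMe": OME_DELTA, "2AB": TWO_AB_DELTA}


def residue_formula(res: Residue) -> MolecularFormula:
    """In-chain (dehydrated) residue formula; chain = sum(residues) + H2O."""
    if res.is_uronate:
        f = _DELTA_RESIDUE if res.epimer == "dUA" else _URONATE_RESIDUE
    else:
        f = _HEXOSAMINE_RESIDUE
        if res.n_substituent == "NAc":
            f = f + _ACETYL
        elif res.n_substituent == "NS":
            f = f + SULFATE
    return f + len(res.sulfation) * SULFATE


def formula_of(chain: GlycanChain, *, sulfation_level: bool = False) -> MolecularFormula:
    """Elemental formula of a chain: residue formulas + terminal water + RE modification.

    GlcA and IdoA are isomers, so the epimer choice never changes the
    formula.  An epimer-erased (HexUA) chain is refused by default because it
    does not name a single structure; pass ``sulfation_level=True`` to get
    the formula its sulfation pattern determines, which is exact since
    saturated uronate epimers are isomeric.
    """
    if not sulfation_level and any(r.epimer == "HexUA" for r in chain.residues if r.is_uronate):
        raise EpimerErasedError(
            "epimer-erased chain has a defined formula only at composition level"
            " (pass sulfation_level=True for the sulfation-level formula)"
        )
    total = MolecularFormula()
    for res in chain.residues:
        total = total + residue_formula(res)
    return total + WATER + RE_MOD_DELTAS[chain.re_modification]


@dataclass(frozen=True)
class GlycosidicFragment:
    """One theoretical B/C/Y/Z glycosidic fragment of a chain."""

    label: str          # e.g. "B1", "C3", "Y2", "Z2"
    series: str         # B, C, Y or Z
    index: int          # residues retained on the fragment's side
    formula: MolecularFormula

    @property
    def monoisotopic_mass(self) -> float:
        return self.formula.monoisotopic_mass


def fragment_ladder(chain: GlycanChain, *, sulfation_level: bool = False) -> list[GlycosidicFragment]:
    """Theoretical glycosidic fragments (Domon–Costello B/C/Y/Z) at every bond.

    For a chain of L residues there are L-1 glycosidic bonds and 4 fragments
    per bond, so 4*(L-1) fragments.  At each bond, C + Y sum to the parent
    formula plus one water.
    """
    if not sulfation_level and any(r.epimer == "HexUA" for r in chain.residues if r.is_uronate):
        raise EpimerErasedError(
            "epimer-erased chain has defined fragment formulas only with sulfation_level=True"
        )
    L = chain.dp
    re_delta = RE_MOD_DELTAS[chain.re_modification]
    prefix = [MolecularFormula()]
    for res in chain.residues:
        prefix.append(prefix[-1] + residue_formula(res))
    total = prefix[-1]
    out: list[GlycosidicFragment] = []
    for i in range(1, L):
        c_formula = prefix[i] + WATER
        y_formula = (total - prefix[i]) + WATER + re_delta
        out.append(GlycosidicFragment(f"B{i}", "B", i, c_formula - WATER))
        out.append(GlycosidicFragment(f"C{i}", "C", i, c_formula))
        out.append(GlycosidicFragment(f"Y{L - i}", "Y", L - i, y_formula))
        out.append(GlycosidicFragment(f"Z{L - i}", "Z", L - i, y_formula - WATER))
    return out
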