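"""In-silico heparin-lyase digestion chemistry.

Heparin lyases cleave the glycosidic bond between a hexosamine and the
uronate on its reducing-end side by beta-elimination, leaving a
4,5-unsaturated uronate (dUA, the 232-nm chromophore) at the new
nonreducing end of the RE-side product.  No water is consumed, so elemental
composition is conserved across any cleavage.

Two action modes are modeled:

* ``endo`` — any internal susceptible linkage may be cut (Hepase I/II/III);
* ``exo``  — the enzyme threads the chain reducing-end first and releases
  the terminal disaccharide, i.e. only the linkage two residues from the RE
  is ever cut, and a reducing end blocked with 2-aminobenzamide abolishes
  all action.

Site susceptibility is a yes/no predicate over the uronate sulfation class
(2-O-sulfated vs unsulfated) plus a 3-O-sulfation block: a site is refused
when the hexosamine at the +2 subsite — the one that would appear in the
newly unsaturated disaccharide — carries 3S.  Epimer-level rate differences
(IdoA2S fastest, then GlcA, then IdoA) belong to :mod:`hepseq.kinetics`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from .glycan import GlycanChain, Residue, uronate as make_uronate

__all__ = [
    "EnzymeSpec",
    "AssayParams",
    "ExoDigest",
    "default_enzymes",
    "load_enzymes",
    "cleavable_linkages",
    "cleave",
    "digest_exo",
    "digest_endo_exhaustive",
    "ozone_treat",
    "label_2ab",
    "activity_from_a232",
]

URONATE_CLASSES = ("2S-uronate", "unsulfated-uronate")


@dataclass(frozen=True)
class EnzymeSpec:
    name: str
    mode: str  # "exo" | "endo"
    cleavable_uronate_classes: frozenset[str] = frozenset(URONATE_CLASSES)
    blocks_on_3S: bool = True
    min_substrate_dp: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "cleavable_uronate_classes", frozenset(self.cleavable_uronate_classes)
        )
        if self.mode not in ("exo", "endo"):
            raise ValueError(f"mode must be 'exo' or 'endo', got {self.mode!r}")
        if not self.cleavable_uronate_classes <= set(URONATE_CLASSES):
            raise ValueError(f"unknown uronate class in {set(self.cleavable_uronate_classes)}")
        floor = 4 if self.mode == "exo" else 3
        if self.min_substrate_dp < floor:
            raise ValueError(f"{self.mode} enzymes need min_substrate_dp >= {floor}")


def _uronate_class(res: Residue) -> str:
    return "2S-uronate" if "2S" in res.sulfation else "unsulfated-uronate"


def load_enzymes(source) -> dict[str, EnzymeSpec]:
    """Load enzyme specs from a YAML mapping (path, file object or string)."""
    if hasattr(source, "read"):
        raw = yaml.safe_load(source.read())
    else:
        text = str(source)
        if "\n" not in text and not text.lstrip().startswith("{"):
            with open(text) as fh:
                raw = yaml.safe_load(fh)
        else:
            raw = yaml.safe_load(text)
    out = {}
    for name, cfg in raw.items():
        out[name] = EnzymeSpec(
            name=name,
            mode=cfg["mode"],
            cleavable_uronate_classes=frozenset(cfg["cleavable_uronate_classes"]),
            blocks_on_3S=bool(cfg.get("blocks_on_3S", True)),
            min_substrate_dp=int(cfg["min_substrate_dp"]),
        )
    return out


def default_enzymes() -> dict[str, EnzymeSpec]:
    """The shipped Hepase I/II/III and exolytic heparinase specs."""
    ref = importlib.resources.files("hepseq.data").joinpath("enzymes.yaml")
    return load_enzymes(ref.read_text())


def _require_concrete(chain: GlycanChain) -> None:
    if not chain.has_concrete_epimers:
        raise ValueError(
            "digestion needs concrete uronate epimers; chain contains HexUA residues"
        )


def cleavable_linkages(chain: GlycanChain, enzyme: EnzymeSpec) -> list[int]:
    """Indices j of susceptible linkages (linkage j joins residues j and j+1).

    Requires residue j to be a hexosamine and residue j+1 a uronate whose
    sulfation class the enzyme accepts, minus the 3S block.  In exo mode only
    j = L-2 is ever eligible, and only on an unblocked reducing end of a
    chain at least ``min_substrate_dp`` long that terminates in a hexosamine.
    """
    _require_concrete(chain)
    L = chain.dp
    if L < enzyme.min_substrate_dp:
        return []
    if enzyme.mode == "exo":
        if chain.re_modification == "2AB":
            return []
        if not chain.residues[-1].is_hexosamine:
            return []
        candidates = [L - 2]
    else:
        candidates = list(range(1, L))
    sites = []
    for j in candidates:
        a = chain.residues[j - 1]
        b = chain.residues[j]
        if not (a.is_hexosamine and b.is_uronate):
            continue
        if b.is_unsaturated:
            continue
        if _uronate_class(b) not in enzyme.cleavable_uronate_classes:
            continue
        if enzyme.blocks_on_3S and j + 2 <= L:
            plus2 = chain.residues[j + 1]
            if plus2.is_hexosamine and "3S" in plus2.sulfation:
                continue
        sites.append(j)
    return sites


def cleave(chain: GlycanChain, j: int) -> tuple[GlycanChain, GlycanChain]:
    """Beta-eliminative cleavage at linkage j.

    Returns ``(nre_fragment, re_fragment)``: residues 1..j with a free
    reducing end, and residues j+1..L with residue j+1 converted to dUA
    (epimer erased, 2S retained) and the parent's RE modification kept.
    The dUA conversion is a net -H2O relative to a saturated uronate, which
    exactly balances the extra terminal water of the second fragment — no
    atoms are created or destroyed.
    """
    L = chain.dp
    if not 1 <= j <= L - 1:
        raise ValueError(f"linkage index {j} out of range for DP{L} chain")
    a, b = chain.residues[j - 1], chain.residues[j]
    if not (a.is_hexosamine and b.is_uronate):
        raise ValueError(f"linkage {j} is not a hexosamine->uronate bond")
    nre = GlycanChain(chain.residues[:j], re_modification="none")
    new_first = make_uronate("dUA", s2="2S" in b.sulfation)
    re_frag = GlycanChain((new_first,) + chain.residues[j + 1:], re_modification=chain.re_modification)
    return nre, re_frag


@dataclass
class ExoDigest:
    """Result of an exolytic digestion.

    ``ladder`` holds the parent and every intermediate of DP >= the enzyme's
    minimum substrate size — the UDP2k rungs used by the sequencing protocol.
    """

    released: list[GlycanChain]
    remainder: GlycanChain
    ladder: list[GlycanChain]


def digest_exo(
    chain: GlycanChain,
    enzyme: EnzymeSpec | None = None,
    steps: int | str = "to_completion",
) -> ExoDigest:
    """Sequential reducing-end disaccharide release.

    Repeatedly cleaves at j = L-2 while a susceptible site remains (and
    ``steps`` allows), recording released DP2 products in order of release.
    """
    if enzyme is None:
        enzyme = default_enzymes()["exoHep"]
    if enzyme.mode != "exo":
        raise ValueError(f"{enzyme.name} is not an exolytic spec")
    _require_concrete(chain)
    n_steps = float("inf") if steps == "to_completion" else int(steps)
    released: list[GlycanChain] = []
    ladder: list[GlycanChain] = [chain]
    current = chain
    while n_steps > 0:
        sites = cleavable_linkages(current, enzyme)
        if not sites:
            break
        current, product = cleave(current, sites[0])
        released.append(product)
        if current.dp >= enzyme.min_substrate_dp:
            ladder.append(current)
        n_steps -= 1
    return ExoDigest(released=released, remainder=current, ladder=ladder)


def digest_endo_exhaustive(
    chain: GlycanChain,
    enzymes,
    rng=None,
) -> list[GlycanChain]:
    """Cleave until no linkage is susceptible to any enzyme in the set.

    The product multiset is independent of internal cleavage order
    (beta-elimination at one site never creates or destroys susceptibility
    elsewhere except by shortening fragments below an enzyme's minimum DP,
    which only ever removes terminal sites last).  ``rng`` randomizes the
    order, used to exercise that confluence in tests.
    """
    if isinstance(enzymes, EnzymeSpec):
        enzymes = [enzymes]
    enzymes = list(enzymes)
    work = [chain]
    done: list[GlycanChain] = []
    while work:
        if rng is not None and len(work) > 1:
            idx = int(rng.integers(len(work)))
            current = work.pop(idx)
        else:
            current = work.pop()
        sites = sorted({s for e in enzymes for s in cleavable_linkages(current, e)})
        if not sites:
            done.append(current)
            continue
        j = sites[int(rng.integers(len(sites)))] if rng is not None else sites[0]
        nre, re_frag = cleave(current, j)
        work.extend([nre, re_frag])
    done.sort(key=lambda c: (c.dp, str(c)))
    return done


def ozone_treat(chain: GlycanChain) -> GlycanChain:
    """Ozonolytic removal of the unsaturated NRE residue.

    Yields the saturated chain of residues 2..L — one residue shorter, with
    a hexosamine at the new NRE and no 232-nm chromophore.
    """
    if not chain.residues[0].is_unsaturated:
        raise ValueError("no Δ4,5-unsaturated residue to remove")
    return GlycanChain(chain.residues[1:], re_modification=chain.re_modification)


def label_2ab(chain: GlycanChain) -> GlycanChain:
    """Reducing-end 2-aminobenzamide labeling; blocks all exolytic action."""
    if chain.re_modification != "none":
        raise ValueError(
            f"reducing end already carries {chain.re_modification!r}; cannot 2-AB label"
        )
    return chain.with_re_modification("2AB")


@dataclass(frozen=True)
class AssayParams:
    """232-nm activity-assay constants.

    epsilon_232 is the molar extinction coefficient of the unsaturated-uronate
    chromophore (M^-1 cm^-1); one unit (U) is 1 umol of dUA-containing product
    per minute.
    """

    epsilon_232: float = 3800.0
    path_length: float = 1.0  # cm
    volume: float = 1e-3      # L

    def __post_init__(self) -> None:
        if self.path_length <= 0:
            raise ValueError("path length must be positive")
        if self.volume <= 0:
            raise ValueError("assay volume must be positive")


def activity_from_a232(slope: float, params: AssayParams = AssayParams()) -> float:
    """Enzyme activity in U from an A232 slope (absorbance/min).

    Beer–Lambert: d[product]/dt = slope / (epsilon * path) in M/min; times the
    assay volume and 1e6 to convert mol to umol.
    """
    if slope < 0:
        raise ValueError("A232 slope must be >= 0")
    return slope / (params.epsilon_232 * params.path_length) * params.volume * 1e6
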