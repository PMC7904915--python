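"""Nested-ladder compositional sequencing of unsaturated oligosaccharides.

The sequencing protocol: partially digest an unsaturated 2n-mer with the
exolytic heparinase to prepare its nonreducing-end fragments UDP2k
(k = n .. 2), exhaustively digest each rung with Hepases I+II, and measure
each rung's disaccharide composition by HPLC.  Because the exolytic enzyme
trims exactly one disaccharide unit per step from the reducing end, the
composition difference between consecutive rungs identifies the unit at
each position from the RE inward.  The innermost tetrasaccharide is
disambiguated by ozonolysis: removing its unsaturated NRE residue and
re-digesting leaves only the unit at position 2, and the remaining count of
the tetrasaccharide composition is the NRE unit (position 1).

Cleavage erases the uronate epimer, so internal positions are reported as
``HexUA``/``HexUA2S`` and the NRE as ``dUA``; the call is a sequence of
disaccharide codes, not full structures.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from .glycan import (
    CODE_PARTS,
    CompositionVector,
    GlycanChain,
    disaccharide_units,
)

__all__ = [
    "AmbiguousError",
    "InconsistentLadderError",
    "LadderDataset",
    "PositionCall",
    "SequenceCall",
    "ValidationReport",
    "integerize",
    "deduce_sequence",
    "validate_call",
    "sequence_accuracy",
    "render_unit",
]

DEFAULT_TOL = 0.2


class AmbiguousError(ValueError):
    """Integerization could not settle on a single count vector within tol."""

    def __init__(self, message: str, candidates: list[dict[str, int]]):
        super().__init__(message)
        self.candidates = candidates


class InconsistentLadderError(ValueError):
    """A composition difference between rungs went negative."""

    def __init__(self, message: str, k: int):
        super().__init__(message)
        self.k = k


@dataclass
class LadderDataset:
    """Compositions of the UDP2k rungs (k = 2..n_units) plus the O3-trimmed
    tetrasaccharide composition; molar amounts or fractions — the sequencer
    uses ratios only."""

    n_units: int
    compositions: dict[int, CompositionVector]
    o3_udp4: CompositionVector
    provenance: str = "measured"

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError("need at least 2 disaccharide units")
        missing = [k for k in range(2, self.n_units + 1) if k not in self.compositions]
        if missing:
            raise ValueError(f"missing composition(s) for k = {missing}")


@dataclass
class PositionCall:
    position: int                  # 1 = NRE unit
    code: str | None               # standard code, or None
    status: str                    # "determined" | "ambiguous" | "undetermined"
    candidates: list[str] = field(default_factory=list)
    amount: float | None = None    # observed amount attached to undetermined calls


@dataclass
class SequenceCall:
    """Ordered unit calls with per-position status and the worst
    integerization deviation seen while reading the ladder."""

    units: list[PositionCall]
    residual: float

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def codes(self) -> list[str | None]:
        return [u.code for u in self.units]

    def sequence_string(self) -> str:
        parts = []
        for u in self.units:
            if u.status == "determined":
                parts.append(render_unit(u.code, nre=u.position == 1))
            elif u.status == "ambiguous":
                parts.append("[" + "|".join(u.candidates) + "]")
            else:
                parts.append("[?]")
        return "-".join(parts)


def render_unit(code: str, nre: bool = False) -> str:
    """Chain-notation rendering of a called unit: dUA-prefixed at the NRE,
    epimer-erased HexUA internally."""
    s2, nsub, s6 = CODE_PARTS[code]
    uro = ("dUA" if nre else "HexUA") + ("2S" if s2 else "")
    hexo = "GlcN" + {"NAc": "Ac", "NS": "S"}[nsub] + ("6S" if s6 else "")
    return f"{uro}-{hexo}"


def integerize(
    fractions: CompositionVector, k: int, tol: float = DEFAULT_TOL
) -> CompositionVector:
    """Convert a measured composition to unit counts summing to ``k``.

    Amounts are normalized, scaled by ``k`` and rounded.  If the rounded
    counts do not sum to ``k``, or any count deviates from its target by more
    than ``tol``, an :class:`AmbiguousError` carries the two closest
    candidate count vectors (closest by largest deviation, then total
    deviation).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    amounts = {c: a for c, a in fractions.amounts.items() if a > 0}
    total = sum(amounts.values())
    if total <= 0:
        raise ValueError("composition has no positive amounts")
    codes = sorted(amounts)
    targets = {c: amounts[c] / total * k for c in codes}
    naive = {c: round(targets[c]) for c in codes}

    def deviation(counts: dict[str, int]) -> tuple[float, float]:
        devs = [abs(targets[c] - counts[c]) for c in codes]
        return (max(devs), sum(devs))

    if sum(naive.values()) == k and deviation(naive)[0] <= tol:
        return CompositionVector({c: float(n) for c, n in naive.items() if n > 0})

    # enumerate candidate vectors: each count at floor or ceil of its target
    options = []
    for c in codes:
        lo = math.floor(targets[c])
        hi = math.ceil(targets[c])
        options.append(sorted({lo, hi}))
    candidates = []
    for combo in itertools.product(*options):
        if sum(combo) == k and all(n >= 0 for n in combo):
            candidates.append(dict(zip(codes, combo)))
    if not candidates:
        candidates = [naive]
    candidates.sort(key=deviation)
    best = candidates[0]
    if deviation(best)[0] <= tol and (
        len(candidates) == 1 or deviation(candidates[1])[0] > deviation(best)[0]
    ) and sum(best.values()) == k:
        # a unique admissible rounding exists even though naive rounding failed
        if deviation(best)[0] <= tol:
            return CompositionVector({c: float(n) for c, n in best.items() if n > 0})
    raise AmbiguousError(
        f"cannot settle counts for k={k} within tol={tol}; "
        f"best candidates {candidates[:2]}",
        candidates=[dict(c) for c in candidates[:2]],
    )


def _int_counts(vec: CompositionVector) -> dict[str, int]:
    return {c: int(round(a)) for c, a in vec.amounts.items() if a > 0}


def _max_dev(fractions: CompositionVector, counts: dict[str, int], k: int) -> float:
    fr = fractions.fractions()
    codes = set(fr) | set(counts)
    return max(abs(fr.get(c, 0.0) * k - counts.get(c, 0)) for c in codes)


def deduce_sequence(ladder: LadderDataset, tol: float = DEFAULT_TOL) -> SequenceCall:
    """Infer the ordered unit sequence from a nested ladder.

    Positions n..3 come from consecutive-rung composition differences,
    position 2 from the O3-trimmed tetrasaccharide, and position 1 from the
    tetrasaccharide composition minus the position-2 unit.  A difference
    that is not a clean unit vector demotes the affected position to
    ambiguous/undetermined rather than failing the whole call; a negative
    difference raises :class:`InconsistentLadderError`.
    """
    n = ladder.n_units
    ints: dict[int, dict[str, int] | None] = {}
    cand: dict[int, list[dict[str, int]]] = {}
    residual = 0.0
    for k in range(2, n + 1):
        try:
            vec = integerize(ladder.compositions[k], k, tol)
            ints[k] = _int_counts(vec)
            residual = max(residual, _max_dev(ladder.compositions[k], ints[k], k))
        except AmbiguousError as err:
            ints[k] = None
            cand[k] = err.candidates

    positions: dict[int, PositionCall] = {}

    def diff_codes(hi: dict[str, int], lo: dict[str, int], k: int) -> dict[str, int]:
        codes = set(hi) | set(lo)
        d = {c: hi.get(c, 0) - lo.get(c, 0) for c in codes}
        neg = [c for c, v in d.items() if v < 0]
        if neg:
            raise InconsistentLadderError(
                f"composition difference negative for {neg} at k={k}", k=k
            )
        return {c: v for c, v in d.items() if v > 0}

    for p in range(n, 2, -1):
        hi, lo = ints.get(p), ints.get(p - 1)
        if hi is None or lo is None:
            cands = set()
            for h in ([hi] if hi is not None else cand[p]):
                for l in ([lo] if lo is not None else cand[p - 1]):
                    try:
                        d = diff_codes(h, l, p)
                    except InconsistentLadderError:
                        continue
                    if sum(d.values()) == 1:
                        cands.add(next(iter(d)))
            positions[p] = PositionCall(p, None, "ambiguous", candidates=sorted(cands))
            continue
        d = diff_codes(hi, lo, p)
        # integerized rungs sum to their k, so d sums to 1 and is a unit vector
        code = next(iter(d))
        if code == "other":
            positions[p] = PositionCall(
                p, None, "undetermined", amount=ladder.compositions[p].get("other")
            )
        else:
            positions[p] = PositionCall(p, code, "determined")

    # position 2: the single unit surviving O3 trimming of the tetrasaccharide
    try:
        o3 = integerize(ladder.o3_udp4, 1, tol)
        o3_counts = _int_counts(o3)
        residual = max(residual, _max_dev(ladder.o3_udp4, o3_counts, 1))
        code2 = next(iter(o3_counts))
        if code2 == "other":
            positions[2] = PositionCall(2, None, "undetermined", amount=ladder.o3_udp4.get("other"))
        else:
            positions[2] = PositionCall(2, code2, "determined")
    except AmbiguousError as err:
        positions[2] = PositionCall(
            2, None, "ambiguous", candidates=sorted({c for d in err.candidates for c in d})
        )

    # position 1: tetrasaccharide composition minus the position-2 unit
    c4 = ints.get(2)
    if c4 is None:
        cands = set()
        for h in cand[2]:
            if positions[2].status == "determined":
                try:
                    d = diff_codes(h, {positions[2].code: 1}, 2)
                except InconsistentLadderError:
                    continue
                if sum(d.values()) == 1:
                    cands.add(next(iter(d)))
        positions[1] = PositionCall(1, None, "ambiguous", candidates=sorted(cands))
    elif positions[2].status == "determined":
        d = diff_codes(c4, {positions[2].code: 1}, 2)
        code1 = next(iter(d))
        if code1 == "other":
            positions[1] = PositionCall(1, None, "undetermined", amount=ladder.compositions[2].get("other"))
        else:
            positions[1] = PositionCall(1, code1, "determined")
    else:
        # position 2 unknown: if the tetrasaccharide holds exactly one
        # standard code besides a non-standard one, attribute it to the NRE
        std = {c: v for c, v in c4.items() if c != "other"}
        if sum(std.values()) == 1:
            positions[1] = PositionCall(1, next(iter(std)), "determined")
        else:
            positions[1] = PositionCall(1, None, "undetermined")

    return SequenceCall(units=[positions[p] for p in range(1, n + 1)], residual=residual)


@dataclass
class ValidationReport:
    """Per-rung residuals between a call's predicted compositions and the
    measured ladder, with rungs exceeding the threshold flagged — the
    signature of a labeling-efficiency or purity anomaly."""

    residuals: dict[int | str, float]
    flagged: list[int | str]
    threshold: float

    @property
    def consistent(self) -> bool:
        return not self.flagged


def validate_call(
    call: SequenceCall, ladder: LadderDataset, threshold: float = DEFAULT_TOL
) -> ValidationReport:
    """Recompute every rung composition from the call and report residuals."""
    residuals: dict[int | str, float] = {}
    flagged: list[int | str] = []
    for k in range(2, ladder.n_units + 1):
        prefix = call.units[:k]
        if any(u.status != "determined" for u in prefix):
            continue
        predicted: dict[str, int] = {}
        for u in prefix:
            predicted[u.code] = predicted.get(u.code, 0) + 1
        residuals[k] = _max_dev(ladder.compositions[k], predicted, k)
        if residuals[k] > threshold:
            flagged.append(k)
    pos2 = call.units[1]
    if pos2.status == "determined":
        residuals["o3_udp4"] = _max_dev(ladder.o3_udp4, {pos2.code: 1}, 1)
        if residuals["o3_udp4"] > threshold:
            flagged.append("o3_udp4")
    return ValidationReport(residuals=residuals, flagged=flagged, threshold=threshold)


@dataclass
class AccuracyReport:
    exact: bool
    per_position: list[bool]
    length_match: bool


def sequence_accuracy(truth: GlycanChain, call: SequenceCall) -> AccuracyReport:
    """Compare a call against the true chain up to epimer erasure.

    The truth's units are reduced to their codes (3S/free-amine units mask
    to "other", which no call can claim) before comparison; internal
    GlcA/IdoA information is unobservable to the method and is not scored.
    """
    if not (truth.dp % 2 == 0 and truth.is_unsaturated):
        raise ValueError("truth must be an unsaturated, even-DP chain")
    truth_units, _ = disaccharide_units(truth)
    truth_codes = [u.code for u in truth_units]
    length_match = len(truth_codes) == call.n_units
    per_position = [
        call.units[i].status == "determined" and call.units[i].code == truth_codes[i]
        for i in range(min(len(truth_codes), call.n_units))
    ]
    exact = length_match and all(per_position)
    return AccuracyReport(exact=exact, per_position=per_position, length_match=length_match)
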