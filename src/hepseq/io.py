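"""File formats: chain-notation files, composition/ladder CSVs, time-course
CSVs, rate-table YAML and JSON reports."""

from __future__ import annotations

import json
from dataclasses import asdict

import pandas as pd
import yaml

from .glycan import CompositionVector, GlycanChain, format_chain, parse_chain
from .kinetics import RateTable, SpeciesTimeCourse
from .sequencing import LadderDataset, SequenceCall

__all__ = [
    "read_chain_file",
    "write_chain_file",
    "read_composition_csv",
    "write_composition_csv",
    "read_ladder_csv",
    "write_ladder_csv",
    "write_timecourse_csv",
    "load_rate_table",
    "sequence_call_report",
]


def read_chain_file(path: str) -> list[GlycanChain]:
    """One chain per line; '#' starts a comment."""
    chains = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            try:
                chains.append(parse_chain(stripped))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from err
    return chains


def write_chain_file(path: str, chains) -> None:
    with open(path, "w") as fh:
        for chain in chains:
            fh.write(format_chain(chain) + "\n")


def write_composition_csv(path: str, vec: CompositionVector, fragment_dp: int = 2) -> None:
    df = pd.DataFrame(
        [{"fragment_dp": fragment_dp, "code": c, "molar_amount": a}
         for c, a in sorted(vec.amounts.items())]
    )
    df.to_csv(path, index=False)


def read_composition_csv(path: str) -> CompositionVector:
    df = pd.read_csv(path)
    return CompositionVector({str(r.code): float(r.molar_amount) for r in df.itertuples()})


def write_ladder_csv(path: str, ladder: LadderDataset) -> None:
    """Rows (fragment_dp, code, molar_amount); the O3-trimmed tetrasaccharide
    uses fragment_dp = 'o3_udp4'."""
    rows = []
    for k in sorted(ladder.compositions):
        for code, amount in sorted(ladder.compositions[k].amounts.items()):
            rows.append({"fragment_dp": 2 * k, "code": code, "molar_amount": amount})
    for code, amount in sorted(ladder.o3_udp4.amounts.items()):
        rows.append({"fragment_dp": "o3_udp4", "code": code, "molar_amount": amount})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ladder_csv(path: str) -> LadderDataset:
    df = pd.read_csv(path)
    compositions: dict[int, dict[str, float]] = {}
    o3: dict[str, float] = {}
    for row in df.itertuples():
        code, amount = str(row.code), float(row.molar_amount)
        tag = str(row.fragment_dp)
        if tag == "o3_udp4":
            o3[code] = o3.get(code, 0.0) + amount
        else:
            dp = int(float(tag))
            if dp % 2 != 0 or dp < 4:
                raise ValueError(f"fragment_dp must be even and >= 4 or 'o3_udp4', got {tag}")
            k = dp // 2
            compositions.setdefault(k, {})[code] = compositions.get(k, {}).get(code, 0.0) + amount
    if not compositions:
        raise ValueError(f"no ladder rows found in {path}")
    n = max(compositions)
    return LadderDataset(
        n_units=n,
        compositions={k: CompositionVector(v) for k, v in compositions.items()},
        o3_udp4=CompositionVector(o3),
        provenance="measured",
    )


def write_timecourse_csv(path: str, tc: SpeciesTimeCourse) -> None:
    rows = []
    for t_i, t in enumerate(tc.times):
        for s_i, chain in enumerate(tc.species):
            amount = float(tc.counts[t_i, s_i])
            if amount == 0:
                continue
            rows.append({
                "time": float(t),
                "species": format_chain(chain),
                "amount": amount,
                "dp": chain.dp,
                "a232_visible": chain.is_unsaturated,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_rate_table(path: str) -> RateTable:
    """Rate-table YAML: {base_rate: float, default: float, rules: [{match: {...}, rate: x}]}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = [
        ({k: (tuple(v) if isinstance(v, list) else v) for k, v in rule.get("match", {}).items()},
         float(rule["rate"]))
        for rule in raw.get("rules", [])
    ]
    kwargs = {}
    if "default" in raw:
        kwargs["default"] = float(raw["default"])
    if "base_rate" in raw:
        kwargs["base_rate"] = float(raw["base_rate"])
    return RateTable(rules=rules, **kwargs)


def sequence_call_report(call: SequenceCall, as_json: bool = False):
    """Machine-readable report of a sequence call."""
    payload = {
        "sequence": call.sequence_string(),
        "n_units": call.n_units,
        "residual": call.residual,
        "positions": [asdict(u) for u in call.units],
    }
    return json.dumps(payload, indent=2) if as_json else payload
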