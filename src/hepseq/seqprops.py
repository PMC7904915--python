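"""Small sequence-property utilities for enzyme gene/protein records.

Thin wrappers over Biopython: average protein mass, isoelectric point by
bisection on the Henderson–Hasselbalch net-charge function with the
Bjellqvist (ExPASy-convention) pKa set, and GC content; plus FASTA/GenBank
flat-file readers.  No network fetching — records are user-supplied files.
"""

from __future__ import annotations

from Bio import SeqIO
from Bio.SeqUtils import gc_fraction
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParam import ProteinAnalysis

__all__ = ["protein_properties", "gc_content", "read_records", "cds_sequences"]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def protein_properties(seq: str) -> dict:
    """Length, average molecular mass (Da) and isoelectric point of a protein.

    Only the standard 20-letter alphabet is accepted.
    """
    s = str(seq).upper().replace("*", "")
    bad = sorted(set(s) - STANDARD_AA)
    if bad:
        raise ValueError(f"non-standard amino acid letters: {bad}")
    if not s:
        raise ValueError("empty protein sequence")
    analysis = ProteinAnalysis(s)
    return {
        "length": len(s),
        "average_mass": analysis.molecular_weight(),
        "isoelectric_point": IsoelectricPoint(s).pi(min_=0.0, max_=14.0),
    }


def gc_content(seq: str, on_ambiguous: str = "error") -> float:
    """GC content in percent of an A/C/G/T sequence (case-insensitive).

    ``on_ambiguous``: "error" rejects any non-ACGT letter; "skip" drops them
    from both numerator and denominator.
    """
    s = str(seq).upper()
    bad = sorted(set(s) - set("ACGT"))
    if bad:
        if on_ambiguous == "error":
            raise ValueError(f"non-ACGT letters: {bad}")
        if on_ambiguous != "skip":
            raise ValueError("on_ambiguous must be 'error' or 'skip'")
        s = "".join(c for c in s if c in "ACGT")
    if not s:
        raise ValueError("no unambiguous nucleotides in sequence")
    return 100.0 * gc_fraction(s, ambiguous="remove")


def read_records(path: str, fmt: str | None = None) -> list:
    """Read FASTA or GenBank flat-file records (format inferred from the
    extension unless given)."""
    if fmt is None:
        lower = str(path).lower()
        fmt = "genbank" if lower.endswith((".gb", ".gbk", ".genbank")) else "fasta"
    return list(SeqIO.parse(path, fmt))


def cds_sequences(record) -> list[str]:
    """Nucleotide sequences of the CDS features of a GenBank record."""
    return [
        str(feat.extract(record.seq))
        for feat in getattr(record, "features", [])
        if feat.type == "CDS"
    ]
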