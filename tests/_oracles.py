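"""Independent brute-force oracles, written separately from the package.

Masses are computed from free-monosaccharide masses minus one water per
glycosidic bond (the package instead sums dehydrated residue formulas plus a
terminal water); protein mass/pI and GC are recomputed by direct summation,
counting and charge bisection.
"""

# hand-summed monoisotopic masses of the free monosaccharides (Da)
FREE_MONO = {
    "dUA": 176.03209,       # C6H8O6, 4,5-unsaturated uronic acid
    "GlcA": 194.04265,      # C6H10O7
    "IdoA": 194.04265,
    "HexUA": 194.04265,
    "GlcN": 179.07937,      # C6H13NO5
    "GlcNAc": 221.08994,    # C8H15NO6
}
SO3 = 79.95682
WATER = 18.01056
OME = 14.01565             # CH2
TWO_AB = 120.06875         # C7H8N2
PROTON = 1.00728


def chain_mass(chain) -> float:
    """Monoisotopic mass by free-monomer summation."""
    total = 0.0
    for res in chain.residues:
        if res.is_uronate:
            total += FREE_MONO[res.epimer]
        else:
            total += FREE_MONO["GlcNAc"] if res.n_substituent == "NAc" else FREE_MONO["GlcN"]
            if res.n_substituent == "NS":
                total += SO3
        total += SO3 * len(res.sulfation)
    total -= WATER * (chain.dp - 1)
    if chain.re_modification == "OMe":
        total += OME
    elif chain.re_modification == "2AB":
        total += TWO_AB
    return total


# --- protein properties ---------------------------------------------------

# average residue (dehydrated) masses, IUPAC standard atomic weights
AA_RESIDUE_AVG = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_AVG = 18.0153

# Bjellqvist pKa set (ExPASy convention): charged side chains, C-terminus,
# and residue-dependent N-terminal pKa
PK_NEG = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PK_POS = {"H": 5.98, "K": 10.0, "R": 12.0}
PK_CTERM_DEFAULT = 3.55
PK_CTERM = {"D": 4.55, "E": 4.75}
PK_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
PK_NTERM_DEFAULT = 7.5


def protein_mass(seq: str) -> float:
    return sum(AA_RESIDUE_AVG[a] for a in seq) + WATER_AVG


def protein_charge(seq: str, ph: float) -> float:
    pos = 10 ** (PK_NTERM.get(seq[0], PK_NTERM_DEFAULT)) / (
        10 ** (PK_NTERM.get(seq[0], PK_NTERM_DEFAULT)) + 10 ** ph
    )
    neg = 10 ** ph / (10 ** PK_CTERM.get(seq[-1], PK_CTERM_DEFAULT) + 10 ** ph)
    for aa in seq:
        if aa in PK_POS:
            pos += 10 ** PK_POS[aa] / (10 ** PK_POS[aa] + 10 ** ph)
        elif aa in PK_NEG:
            neg += 10 ** ph / (10 ** PK_NEG[aa] + 10 ** ph)
    return pos - neg


def protein_pi(seq: str) -> float:
    lo, hi = 0.0, 14.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if protein_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def gc_percent(seq: str) -> float:
    s = seq.upper()
    return 100.0 * sum(1 for c in s if c in "GC") / len(s)
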