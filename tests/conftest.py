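import pytest
from hypothesis import strategies as st

import hepseq as hs
from hepseq.glycan import STANDARD_CODES, hexosamine, uronate


@pytest.fixture(scope="session")
def fx():
    return hs.fixtures()


@pytest.fixture(scope="session")
def enzymes():
    return hs.default_enzymes()


# --- hypothesis strategies for random chains ------------------------------

_N_SUBS = st.sampled_from(["NAc", "NS", "NH2"])


@st.composite
def residue_pairs(draw, allow_3s=True, concrete=True):
    """(uronate, hexosamine) residue pair."""
    epimers = ["GlcA", "IdoA"] if concrete else ["GlcA", "IdoA", "HexUA"]
    uro = uronate(draw(st.sampled_from(epimers)), s2=draw(st.booleans()))
    hexo = hexosamine(
        draw(_N_SUBS),
        s3=draw(st.booleans()) if allow_3s else False,
        s6=draw(st.booleans()),
    )
    return uro, hexo


@st.composite
def glycan_chains(draw, min_units=1, max_units=6, allow_3s=True, concrete=True,
                  delta_start=None, allow_odd=True, allow_re_mod=True):
    n_units = draw(st.integers(min_units, max_units))
    residues = []
    for i in range(n_units):
        uro, hexo = draw(residue_pairs(allow_3s=allow_3s, concrete=concrete))
        residues.extend([uro, hexo])
    start_delta = draw(st.booleans()) if delta_start is None else delta_start
    if start_delta:
        first = residues[0]
        residues[0] = uronate("dUA", s2="2S" in first.sulfation)
    elif allow_odd and draw(st.booleans()):
        residues = residues[1:]  # odd chain starting at the hexosamine
    re_mod = draw(st.sampled_from(["none", "OMe", "2AB"])) if allow_re_mod else "none"
    return hs.GlycanChain(tuple(residues), re_modification=re_mod)


@st.composite
def standard_code_chains(draw, min_units=2, max_units=10):
    """Unsaturated even-DP chains built only from the 8 standard codes —
    the sequencing protocol's scope."""
    from hepseq.glycan import CODE_PARTS
    n_units = draw(st.integers(min_units, max_units))
    residues = []
    for i in range(n_units):
        code = draw(st.sampled_from(STANDARD_CODES))
        s2, nsub, s6 = CODE_PARTS[code]
        if i == 0:
            residues.append(uronate("dUA", s2=s2))
        else:
            residues.append(uronate(draw(st.sampled_from(["GlcA", "IdoA"])), s2=s2))
        residues.append(hexosamine(nsub, s6=s6))
    return hs.GlycanChain(tuple(residues))
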