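"""Digestion chemistry: site specificity, cleavage conservation, exolytic
release, ozonolysis, 2-AB blocking and assay arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings

import hepseq as hs
from hepseq.enzymes import AssayParams
from hepseq.glycan import unit_code

from conftest import glycan_chains


class TestCleavableLinkages:
    def test_p4_7_exo_site(self, fx, enzymes):
        assert hs.cleavable_linkages(fx["P4-7"], enzymes["exoHep"]) == [2]

    def test_2ab_blocks_exo(self, fx, enzymes):
        labeled = hs.label_2ab(fx["DP13"])
        assert hs.cleavable_linkages(labeled, enzymes["exoHep"]) == []

    def test_hepIII_resists_fully_sulfated_chain(self, fx, enzymes):
        assert hs.cleavable_linkages(fx["UDP14"], enzymes["hepIII"]) == []

    def test_specificity_containment(self, enzymes):
        """sites(HepI) U sites(HepIII) == sites(HepII) on 3S-free chains."""
        rng = np.random.default_rng(7)
        dist = hs.ChainDistribution()
        for _ in range(50):
            chain = hs.generate_chain(dist, int(rng.integers(2, 8)), seed=rng)
            s1 = set(hs.cleavable_linkages(chain, enzymes["hepI"]))
            s3 = set(hs.cleavable_linkages(chain, enzymes["hepIII"]))
            s2 = set(hs.cleavable_linkages(chain, enzymes["hepII"]))
            assert s1 | s3 == s2
            assert not s1 & s3

    def test_3s_blocks_site_with_3s_in_released_unit(self, fx, enzymes):
        # fondaparinux: only the RE-most site is usable; the site that would
        # release the 3S-bearing unit is blocked for every enzyme
        fon = fx["fondaparinux"]
        assert hs.cleavable_linkages(fon, enzymes["hepII"]) == [3]
        assert hs.cleavable_linkages(fon, enzymes["hepI"]) == [3]


class TestCleave:
    def test_fondaparinux_products(self, fx):
        nre, re_frag = hs.cleave(fx["fondaparinux"], 3)
        assert hs.format_chain(nre) == "GlcNS6S-GlcA-GlcNS3S6S"
        assert hs.format_chain(re_frag) == "dUA2S-GlcNS6S(OMe)"

    def test_p8_4_re_fragment_code(self, fx):
        _, re_frag = hs.cleave(fx["P8-4"], 6)
        assert unit_code(re_frag) == "2SNS6S"

    def test_invalid_linkage_rejected(self, fx):
        with pytest.raises(ValueError):
            hs.cleave(fx["P8-4"], 1)  # uronate->hexosamine bond
        with pytest.raises(ValueError):
            hs.cleave(fx["P8-4"], 8)

    @settings(max_examples=100, derandomize=True)
    @given(glycan_chains(concrete=True, min_units=2))
    def test_elemental_conservation(self, chain):
        """Beta-elimination neither consumes nor releases water."""
        sites = [
            j for j in range(1, chain.dp)
            if chain.residues[j - 1].is_hexosamine and chain.residues[j].is_uronate
            and not chain.residues[j].is_unsaturated
        ]
        parent = hs.formula_of(chain)
        for j in sites:
            nre, re_frag = hs.cleave(chain, j)
            assert hs.formula_of(nre) + hs.formula_of(re_frag) == parent


class TestDigestExo:
    def test_p8_4_ladder(self, fx):
        res = hs.digest_exo(fx["P8-4"])
        assert [unit_code(c) for c in res.released] == ["2SNS6S"] * 3
        assert hs.format_chain(res.remainder) == "dUA-GlcNS6S"
        assert [c.dp for c in res.ladder] == [8, 6, 4]

    def test_fondaparinux_single_release(self, fx):
        res = hs.digest_exo(fx["fondaparinux"])
        assert len(res.released) == 1
        assert hs.format_chain(res.released[0]) == "dUA2S-GlcNS6S(OMe)"
        assert res.remainder.dp == 3
        assert any("3S" in r.sulfation for r in res.remainder.residues)

    def test_2ab_blocked(self, fx):
        res = hs.digest_exo(hs.label_2ab(fx["DP13"]))
        assert res.released == []
        assert res.remainder == hs.label_2ab(fx["DP13"])

    def test_step_limit(self, fx):
        res = hs.digest_exo(fx["P8-4"], steps=1)
        assert len(res.released) == 1 and res.remainder.dp == 6

    @settings(max_examples=100, derandomize=True)
    @given(glycan_chains(concrete=True, min_units=2, allow_re_mod=False))
    def test_delta_placement_and_ladder_steps(self, chain):
        """Released products carry dUA at position 1 only; ladder DPs fall in
        steps of exactly 2; remainder keeps the parent's NRE saturation."""
        res = hs.digest_exo(chain)
        for prod in res.released:
            assert prod.dp == 2 and prod.residues[0].is_unsaturated
        dps = [c.dp for c in res.ladder]
        assert all(a - b == 2 for a, b in zip(dps, dps[1:]))
        assert res.remainder.is_unsaturated == chain.is_unsaturated


class TestDigestEndo:
    def test_dp3_digest(self, fx, enzymes):
        trimmed = hs.ozone_treat(hs.digest_exo(fx["P8-4"]).ladder[-1])
        frags = hs.digest_endo_exhaustive(trimmed, [enzymes["hepI"], enzymes["hepII"]])
        assert sorted(c.dp for c in frags) == [1, 2]

    def test_hepIII_digests_unsulfated_precursor(self, enzymes):
        chain = hs.parse_chain("-".join(["GlcA-GlcNAc"] * 5))
        frags = hs.digest_endo_exhaustive(chain, [enzymes["hepIII"]])
        vec = hs.composition_of(frags)
        # n-1 internal cleavages leave n-1 unsaturated 0S units + the NRE unit
        assert vec.amounts == {"0S": 5.0}

    def test_confluence_random_orders(self, enzymes):
        """Product multisets are independent of internal cleavage order."""
        rng = np.random.default_rng(11)
        dist = hs.ChainDistribution()
        hep12 = [enzymes["hepI"], enzymes["hepII"]]
        for _ in range(100):
            chain = hs.generate_chain(dist, int(rng.integers(2, 7)), seed=rng)
            ref = [hs.format_chain(c) for c in hs.digest_endo_exhaustive(chain, hep12)]
            shuffled = [
                hs.format_chain(c)
                for c in hs.digest_endo_exhaustive(chain, hep12, rng=rng)
            ]
            assert ref == shuffled


class TestOzoneAnd2AB:
    def test_ozone_trims_udp4(self, fx):
        udp4 = hs.digest_exo(fx["P8-4"]).ladder[-1]
        trimmed = hs.ozone_treat(udp4)
        assert hs.format_chain(trimmed) == "GlcNS6S-IdoA2S-GlcNS6S"
        assert not trimmed.is_unsaturated

    def test_ozone_udp14_gives_dp13(self, fx):
        assert hs.ozone_treat(fx["UDP14"]) == fx["DP13"]

    def test_ozone_requires_unsaturated_nre(self, fx):
        with pytest.raises(ValueError, match="4,5-unsaturated"):
            hs.ozone_treat(fx["DP13"])

    def test_double_labeling_forbidden(self, fx):
        labeled = hs.label_2ab(fx["DP13"])
        with pytest.raises(ValueError):
            hs.label_2ab(labeled)

    def test_2ab_mass_delta(self, fx):
        import _oracles
        plain = hs.formula_of(fx["DP13"]).monoisotopic_mass
        labeled = hs.formula_of(hs.label_2ab(fx["DP13"])).monoisotopic_mass
        assert labeled - plain == pytest.approx(_oracles.TWO_AB, abs=1e-3)


class TestActivityAssay:
    def test_beer_lambert_arithmetic(self):
        params = AssayParams(path_length=1.0, volume=1e-3)
        assert hs.activity_from_a232(0.0, params) == 0.0
        assert hs.activity_from_a232(0.0038, params) == pytest.approx(1e-3)

    def test_volume_linearity(self):
        one = hs.activity_from_a232(0.01, AssayParams(volume=1e-3))
        two = hs.activity_from_a232(0.01, AssayParams(volume=2e-3))
        assert two == pytest.approx(2 * one)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AssayParams(path_length=0.0)
        with pytest.raises(ValueError):
            AssayParams(volume=-1.0)
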