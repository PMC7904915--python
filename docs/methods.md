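# Methods

## Chain model and notation

A chain is a strictly alternating sequence of uronate and hexosamine
residues, position 1 at the nonreducing end (NRE), all linkages 1→4.
Uronates carry an epimer label — `GlcA`, `IdoA`, `dUA` (Δ4,5-unsaturated,
permitted only at position 1) or `HexUA` (saturated, epimer unknown — the
state left by sequence deduction) — and at most a 2-*O*-sulfate.
Hexosamines carry an N-substituent (`NAc`, `NS`, free amine) and any subset
of {3-*O*-, 6-*O*-sulfate}. Reducing-end state is `none`, `OMe`
(methyl glycoside) or `2AB` (2-aminobenzamide). Ring conformation and
anomeric configuration are out of scope.

Disaccharide units pair each uronate with the hexosamine on its RE side,
anchored at the reducing end (consistent with exolytic release); an
odd-length chain therefore has its unpaired residue at the NRE. The eight
standard codes map bijectively onto
{uronate 2S} × {NAc, NS} × {6S}; any unit containing 3-*O*-sulfate or a free
amine codes as `other`, since no disaccharide standard exists for it.

## Masses

Formulas are CHNOS counts over a fixed atomic table (monoisotopic and IUPAC
average). In-chain residue formulas are the dehydrated monosaccharides
(uronate C6H8O6; Δ-uronate C6H6O5; glucosamine C6H11NO4 plus C2H2O for
N-acetyl or SO3 for N-sulfo; +SO3 per O-sulfate); a chain is the residue sum
plus one water. Fixed modification deltas: OMe = +CH2; 2-AB reductive
amination = +C7H8N2 (the conventional +120.0687 Da label increment).
GlcA/IdoA are isomers, so epimer choice never changes a mass — which is why
a `HexUA`-containing call still has a well-defined "sulfation-level"
formula, offered behind an explicit flag. Negative-mode ions are
[M − zH]ᶻ⁻ with the proton mass 1.00727646688 Da. Theoretical glycosidic
fragments follow the Domon–Costello B/C/Y/Z scheme at every bond
(4(L−1) fragments; C + Y = parent + H2O at each bond).

## Digestion chemistry

Lyases cleave hexosamine→uronate bonds by β-elimination: the RE-side
fragment's first residue becomes `dUA` (2S retained, epimer erased), no
water is consumed, and elemental composition is conserved exactly — an
invariant the tests assert for every cleavage.

An `EnzymeSpec` is (mode, cleavable uronate classes, 3S blocking, minimum
substrate DP). Specificity is deliberately a yes/no predicate over two
uronate classes — 2-*O*-sulfated (GlcA2S/IdoA2S) vs unsulfated (GlcA/IdoA) —
with shipped defaults: Hepase I cleaves 2S-uronates only, Hepase III
unsulfated only ("prefers" hardened to "only" for exhaustive digests),
Hepase II both, and the exolytic enzyme both. Epimer-level preferences are
kinetic, not qualitative, and live in the rate table.

Design choices that were genuinely open:

- **3S block.** A site is refused when the hexosamine at the +2 subsite —
  the one that would appear in the newly unsaturated disaccharide — carries
  3-*O*-sulfate. This single rule reproduces both the resistance of
  3-*O*-sulfated substrates to all the lyases and the single-release
  behavior on the synthetic pentasaccharide, where the DP-4 minimum
  independently stops digestion as well; which rule is "the" operative stop
  there is experimentally indistinguishable, so both are implemented.
- **Exolytic rule.** Only the linkage two residues from the reducing end is
  eligible; the chain must end in a hexosamine, be at least DP4 (the
  smallest demonstrated substrate is a tetrasaccharide), and carry no 2-AB
  label. An `OMe` reducing end does **not** block (the methyl-glycoside
  pentasaccharide is cleaved once). Exolytic remainders of DP3 are inert;
  whether a real enzyme could trim a DP3 once more is not determinable from
  the available digests, so the conservative choice is made and surfaced in
  the remainder field.
- **Endolytic minimum DP 3** (a DP3 is demonstrably digestible by
  Hepases I+II).

Exhaustive endolytic digestion is confluent — the product multiset does not
depend on internal cleavage order — because susceptibility is local;
a property test verifies this on randomized cleavage orders.

Ozonolysis removes an unsaturated NRE residue (chain must start with
`dUA`), yielding a saturated, 232-nm-silent chain one residue shorter.
Activity arithmetic uses Beer–Lambert with ε₂₃₂ = 3800 M⁻¹cm⁻¹ and
1 U = 1 µmol unsaturated product/min.

## Kinetics

First-order hazards per susceptible site, enzyme in excess — the data
motivating the model are specific activities, not Michaelis–Menten
constants, so no saturation is modeled and the published tetrasaccharide
*conversion efficiencies* are deliberately not fitted (they are mutually
inconsistent with any single-rate first-order model scaled by the
activities).

The rate table keys on the cleaved uronate (epimer + 2S), the hexosamine of
the released unit, and the substrate's NRE unit (hexosamine descriptor and
uronate 2S state). The NRE-hexosamine term is needed because three of the
five structure-defined tetrasaccharide substrates differ *only* in that
residue; without it their measured activities (<1, 3.98, 24.22 vs 49.12,
79.49 U/mg) could not occupy distinct cells. Defaults: the five
tetrasaccharide contexts carry their printed activities ("<1" encoded 0.5),
with fallbacks IdoA2S 79.49 > GlcA2S 49.12 > GlcA 24.22 > IdoA 12
(unsulfated GlcA observed more susceptible than IdoA) and a generic default
of 10. Time unit: minutes, with the base rate normalized so the
trisulfated-GlcA tetrasaccharide cell (49.12) has a half-life of 1 min — an
arbitrary but documented scale; all orderings are scale-invariant.

Stochastic mode is an exact event-driven simulation (exponential waiting
times over per-chain hazards, species multiset bookkeeping); deterministic
mode integrates the linear rate equations over the finite species graph
discovered from the pool (LSODA, rtol 1e-10), conserving residues to
integrator tolerance. Both modes share one reaction graph, so their mean
trajectories agree within Monte-Carlo error — tested at a pool of 10⁴.

The **exolytic index** of a time course is the maximum over time of
(unsaturated material at DP > 2)/(all unsaturated material). Under the
exolytic rule a saturated parent can never place the chromophore on a
fragment larger than DP2, so the index is exactly 0; endolytic action makes
it positive mid-digestion. This operationalizes the size-exclusion
chromatography contrast between the wild-type enzyme and the
endolytically acting exit-tunnel variant.

## Ladder sequencing

`integerize` converts measured molar amounts to unit counts: normalize,
scale by the fragment's unit count k, round; accept if the counts sum to k
and no count deviates from its target by more than `tol`
(default 0.2 unit — wide enough to pass clean printed ratios, tight enough
to flag the anomalous rung ratios attributed to labeling efficiency or
purity). Otherwise an `AmbiguousError` carries the two closest admissible
count vectors. The sequencer is scale-invariant: only ratios matter.

`deduce_sequence` reads positions n…3 as the unique positive entry of
C₂ₖ − C₂₍ₖ₋₁₎ (a negative entry raises `InconsistentLadderError` naming the
level), position 2 from the ozonolysed tetrasaccharide, and position 1 as
the tetrasaccharide composition minus the position-2 unit. Failures are
local: an ambiguous integerization demotes the affected positions to
`ambiguous` (with candidates), an `other` difference to `undetermined`
(with the observed amount), and the rest of the call proceeds. Internal
calls render `HexUA(2S)` and the NRE `dUA(2S)` — cleavage erases the
epimer, and the method cannot recover it; accuracy scoring therefore
compares up to epimer erasure. `validate_call` recomputes every rung from
the call and flags rungs whose measured fractions deviate beyond the
threshold — it flags anomalies, never corrects them.

The generalization to any n ≥ 2 follows the protocol shape (the O₃ step is
always applied to the DP4 rung).

## Synthetic data

The chain generator samples disaccharide codes i.i.d. from a frequency map.
The default emulates the highly sulfated, Hepase III-resistant heparin
fraction used as the preferred substrate: 60% trisulfated (2SNS6S), 15%
NS6S, 10% 2SNS, 5% NS, 5% 6S, 3% 2S6S, 1% 0S, 1% 2S. 2-*O*-sulfated
uronates are IdoA with probability 0.9 and unsulfated ones with probability
0.3 (heparin-typical epimer bias); composition-level results are
epimer-invariant, so these two numbers are unobservable to the sequencer.
The octasaccharide fixture instantiates its internal 2S uronates as IdoA2S
for the same reason. The 13-mer fixture defaults to uniform trisulfated
units, with a mixed tri/disulfated variant echoing the two product peaks of
the degradation time course, without claiming the real (unknown) sequence.

The ladder simulator runs the actual protocol code paths (exolysis, per-rung
endolytic digestion, ozonolysis), then converts exact unit counts to
measured amounts by applying an optional per-code labeling-efficiency
factor and multiplicative lognormal noise of s.d. σ per species —
noise on amounts, not ratios, matching how peak areas are measured. σ = 0
reproduces the exact integers. The recovery benchmark reuses the same
chains and underlying noise draws across σ levels so each chain's success
is a threshold in σ and the aggregate curve is non-increasing by
construction of the comparison, not by luck.

What the generator does **not** emulate: chromatogram waveforms, retention
times, co-elution, MS spectral noise, or chains containing the linkage
region — so passing tests demonstrate correctness of the inference given
composition-level measurements, not robustness to peak-picking errors.

## Sequence-property utilities

Protein average mass and pI wrap Biopython's ProtParam/IsoelectricPoint
(Bjellqvist pKa set, ExPASy convention), with the pI bisection widened to
the full 0–14 range so strongly acidic or basic proteins are not clipped at
the library's default search bounds; GC content validates its alphabet and
counts over unambiguous bases. Records come from user-supplied FASTA or
GenBank flat files; there is no network fetching, so accession-dependent
numbers can only be checked against a locally provided record.

## Problem sizes and numerical notes

Test and acceptance workloads use pools of 10²–10³ chains, 500-chain
recovery benchmarks at DP8, and 200–500-seed completion-time samples —
sizes at which every stochastic check is comfortably resolved (the
discriminating statistics are zero-vs-positive indices and strict
orderings, not tight numerical estimates). Deterministic integration
tolerances are rtol 1e-10/atol 1e-12 on linear systems of at most a few
hundred species. Ties in integerization candidates are broken by largest
deviation then total deviation; exact ties raise ambiguity rather than
guessing.

## Known limitations

- Internal uronate epimers are unrecoverable by design (they require NMR or
  MS follow-up), and units outside the 8-code table can be located but not
  identified.
- Kinetic rates outside the five measured tetrasaccharide contexts are
  plausibility-ordered defaults, not measurements.
- The endolytic variant is emulated qualitatively (same specificity, endo
  mode); no claim is made about its absolute rates.
- The 2-AB block is modeled as absolute, and OMe as fully permissive; real
  reducing-end chemistry may be intermediate.
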