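"""Sequence-recovery rate of the ladder method under measurement noise.

Generates random heparin-like octasaccharides, simulates their ladders with
multiplicative lognormal noise on the HPLC molar amounts, and reports the
fraction recovered exactly (up to epimer erasure) at each noise level.
"""

import hepseq as hs

df = hs.recovery_benchmark(n_chains=200, n_units=4,
                           sigmas=(0.0, 0.02, 0.05, 0.1), seed=17)
print(df.to_string(index=False))
# sigma is the lognormal s.d. per measured species; zero noise recovers every
# chain, and recovery degrades monotonically as the noise approaches the
# integerization tolerance.
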