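"""Kimura two-parameter dating: divergence times, rates, and LTR ages.

Reproduces the dating chain from published mutation counts of an
orthologous wheat comparison, then dates a simulated LTR pair.
"""

from tescan import (
    divergence_time,
    k2p_distance,
    ltr_insertion_time,
    simulate_ltr_pair,
    substitution_rate,
)

# intron / low-copy partition: 76 transitions, 51 transversions, 10,397 bp
intron = k2p_distance(76, 51, 10_397)
t = divergence_time(intron.d, rate=5.5e-9)
print(f"intron/low-copy: d = {intron.d:.5f} -> divergence {t.time_my:.2f} MY "
      "at 5.5e-9 subs/site/year")

# TE partition: 431 transitions, 156 transversions, 16,430 aligned sites,
# anchored to the same 1.1 MY divergence
te = k2p_distance(431, 156, 16_430)
r = substitution_rate(te.d, 1.1e6)
print(f"TE partition: d = {te.d:.5f} -> rate {r.rate:.3g} subs/site/year "
      f"({r.rate / 5.5e-9:.1f}-fold the genic rate; ti:tv = {431 / 156:.1f})")

# LTR pair dating: the two LTRs are identical at insertion, so their
# divergence at the TE rate dates the insertion
pair, _ = simulate_ltr_pair(seed=3, ltr_length=2_000, age_years=0.8e6, rate=1.67e-8)
age = ltr_insertion_time(pair.seq_a, pair.seq_b, rate=1.67e-8)
print(f"simulated LTR pair (true age 0.80 MY): "
      f"{age.k2p.n_sites} sites, d = {age.k2p.d:.5f} -> {age.time_my:.2f} MY")
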