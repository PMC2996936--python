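"""Read the mutational footprint of methylation from an aligned ortholog pair.

Evolves two descendants of one ancestor for 1.1 million years with the
transition rate elevated 10-fold at potentially methylated sites (PMS:
any C or G in a CG, CHG, or CHH context) inside a "TE" stratum, then runs
the context classifier and mutation tally, and recovers the elevation
from the stratum contrast — the same inference that identifies TEs as
methylated in real orthologous alignments.
"""

from tescan import DivergenceSimConfig, evolve_pair, pms_frequencies, tally_mutations
from tescan.cmet import estimate_stratum_elevation

L = 100_000
te_stratum = (0, L // 2)  # first half is "TE", second half "intron/UTR"
cfg = DivergenceSimConfig(
    seed=21, ancestor_length=L, age_years=1.1e6,
    pms_transition_multiplier=10.0, methylated_strata=[te_stratum],
    indel_rate=0.0005,
)
pair, truth = evolve_pair(cfg)
print(f"aligned pair: {pair.columns} columns, "
      f"{truth['n_elevated_sites']} methylation-elevated ancestral sites")

tally = tally_mutations(pair)
freqs = pms_frequencies(tally)
for ctx in ("CG", "CHG", "CHH", "nonPMS"):
    print(f"  {ctx:>6}: {tally.sites[ctx]:>6} sites, "
          f"transitions {freqs.transition_pct[ctx]:.2f}%, "
          f"transversions {freqs.transversion_pct[ctx]:.2f}%")

te = tally_mutations(pair, columns=slice(*te_stratum))
genic = tally_mutations(pair, columns=slice(te_stratum[1], L))
m_hat = estimate_stratum_elevation(te, genic)
print(f"estimated transition-rate elevation in the TE stratum: {m_hat:.1f}x "
      f"(simulated: {cfg.pms_transition_multiplier:.0f}x)")
# The per-context transition percentages are the methylation proxy: they
# are far higher in the methylated stratum because 5-methylcytosine
# deaminates to thymine.
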