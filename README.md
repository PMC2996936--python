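# tescan

Small RNAs silence transposable elements (TEs). In large repeat-rich plant
genomes such as wheat, 21-nt small RNAs (sRNAs) guide post-transcriptional
silencing while 24-nt sRNAs direct DNA methylation of matching loci; the
methylated cytosines then deaminate to thymine at an elevated rate, so
methylation leaves a lasting mutational footprint — an excess of
transitions at potentially methylated sites (PMS). `tescan` is a toolkit
for tracing this whole chain in sequence data:

* **sRNA database** — merge adapter-trimmed sRNA libraries (FASTA/FASTQ,
  18–33 nt) into one abundance database of distinct sequences with
  per-library counts, and profile the bimodal 21/24-nt size structure.
* **Perfect-match scanning** — a scrolling window of every allowed frame
  size moves along a query sequence at 1-nt steps; every window matching a
  database sRNA (on either strand) is reported with coordinate, length,
  strand, and abundance. The output is defined to equal brute-force
  enumeration of all substrings.
* **TE profiling** — attribute hits to GFF3-annotated TEs and genes
  (innermost feature under nesting), compute abundance-weighted densities
  (counts/bp), 21/24-nt shares, decile position profiles with chi-square
  uniformity tests (with mirror-merging of duplicated LTR deciles), Welch
  density contrasts, repeat-database filtering, and correlations.
* **Methylation footprint** — classify every site of a pairwise-aligned
  ortholog pair as CG / CHG / CHH (H = A, T, or C; both strands; both C
  and G of a motif count as PMS) and tally transitions vs transversions
  per context, the *in silico* proxy for methylation.
* **K2P dating** — Kimura two-parameter distances
  `d = -½·ln[(1-2P-Q)·√(1-2Q)]` from transition/transversion proportions,
  with divergence times `T = d/(2r)`, substitution rates `r = d/(2T)`, and
  LTR-pair insertion ages (two LTRs are identical copies at insertion).
* **Synthetic data** — generators for nested-TE genomes with LTR/TIR
  substructure, sRNA libraries with realistic size/origin mixtures, and
  orthologous pairs evolved under exact K2P per-branch probabilities with
  methylation-elevated transitions, each with a machine-checkable truth
  record.

It is a library first: `import tescan` and the scripts in `examples/`
are the intended interface, with a thin `tescan` command-line wrapper for
the common file-to-file steps (`build-db`, `scan`, `profile`, `deciles`,
`cmet`, `k2p`, `ltr-age`, `simulate`).

## Worked example

Dating from substitution counts (see `examples/04_k2p_dating.py`):

```python
from tescan import k2p_distance, divergence_time, substitution_rate

intron = k2p_distance(76, 51, 10_397)        # ts, tv, aligned sites
t = divergence_time(intron.d, rate=5.5e-9)   # genic rate, subs/site/year
te = k2p_distance(431, 156, 16_430)
r = substitution_rate(te.d, 1.1e6)
```

prints

```
intron/low-copy: d = 0.01232 -> divergence 1.12 MY at 5.5e-9 subs/site/year
TE partition: d = 0.03677 -> rate 1.67e-08 subs/site/year (3.0-fold the genic rate; ti:tv = 2.8)
```

The intron/low-copy partition of an orthologous wheat comparison dates the
two genomes at ~1.1 million years of divergence; anchoring the TE
partition to that same age yields a TE substitution rate three-fold the
genic one — the signature of preferential TE methylation.

The methylation footprint end-to-end on synthetic data
(`examples/03_methylation_footprint.py`), with the transition rate
elevated 10-fold at PMS in a "TE" stratum, recovers the elevation from
the emitted alignment alone:

```
  CG:  12948 sites, transitions 4.29%, transversions 0.77%
  ...
estimated transition-rate elevation in the TE stratum: 9.4x (simulated: 10x)
```

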