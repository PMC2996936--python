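# Methods

This note records the models, conventions, and numerical choices behind
`tescan`, and what the synthetic-data generators do and do not emulate.

## sRNA database

Reads are normalized at ingestion (uppercase, U→T) so RNA- and
DNA-alphabet inputs unify; matching downstream is against DNA. Reads
outside the length window (default 18–33 nt, both bounds configurable) or
containing any non-A/C/G/T character are rejected and counted by reason.
Distinct-sequence identity is exact string equality after normalization —
no collapsing of near-identical reads. Size distributions are
abundance-weighted (each read counts once, not each distinct sequence);
per-library percentages are summarized across libraries as mean ± sample
standard deviation (ddof = 1).

## Perfect-match scanner

The scanner's contract is extensional: its output must equal brute-force
enumeration of every substring of every allowed length at every offset,
checked against the database (and, for minus-strand hits, against the
reverse complement). The implementation hashes database sequences per
length and slides one window per length at 1-nt increments; this is an
optimization only, and a property test holds it to the brute-force
definition on random inputs. Conventions:

* Coordinates are 0-based half-open internally; 1-based inclusive only at
  the GFF3 boundary.
* Both strands are scanned by default (sRNAs derive from both strands of
  a double-stranded precursor); a minus-strand hit is recorded at its
  forward-strand footprint. Single-strand mode is available.
* Every genomic occurrence contributes the sRNA's full database
  abundance; counts are not divided among loci.
* N in the query matches nothing.

## Feature attribution and profiling

A hit is assigned to the feature whose interval contains its full
footprint; under nesting the innermost (highest nesting level, then
smallest span) containing feature wins, reflecting that sRNA profiles
follow the most recent insertion. A hit straddling a boundary is assigned
by start containment and listed in a boundary report — the treatment of
straddling hits is a documented choice, not an external convention.
Features with zero hits are retained at zero density so group tests see
the whole population.

Decile profiles bin each hit by its **start offset** (not midpoint):
`bin = floor(10·(start − element_start)/element_length)`, clamped to
[0, 9]. Start-binning matches a 1-nt-increment scanner's natural
coordinate; it means a mirror-symmetric element yields terminal-decile
symmetry of total mass, not bin-by-bin mirror equality (a reflected hit's
start is `N − start − length`).

The uniformity test is a chi-square goodness of fit against the uniform
expectation. For elements with duplicated terminal repeats the `k`
leading deciles are averaged pairwise with their mirror deciles before
testing (the duplicated repeat makes those bins copies of one sequence
class), leaving `10 − k` categories and `df = 9 − k`: `k = 2` for
Copia-like elements (df 7), `k = 1` for Gypsy-like (df 8).

Group density contrasts use Welch's two-sample t-test on per-feature
counts/bp (no equal-variance assumption across TE populations); the
nesting-layer contrast uses the one-sided variant (top layer > buried
layers), since younger insertions are expected to attract more sRNA.
Correlations are Pearson's r with the two-sided t-transform p.

Repeat-database headers are parsed by the three-letter classification
code (RLC→Copia, RLG→Gypsy, RIX/RIL→LINE, DTC→CACTA, DTT→Mariner,
DTH→Harbinger, DTM→Mutator; leading R = class I, D = class II), a
four-letter species abbreviation mapped to genus, and a free-text
completeness keyword. Filtering applies complete → genus → no-ambiguous-
base in order, reporting survivors after each stage; records lacking the
metadata a stage needs fail that stage.

## Methylation-context classification

Potentially methylated sites (PMS) are every C or G participating in a
CG, CHG, or CHH motif (H = A, T, or C), on either strand. Conventions:

* Context neighbours come from each sequence's **own ungapped**
  coordinates — a methylation context is a property of a chromosome, not
  of an alignment column.
* Precedence CG > CHG > CHH resolves multi-motif membership (a C in
  `CGG` is CG), the standard plant-methylation convention.
* A CG or CHG motif marks both its C and its G columns; a motif in either
  sequence suffices, and the combined column class is the stronger of the
  two sequences' classes.
* A terminal C (or G) whose motif runs off the sequence end is classed
  CHH when at least one in-motif neighbour exists, else nonPMS;
  `exclude_terminal=True` drops such sites to nonPMS instead. An N as a
  context neighbour disqualifies the motifs it touches.
* Columns gapped in either sequence are excluded from all tallies;
  columns with N in either sequence are excluded into a separate bucket.

Each non-excluded mismatched column is counted exactly once as a
transition (A↔G, C↔T) or transversion in its combined context.

### Estimating the methylation elevation

A structural property of this classification deserves emphasis: every
transition column carries a C or a G in one sequence (A↔G has the G,
C↔T has the C), so transition columns are almost always PMS and the raw
PMS-vs-nonPMS mutation ratio is dominated by this confound rather than by
methylation (which is why such ratios come out ~10–20-fold while the
methylation effect between TE and genic strata is ~2–3-fold). The
estimable contrast is between strata. With `f` a stratum's transitions
per aligned site and `x` its C/G fraction (estimated by the PMS site
fraction), `f = c·(x·m + (1 − x))` in a methylated stratum against
`f = c` elsewhere, giving

    m̂ = (f_meth − (1 − x)·f_other) / (x·f_other)

implemented as `cmet.estimate_stratum_elevation`. On 100-kb simulated
pairs this recovers a 10-fold elevation within 15%.

## K2P dating

`d = −½·ln[(1 − 2P − Q)·√(1 − 2Q)]` with P, Q the transition and
transversion proportions per aligned non-gap site. Arguments of the
logarithm ≤ 0 (saturation) raise a typed `SaturationError` rather than
returning infinity. All datings use `d = 2·r·T`: orthologous regions and
the two LTRs of one retroelement both accumulate substitutions along two
independent lineages after the split/insertion. Rates are always explicit
parameters; the module ships two conventional defaults (5.5e-9 /site/year
for genic and low-copy context, 1.67e-8 for TE context) but hard-codes
neither into any result.

## Synthetic data

The generators provide the statistical structure the pipeline assumes,
not sequence realism:

* **Genome.** I.i.d. background with configurable GC; one random
  prototype per TE family (Copia/Gypsy with identical LTRs at birth,
  MITEs and CACTA elements with terminal inverted repeats, CACTA repeats
  starting with the CACTA motif); copies are the prototype with per-copy
  point mutations (default 2%), so multi-copy perfect matches arise
  naturally. Each TE inserts either into an existing TE (probability 0.3
  by default, nesting capped at depth 4, matching the deepest nesting
  observed in annotated wheat regions) or into non-genic background, with
  full coordinate shifting of everything downstream — exactly how real
  nested structures form. Defaults (60-kb background, 3 Copia, 2 Gypsy,
  2 CACTA, 6 MITEs, 3 genes) keep a laptop-scale region with every
  structural case present.
* **Library.** Read lengths follow the observed bimodal mixture (21-nt
  17.7%, 24-nt 28.7% of reads; remainder uniform over the window);
  Mariner/MITE-derived reads use a 21-nt-dominated mixture (54% / 27%)
  and other TE reads a 24-nt-dominated one, reproducing the size-class
  contrast between MITEs and the large retroelements. Origins default to
  50% TE subregions (LTRs/TIRs), 22% TE bodies, 3% genes, 15% intergenic,
  10% non-genomic background; genomic reads are exact substrings of
  either strand. Not emulated: sequencing error, expression dynamics,
  family sequence diversity beyond the per-copy mutations.
* **Divergence.** Two descendants evolve from one ancestor under the
  exact K2P per-branch substitution probabilities per site (so the K2P
  estimator is consistent on the output — required for the 5%-median
  LTR-age recovery check), with the transition rate multiplied by `m`
  (default 10, the conventional deamination elevation) at ancestor-PMS
  sites inside methylated strata. Default base rates are 3.3e-9
  transitions and 2.2e-9 transversions /site/year (total 5.5e-9 with the
  ti:tv ratio implied by the genic-partition counts) over 1.1 MY. Indels
  are independent per-site deletions per lineage (no insertions); columns
  deleted in both lineages are dropped. The emitted alignment is the true
  alignment — no aligner in the loop.

Truth records accompany every output. The divergence truth tallies are
computed by a regex-based enumerator kept structurally independent of the
`cmet` classifier, so the truth-equals-tally test is a genuine dual
route, and they equal the `cmet` tallies exactly (including under
deletions, since context is defined on ungapped coordinates).

Because the generators draw from these idealized models, passing tests
demonstrate correctness of the computations and internal consistency of
the pipeline on data with known structure — not robustness to alignment
error, sequencing artifacts, or TE family diversity in real libraries.

## Problem sizes

Default test-time sizes are chosen so every statistical check has
comfortable resolution on one CPU: scanner-oracle equivalence on 1,000
regions up to 5 kb; context-tally enumeration over all length-4
three-letter alignments plus random gapped alignments; type-I calibration
of the uniformity test over 1,000 simulated elements (600 counts each);
elevation recovery on 100-kb pairs; LTR-age recovery over 200 pairs of
2-kb LTRs.
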