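"""Methylation-context site classification and substitution tallying.

Given a pairwise alignment of orthologous sequences, every cytosine and
guanine is classified by its methylation context — CG, CHG or CHH (H = A,
T or C), read on the strand carrying the C — and every mismatched column
is tallied as a transition or transversion within the combined context of
the column.  Because methylated cytosines deaminate to thymine faster than
unmethylated ones, an excess of transitions at potentially methylated
sites (PMS) is a mutational footprint of methylation.

Conventions:

* Context neighbours are taken from each sequence's own ungapped
  coordinates (a methylation context belongs to a chromosome, not to an
  alignment column).
* Precedence CG > CHG > CHH: a C in ``CGG`` is CG, not CHG.
* A CG or CHG motif marks both its C and its G column with the class; a
  motif in either sequence suffices (the stronger class wins per column).
* A C (or G) whose motif runs off the end of the sequence is classed CHH
  when at least one in-motif neighbour exists, otherwise nonPMS; set
  ``exclude_terminal=True`` to drop such sites to nonPMS instead.
* Columns gapped in either sequence are excluded from everything; columns
  with N in either sequence are excluded into a separate bucket.  An N
  appearing only as a context neighbour disqualifies the motifs it touches
  (the site falls through to nonPMS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "AlignedPair",
    "SiteClass",
    "MutationTally",
    "ContextFrequencies",
    "CONTEXTS",
    "load_aligned_pair",
    "classify_ungapped",
    "classify_sites",
    "tally_mutations",
    "pms_frequencies",
    "estimate_stratum_elevation",
    "is_transition",
]

CONTEXTS = ("CG", "CHG", "CHH", "nonPMS")

# numeric class levels; larger = stronger under the CG > CHG > CHH precedence
NON_PMS, CHH, CHG, CG = 0, 1, 2, 3
GAP = -1
_LEVEL_NAME = {NON_PMS: "nonPMS", CHH: "CHH", CHG: "CHG", CG: "CG", GAP: "gap"}

_H = frozenset("ATC")  # H = not G
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class AlignedPair:
    """Two gapped sequences of equal length from a pairwise alignment."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"aligned sequences differ in length: "
                f"{len(self.seq_a)} vs {len(self.seq_b)}"
            )
        for name, s in (("seq_a", self.seq_a), ("seq_b", self.seq_b)):
            bad = set(s) - set("ACGTN-")
            if bad:
                raise ValueError(f"{name}: invalid characters {sorted(bad)}")
        for i, (a, b) in enumerate(zip(self.seq_a, self.seq_b)):
            if a == "-" and b == "-":
                raise ValueError(f"column {i} is gapped in both sequences")

    @property
    def columns(self) -> int:
        return len(self.seq_a)

    def swapped(self) -> "AlignedPair":
        return AlignedPair(self.id_b, self.id_a, self.seq_b, self.seq_a)


def load_aligned_pair(path: str | Path) -> AlignedPair:
    """Read an aligned FASTA with exactly two records of equal gapped length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 aligned records, found {len(records)}")
    return AlignedPair(records[0].id, records[1].id, str(records[0].seq), str(records[1].seq))


def classify_ungapped(seq: str, exclude_terminal: bool = False) -> np.ndarray:
    """Per-position context levels for one ungapped sequence.

    Returns an int8 array with NON_PMS/CHH/CHG/CG levels.  Motif logic,
    for a C at position i (and mirrored upstream for a G, which is a C on
    the reverse strand):

    ========  ==================================  =======================
    motif     condition                           columns marked
    ========  ==================================  =======================
    CG        s[i+1] == G                         i, i+1
    CHG       s[i+1] in H and s[i+2] == G         i, i+2
    CHH       s[i+1] in H and s[i+2] in H         i
    truncated any neighbour exists, no motif      i (CHH), unless
                                                  exclude_terminal
    ========  ==================================  =======================
    """
    n = len(seq)
    levels = np.zeros(n, dtype=np.int8)

    def bump(i: int, level: int) -> None:
        if level > levels[i]:
            levels[i] = level

    for i, base in enumerate(seq):
        if base == "C":
            n1 = seq[i + 1] if i + 1 < n else None
            n2 = seq[i + 2] if i + 2 < n else None
            if n1 == "G":
                bump(i, CG)
                bump(i + 1, CG)
            elif n1 in _H and n2 == "G":
                bump(i, CHG)
                bump(i + 2, CHG)
            elif n1 in _H and n2 in _H:
                bump(i, CHH)
            elif n1 in _H and n2 is None and not exclude_terminal:
                # motif truncated by the sequence end
                bump(i, CHH)
        elif base == "G":
            # C on the reverse strand: neighbours upstream, complemented.
            # Reverse-strand H means forward base in {T, A, G}.
            p1 = seq[i - 1] if i - 1 >= 0 else None
            p2 = seq[i - 2] if i - 2 >= 0 else None
            if p1 == "C":
                bump(i, CG)
                bump(i - 1, CG)
            elif p1 in ("T", "A", "G") and p2 == "C":
                bump(i, CHG)
                bump(i - 2, CHG)
            elif p1 in ("T", "A", "G") and p2 in ("T", "A", "G"):
                bump(i, CHH)
            elif p1 in ("T", "A", "G") and p2 is None and not exclude_terminal:
                bump(i, CHH)
    return levels


@dataclass
class SiteClass:
    """Per-column context levels for each sequence and combined."""

    levels_a: np.ndarray  # per alignment column; GAP where seq_a is gapped
    levels_b: np.ndarray
    combined: np.ndarray  # max of the two; GAP where either is gapped

    def combined_names(self) -> list[str]:
        return [_LEVEL_NAME[int(v)] for v in self.combined]


def _column_levels(gapped: str, exclude_terminal: bool) -> np.ndarray:
    cols = np.full(len(gapped), GAP, dtype=np.int8)
    idx = [i for i, ch in enumerate(gapped) if ch != "-"]
    ungapped = "".join(gapped[i] for i in idx)
    levels = classify_ungapped(ungapped, exclude_terminal)
    for pos, col in enumerate(idx):
        cols[col] = levels[pos]
    return cols


def classify_sites(pair: AlignedPair, exclude_terminal: bool = False) -> SiteClass:
    """Classify every alignment column of the pair.

    Contexts are computed on each sequence's own ungapped string; the
    combined class of a column is the stronger of the two (a motif in one
    genome suffices to call both columns of the motif potentially
    methylated).  Columns gapped in either sequence are gap-excluded.
    """
    a = _column_levels(pair.seq_a, exclude_terminal)
    b = _column_levels(pair.seq_b, exclude_terminal)
    combined = np.maximum(a, b)
    combined[(a == GAP) | (b == GAP)] = GAP
    return SiteClass(a, b, combined)


def is_transition(x: str, y: str) -> bool:
    """A <-> G or C <-> T (assumes x != y, both unambiguous)."""
    pair = {x, y}
    return pair <= _PURINES or pair <= _PYRIMIDINES


@dataclass
class MutationTally:
    """Aligned sites, transitions and transversions per context."""

    sites: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CONTEXTS})
    transitions: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CONTEXTS})
    transversions: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CONTEXTS})
    aligned_columns_used: int = 0
    columns_excluded_by_gap: int = 0
    columns_excluded_by_n: int = 0

    def pooled(self, contexts: tuple[str, ...] = ("CG", "CHG", "CHH")) -> tuple[int, int, int]:
        """(sites, transitions, transversions) summed over ``contexts``."""
        return (
            sum(self.sites[c] for c in contexts),
            sum(self.transitions[c] for c in contexts),
            sum(self.transversions[c] for c in contexts),
        )

    def __add__(self, other: "MutationTally") -> "MutationTally":
        out = MutationTally()
        for c in CONTEXTS:
            out.sites[c] = self.sites[c] + other.sites[c]
            out.transitions[c] = self.transitions[c] + other.transitions[c]
            out.transversions[c] = self.transversions[c] + other.transversions[c]
        out.aligned_columns_used = self.aligned_columns_used + other.aligned_columns_used
        out.columns_excluded_by_gap = (
            self.columns_excluded_by_gap + other.columns_excluded_by_gap
        )
        out.columns_excluded_by_n = self.columns_excluded_by_n + other.columns_excluded_by_n
        return out


def tally_mutations(
    pair: AlignedPair,
    site_class: SiteClass | None = None,
    columns: slice | None = None,
) -> MutationTally:
    """Tally sites and substitutions per combined context.

    Every non-gap, non-N column contributes one site to its combined
    context; a mismatch is counted as exactly one transition or
    transversion.  ``columns`` restricts the tally to an alignment-column
    window (for stratified analyses, e.g. TE vs intron/UTR footprints).
    """
    if site_class is None:
        site_class = classify_sites(pair)
    tally = MutationTally()
    rng = range(pair.columns) if columns is None else range(*columns.indices(pair.columns))
    for i in rng:
        a, b = pair.seq_a[i], pair.seq_b[i]
        if a == "-" or b == "-":
            tally.columns_excluded_by_gap += 1
            continue
        if a == "N" or b == "N":
            tally.columns_excluded_by_n += 1
            continue
        ctx = _LEVEL_NAME[int(site_class.combined[i])]
        tally.sites[ctx] += 1
        tally.aligned_columns_used += 1
        if a != b:
            if is_transition(a, b):
                tally.transitions[ctx] += 1
            else:
                tally.transversions[ctx] += 1
    return tally


@dataclass
class ContextFrequencies:
    """Percent transitions/transversions per site, per context, plus the
    pooled PMS vs nonPMS mutations-per-site contrast."""

    transition_pct: dict[str, float | None]
    transversion_pct: dict[str, float | None]
    pms_mutations_per_site: float | None
    nonpms_mutations_per_site: float | None

    @property
    def pms_fold_elevation(self) -> float | None:
        """Pooled PMS mutations/site over nonPMS mutations/site."""
        if not self.pms_mutations_per_site or not self.nonpms_mutations_per_site:
            return None
        return self.pms_mutations_per_site / self.nonpms_mutations_per_site


def estimate_stratum_elevation(
    tally_methylated: MutationTally, tally_other: MutationTally
) -> float:
    """Estimate the methylation transition-rate multiplier between strata.

    Any transition column carries a C or G in one sequence, so transitions
    from ancestral A/T sites are classified into PMS contexts alongside
    the genuinely methylation-elevated C/G transitions; a raw PMS
    transition-frequency ratio between strata therefore converges to
    (m + 1 - x)/1 terms rather than m.  With f the per-site transition
    frequency of a stratum and x the fraction of sites that are C/G
    (estimated by the PMS site fraction), f = c (x m + (1 - x)) in the
    methylated stratum and f = c in the other, giving

        m_hat = (f_meth - (1 - x) f_other) / (x f_other)
    """

    def freq(t: MutationTally) -> tuple[float, float]:
        sites = sum(t.sites.values())
        if sites == 0:
            raise ValueError("empty stratum tally")
        ts = sum(t.transitions.values())
        pms = t.pooled()[0]
        return ts / sites, pms / sites

    f_m, x_m = freq(tally_methylated)
    f_o, x_o = freq(tally_other)
    if f_o == 0:
        raise ValueError("no transitions in the reference stratum")
    x = (x_m + x_o) / 2.0
    return (f_m - (1.0 - x) * f_o) / (x * f_o)


def pms_frequencies(tally: MutationTally) -> ContextFrequencies:
    """Per-context substitution percentages; zero-site contexts report None."""
    ts_pct: dict[str, float | None] = {}
    tv_pct: dict[str, float | None] = {}
    for c in CONTEXTS:
        n = tally.sites[c]
        ts_pct[c] = 100.0 * tally.transitions[c] / n if n else None
        tv_pct[c] = 100.0 * tally.transversions[c] / n if n else None
    pms_sites, pms_ts, pms_tv = tally.pooled()
    pms_rate = (pms_ts + pms_tv) / pms_sites if pms_sites else None
    non_n = tally.sites["nonPMS"]
    non_rate = (
        (tally.transitions["nonPMS"] + tally.transversions["nonPMS"]) / non_n
        if non_n
        else None
    )
    return ContextFrequencies(ts_pct, tv_pct, pms_rate, non_rate)
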