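"""Synthetic inputs with the statistical structure of repeat-rich cereal genomes.

Three generators cover the pipeline end to end with no external data:

* :func:`simulate_genome` — a background sequence into which TE copies
  (LTR retroelements with duplicated LTRs, MITEs and CACTA elements with
  terminal inverted repeats) and genes are inserted, with nested TE
  insertions up to a configurable depth (real wheat BAC regions show up
  to four layers).
* :func:`simulate_srna_library` — reads with a bimodal 21/24-nt length
  mixture drawn preferentially from TE subregions (LTRs, TIRs), with a
  21-nt bias for Mariner/MITE-derived reads, plus non-genomic background.
* :func:`evolve_pair` — two descendants of one ancestor evolved for T
  years under exact Kimura two-parameter per-branch substitution
  probabilities, with the transition rate multiplied by ``m`` at
  potentially methylated sites inside methylated strata (the mutational
  footprint of cytosine methylation), and per-site deletions emitted as
  '-' in the true alignment.

Every generator is deterministic for a fixed seed and returns a truth
record alongside its output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cmet import AlignedPair, MutationTally, classify_ungapped, is_transition
from .match_scan import GenomicRegion, reverse_complement
from .srna_db import SmallRNARead
from .te_profile import FeatureAnnotation, SubFeature

__all__ = [
    "TEFamilySpec",
    "GenomeSimConfig",
    "LibrarySimConfig",
    "DivergenceSimConfig",
    "simulate_genome",
    "simulate_srna_library",
    "evolve_pair",
    "simulate_ltr_pair",
    "default_genome_config",
    "default_library_config",
    "write_genome_fasta",
    "write_gff3",
    "write_reads_fastq",
    "write_aligned_fasta",
]

_SUPERFAMILY_CLASS = {
    "Copia": "I", "Gypsy": "I", "LINE": "I",
    "CACTA": "II", "Mariner": "II", "Harbinger": "II", "Mutator": "II",
}

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base with probability ``rate`` (uniform to the others)."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


@dataclass
class TEFamilySpec:
    """How to build copies of one TE family.

    ``ltr_length`` applies to Copia/Gypsy-like elements (identical LTRs at
    both ends); ``tir_length`` to Mariner/MITE and CACTA-like elements
    (terminal inverted repeats; CACTA repeats start with the CACTA motif).
    """

    superfamily: str
    family: str
    count: int
    length_range: tuple[int, int]
    ltr_length: int | None = None
    tir_length: int | None = None


@dataclass
class GenomeSimConfig:
    seed: int
    genome_length: int = 60_000
    te_catalogue: Sequence[TEFamilySpec] = ()
    nesting_probability: float = 0.3
    max_nesting_depth: int = 4
    gene_count: int = 3
    gene_length_range: tuple[int, int] = (1_000, 2_500)
    gc_content: float = 0.45
    per_copy_mutation_rate: float = 0.02


def default_genome_config(seed: int) -> GenomeSimConfig:
    """A small repeat-rich region: nested LTR elements, MITEs, a CACTA, genes."""
    catalogue = [
        TEFamilySpec("Copia", "Angela", 3, (2_400, 3_200), ltr_length=300),
        TEFamilySpec("Gypsy", "Sabrina", 2, (2_800, 3_600), ltr_length=400),
        TEFamilySpec("CACTA", "Caspar", 2, (1_200, 1_800), tir_length=30),
        TEFamilySpec("Mariner", "Thalos", 6, (160, 260), tir_length=70),
    ]
    return GenomeSimConfig(seed=seed, te_catalogue=catalogue)


def _build_prototype(
    rng: np.random.Generator, spec: TEFamilySpec, gc: float
) -> tuple[str, list[tuple[str, int, int]]]:
    """One family template plus its subfeature layout (element coordinates)."""
    total = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    subs: list[tuple[str, int, int]] = []
    if spec.ltr_length:
        L = spec.ltr_length
        total = max(total, 2 * L + 50)
        ltr = _random_seq(rng, L, gc)
        internal = _random_seq(rng, total - 2 * L, gc)
        seq = ltr + internal + ltr  # LTRs identical at birth
        subs = [("LTR5", 0, L), ("internal", L, total - L), ("LTR3", total - L, total)]
    elif spec.tir_length:
        L = spec.tir_length
        total = max(total, 2 * L + 10)
        tir = _random_seq(rng, L, gc)
        if spec.superfamily == "CACTA":
            tir = "CACTA" + tir[5:]
        internal = _random_seq(rng, total - 2 * L, gc)
        seq = tir + internal + reverse_complement(tir)
        subs = [("TIR5", 0, L), ("internal", L, total - L), ("TIR3", total - L, total)]
    else:
        seq = _random_seq(rng, total, gc)
    return seq, subs


def _shift_features(features: list[FeatureAnnotation], x: int, m: int) -> None:
    """Re-coordinate features after inserting ``m`` bp at position ``x``."""
    for f in features:
        new_subs = []
        for sf in f.subfeatures:
            if sf.start >= x:
                new_subs.append(SubFeature(sf.kind, sf.start + m, sf.end + m))
            elif sf.start < x < sf.end:
                new_subs.append(SubFeature(sf.kind, sf.start, sf.end + m))
            else:
                new_subs.append(sf)
        f.subfeatures = new_subs
        if f.start >= x:
            f.start += m
            f.end += m
        elif f.start < x < f.end:
            f.end += m


def simulate_genome(
    config: GenomeSimConfig,
) -> tuple[GenomicRegion, list[FeatureAnnotation], dict]:
    """Build an annotated region by successive insertions into background.

    Genes are placed first; TE copies are then inserted one at a time,
    each with probability ``nesting_probability`` into an existing TE
    (raising the nesting level, capped at ``max_nesting_depth``) and
    otherwise into non-genic background.  Later insertions shift the
    coordinates of everything downstream, exactly as real nested
    insertions do.  Each copy is the family prototype with per-copy point
    mutations, so multi-copy perfect matches arise naturally.
    """
    rng = np.random.default_rng(config.seed)
    genome = _random_seq(rng, config.genome_length, config.gc_content)
    features: list[FeatureAnnotation] = []
    region_id = f"simregion_seed{config.seed}"

    for g in range(config.gene_count):
        glen = int(rng.integers(*config.gene_length_range))
        for _ in range(200):
            x = int(rng.integers(0, len(genome) + 1))
            if not any(f.start < x < f.end for f in features):
                break
        else:
            raise RuntimeError("could not place a gene in free background")
        gene_seq = _random_seq(rng, glen, config.gc_content)
        genome = genome[:x] + gene_seq + genome[x:]
        _shift_features(features, x, glen)
        features.append(
            FeatureAnnotation(
                feature_id=f"gene_{g + 1}", region_id=region_id,
                start=x, end=x + glen, category="gene",
            )
        )

    prototypes = {
        spec.family: _build_prototype(rng, spec, config.gc_content)
        for spec in config.te_catalogue
    }
    copy_no = 0
    for spec in config.te_catalogue:
        proto_seq, proto_subs = prototypes[spec.family]
        for c in range(spec.count):
            copy_no += 1
            seq = _mutate(rng, proto_seq, config.per_copy_mutation_rate)
            fid = f"{spec.family}_{c + 1}"
            nestable = [
                f for f in features
                if f.category == "TE" and f.nesting_level < config.max_nesting_depth
                and f.length > 2
            ]
            parent: FeatureAnnotation | None = None
            if nestable and rng.random() < config.nesting_probability:
                parent = nestable[int(rng.integers(len(nestable)))]
                x = int(rng.integers(parent.start + 1, parent.end))
            else:
                for _ in range(200):
                    x = int(rng.integers(0, len(genome) + 1))
                    if not any(
                        f.category == "gene" and f.start < x < f.end for f in features
                    ):
                        break
                else:
                    raise RuntimeError("could not place a TE outside genes")
            genome = genome[:x] + seq + genome[x:]
            _shift_features(features, x, len(seq))
            features.append(
                FeatureAnnotation(
                    feature_id=fid, region_id=region_id,
                    start=x, end=x + len(seq), category="TE",
                    te_class=_SUPERFAMILY_CLASS.get(spec.superfamily, "unknown"),
                    superfamily=spec.superfamily, family=spec.family,
                    nesting_level=(parent.nesting_level + 1) if parent else 0,
                    parent_id=parent.feature_id if parent else None,
                    subfeatures=[
                        SubFeature(kind, x + s, x + e) for kind, s, e in proto_subs
                    ],
                )
            )
    truth = {
        "seed": config.seed,
        "insertions": [
            {
                "feature_id": f.feature_id, "category": f.category,
                "superfamily": f.superfamily, "family": f.family,
                "start": f.start, "end": f.end,
                "nesting_level": f.nesting_level, "parent_id": f.parent_id,
            }
            for f in features
        ],
    }
    region = GenomicRegion(region_id, genome)
    return region, features, truth


# --- sRNA library ---------------------------------------------------------


@dataclass
class LibrarySimConfig:
    """Read-generation conditions.

    Length shares default to the observed bimodal peaks (21-nt 17.7%,
    24-nt 28.7% of reads); the remaining mass is uniform over the other
    lengths of the 18-33-nt window.  Reads from Mariner/MITE elements use
    a 21-nt-dominated mixture (54% / 27%), other TE-derived reads a
    24-nt-dominated one.  ``origin_weights`` allocates reads among TE
    subregions (LTRs/TIRs), TE bodies, genes, intergenic background, and
    non-genomic (sequencing background) reads.
    """

    seed: int
    total_reads: int
    library_id: str = "SIM1"
    min_len: int = 18
    max_len: int = 33
    global_21_share: float = 0.177
    global_24_share: float = 0.287
    mariner_21_share: float = 0.54
    mariner_24_share: float = 0.27
    te_21_share: float = 0.15
    te_24_share: float = 0.55
    origin_weights: dict[str, float] = field(
        default_factory=lambda: {
            "te_subregion": 0.50,
            "te_body": 0.22,
            "gene": 0.03,
            "intergenic": 0.15,
            "nongenomic": 0.10,
        }
    )


def default_library_config(seed: int, total_reads: int = 20_000) -> LibrarySimConfig:
    return LibrarySimConfig(seed=seed, total_reads=total_reads)


def _length_probs(cfg: LibrarySimConfig, p21: float, p24: float) -> np.ndarray:
    lengths = np.arange(cfg.min_len, cfg.max_len + 1)
    other = [l for l in lengths if l not in (21, 24)]
    probs = np.full(len(lengths), (1.0 - p21 - p24) / len(other))
    probs[lengths == 21] = p21
    probs[lengths == 24] = p24
    return probs


def simulate_srna_library(
    region: GenomicRegion,
    features: Sequence[FeatureAnnotation],
    config: LibrarySimConfig,
) -> tuple[list[SmallRNARead], dict]:
    """Draw reads from the annotated region per the configured mixture.

    Genomic reads are exact substrings of the region (or its reverse
    complement, with probability 1/2); non-genomic reads are random
    sequence.  The truth record stores each read's origin category,
    feature, subfeature kind, start and strand, plus a count of draws
    resampled because the read did not fit its chosen subregion.
    """
    rng = np.random.default_rng(config.seed)
    w = config.origin_weights
    if abs(sum(w.values()) - 1.0) > 1e-9:
        raise ValueError("origin weights must sum to 1")
    lengths = np.arange(config.min_len, config.max_len + 1)
    global_p = _length_probs(config, config.global_21_share, config.global_24_share)
    mariner_p = _length_probs(config, config.mariner_21_share, config.mariner_24_share)
    te_p = _length_probs(config, config.te_21_share, config.te_24_share)

    tes = [f for f in features if f.category == "TE"]
    tes_with_subs = [f for f in tes if any(s.kind != "internal" for s in f.subfeatures)]
    genes = [f for f in features if f.category == "gene"]
    intergenic = _complement_intervals(
        len(region), [(f.start, f.end) for f in features if f.nesting_level == 0]
    )
    categories = sorted(w)
    cat_probs = np.array([w[c] for c in categories])

    def pick_weighted(items, weights):
        weights = np.asarray(weights, dtype=float)
        return items[rng.choice(len(items), p=weights / weights.sum())]

    reads: list[SmallRNARead] = []
    truth_rows: list[dict] = []
    resampled = 0
    while len(reads) < config.total_reads:
        cat = categories[rng.choice(len(categories), p=cat_probs)]
        if cat == "nongenomic":
            L = int(rng.choice(lengths, p=global_p))
            seq = _random_seq(rng, L, 0.5)
            reads.append(SmallRNARead(seq, config.library_id))
            truth_rows.append({"origin": cat, "feature_id": None, "subfeature": None,
                               "start": None, "strand": None, "length": L})
            continue
        if cat == "te_subregion" and tes_with_subs:
            feat = pick_weighted(
                tes_with_subs,
                [sum(s.end - s.start for s in f.subfeatures if s.kind != "internal")
                 for f in tes_with_subs],
            )
            subs = [s for s in feat.subfeatures if s.kind != "internal"]
            sub = pick_weighted(subs, [s.end - s.start for s in subs])
            lo, hi, sub_kind = sub.start, sub.end, sub.kind
            p = mariner_p if feat.superfamily == "Mariner" else te_p
        elif cat == "te_body" and tes:
            feat = pick_weighted(tes, [f.length for f in tes])
            lo, hi, sub_kind = feat.start, feat.end, "body"
            p = mariner_p if feat.superfamily == "Mariner" else te_p
        elif cat == "gene" and genes:
            feat = pick_weighted(genes, [f.length for f in genes])
            lo, hi, sub_kind = feat.start, feat.end, None
            p = global_p
        else:  # intergenic, or an empty category fell through
            iv = pick_weighted(intergenic, [e - s for s, e in intergenic])
            feat, (lo, hi), sub_kind = None, iv, None
            p = global_p
            cat = "intergenic"
        L = int(rng.choice(lengths, p=p))
        if hi - lo < L:
            resampled += 1
            continue
        start = int(rng.integers(lo, hi - L + 1))
        seq = region.sequence[start : start + L]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = reverse_complement(seq)
        reads.append(SmallRNARead(seq, config.library_id))
        truth_rows.append({
            "origin": cat,
            "feature_id": feat.feature_id if feat else None,
            "subfeature": sub_kind, "start": start, "strand": strand, "length": L,
        })
    truth = {"seed": config.seed, "reads": truth_rows, "resampled": resampled}
    return reads, truth


def _complement_intervals(
    total_length: int, intervals: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    pos = 0
    for s, e in sorted(intervals):
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < total_length:
        out.append((pos, total_length))
    return out or [(0, total_length)]


# --- orthologous divergence ----------------------------------------------


@dataclass
class DivergenceSimConfig:
    """Two-lineage divergence with methylation-elevated transitions.

    Rates are per site per year; the transversion rate is the total over
    both alternatives.  ``pms_transition_multiplier`` scales the
    transition rate at sites that are potentially methylated in the
    ancestor and fall inside ``methylated_strata`` (alignment intervals in
    ancestor coordinates, e.g. TE footprints).  ``indel_rate`` is the
    per-site deletion probability per lineage.  Defaults match the
    genic-context calibration: total rate 5.5e-9/site/year with the
    transition:transversion ratio implied by the orthologous-region
    counts, a 10-fold deamination elevation at methylated cytosines, and
    1.1 MY of divergence.
    """

    seed: int
    ancestor_length: int = 50_000
    age_years: float = 1.1e6
    transition_rate: float = 3.3e-9
    transversion_rate: float = 2.2e-9
    pms_transition_multiplier: float = 10.0
    methylated_strata: Sequence[tuple[int, int]] = ()
    indel_rate: float = 0.0
    gc_content: float = 0.5
    ancestor: str | None = None


_IDX = {b: i for i, b in enumerate("ACGT")}


def _k2p_branch_probs(a: float, b_each: float, t: float) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after branch time t."""
    e4 = np.exp(-4.0 * b_each * t)
    e2 = np.exp(-2.0 * (a + b_each) * t)
    p_same = 0.25 + 0.25 * e4 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e4
    return p_same, p_ts, p_tv


def _evolve_branch(
    rng: np.random.Generator,
    anc_idx: np.ndarray,
    elevated: np.ndarray,
    cfg: DivergenceSimConfig,
) -> np.ndarray:
    """One descendant of the ancestor under per-site K2P probabilities."""
    b_each = cfg.transversion_rate / 2.0
    probs = {}
    for elev in (False, True):
        a = cfg.transition_rate * (cfg.pms_transition_multiplier if elev else 1.0)
        probs[elev] = _k2p_branch_probs(a, b_each, cfg.age_years)
    n = len(anc_idx)
    p_same = np.where(elevated, probs[True][0], probs[False][0])
    p_ts = np.where(elevated, probs[True][1], probs[False][1])
    u = rng.random(n)
    out = anc_idx.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    out[ts_mask] = (anc_idx[ts_mask] + 2) % 4  # A<->G, C<->T
    tv_mask = u >= p_same + p_ts
    # two transversion alternatives, equally likely
    offset = np.where(rng.random(n) < 0.5, 1, 3)
    out[tv_mask] = (anc_idx[tv_mask] + offset[tv_mask]) % 4
    return out


def evolve_pair(config: DivergenceSimConfig) -> tuple[AlignedPair, dict]:
    """Evolve two descendants of one ancestor and emit the true alignment.

    Substitutions follow the exact Kimura two-parameter branch
    probabilities per site, so the K2P distance estimator is consistent on
    the output.  Deletions (no insertions) are drawn independently per
    site per lineage; columns deleted in both lineages are dropped.  The
    truth record stores per-context/per-stratum tallies of the emitted
    pair computed by an independent enumerator, and the generative
    parameters.
    """
    rng = np.random.default_rng(config.seed)
    if config.ancestor is not None:
        ancestor = config.ancestor.upper()
    else:
        ancestor = _random_seq(rng, config.ancestor_length, config.gc_content)
    n = len(ancestor)
    anc_idx = np.array([_IDX[b] for b in ancestor])
    contexts = classify_ungapped(ancestor)
    in_strata = np.zeros(n, dtype=bool)
    for s, e in config.methylated_strata:
        in_strata[s:e] = True
    elevated = (contexts > 0) & in_strata

    idx_a = _evolve_branch(rng, anc_idx, elevated, config)
    idx_b = _evolve_branch(rng, anc_idx, elevated, config)
    del_a = rng.random(n) < config.indel_rate
    del_b = rng.random(n) < config.indel_rate
    keep = ~(del_a & del_b)  # a column deleted in both lineages vanishes

    chars_a = np.where(del_a, "-", _BASES[idx_a])[keep]
    chars_b = np.where(del_b, "-", _BASES[idx_b])[keep]
    pair = AlignedPair(
        f"lineage_a_seed{config.seed}", f"lineage_b_seed{config.seed}",
        "".join(chars_a), "".join(chars_b),
    )
    strata_cols = in_strata[keep]
    truth = {
        "seed": config.seed,
        "config": config,
        "ancestor": ancestor,
        "n_elevated_sites": int(elevated.sum()),
        "tally_total": _truth_tally(pair.seq_a, pair.seq_b),
        "tally_by_stratum": {
            "methylated": _truth_tally(pair.seq_a, pair.seq_b, mask=strata_cols),
            "other": _truth_tally(pair.seq_a, pair.seq_b, mask=~strata_cols),
        },
    }
    return pair, truth


def simulate_ltr_pair(
    seed: int,
    ltr_length: int,
    age_years: float,
    rate: float,
    ti_tv_ratio: float = 2.0,
) -> tuple[AlignedPair, dict]:
    """Two LTR copies of one template diverged for ``age_years``.

    ``rate`` is the total substitution rate per site per year, split into
    transition and transversion components by ``ti_tv_ratio``.
    """
    a = rate * ti_tv_ratio / (ti_tv_ratio + 1.0)
    b_total = rate / (ti_tv_ratio + 1.0)
    cfg = DivergenceSimConfig(
        seed=seed, ancestor_length=ltr_length, age_years=age_years,
        transition_rate=a, transversion_rate=b_total,
        pms_transition_multiplier=1.0, gc_content=0.5,
    )
    return evolve_pair(cfg)


# --- independent truth enumerator (kept separate from the cmet classifier
#     so truth-vs-tally comparisons are a genuine dual route) --------------


def _regex_levels(seq: str) -> np.ndarray:
    """Context levels via regex motif search on both strands."""
    n = len(seq)
    lv = np.zeros(n, dtype=np.int8)
    rc = reverse_complement(seq)

    def mark(i: int, level: int) -> None:
        if 0 <= i < n and level > lv[i]:
            lv[i] = level

    for m in re.finditer(r"(?=CG)", seq):
        mark(m.start(), 3)
        mark(m.start() + 1, 3)
    for m in re.finditer(r"(?=C[ATC]G)", seq):
        mark(m.start(), 2)
        mark(m.start() + 2, 2)
    for m in re.finditer(r"(?=C[ATC][ATC])", seq):
        mark(m.start(), 1)
    for m in re.finditer(r"(?=C[ATC]G)", rc):
        i = n - 1 - m.start()
        mark(i, 2)
        mark(i - 2, 2)
    for m in re.finditer(r"(?=C[ATC][ATC])", rc):
        mark(n - 1 - m.start(), 1)
    # truncated terminal motifs: a C one base from the 3' end (or a G one
    # base from the 5' end) with an H neighbour and nothing beyond
    if n >= 2 and seq[n - 2] == "C" and seq[n - 1] in "ATC":
        mark(n - 2, 1)
    if n >= 2 and seq[1] == "G" and seq[0] in "TAG":
        mark(1, 1)
    return lv


_LEVEL_TO_NAME = {0: "nonPMS", 1: "CHH", 2: "CHG", 3: "CG"}


def _truth_tally(
    gapped_a: str, gapped_b: str, mask: np.ndarray | None = None
) -> MutationTally:
    """Plain-loop tally of the pair, with contexts from :func:`_regex_levels`.

    ``mask`` restricts to a boolean selection over alignment columns.
    """
    n_cols = len(gapped_a)

    def column_levels(gapped: str) -> list[int]:
        cols = [-1] * n_cols
        idx = [i for i, ch in enumerate(gapped) if ch != "-"]
        levels = _regex_levels("".join(gapped[i] for i in idx))
        for pos, col in enumerate(idx):
            cols[col] = int(levels[pos])
        return cols

    la, lb = column_levels(gapped_a), column_levels(gapped_b)
    tally = MutationTally()
    for i in range(n_cols):
        if mask is not None and not mask[i]:
            continue
        a, b = gapped_a[i], gapped_b[i]
        if a == "-" or b == "-":
            tally.columns_excluded_by_gap += 1
            continue
        if a == "N" or b == "N":
            tally.columns_excluded_by_n += 1
            continue
        ctx = _LEVEL_TO_NAME[max(la[i], lb[i])]
        tally.sites[ctx] += 1
        tally.aligned_columns_used += 1
        if a != b:
            if is_transition(a, b):
                tally.transitions[ctx] += 1
            else:
                tally.transversions[ctx] += 1
    return tally


# --- writers --------------------------------------------------------------


def write_genome_fasta(region: GenomicRegion, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{region.id}\n")
        for i in range(0, len(region), 70):
            fh.write(region.sequence[i : i + 70] + "\n")


_GFF_TYPES = {"LTR": "long_terminal_repeat", "TIR": "terminal_inverted_repeat"}


def write_gff3(
    region: GenomicRegion, features: Sequence[FeatureAnnotation], path: str | Path
) -> None:
    """Emit annotations as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {region.id} 1 {len(region)}\n")
        for f in sorted(features, key=lambda f: (f.start, -f.length)):
            ftype = "gene" if f.category == "gene" else "transposable_element"
            attrs = [f"ID={f.feature_id}"]
            if f.category == "TE":
                attrs += [
                    f"te_class={f.te_class}",
                    f"superfamily={f.superfamily}",
                    f"family={f.family}",
                    f"nesting_level={f.nesting_level}",
                ]
            if f.parent_id:
                attrs.append(f"Parent={f.parent_id}")
            fh.write(
                f"{region.id}\ttescan_sim\t{ftype}\t{f.start + 1}\t{f.end}\t.\t+\t.\t"
                + ";".join(attrs) + "\n"
            )
            for sf in f.subfeatures:
                if sf.kind == "internal":
                    continue
                stype = _GFF_TYPES[sf.kind[:3]]
                fh.write(
                    f"{region.id}\ttescan_sim\t{stype}\t{sf.start + 1}\t{sf.end}\t.\t+\t.\t"
                    f"ID={f.feature_id}_{sf.kind};Parent={f.feature_id}\n"
                )


def write_reads_fastq(reads: Sequence[SmallRNARead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@{r.library_id}_read{i + 1}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_aligned_fasta(pair: AlignedPair, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in ((pair.id_a, pair.seq_a), (pair.id_b, pair.seq_b)):
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
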