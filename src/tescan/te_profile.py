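"""Attribution of sRNA matches to annotated features and downstream profiling.

Covers the statistics reported for annotated wheat BAC regions and the
TREP repeat reference: per-feature abundance-weighted densities, TE vs
gene and nesting-layer contrasts (Welch's t), 21/24-nt size-class shares,
positional decile profiles with chi-square uniformity tests, repeat-
database filtering, and correlation of sRNA counts with element abundance.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .match_scan import GenomicRegion, MatchHit

logger = logging.getLogger(__name__)

__all__ = [
    "SubFeature",
    "FeatureAnnotation",
    "FeatureSRNAProfile",
    "DecileProfile",
    "TestResult",
    "TEClassification",
    "TERecord",
    "FilterReport",
    "AssignmentResult",
    "read_gff3",
    "assign_hits",
    "profile_feature",
    "decile_profile",
    "uniformity_test",
    "group_density_comparison",
    "pearson_correlation",
    "parse_te_header",
    "filter_te_database",
]

INTERGENIC = "intergenic"


@dataclass(frozen=True)
class SubFeature:
    """A structural sub-interval of a TE: LTRs, TIRs, or the internal domain."""

    kind: str  # LTR5, LTR3, TIR5, TIR3, internal
    start: int  # 0-based, half-open, region coordinates
    end: int


@dataclass
class FeatureAnnotation:
    """An annotated TE or gene interval with classification and nesting."""

    feature_id: str
    region_id: str
    start: int  # 0-based half-open
    end: int
    category: str  # "TE" or "gene"
    te_class: str = "none"  # "I", "II", or "none"
    superfamily: str = ""
    family: str = ""
    nesting_level: int = 0
    parent_id: str | None = None
    subfeatures: list[SubFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.feature_id}: start must precede end")
        for sf in self.subfeatures:
            if sf.start < self.start or sf.end > self.end:
                raise ValueError(
                    f"{self.feature_id}: subfeature {sf.kind} outside the feature"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


# --- GFF3 I/O -------------------------------------------------------------

_SUBFEATURE_TYPES = {
    "long_terminal_repeat": "LTR",
    "terminal_inverted_repeat": "TIR",
}


def read_gff3(path: str | Path) -> list[FeatureAnnotation]:
    """Parse feature annotations from GFF3 (1-based inclusive -> half-open).

    Top-level rows of type ``transposable_element``/``repeat_region`` or
    ``gene`` carry the attributes ``ID``, ``te_class``, ``superfamily``,
    ``family``, ``nesting_level`` and optionally ``Parent``; rows of type
    ``long_terminal_repeat``/``terminal_inverted_repeat`` attach to their
    ``Parent`` as subfeatures (5' vs 3' resolved by coordinate order).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", from_string=False,
        merge_strategy="create_unique", keep_order=True,
    )
    features: dict[str, FeatureAnnotation] = {}
    pending_subs: list[tuple[str, str, int, int]] = []
    for f in db.all_features():
        attrs = {k: v[0] for k, v in f.attributes.items()}
        start, end = f.start - 1, f.end  # to 0-based half-open
        if f.featuretype in _SUBFEATURE_TYPES:
            parent = attrs.get("Parent")
            if parent is None:
                logger.warning("subfeature without Parent at %s:%s", f.seqid, f.start)
                continue
            pending_subs.append((parent, _SUBFEATURE_TYPES[f.featuretype], start, end))
            continue
        category = "gene" if f.featuretype == "gene" else "TE"
        fid = attrs.get("ID", f.id)
        features[fid] = FeatureAnnotation(
            feature_id=fid,
            region_id=f.seqid,
            start=start,
            end=end,
            category=category,
            te_class=attrs.get("te_class", "none"),
            superfamily=attrs.get("superfamily", ""),
            family=attrs.get("family", ""),
            nesting_level=int(attrs.get("nesting_level", 0)),
            parent_id=attrs.get("Parent"),
        )
    by_parent: dict[str, list[tuple[str, int, int]]] = {}
    for parent, kind, start, end in pending_subs:
        by_parent.setdefault(parent, []).append((kind, start, end))
    for parent, subs in by_parent.items():
        if parent not in features:
            logger.warning("subfeatures reference unknown parent %s", parent)
            continue
        for kind in ("LTR", "TIR"):
            pair = sorted((s for s in subs if s[0] == kind), key=lambda s: s[1])
            for i, (_, s, e) in enumerate(pair):
                suffix = "5" if i == 0 else "3"
                features[parent].subfeatures.append(SubFeature(kind + suffix, s, e))
    return list(features.values())


# --- hit assignment -------------------------------------------------------


@dataclass
class AssignmentResult:
    """Hits grouped by feature, plus the intergenic bucket and a report of
    hits that straddled a feature boundary (assigned by start containment)."""

    by_feature: dict[str, list[MatchHit]]
    boundary_hits: list[tuple[str, MatchHit]] = field(default_factory=list)


def assign_hits(
    hits: Iterable[MatchHit],
    annotations: Sequence[FeatureAnnotation],
) -> AssignmentResult:
    """Assign each hit to the innermost feature containing its footprint.

    Under nesting the feature with the highest nesting level (ties broken
    by the smallest span) wins; a hit whose footprint straddles a boundary
    is assigned to the innermost feature containing its start and recorded
    in the boundary report; a hit contained in no feature goes to the
    ``intergenic`` bucket.
    """
    result = AssignmentResult({f.feature_id: [] for f in annotations})
    result.by_feature[INTERGENIC] = []
    for hit in hits:
        full = [f for f in annotations if f.contains(hit.start, hit.end)]
        if full:
            chosen = max(full, key=lambda f: (f.nesting_level, -f.length))
            result.by_feature[chosen.feature_id].append(hit)
            continue
        partial = [f for f in annotations if f.start <= hit.start < f.end]
        if partial:
            chosen = max(partial, key=lambda f: (f.nesting_level, -f.length))
            result.by_feature[chosen.feature_id].append(hit)
            result.boundary_hits.append((chosen.feature_id, hit))
        else:
            result.by_feature[INTERGENIC].append(hit)
    return result


@dataclass
class FeatureSRNAProfile:
    """Abundance-weighted sRNA profile of one feature."""

    feature_id: str
    length_bp: int
    total_counts: int
    counts_per_bp: float
    counts_by_srna_length: dict[int, int]
    counts_by_library: dict[str, int]
    pct_21: float
    pct_24: float
    zero_total: bool


def profile_feature(
    feature: FeatureAnnotation, assigned_hits: Sequence[MatchHit]
) -> FeatureSRNAProfile:
    """Totals, density and 21/24-nt shares for one feature's hits."""
    by_length: Counter = Counter()
    by_library: Counter = Counter()
    total = 0
    for h in assigned_hits:
        total += h.total_count
        by_length[h.length] += h.total_count
        for lib, c in h.counts_by_library:
            by_library[lib] += c
    zero = total == 0
    return FeatureSRNAProfile(
        feature_id=feature.feature_id,
        length_bp=feature.length,
        total_counts=total,
        counts_per_bp=total / feature.length,
        counts_by_srna_length=dict(by_length),
        counts_by_library=dict(by_library),
        pct_21=0.0 if zero else 100.0 * by_length.get(21, 0) / total,
        pct_24=0.0 if zero else 100.0 * by_length.get(24, 0) / total,
        zero_total=zero,
    )


# --- positional decile profiles -------------------------------------------


@dataclass
class DecileProfile:
    """Abundance-weighted counts in ten equal-length fractions of an element."""

    element_id: str
    bins: np.ndarray  # 10 non-negative totals
    srna_length_filter: int | None = None

    @property
    def total(self) -> int:
        return int(self.bins.sum())


def decile_profile(
    element: FeatureAnnotation | GenomicRegion,
    assigned_hits: Sequence[MatchHit],
    srna_length_filter: int | None = None,
) -> DecileProfile:
    """Bin hits by start offset into ten equal fractions of the element.

    bin = floor(10 * (start - element_start) / element_length), clamped to
    [0, 9].  ``element`` may be an annotated feature or a standalone
    sequence record (e.g. a repeat-database element scanned on its own).
    """
    if isinstance(element, GenomicRegion):
        el_id, el_start, el_len = element.id, 0, len(element)
    else:
        el_id, el_start, el_len = element.feature_id, element.start, element.length
    if el_len < 10:
        raise ValueError(f"{el_id}: element shorter than 10 bp cannot be decile-binned")
    bins = np.zeros(10, dtype=np.int64)
    for h in assigned_hits:
        if srna_length_filter is not None and h.length != srna_length_filter:
            continue
        b = min(9, max(0, (10 * (h.start - el_start)) // el_len))
        bins[b] += h.total_count
    return DecileProfile(el_id, bins, srna_length_filter)


@dataclass
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    test_name: str
    sidedness: str = "two-sided"
    estimate: float | None = None  # e.g. Pearson r


def uniformity_test(profile: DecileProfile, merge_terminal_bins: int = 0) -> TestResult:
    """Chi-square goodness of fit of a decile profile against uniformity.

    ``merge_terminal_bins=k`` averages the k leading bins pairwise with
    their mirror bins (bin i with bin 9-i) before testing — appropriate for
    LTR elements whose duplicated terminal repeats make the mirrored bins
    copies of the same sequence class.  This leaves 10-k categories and
    df = 9-k (k=2 for Copia-like, k=1 for Gypsy-like elements).
    """
    if not 0 <= merge_terminal_bins <= 4:
        raise ValueError("merge_terminal_bins must be in [0, 4]")
    bins = profile.bins.astype(float)
    if bins.sum() == 0:
        raise ValueError("cannot test an all-zero profile")
    k = merge_terminal_bins
    merged = [(bins[i] + bins[9 - i]) / 2.0 for i in range(k)]
    obs = np.array(merged + list(bins[k : 10 - k]), dtype=float)
    expected = np.full(obs.size, obs.sum() / obs.size)
    stat, p = stats.chisquare(obs, expected)
    return TestResult(float(stat), obs.size - 1, float(p), "chi-square uniformity")


def group_density_comparison(
    profiles_a: Sequence[FeatureSRNAProfile] | Sequence[float],
    profiles_b: Sequence[FeatureSRNAProfile] | Sequence[float],
    sidedness: str = "two-sided",
) -> TestResult:
    """Welch two-sample t-test on per-feature sRNA densities (counts/bp).

    ``sidedness='greater'`` tests group A > group B (used for the
    nesting-layer contrast: top-layer elements vs buried ones).
    """

    def densities(group) -> np.ndarray:
        return np.array(
            [p.counts_per_bp if isinstance(p, FeatureSRNAProfile) else float(p) for p in group]
        )

    a, b = densities(profiles_a), densities(profiles_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 features")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=sidedness)
    return TestResult(
        float(res.statistic), float(res.df), float(res.pvalue), "Welch t", sidedness
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson r with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input vector")
    res = stats.pearsonr(x, y)
    return TestResult(
        float(res.statistic), len(x) - 2, float(res.pvalue),
        "Pearson correlation", estimate=float(res.statistic),
    )


# --- repeat-database headers and filtering --------------------------------

# three-letter repeat classification codes -> superfamily
_CODE_SUPERFAMILY = {
    "RLC": "Copia",
    "RLG": "Gypsy",
    "RIX": "LINE",
    "RIL": "LINE",
    "DTC": "CACTA",
    "DTT": "Mariner",
    "DTH": "Harbinger",
    "DTM": "Mutator",
}

# four-letter species abbreviations -> genus
_SPECIES_GENUS = {
    "TAES": "Triticum", "TTUR": "Triticum", "TMON": "Triticum", "TDUR": "Triticum",
    "TURA": "Triticum", "AETA": "Aegilops", "AESP": "Aegilops", "ASPE": "Aegilops",
    "HVUL": "Hordeum", "SCER": "Secale",
}


@dataclass
class TEClassification:
    te_class: str  # "I", "II", or "unknown"
    superfamily: str
    family: str
    completeness: str  # "complete", "incomplete", or "unknown"
    genus: str


@dataclass
class TERecord:
    """One repeat-database entry: header-derived classification plus sequence."""

    id: str
    classification: TEClassification
    sequence: str


def parse_te_header(header_text: str) -> TEClassification:
    """Classify a repeat-database entry from its FASTA header.

    Expects the convention ``CODE_Species_Family_accession description``
    where CODE is the three-letter classification (e.g. RLC = class I
    Copia, DTT = class II Mariner) and the description may state
    ``complete`` or ``incomplete``/``fragment``.  Unparseable headers
    yield an "unknown" classification with a warning, never a crash.
    """
    header_text = header_text.lstrip(">").strip()
    m = re.match(r"([A-Z]{3})_([A-Za-z]+)_([A-Za-z0-9.-]+)", header_text)
    if not m:
        logger.warning("unparseable repeat header: %r", header_text)
        return TEClassification("unknown", "unknown", "unknown", "unknown", "unknown")
    code, species, family = m.groups()
    superfamily = _CODE_SUPERFAMILY.get(code)
    if superfamily is None:
        logger.warning("unknown classification code %s in %r", code, header_text)
        superfamily = "other"
    if code.startswith("R"):
        te_class = "I"
    elif code.startswith("D"):
        te_class = "II"
    else:
        te_class = "unknown"
    genus = _SPECIES_GENUS.get(species.upper(), "unknown")
    lower = header_text.lower()
    if "incomplete" in lower or "fragment" in lower:
        completeness = "incomplete"
    elif "complete" in lower:
        completeness = "complete"
    else:
        completeness = "unknown"
    return TEClassification(te_class, superfamily, family, completeness, genus)


@dataclass
class FilterReport:
    """Surviving counts after each filtering stage."""

    input_count: int
    after_complete: int
    after_genus: int
    after_ambiguous: int
    failed: dict[str, list[str]] = field(default_factory=dict)


def filter_te_database(
    te_records: Sequence[TERecord],
    complete_only: bool = True,
    genera: Sequence[str] | None = ("Triticum", "Aegilops"),
    exclude_ambiguous: bool = True,
) -> tuple[list[TERecord], FilterReport]:
    """Filter repeat-database records: complete -> genus -> no ambiguous base.

    Records lacking the metadata a criterion needs count as failing it.
    The report carries surviving counts after each stage and the ids that
    fell at each.
    """
    report = FilterReport(len(te_records), 0, 0, 0)
    survivors = list(te_records)
    if complete_only:
        kept, fell = [], []
        for r in survivors:
            (kept if r.classification.completeness == "complete" else fell).append(r)
        survivors = kept
        report.failed["incomplete"] = [r.id for r in fell]
    report.after_complete = len(survivors)
    if genera is not None:
        kept, fell = [], []
        for r in survivors:
            (kept if r.classification.genus in genera else fell).append(r)
        survivors = kept
        report.failed["genus"] = [r.id for r in fell]
    report.after_genus = len(survivors)
    if exclude_ambiguous:
        kept, fell = [], []
        for r in survivors:
            clean = set(r.sequence.upper()) <= set("ACGT")
            (kept if clean else fell).append(r)
        survivors = kept
        report.failed["ambiguous"] = [r.id for r in fell]
    report.after_ambiguous = len(survivors)
    return survivors, report
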