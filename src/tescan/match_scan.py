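"""Exhaustive perfect-match scanning of genomic sequence against the sRNA database.

A scrolling window of every allowed frame size (default 18-33 nt) moves
along the query with a 1-nt increment; every window whose sequence (or
reverse complement, for minus-strand hits) exactly equals a database sRNA
is reported with its coordinate, length, strand and abundance.  The result
is defined to equal brute-force enumeration of all substrings; hashed
per-length lookups are only an implementation detail.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .srna_db import SRNADatabase, normalize_sequence

__all__ = [
    "GenomicRegion",
    "MatchHit",
    "HitSummary",
    "reverse_complement",
    "read_regions_fasta",
    "scan_region",
    "aggregate_counts",
    "match_density",
    "write_hits_tsv",
    "read_hits_tsv",
    "write_hits_bed",
]

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class GenomicRegion:
    """A query sequence (BAC region, TE reference, ...) over A/C/G/T/N."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"region {self.id}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatchHit:
    """One perfect occurrence of a database sRNA on a region.

    ``start`` is the 0-based offset of the forward-strand footprint; a
    minus-strand hit means the sRNA equals the reverse complement of the
    substring at [start, start+length).
    """

    region_id: str
    start: int
    length: int
    strand: str
    srna_sequence: str
    counts_by_library: tuple[tuple[str, int], ...]
    total_count: int

    @property
    def end(self) -> int:
        return self.start + self.length


def read_regions_fasta(path: str | Path) -> list[GenomicRegion]:
    return [GenomicRegion(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def scan_region(
    db: SRNADatabase,
    region: GenomicRegion,
    strands: Sequence[str] = ("+", "-"),
) -> list[MatchHit]:
    """Find every perfect sRNA match in ``region`` on the requested strands.

    Hits are sorted by (start, length, strand).  N in the query matches
    nothing.  A minus-strand hit is recorded at its forward-strand
    footprint.
    """
    bad = set(strands) - {"+", "-"}
    if bad:
        raise ValueError(f"invalid strands: {sorted(bad)}")
    seq = region.sequence
    hits: list[MatchHit] = []
    # per-length lookups: forward sequences and (for minus hits) the set of
    # forward-strand footprints whose reverse complement is in the database
    by_len: dict[int, dict[str, object]] = {}
    for s, rec in db.records.items():
        by_len.setdefault(len(s), {"fwd": {}, "rc": {}})
        by_len[len(s)]["fwd"][s] = rec
        by_len[len(s)]["rc"][reverse_complement(s)] = rec
    for L, maps in sorted(by_len.items()):
        fwd = maps["fwd"] if "+" in strands else {}
        rc = maps["rc"] if "-" in strands else {}
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            rec = fwd.get(window)
            if rec is not None:
                hits.append(
                    MatchHit(
                        region.id, i, L, "+", rec.sequence,
                        tuple(sorted(rec.counts_by_library.items())),
                        rec.total_count,
                    )
                )
            rec = rc.get(window)
            if rec is not None:
                hits.append(
                    MatchHit(
                        region.id, i, L, "-", rec.sequence,
                        tuple(sorted(rec.counts_by_library.items())),
                        rec.total_count,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.length, h.strand))
    return hits


@dataclass
class HitSummary:
    """Abundance-weighted aggregation of a hit list."""

    total: int
    by_length: dict[int, int]
    by_library: dict[str, int]
    by_strand: dict[str, int]

    def length_share(self, length: int) -> float:
        """Percentage of total counts carried by hits of ``length`` nt."""
        if self.total == 0:
            return 0.0
        return 100.0 * self.by_length.get(length, 0) / self.total


def aggregate_counts(hits: Iterable[MatchHit]) -> HitSummary:
    """Each hit contributes its full database abundance to every cell."""
    by_length: Counter = Counter()
    by_library: Counter = Counter()
    by_strand: Counter = Counter()
    total = 0
    for h in hits:
        total += h.total_count
        by_length[h.length] += h.total_count
        by_strand[h.strand] += h.total_count
        for lib, c in h.counts_by_library:
            by_library[lib] += c
    return HitSummary(total, dict(by_length), dict(by_library), dict(by_strand))


def match_density(hits: Iterable[MatchHit] | int, interval_length_bp: int) -> float:
    """Total abundance-weighted counts per bp of interval.

    Accepts either a hit list or a precomputed total count.
    """
    if interval_length_bp <= 0:
        raise ValueError("interval length must be positive")
    total = hits if isinstance(hits, int) else aggregate_counts(hits).total
    return total / interval_length_bp


def hits_to_frame(hits: Iterable[MatchHit], library_ids: Sequence[str] = ()) -> pd.DataFrame:
    rows = []
    for h in hits:
        row = {
            "region_id": h.region_id, "start": h.start, "end": h.end,
            "strand": h.strand, "length": h.length, "sequence": h.srna_sequence,
        }
        per_lib = dict(h.counts_by_library)
        for lib in library_ids:
            row[lib] = per_lib.get(lib, 0)
        row["total"] = h.total_count
        rows.append(row)
    cols = ["region_id", "start", "end", "strand", "length", "sequence",
            *library_ids, "total"]
    return pd.DataFrame(rows, columns=cols)


def write_hits_tsv(hits: Iterable[MatchHit], path: str | Path,
                   library_ids: Sequence[str] = ()) -> None:
    hits_to_frame(hits, library_ids).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[MatchHit]:
    df = pd.read_csv(path, sep="\t")
    lib_cols = [c for c in df.columns
                if c not in ("region_id", "start", "end", "strand", "length",
                             "sequence", "total")]
    hits = []
    for row in df.to_dict("records"):
        per_lib = tuple(
            (lib, int(row[lib])) for lib in lib_cols if row[lib] > 0
        )
        hits.append(
            MatchHit(row["region_id"], int(row["start"]), int(row["length"]),
                     row["strand"], row["sequence"], per_lib, int(row["total"]))
        )
    return hits


def write_hits_bed(hits: Iterable[MatchHit], path: str | Path) -> None:
    """BED6 export; score is the total count capped at 1000."""
    with open(path, "w") as fh:
        for h in hits:
            score = min(h.total_count, 1000)
            fh.write(
                f"{h.region_id}\t{h.start}\t{h.end}\t{h.srna_sequence}\t{score}\t{h.strand}\n"
            )
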