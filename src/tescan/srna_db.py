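"""Small-RNA read ingestion and the consolidated abundance database.

Deep-sequenced small-RNA libraries (adapter-trimmed, 18-33 nt) are merged
into a single database of distinct sequences, each carrying per-library and
total read counts.  All downstream matching is abundance-weighted against
this store, so a sequence read one million times contributes one million
counts wherever it matches.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SmallRNARead",
    "RejectionReport",
    "SRNARecord",
    "SRNADatabase",
    "SizeDistribution",
    "normalize_sequence",
    "load_reads",
    "build_database",
    "size_distribution",
    "query_exact",
    "write_database_tsv",
    "read_database_tsv",
]

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 33

_VALID_BASES = frozenset("ACGT")
_NORM = str.maketrans("acgtuU", "ACGTTT")


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U to T so RNA- and DNA-alphabet inputs unify."""
    return seq.translate(_NORM)


@dataclass(frozen=True)
class SmallRNARead:
    """One accepted small-RNA read (normalized to the DNA alphabet)."""

    sequence: str
    library_id: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RejectionReport:
    """Counts of reads rejected at ingestion, by reason."""

    too_short: int = 0
    too_long: int = 0
    ambiguous: int = 0

    @property
    def total(self) -> int:
        return self.too_short + self.too_long + self.ambiguous


@dataclass
class SRNARecord:
    """A distinct sRNA sequence with its per-library abundance."""

    sequence: str
    counts_by_library: dict[str, int]
    total_count: int

    def __post_init__(self) -> None:
        if self.total_count != sum(self.counts_by_library.values()):
            raise ValueError("total_count must equal the sum of per-library counts")
        if self.total_count < 1:
            raise ValueError("a record must represent at least one read")


@dataclass
class SRNADatabase:
    """Consolidated store of distinct sRNA sequences across libraries."""

    records: dict[str, SRNARecord]
    library_ids: tuple[str, ...]
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_reads(self) -> int:
        return sum(r.total_count for r in self.records.values())

    def lengths_present(self) -> tuple[int, ...]:
        return tuple(sorted({len(s) for s in self.records}))


@dataclass
class SizeDistribution:
    """Abundance-weighted read-length distribution, optionally per library.

    ``mean_pct``/``sd_pct`` are the across-library mean and sample standard
    deviation (ddof=1) of the per-library percentage at each length — the
    form in which bimodal 21/24-nt peaks are conventionally reported.
    """

    counts: pd.Series
    percentages: pd.Series
    per_library_pct: pd.DataFrame | None = None
    mean_pct: pd.Series | None = None
    sd_pct: pd.Series | None = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: str | Path) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            raise ValueError(f"unrecognized read-file format: {path}")
    return "empty"


def load_reads(
    path: str | Path,
    library_id: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[SmallRNARead], RejectionReport]:
    """Read trimmed sRNA reads from FASTA/FASTQ (gzip-transparent).

    Returns the accepted reads plus a rejection report (too short / too
    long / ambiguous base).  Reads containing any character outside
    A/C/G/T after normalization are rejected as ambiguous.
    """
    fmt = _sniff_format(path)
    reads: list[SmallRNARead] = []
    report = RejectionReport()
    if fmt == "empty":
        return reads, report
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            seq = normalize_sequence(str(rec.seq))
            if len(seq) < min_len:
                report.too_short += 1
            elif len(seq) > max_len:
                report.too_long += 1
            elif not _VALID_BASES.issuperset(seq):
                report.ambiguous += 1
            else:
                reads.append(SmallRNARead(seq, library_id))
    return reads, report


def build_database(
    read_collections: Iterable[Sequence[SmallRNARead]],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> SRNADatabase:
    """Merge per-library read collections into one abundance database.

    One record per distinct sequence; content is independent of input
    order (records are stored sorted by sequence).  A library id occurring
    in more than one collection is a configuration error.
    """
    library_ids: list[str] = []
    tallies: dict[str, dict[str, int]] = {}
    for collection in read_collections:
        collection = list(collection)
        libs_here = {r.library_id for r in collection}
        for lib in sorted(libs_here):
            if lib in library_ids:
                raise ValueError(f"duplicate library_id across collections: {lib!r}")
        library_ids.extend(sorted(libs_here))
        for read in collection:
            if not (min_len <= len(read.sequence) <= max_len):
                raise ValueError(
                    f"read length {len(read.sequence)} outside window "
                    f"[{min_len}, {max_len}]"
                )
            per_lib = tallies.setdefault(read.sequence, {})
            per_lib[read.library_id] = per_lib.get(read.library_id, 0) + 1
    records = {
        seq: SRNARecord(seq, dict(sorted(per_lib.items())), sum(per_lib.values()))
        for seq, per_lib in sorted(tallies.items())
    }
    return SRNADatabase(records, tuple(library_ids), min_len, max_len)


def query_exact(db: SRNADatabase, sequence: str) -> SRNARecord | None:
    """Exact lookup after the same normalization applied at ingestion."""
    return db.records.get(normalize_sequence(sequence))


def size_distribution(db: SRNADatabase, by_library: bool = False) -> SizeDistribution:
    """Abundance-weighted length distribution of the database.

    Each read (not each distinct sequence) contributes one count at its
    length.  With ``by_library`` the per-library percentage table and its
    across-library mean +/- sd are included.
    """
    lengths = range(db.min_len, db.max_len + 1)
    counts = pd.Series(0, index=pd.Index(lengths, name="length"), dtype="int64")
    per_lib = pd.DataFrame(
        0, index=counts.index, columns=list(db.library_ids), dtype="int64"
    )
    for rec in db.records.values():
        L = len(rec.sequence)
        counts.loc[L] += rec.total_count
        for lib, c in rec.counts_by_library.items():
            per_lib.loc[L, lib] += c
    total = counts.sum()
    if total == 0:
        pct = counts.astype(float)
    else:
        pct = 100.0 * counts / total
    if not by_library:
        return SizeDistribution(counts, pct)
    lib_totals = per_lib.sum(axis=0)
    lib_pct = per_lib.astype(float)
    nonzero = lib_totals > 0
    lib_pct.loc[:, nonzero] = 100.0 * per_lib.loc[:, nonzero] / lib_totals[nonzero]
    mean = lib_pct.mean(axis=1)
    sd = lib_pct.std(axis=1, ddof=1)
    return SizeDistribution(counts, pct, lib_pct, mean, sd)


def write_database_tsv(db: SRNADatabase, path: str | Path) -> None:
    """Serialize as TSV: sequence, length, one column per library, total."""
    rows = []
    for rec in db.records.values():
        row = {"sequence": rec.sequence, "length": len(rec.sequence)}
        for lib in db.library_ids:
            row[lib] = rec.counts_by_library.get(lib, 0)
        row["total"] = rec.total_count
        rows.append(row)
    cols = ["sequence", "length", *db.library_ids, "total"]
    df = pd.DataFrame(rows, columns=cols)
    header = f"#min_len={db.min_len}\tmax_len={db.max_len}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_database_tsv(path: str | Path) -> SRNADatabase:
    """Load a database previously written by :func:`write_database_tsv`."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#min_len="):
            raise ValueError("not a tescan database TSV (missing length-window header)")
        fields = dict(kv.split("=") for kv in first.lstrip("#").split())
        df = pd.read_csv(fh, sep="\t")
    library_ids = tuple(c for c in df.columns if c not in ("sequence", "length", "total"))
    records = {}
    for row in df.to_dict("records"):
        per_lib = {lib: int(row[lib]) for lib in library_ids if row[lib] > 0}
        records[row["sequence"]] = SRNARecord(row["sequence"], per_lib, int(row["total"]))
    return SRNADatabase(
        records, library_ids, int(fields["min_len"]), int(fields["max_len"])
    )
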