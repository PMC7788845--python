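"""Pairwise contig alignment parsing and purge metrics.

Haplotig purging starts from an all-by-all alignment of the contigs of a
diploid assembly against themselves, produced by BLAT (PSL) or minimap2
(PAF).  Each aligned contig pair is summarised by four metrics:

``identity``
    fraction of aligned bases that match, ``matches / (matches +
    mismatches + rep_matches)``.  Indel bases are excluded from the
    denominator.
``q``
    fraction of the *query* contig covered by the alignment.  Alternative
    haplotigs tend to align over most of their length to the primary
    contig that represents the same locus, so ``q`` near 1 is a purge
    signal.
``r``
    fraction of the *target* (reference) contig covered.
``qr``
    ``q / r`` — sensitive to clipping and structural differences between
    the two contigs.  It is asymmetric and unbounded above, so the
    symmetric transform ``qr_prime = exp(-log2(qr))`` is carried along:
    ``qr_prime(1) == 1`` and ``qr_prime(x) * qr_prime(1/x) == 1``.

Both alignment formats use 0-based half-open coordinates, which are kept
verbatim.  Strand is ignored: all metrics are span-length based.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "RawAlignment",
    "AlignmentRecord",
    "AlignmentTable",
    "AlignmentParseError",
    "parse_psl",
    "parse_paf",
    "write_psl",
    "compute_metrics",
    "filter_eligible",
]

log = logging.getLogger(__name__)

#: queries longer than this are never purge candidates (long contigs are
#: unlikely to be alternative haplotigs and are kept as references only)
DEFAULT_MAX_QUERY_LENGTH = 10_000_000


class AlignmentParseError(ValueError):
    """Malformed PSL/PAF input (bad column count or field value)."""


@dataclass(frozen=True)
class RawAlignment:
    """One alignment row with raw, format-agnostic coordinates."""

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    target_name: str
    target_length: int
    target_start: int
    target_end: int
    matches: int
    mismatches: int
    rep_matches: int = 0
    block_length: int = 0

    def validate(self, line_no: int | None = None) -> None:
        where = f" (line {line_no})" if line_no is not None else ""
        if min(self.query_start, self.query_end, self.target_start,
               self.target_end, self.matches, self.mismatches,
               self.rep_matches) < 0:
            raise AlignmentParseError(f"negative field value{where}: {self}")
        if not (self.query_start <= self.query_end <= self.query_length):
            raise AlignmentParseError(
                f"query coordinates out of range{where}: {self}")
        if not (self.target_start <= self.target_end <= self.target_length):
            raise AlignmentParseError(
                f"target coordinates out of range{where}: {self}")
        if self.query_length <= 0 or self.target_length <= 0:
            raise AlignmentParseError(f"non-positive contig length{where}")


@dataclass(frozen=True)
class AlignmentRecord:
    """A raw alignment annotated with the purge metrics."""

    raw: RawAlignment
    identity: float
    q: float
    r: float
    qr: float
    qr_prime: float


@dataclass
class AlignmentTable:
    """Metric-annotated alignment rows plus the contig length map.

    Self-alignments and degenerate rows have already been dropped; every
    contig name appearing in ``records`` has an entry in
    ``contig_lengths``.
    """

    records: list[AlignmentRecord]
    contig_lengths: dict[str, int]

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "query": rec.raw.query_name,
                "target": rec.raw.target_name,
                "ID": rec.identity,
                "Q": rec.q,
                "R": rec.r,
                "QR": rec.qr,
                "QR_prime": rec.qr_prime,
            }
            for rec in self.records
        ]
        return pd.DataFrame(
            rows, columns=["query", "target", "ID", "Q", "R", "QR", "QR_prime"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def qr_prime_of(qr: float) -> float:
    """The symmetric transform ``exp(-log2(qr))`` of a QR ratio."""
    if qr <= 0:
        raise ValueError(f"QR must be positive, got {qr}")
    return math.exp(-math.log2(qr))


def _open_text(path: str | Path, gzipped: bool | None) -> IO[str]:
    path = Path(path)
    if gzipped is None:
        gzipped = path.suffix == ".gz"
    if gzipped:
        return gzip.open(path, "rt")
    return open(path, "rt")


_PSL_HEADER_PREFIXES = ("psLayout", "match", "-", " ")


def parse_psl(path: str | Path, gzipped: bool | None = None) -> list[RawAlignment]:
    """Parse a 21-column BLAT PSL file (optionally gzip-compressed).

    A ``psLayout`` header block, blank lines and the dashed separator are
    skipped.  Coordinates are taken verbatim (PSL is 0-based half-open).
    """
    out: list[RawAlignment] = []
    with _open_text(path, gzipped) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_PSL_HEADER_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated test rows
                fields = line.split()
            if len(fields) != 21:
                raise AlignmentParseError(
                    f"PSL line {line_no}: expected 21 columns, got {len(fields)}"
                )
            try:
                matches = int(fields[0])
                mismatches = int(fields[1])
                rep = int(fields[2])
                rec = RawAlignment(
                    query_name=fields[9],
                    query_length=int(fields[10]),
                    query_start=int(fields[11]),
                    query_end=int(fields[12]),
                    target_name=fields[13],
                    target_length=int(fields[14]),
                    target_start=int(fields[15]),
                    target_end=int(fields[16]),
                    matches=matches,
                    mismatches=mismatches,
                    rep_matches=rep,
                    block_length=matches + mismatches + rep,
                )
            except ValueError as exc:
                raise AlignmentParseError(
                    f"PSL line {line_no}: {exc}") from exc
            rec.validate(line_no)
            out.append(rec)
    return out


def parse_paf(path: str | Path, gzipped: bool | None = None) -> list[RawAlignment]:
    """Parse a minimap2 PAF file (12+ columns; SAM-style tags ignored).

    PAF carries no separate mismatch count without the ``cg``/``NM`` tags,
    so mismatches are taken as ``block_length - matches``, collapsing
    substitution and indel error together.
    """
    out: list[RawAlignment] = []
    with _open_text(path, gzipped) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 12:
                raise AlignmentParseError(
                    f"PAF line {line_no}: expected >= 12 columns, got {len(fields)}"
                )
            try:
                matches = int(fields[9])
                block = int(fields[10])
                rec = RawAlignment(
                    query_name=fields[0],
                    query_length=int(fields[1]),
                    query_start=int(fields[2]),
                    query_end=int(fields[3]),
                    target_name=fields[5],
                    target_length=int(fields[6]),
                    target_start=int(fields[7]),
                    target_end=int(fields[8]),
                    matches=matches,
                    mismatches=max(block - matches, 0),
                    rep_matches=0,
                    block_length=block,
                )
            except ValueError as exc:
                raise AlignmentParseError(
                    f"PAF line {line_no}: {exc}") from exc
            rec.validate(line_no)
            out.append(rec)
    return out


def write_psl(raws: Iterable[RawAlignment], path: str | Path,
              header: bool = True) -> None:
    """Serialize alignments as single-block PSL rows (round-trips parse_psl)."""
    path = Path(path)
    with open(path, "wt") as fh:
        if header:
            fh.write("psLayout version 3\n\n")
            fh.write("match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\t"
                     "strand\tQ        \tQ   \tQ    \tQ  \tT        \tT   \t"
                     "T    \tT  \tblock\tblockSizes \tqStarts\t tStarts\n")
            fh.write("     \tmatch\tmatch\t   \tcount\tbases\tcount\tbases\t"
                     "      \tname     \tsize\tstart\tend\tname     \tsize\t"
                     "start\tend\tcount\n")
            fh.write("-" * 160 + "\n")
        for r in raws:
            qspan = r.query_end - r.query_start
            fh.write("\t".join(str(x) for x in (
                r.matches, r.mismatches, r.rep_matches, 0, 0, 0, 0, 0, "+",
                r.query_name, r.query_length, r.query_start, r.query_end,
                r.target_name, r.target_length, r.target_start, r.target_end,
                1, f"{qspan},", f"{r.query_start},", f"{r.target_start},",
            )) + "\n")


def compute_metrics(raws: Iterable[RawAlignment],
                    count_rep_matches: bool = True,
                    best_row_per_pair: bool = False) -> AlignmentTable:
    """Annotate raw alignments with identity/Q/R/QR/QR' and build the table.

    Self-alignments are dropped; rows with an empty target span (R = 0)
    are rejected with a warning.  With ``best_row_per_pair`` each
    (query, target) pair keeps only its highest-identity row; by default
    all rows are kept independently and the purge rule fires if any row
    for a contig passes.
    """
    records: list[AlignmentRecord] = []
    lengths: dict[str, int] = {}
    for raw in raws:
        if raw.query_name == raw.target_name:
            continue
        denom = raw.matches + raw.mismatches
        if count_rep_matches:
            denom += raw.rep_matches
        r_frac = (raw.target_end - raw.target_start) / raw.target_length
        if r_frac == 0 or denom == 0:
            log.warning("degenerate alignment %s -> %s rejected (R=0)",
                        raw.query_name, raw.target_name)
            continue
        identity = raw.matches / denom
        q_frac = (raw.query_end - raw.query_start) / raw.query_length
        qr = q_frac / r_frac
        records.append(AlignmentRecord(
            raw=raw, identity=identity, q=q_frac, r=r_frac,
            qr=qr, qr_prime=qr_prime_of(qr),
        ))
        lengths[raw.query_name] = raw.query_length
        lengths[raw.target_name] = raw.target_length
    if best_row_per_pair:
        best: dict[tuple[str, str], AlignmentRecord] = {}
        for rec in records:
            key = (rec.raw.query_name, rec.raw.target_name)
            if key not in best or rec.identity > best[key].identity:
                best[key] = rec
        records = list(best.values())
    return AlignmentTable(records=records, contig_lengths=lengths)


def filter_eligible(table: AlignmentTable,
                    max_query_length: int = DEFAULT_MAX_QUERY_LENGTH,
                    require_query_not_longer: bool = True) -> AlignmentTable:
    """Restrict the table to rows whose query is a plausible haplotig.

    Long queries (> ``max_query_length``, default 10 Mb) are unlikely to be
    alternative haplotigs and are removed as queries (they remain usable as
    targets).  With ``require_query_not_longer`` (default), only the shorter
    contig of each pair is purge-eligible; for equal-length pairs exactly
    one of the reciprocal rows is kept — the one whose query name sorts
    lexicographically later.
    """
    kept: list[AlignmentRecord] = []
    for rec in table.records:
        raw = rec.raw
        if raw.query_length > max_query_length:
            continue
        if require_query_not_longer:
            if raw.query_length > raw.target_length:
                continue
            if (raw.query_length == raw.target_length
                    and raw.query_name < raw.target_name):
                continue
        kept.append(rec)
    return AlignmentTable(records=kept, contig_lengths=dict(table.contig_lengths))
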