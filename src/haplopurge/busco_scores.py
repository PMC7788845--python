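"""Per-contig BUSCO tables and candidate-assembly count aggregation.

BUSCO scores a lineage-specific set of universally single-copy genes
against an assembly; each gene comes back Complete (Single-copy or
Duplicated), Fragmented, or Missing.  Running BUSCO once per contig and
keeping, for every contig, the sets of complete and fragmented gene IDs
lets the counts (S, D, F, M) of *any* subset of contigs be recomputed in
memory without re-running BUSCO — the key trick that makes threshold
optimization over thousands of candidate assemblies affordable.

Classification over a retained contig set: a gene complete on exactly one
retained contig is Single-copy, on two or more Duplicated; a gene never
complete but fragmented somewhere is Fragmented; the rest of the lineage
universe is Missing.  Complete evidence dominates fragmented evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ContigBuscoRecord",
    "BuscoCatalog",
    "BuscoCounts",
    "BuscoParseError",
    "parse_busco_full_table",
    "load_busco_dir",
    "load_busco_table",
    "aggregate_counts",
]

log = logging.getLogger(__name__)

_COMPLETE_STATUSES = frozenset({"Complete", "Duplicated"})
_KNOWN_STATUSES = frozenset({"Complete", "Duplicated", "Fragmented", "Missing"})


class BuscoParseError(ValueError):
    """Malformed BUSCO full_table input."""


@dataclass
class ContigBuscoRecord:
    """Complete and fragmented BUSCO gene IDs found on one contig.

    A gene Duplicated *within* one contig still counts as complete on that
    contig (cross-contig duplication is what purging targets); a gene both
    complete and fragmented on the same contig is kept only as complete.
    """

    contig: str
    complete_ids: set[str] = field(default_factory=set)
    fragmented_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.fragmented_ids -= self.complete_ids


@dataclass
class BuscoCatalog:
    """All per-contig BUSCO records plus the lineage universe size."""

    records: dict[str, ContigBuscoRecord]
    universe_size: int

    def __post_init__(self) -> None:
        observed: set[str] = set()
        for rec in self.records.values():
            observed |= rec.complete_ids | rec.fragmented_ids
        if self.universe_size < len(observed):
            raise ValueError(
                f"universe_size {self.universe_size} smaller than the "
                f"{len(observed)} distinct BUSCO genes observed")


@dataclass(frozen=True)
class BuscoCounts:
    """Missing / Duplicated / Fragmented / Single-copy gene counts."""

    M: int
    D: int
    F: int
    S: int

    @property
    def total(self) -> int:
        return self.M + self.D + self.F + self.S


def parse_busco_full_table(path: str | Path,
                           contig_override: str | None = None) -> ContigBuscoRecord:
    """Parse one BUSCO v3 ``full_table`` TSV for a single contig.

    Comment lines start with ``#``.  Data columns are busco_id, status,
    then optional location columns.  Missing genes are ignored; Complete
    and Duplicated both land in ``complete_ids``.
    """
    path = Path(path)
    contig = contig_override if contig_override is not None else path.stem
    complete: set[str] = set()
    fragmented: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BuscoParseError(
                    f"{path} line {line_no}: expected >= 2 columns")
            busco_id, status = fields[0], fields[1]
            if status not in _KNOWN_STATUSES:
                raise BuscoParseError(
                    f"{path} line {line_no}: unknown BUSCO status {status!r}")
            if status in _COMPLETE_STATUSES:
                complete.add(busco_id)
            elif status == "Fragmented":
                fragmented.add(busco_id)
    return ContigBuscoRecord(contig=contig, complete_ids=complete,
                             fragmented_ids=fragmented)


def _full_table_in(directory: Path) -> Path | None:
    hits = sorted(directory.glob("full_table*"))
    return hits[0] if hits else None


def load_busco_dir(directory: str | Path, universe_size: int) -> BuscoCatalog:
    """Build a catalog from per-contig BUSCO output directories.

    Accepts either one subdirectory per contig containing a
    ``full_table*`` file (contig = subdirectory name, with any BUSCO
    ``run_`` prefix stripped), or flat ``full_table_<contig>.tsv`` files.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"BUSCO directory not found: {directory}")
    records: dict[str, ContigBuscoRecord] = {}
    for entry in sorted(directory.iterdir()):
        if entry.is_dir():
            table = _full_table_in(entry)
            if table is None:
                continue
            contig = entry.name.removeprefix("run_")
            records[contig] = parse_busco_full_table(table, contig_override=contig)
        elif entry.name.startswith("full_table"):
            contig = entry.stem.removeprefix("full_table").lstrip("_.")
            if not contig:
                raise BuscoParseError(
                    f"cannot recover contig name from {entry.name}")
            records[contig] = parse_busco_full_table(entry, contig_override=contig)
    return BuscoCatalog(records=records, universe_size=universe_size)


def load_busco_table(path: str | Path, universe_size: int) -> BuscoCatalog:
    """Build a catalog from a single merged TSV with a contig column.

    Columns: contig, busco_id, status.  Comment lines start with ``#``.
    """
    path = Path(path)
    complete: dict[str, set[str]] = {}
    fragmented: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BuscoParseError(
                    f"{path} line {line_no}: expected >= 3 columns "
                    "(contig, busco_id, status)")
            contig, busco_id, status = fields[0], fields[1], fields[2]
            if status not in _KNOWN_STATUSES:
                raise BuscoParseError(
                    f"{path} line {line_no}: unknown BUSCO status {status!r}")
            complete.setdefault(contig, set())
            fragmented.setdefault(contig, set())
            if status in _COMPLETE_STATUSES:
                complete[contig].add(busco_id)
            elif status == "Fragmented":
                fragmented[contig].add(busco_id)
    records = {
        contig: ContigBuscoRecord(contig=contig, complete_ids=complete[contig],
                                  fragmented_ids=fragmented[contig])
        for contig in complete
    }
    return BuscoCatalog(records=records, universe_size=universe_size)


def aggregate_counts(catalog: BuscoCatalog,
                     retained: Iterable[str]) -> BuscoCounts:
    """S/D/F/M counts over the contigs retained in a candidate assembly.

    Contig names absent from the catalog contribute empty sets (a contig
    with no BUSCO hits is legitimate).  M + D + F + S always equals the
    lineage universe size.
    """
    complete_count: dict[str, int] = {}
    fragmented_seen: set[str] = set()
    for name in retained:
        rec = catalog.records.get(name)
        if rec is None:
            continue
        for g in rec.complete_ids:
            complete_count[g] = complete_count.get(g, 0) + 1
        fragmented_seen |= rec.fragmented_ids
    single = sum(1 for c in complete_count.values() if c == 1)
    dup = sum(1 for c in complete_count.values() if c >= 2)
    frag = len(fragmented_seen - complete_count.keys())
    missing = catalog.universe_size - single - dup - frag
    return BuscoCounts(M=missing, D=dup, F=frag, S=single)
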