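"""FASTA handling, contig size-sorting/splitting and assembly statistics."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ContigSet",
    "AssemblyStats",
    "read_fasta",
    "write_fasta",
    "size_sort",
    "split_contigs",
    "assembly_stats",
]

log = logging.getLogger(__name__)


@dataclass
class ContigSet:
    """Ordered named contigs with sequences and a length map.

    Contig identity is the header token before the first whitespace;
    sequences are stored upper-cased.
    """

    names: list[str]
    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(self.sequences[n]) for n in self.names}

    def __len__(self) -> int:
        return len(self.names)

    def subset(self, names: Iterable[str]) -> "ContigSet":
        wanted = set(names)
        kept = [n for n in self.names if n in wanted]
        return ContigSet(names=kept,
                         sequences={n: self.sequences[n] for n in kept})


@dataclass(frozen=True)
class AssemblyStats:
    """QUAST-style contiguity summary of a contig length distribution."""

    n_contigs: int
    total_length: int
    largest: int
    N50: int
    L50: int


def read_fasta(path: str | Path) -> ContigSet:
    """Read a FASTA file into a ContigSet (duplicate headers rejected)."""
    names: list[str] = []
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id  # Biopython already truncates at whitespace
        if name in sequences:
            raise ValueError(f"duplicate FASTA header: {name!r}")
        seq = str(record.seq).upper()
        if not seq:
            log.warning("empty sequence for contig %s", name)
        names.append(name)
        sequences[name] = seq
    return ContigSet(names=names, sequences=sequences)


def write_fasta(contigs: ContigSet, names: Sequence[str] | None,
                path: str | Path, width: int = 80) -> None:
    """Write the named subset (or all contigs) as 80-column-wrapped FASTA."""
    if names is None:
        names = contigs.names
    unknown = [n for n in names if n not in contigs.sequences]
    if unknown:
        raise ValueError(f"names not in contig set: {unknown}")
    records = [SeqRecord(Seq(contigs.sequences[n]), id=n, description="")
               for n in names]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(records)


def size_sort(contigs: ContigSet) -> list[str]:
    """Contig names by descending length; equal lengths sort by name."""
    return sorted(contigs.names, key=lambda n: (-len(contigs.sequences[n]), n))


_SANITIZE_RE = re.compile(r"[^A-Za-z0-9._-]")


def sanitize_name(name: str) -> str:
    return _SANITIZE_RE.sub("_", name)


def split_contigs(contigs: ContigSet, out_dir: str | Path) -> list[Path]:
    """Write one single-record FASTA per contig (names sanitized for paths)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seen: dict[str, str] = {}
    paths = []
    for name in contigs.names:
        safe = sanitize_name(name)
        if safe in seen:
            raise ValueError(
                f"contig names {seen[safe]!r} and {name!r} collide after "
                f"sanitizing to {safe!r}")
        seen[safe] = name
        path = out_dir / f"{safe}.fasta"
        write_fasta(contigs, [name], path)
        paths.append(path)
    return paths


def assembly_stats(lengths: Iterable[int]) -> AssemblyStats:
    """N50/L50 summary of contig lengths.

    N50 is the length of the contig at which the cumulative sum of
    descending-sorted lengths first reaches half the total; L50 is that
    contig's 1-based rank.
    """
    lens = sorted(lengths, reverse=True)
    if not lens:
        raise ValueError("no contig lengths given")
    if lens[-1] <= 0:
        raise ValueError("contig lengths must be positive")
    total = sum(lens)
    half = total / 2
    cum = 0
    for i, ln in enumerate(lens, start=1):
        cum += ln
        if cum >= half:
            return AssemblyStats(n_contigs=len(lens), total_length=total,
                                 largest=lens[0], N50=ln, L50=i)
    raise AssertionError("unreachable")  # cum == total >= half
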