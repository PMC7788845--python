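"""Unique priority queue (UPQ) of the x best candidate assemblies.

The optimizer evaluates many threshold triples that collapse to the same
retained contig set, so candidates are deduplicated by that set, keeping
the lowest cost seen for it.  Two sets of different size can never be
equal, so set comparison is bucketed by retained-set size; within a
bucket a hash lookup on the frozen set decides equality.  Entries are
kept sorted by cost so the worst retained score is readable from the
tail without scanning, letting clearly-worse candidates be rejected with
a single comparison.

Cost ties between distinct sets are broken deterministically by larger
retained set first, then by the sorted contig-name tuple, so store
contents are independent of push order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .purge_engine import CandidateAssembly, write_purge_report

__all__ = ["CandidateStore"]


def _entry_key(entry: CandidateAssembly) -> tuple:
    return (entry.cost, -len(entry.retained), tuple(sorted(entry.retained)))


def _thr_key(entry: CandidateAssembly) -> tuple[float, float, float]:
    t = entry.thresholds
    return (t.id_t, t.q_t, t.qr_t)


@dataclass
class CandidateStore:
    """Capacity-bounded, deduplicating, cost-sorted candidate container."""

    capacity: int
    entries: list[CandidateAssembly] = field(default_factory=list)
    _buckets: dict[int, dict[frozenset, CandidateAssembly]] = field(
        default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def worst_score(self) -> float:
        """Cost of the worst retained entry; +inf when empty (anything qualifies)."""
        if not self.entries:
            return float("inf")
        return self.entries[-1].cost

    def push(self, candidate: CandidateAssembly) -> bool:
        """Insert a fully scored candidate; returns True if the store changed."""
        if candidate.cost is None:
            raise ValueError("candidate must be scored before pushing")
        if len(self.entries) >= self.capacity and candidate.cost > self.worst_score():
            return False
        size = len(candidate.retained)
        bucket = self._buckets.setdefault(size, {})
        existing = bucket.get(candidate.retained)
        if existing is not None:
            # equal-cost duplicates tie-break on thresholds so the surviving
            # entry does not depend on push order
            if (candidate.cost, _thr_key(candidate)) >= (existing.cost, _thr_key(existing)):
                return False
            self.entries.remove(existing)
        bucket[candidate.retained] = candidate
        self.entries.append(candidate)
        self.entries.sort(key=_entry_key)
        while len(self.entries) > self.capacity:
            evicted = self.entries.pop()
            del self._buckets[len(evicted.retained)][evicted.retained]
        return True

    def best(self) -> CandidateAssembly:
        if not self.entries:
            raise IndexError("empty candidate store")
        return self.entries[0]

    def export(self, contigs, out_dir: str | Path) -> list[Path]:
        """Write one FASTA + purge report per candidate, ranked by cost.

        ``contigs`` is an :class:`~haplopurge.assembly_io.ContigSet`
        covering the full assembly.  Returns the FASTA paths written.
        """
        from .assembly_io import write_fasta  # deferred: avoid import cycle

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for rank, entry in enumerate(self.entries, start=1):
            fasta = out_dir / f"candidate_{rank:03d}.fasta"
            names = [n for n in contigs.names if n in entry.retained]
            write_fasta(contigs, names, fasta)
            write_purge_report(entry, out_dir / f"candidate_{rank:03d}.purge.tsv")
            paths.append(fasta)
        return paths
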