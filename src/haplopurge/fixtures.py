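"""Synthetic diploid-like assemblies with planted alternative haplotigs.

Real haplotig-purging inputs are multi-gigabyte assemblies plus aligner
and BUSCO runs.  This generator emulates all three inputs at toy scale
with exact ground truth:

* primary contigs are independent random nucleotide strings;
* each planted haplotig copies a contiguous span of one primary contig
  and applies substitutions at a fixed rate — substitution-only
  divergence keeps the alignment identity analytically exact
  (``1 - n_substitutions / span``), so alignment rows can be written
  without running an aligner;
* each primary contig carries a block of distinct BUSCO genes laid out in
  equal windows along its length; a haplotig inherits the genes whose
  window midpoint falls inside the copied span, planting the duplicated
  BUSCOs that purging should remove.

Contig names are assigned in a shuffled order so a name reveals nothing
about primary/secondary status; truth lives only in
:class:`FixtureTruth`.  Decoy alignments between unrelated primary
contigs (identity 0.30, far below any plausible threshold) exercise the
negative path of the purge rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .alignment_metrics import (
    AlignmentTable,
    RawAlignment,
    compute_metrics,
    write_psl,
)
from .assembly_io import ContigSet
from .busco_scores import BuscoCatalog, ContigBuscoRecord

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "make_fixture",
    "make_alignment_table",
    "make_raw_alignments",
    "make_busco_catalog",
    "write_fixture_dir",
]

_BASES = np.array(list("ACGT"))

DECOY_IDENTITY = 0.30
DECOY_SPAN_FRACTION = 0.40


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic assembly."""

    n_primary: int = 4
    primary_length_range: tuple[int, int] = (6_000, 10_000)
    n_haplotigs: int = 2
    divergence: float = 0.02
    haplotig_span: float = 0.8
    n_busco_genes: int = 40
    busco_per_contig: int = 5
    seed: int = 42
    decoys: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence < 0.5):
            raise ValueError("divergence must lie in [0, 0.5)")
        if not (0.0 < self.haplotig_span <= 1.0):
            raise ValueError("haplotig_span must lie in (0, 1]")
        if self.n_primary < 1:
            raise ValueError("need at least one primary contig")
        if self.n_primary * self.busco_per_contig > self.n_busco_genes:
            raise ValueError(
                "BUSCO genes oversubscribed: "
                f"{self.n_primary} x {self.busco_per_contig} > {self.n_busco_genes}")


@dataclass
class FixtureTruth:
    """Ground-truth labels for a generated fixture.

    ``spans`` and ``n_substitutions`` record, per haplotig, the copied
    source interval (0-based half-open) and the exact substitution count,
    from which alignment rows and expected identities follow.
    """

    secondary_names: set[str]
    source_of: dict[str, str]
    primary_names: list[str] = field(default_factory=list)
    spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_substitutions: dict[str, int] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply exactly n_subs substitutions at distinct positions."""
    if n_subs == 0:
        return seq
    arr = np.array(list(seq))
    positions = rng.choice(len(arr), size=n_subs, replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(0, 3)]
    return "".join(arr)


def make_fixture(spec: FixtureSpec) -> tuple[ContigSet, FixtureTruth]:
    """Generate the contig set and its truth labels (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.primary_length_range
    primary_seqs = [_random_seq(rng, int(rng.integers(lo, hi + 1)))
                    for _ in range(spec.n_primary)]

    haplotigs: list[tuple[int, str, tuple[int, int], int]] = []
    for h in range(spec.n_haplotigs):
        src_idx = h % spec.n_primary
        src = primary_seqs[src_idx]
        span_len = max(1, round(spec.haplotig_span * len(src)))
        start = int(rng.integers(0, len(src) - span_len + 1))
        copied = src[start:start + span_len]
        n_subs = round(spec.divergence * span_len)
        haplotigs.append((src_idx, _mutate(rng, copied, n_subs),
                          (start, start + span_len), n_subs))

    total = spec.n_primary + spec.n_haplotigs
    order = rng.permutation(total)  # names reveal nothing about truth
    names = [f"ctg{order[i]:03d}" for i in range(total)]
    primary_names = names[:spec.n_primary]
    haplotig_names = names[spec.n_primary:]

    sequences = {n: s for n, s in zip(primary_names, primary_seqs)}
    truth = FixtureTruth(secondary_names=set(haplotig_names),
                         source_of={}, primary_names=list(primary_names))
    for name, (src_idx, seq, span, n_subs) in zip(haplotig_names, haplotigs):
        sequences[name] = seq
        truth.source_of[name] = primary_names[src_idx]
        truth.spans[name] = span
        truth.n_substitutions[name] = n_subs

    ordered = sorted(sequences)  # stable, truth-agnostic file order
    return ContigSet(names=ordered, sequences=sequences), truth


def make_raw_alignments(contigs: ContigSet,
                        truth: FixtureTruth,
                        spec: FixtureSpec) -> list[RawAlignment]:
    """Alignment rows implied by the planted haplotigs, plus decoys.

    Each haplotig aligns full-length (Q = 1) to its source span with
    identity exactly ``1 - n_subs / span``.  Decoys pair consecutive
    primaries at identity 0.30 over 40% of the (shorter) query.
    """
    rows: list[RawAlignment] = []
    for hap in sorted(truth.secondary_names):
        source = truth.source_of[hap]
        start, end = truth.spans[hap]
        hap_len = len(contigs.sequences[hap])
        n_subs = truth.n_substitutions[hap]
        rows.append(RawAlignment(
            query_name=hap, query_length=hap_len,
            query_start=0, query_end=hap_len,
            target_name=source, target_length=len(contigs.sequences[source]),
            target_start=start, target_end=end,
            matches=hap_len - n_subs, mismatches=n_subs,
            rep_matches=0, block_length=hap_len,
        ))
    if spec.decoys and len(truth.primary_names) >= 2:
        prims = sorted(truth.primary_names)
        for a, b in zip(prims, prims[1:]):
            # shorter contig as query so the row survives filter_eligible
            q, t = sorted((a, b), key=lambda n: (len(contigs.sequences[n]), n))
            q_len = len(contigs.sequences[q])
            t_len = len(contigs.sequences[t])
            span = max(1, round(DECOY_SPAN_FRACTION * q_len))
            matches = round(DECOY_IDENTITY * span)
            rows.append(RawAlignment(
                query_name=q, query_length=q_len,
                query_start=0, query_end=span,
                target_name=t, target_length=t_len,
                target_start=0, target_end=span,
                matches=matches, mismatches=span - matches,
                rep_matches=0, block_length=span,
            ))
    return rows


def make_alignment_table(contigs: ContigSet, truth: FixtureTruth,
                         spec: FixtureSpec,
                         psl_path: str | Path | None = None) -> AlignmentTable:
    """Metric table for the fixture; optionally serialized as a PSL file."""
    rows = make_raw_alignments(contigs, truth, spec)
    if psl_path is not None:
        write_psl(rows, psl_path)
    table = compute_metrics(rows)
    # contigs without alignments still need length entries downstream
    for name in contigs.names:
        table.contig_lengths.setdefault(name, len(contigs.sequences[name]))
    return table


def _gene_windows(contig_length: int, n_genes: int) -> list[tuple[int, int]]:
    bounds = np.linspace(0, contig_length, n_genes + 1)
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(n_genes)]


def make_busco_catalog(contigs: ContigSet, truth: FixtureTruth,
                       spec: FixtureSpec) -> BuscoCatalog:
    """Per-contig complete-gene sets with planted cross-contig duplicates."""
    gene_of: dict[str, list[str]] = {}
    counter = 0
    records: dict[str, ContigBuscoRecord] = {}
    for prim in truth.primary_names:
        genes = [f"g{counter + i:04d}" for i in range(spec.busco_per_contig)]
        counter += spec.busco_per_contig
        gene_of[prim] = genes
        records[prim] = ContigBuscoRecord(contig=prim, complete_ids=set(genes))
    for hap in sorted(truth.secondary_names):
        source = truth.source_of[hap]
        start, end = truth.spans[hap]
        windows = _gene_windows(len(contigs.sequences[source]),
                                spec.busco_per_contig)
        inherited = {
            gene for gene, (wlo, whi) in zip(gene_of[source], windows)
            if start <= (wlo + whi) / 2 < end
        }
        records[hap] = ContigBuscoRecord(contig=hap, complete_ids=inherited)
    return BuscoCatalog(records=records, universe_size=spec.n_busco_genes)


def write_fixture_dir(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit fixture FASTA, PSL, merged BUSCO TSV and truth labels.

    Returns the mapping of artifact kind to path.  Byte-identical for a
    given spec (including seed).
    """
    from .assembly_io import write_fasta  # local import keeps module load light

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs, truth = make_fixture(spec)
    paths = {
        "fasta": out_dir / "assembly.fasta",
        "psl": out_dir / "alignments.psl",
        "busco": out_dir / "busco_full_table.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_fasta(contigs, None, paths["fasta"])
    make_alignment_table(contigs, truth, spec, psl_path=paths["psl"])
    catalog = make_busco_catalog(contigs, truth, spec)
    with open(paths["busco"], "wt") as fh:
        fh.write(f"# synthetic merged BUSCO table; universe_size={spec.n_busco_genes}\n")
        fh.write("# contig\tbusco_id\tstatus\n")
        for contig in sorted(catalog.records):
            rec = catalog.records[contig]
            for g in sorted(rec.complete_ids):
                fh.write(f"{contig}\t{g}\tComplete\n")
            for g in sorted(rec.fragmented_ids):
                fh.write(f"{contig}\t{g}\tFragmented\n")
    with open(paths["truth"], "wt") as fh:
        fh.write("contig\tlabel\tsource\n")
        for name in contigs.names:
            if name in truth.secondary_names:
                fh.write(f"{name}\tsecondary\t{truth.source_of[name]}\n")
            else:
                fh.write(f"{name}\tprimary\t-\n")
    return paths
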