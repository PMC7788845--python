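"""Threshold-based purging of putative secondary haplotigs.

One point in search space is a triple of thresholds (ID_T, Q_T, QR_T).  A
query contig is purged iff *any* of its alignment rows satisfies all
three conditions:

1. identity >= ID_T,
2. aligned query fraction Q >= Q_T,
3. QR within the inclusive window [min(QR_T, QR'_T), max(QR_T, QR'_T)],
   where QR'_T = exp(-log2(QR_T)) makes the window symmetric around 1.

Purging is single-pass: a purged contig still serves as reference for
other rows within the same evaluation.  The candidate assembly (the
retained set) is scored by its BUSCO counts through

    Cost = (theta1*M + theta2*D + theta3*F) / (theta4*S)

so candidates that keep many single-copy genes while shedding duplicated
ones are cheap.  Default weights are 1 for M, D, S and 0 for F.  S = 0
yields an infinite cost rather than an error, so an optimizer can
traverse degenerate regions of threshold space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from .alignment_metrics import AlignmentTable, qr_prime_of
from .busco_scores import BuscoCatalog, BuscoCounts, aggregate_counts

__all__ = [
    "Thresholds",
    "Weights",
    "CandidateAssembly",
    "DEFAULT_THRESHOLDS",
    "qr_window",
    "candidate_assembly",
    "cost",
    "score_candidate",
    "write_purge_report",
]


@dataclass(frozen=True)
class Thresholds:
    """One point (ID_T, Q_T, QR_T) in threshold space."""

    id_t: float
    q_t: float
    qr_t: float

    def __post_init__(self) -> None:
        if not (0.0 < self.id_t <= 1.0 and 0.0 < self.q_t <= 1.0):
            raise ValueError(
                f"ID_T and Q_T must lie in (0, 1]: {self.id_t}, {self.q_t}")
        if self.qr_t <= 0.0:
            raise ValueError(f"QR_T must be positive: {self.qr_t}")

    @property
    def qr_prime_t(self) -> float:
        return qr_prime_of(self.qr_t)


DEFAULT_THRESHOLDS = Thresholds(id_t=0.70, q_t=0.70, qr_t=0.70)


@dataclass(frozen=True)
class Weights:
    """Cost weights for (M, D, F, S); each in [0, 1], S weight positive."""

    theta_m: float = 1.0
    theta_d: float = 1.0
    theta_f: float = 0.0
    theta_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("theta_m", "theta_d", "theta_f", "theta_s"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]: {v}")
        if self.theta_s == 0.0:
            raise ValueError("theta_s must be > 0 (cost denominator)")


@dataclass(frozen=True)
class CandidateAssembly:
    """A retained/purged contig partition with optional score."""

    retained: frozenset[str]
    purged: frozenset[str]
    thresholds: Thresholds
    counts: BuscoCounts | None = None
    cost: float | None = None


def qr_window(thresholds: Thresholds) -> tuple[float, float]:
    """Inclusive [lo, hi] window of acceptable QR values."""
    lo = min(thresholds.qr_t, thresholds.qr_prime_t)
    hi = max(thresholds.qr_t, thresholds.qr_prime_t)
    return lo, hi


def candidate_assembly(table: AlignmentTable, thresholds: Thresholds,
                       all_contigs: Iterable[str]) -> CandidateAssembly:
    """Apply one threshold triple to the (already filtered) table.

    Single-pass purge over all rows; counts and cost are left unset for
    :func:`score_candidate` to fill.
    """
    universe = frozenset(all_contigs)
    missing = {
        name
        for rec in table.records
        for name in (rec.raw.query_name, rec.raw.target_name)
        if name not in universe
    }
    if missing:
        raise ValueError(
            f"alignment table names contigs absent from the assembly: "
            f"{sorted(missing)}")
    lo, hi = qr_window(thresholds)
    purged = {
        rec.raw.query_name
        for rec in table.records
        if rec.identity >= thresholds.id_t
        and rec.q >= thresholds.q_t
        and lo <= rec.qr <= hi
    }
    return CandidateAssembly(
        retained=universe - purged,
        purged=frozenset(purged),
        thresholds=thresholds,
    )


def cost(counts: BuscoCounts, weights: Weights = Weights()) -> float:
    """(theta1*M + theta2*D + theta3*F) / (theta4*S); +inf when S = 0."""
    if counts.S == 0:
        return math.inf
    numerator = (weights.theta_m * counts.M + weights.theta_d * counts.D
                 + weights.theta_f * counts.F)
    return numerator / (weights.theta_s * counts.S)


def score_candidate(candidate: CandidateAssembly, catalog: BuscoCatalog,
                    weights: Weights = Weights()) -> CandidateAssembly:
    """Fill in BUSCO counts and Cost for a candidate's retained set."""
    counts = aggregate_counts(catalog, candidate.retained)
    return replace(candidate, counts=counts, cost=cost(counts, weights))


def write_purge_report(candidate: CandidateAssembly, path: str | Path) -> None:
    """Two-column TSV listing each contig as primary or secondary."""
    with open(path, "wt") as fh:
        fh.write("contig\tstatus\n")
        for name in sorted(candidate.retained | candidate.purged):
            status = "secondary" if name in candidate.purged else "primary"
            fh.write(f"{name}\t{status}\n")
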