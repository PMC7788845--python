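"""Hill-climbing minimization of the BUSCO cost over threshold space.

The search walks (ID_T, Q_T, QR_T) as a randomized forward agent: each
iteration evaluates the candidate assembly at the current point, then
adds ``step_increment * U(0,1)`` (independent draws) to every threshold.
If the cost has not changed for ``plateau_limit`` consecutive iterations,
or any threshold crosses its upper limit (1.00 for all three — QR values
above 1 are already covered through the symmetric QR' window), the agent
restarts at fresh thresholds drawn uniformly from (0, 1].

The default-threshold point (0.70, 0.70, 0.70) — the single-shot "-HC"
purge — is always evaluated at iteration 0 (unless an explicit start is
given), so a hill-climbed result is never worse than the default one.
All evaluated candidates flow into a :class:`CandidateStore`, which keeps
the x best unique retained sets.  Retained-set costs are cached, since
many threshold triples collapse to the same purge outcome.

Parallelism is expressed as independent seeded runs merged afterwards
with :func:`merge_runs`, keeping every single run exactly reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment_metrics import AlignmentTable
from .busco_scores import BuscoCatalog, aggregate_counts
from .candidate_store import CandidateStore
from .purge_engine import (
    DEFAULT_THRESHOLDS,
    CandidateAssembly,
    Thresholds,
    Weights,
    cost,
    qr_window,
)

__all__ = [
    "HillClimbConfig",
    "ClimbTrace",
    "hill_climb",
    "merge_runs",
    "normalize_costs",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HillClimbConfig:
    """Tuning knobs of the hill climb.

    ``step_increment`` is the fixed step scale (default 0.0001) that gets
    multiplied by a fresh U(0,1) draw per threshold per iteration;
    ``plateau_limit`` is the number of consecutive unchanged-cost steps
    tolerated before a random restart; ``best_x`` is the store capacity;
    ``qr_cap`` is the restart boundary for QR_T.
    """

    iterations: int = 50_000
    step_increment: float = 0.0001
    plateau_limit: int = 50
    best_x: int = 10
    weights: Weights = field(default_factory=Weights)
    seed: int = 0
    start: Thresholds | None = None
    qr_cap: float = 1.0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.step_increment <= 0:
            raise ValueError("step_increment must be > 0")
        if self.plateau_limit < 1:
            raise ValueError("plateau_limit must be >= 1")
        if self.best_x < 1:
            raise ValueError("best_x must be >= 1")


@dataclass
class ClimbTrace:
    """Per-iteration record of the walk (thresholds, cost, running best)."""

    iterations: list[int] = field(default_factory=list)
    id_t: list[float] = field(default_factory=list)
    q_t: list[float] = field(default_factory=list)
    qr_t: list[float] = field(default_factory=list)
    costs: list[float] = field(default_factory=list)
    best_costs: list[float] = field(default_factory=list)
    restarts: list[bool] = field(default_factory=list)

    def append(self, k: int, thresholds: Thresholds, c: float,
               best: float, restarted: bool) -> None:
        self.iterations.append(k)
        self.id_t.append(thresholds.id_t)
        self.q_t.append(thresholds.q_t)
        self.qr_t.append(thresholds.qr_t)
        self.costs.append(c)
        self.best_costs.append(best)
        self.restarts.append(restarted)

    def __len__(self) -> int:
        return len(self.iterations)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": self.iterations,
            "ID_T": self.id_t,
            "Q_T": self.q_t,
            "QR_T": self.qr_t,
            "cost": self.costs,
            "best_cost": self.best_costs,
            "restart": self.restarts,
        })

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _uniform_open_closed(rng: np.random.Generator, n: int) -> np.ndarray:
    """n independent draws from U(0, 1] (restart thresholds must be > 0)."""
    return 1.0 - rng.random(n)


def hill_climb(table: AlignmentTable, catalog: BuscoCatalog,
               all_contigs: Iterable[str],
               config: HillClimbConfig) -> tuple[CandidateStore, ClimbTrace]:
    """Minimize the candidate-assembly cost over threshold space.

    Returns the store of the ``best_x`` unique best candidates and the
    full per-iteration trace.  Fully deterministic for a given seed.
    """
    universe = frozenset(all_contigs)
    rng = np.random.default_rng(config.seed)
    store = CandidateStore(capacity=config.best_x)
    trace = ClimbTrace()

    # purge predicate inputs, flattened once for the hot loop
    rows = [(rec.raw.query_name, rec.identity, rec.q, rec.qr)
            for rec in table.records]
    bad = {name for name, *_ in rows if name not in universe} | {
        rec.raw.target_name for rec in table.records
        if rec.raw.target_name not in universe}
    if bad:
        raise ValueError(
            f"alignment table names contigs absent from the assembly: "
            f"{sorted(bad)}")

    cache: dict[frozenset, tuple] = {}

    def evaluate(thr: Thresholds) -> CandidateAssembly:
        lo, hi = qr_window(thr)
        purged = frozenset(
            name for name, ident, qv, qr in rows
            if ident >= thr.id_t and qv >= thr.q_t and lo <= qr <= hi)
        retained = universe - purged
        hit = cache.get(retained)
        if hit is None:
            counts = aggregate_counts(catalog, retained)
            hit = (counts, cost(counts, config.weights))
            cache[retained] = hit
        return CandidateAssembly(retained=retained, purged=purged,
                                 thresholds=thr, counts=hit[0], cost=hit[1])

    current = config.start if config.start is not None else DEFAULT_THRESHOLDS
    best = math.inf
    prev_cost: float | None = None
    plateau = 0
    restarted = False

    for k in range(config.iterations):
        cand = evaluate(current)
        store.push(cand)
        best = min(best, cand.cost)
        trace.append(k, current, cand.cost, best, restarted)

        if prev_cost is not None and cand.cost == prev_cost:
            plateau += 1
        else:
            plateau = 0
        prev_cost = cand.cost

        step = config.step_increment * rng.random(3)
        nxt_id = float(current.id_t + step[0])
        nxt_q = float(current.q_t + step[1])
        nxt_qr = float(current.qr_t + step[2])
        out_of_bounds = nxt_id > 1.0 or nxt_q > 1.0 or nxt_qr > config.qr_cap
        if plateau >= config.plateau_limit or out_of_bounds:
            draws = _uniform_open_closed(rng, 3)
            current = Thresholds(id_t=float(draws[0]), q_t=float(draws[1]),
                                 qr_t=float(draws[2]))
            plateau = 0
            prev_cost = None
            restarted = True
        else:
            current = Thresholds(id_t=nxt_id, q_t=nxt_q, qr_t=nxt_qr)
            restarted = False

    return store, trace


def merge_runs(stores: Sequence[CandidateStore], best_x: int) -> CandidateStore:
    """Union independent seeded runs into one best-x store.

    Candidates are deduplicated by retained set (keeping the lower cost)
    and truncated to ``best_x`` by cost.  All stores must have been built
    over the same contig universe.
    """
    universes = {
        entry.retained | entry.purged
        for store in stores for entry in store.entries
    }
    if len(universes) > 1:
        raise ValueError("stores were built over differing contig universes")
    merged = CandidateStore(capacity=best_x)
    for store in stores:
        for entry in store.entries:
            merged.push(entry)
    return merged


def normalize_costs(trace: ClimbTrace) -> np.ndarray:
    """Min-max normalize the trace costs to [0, 1]: (c - min)/(max - min).

    Infinite costs (S = 0 candidates) are excluded from the min/max range
    and map to 1.0.  A constant (or single-element) trace normalizes to
    all zeros with a warning.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    costs = np.asarray(trace.costs, dtype=float)
    finite = costs[np.isfinite(costs)]
    if finite.size == 0 or finite.max() == finite.min():
        log.warning("degenerate trace (constant cost): normalizing to zeros")
        return np.zeros_like(costs)
    lo, hi = finite.min(), finite.max()
    out = (costs - lo) / (hi - lo)
    out[~np.isfinite(costs)] = 1.0
    return np.clip(out, 0.0, 1.0)
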