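# Methods

## Model and assumptions

The purging model assumes that an alternative haplotig is a contig whose
sequence is a (possibly diverged, possibly clipped) copy of a region
already represented by another, usually longer, contig. Such a contig
shows up in the all-by-all self-alignment as a query aligning over most
of its length (`Q` near 1) at high identity (`ID`), with a
query/reference aligned-fraction ratio `QR = Q/R` near the span ratio of
the two contigs. Repetitive or partially homologous contig pairs produce
rows with low `Q` or low `ID` and are left alone. No coverage-depth
information is used; distinguishing collapsed repeats from haplotigs by
read depth is out of scope.

The decision rule is a conjunction of three per-row conditions
(`ID ≥ ID_T`, `Q ≥ Q_T`, `QR` inside `[min(QR_T, QR′_T), max(QR_T,
QR′_T)]`, both ends inclusive) and a contig is purged if *any* of its
query rows passes. Purging is single-pass: within one evaluation, a
contig purged by one row still counts as a reference for other rows.
Iterative re-purging would make the retained set depend on evaluation
order; the single-pass rule keeps each candidate assembly a pure
function of the thresholds.

## Metrics

- `ID = matches / (matches + mismatches + repMatches)`. The denominator
  excludes indel bases; for PSL input, repMatches are counted as aligned
  bases (toggle `count_rep_matches=False` to exclude them). For PAF
  input, which carries no separate mismatch count in its 12 mandatory
  columns, `mismatches = block_length − matches`, which collapses
  substitution and indel error together and therefore yields slightly
  lower identities than the PSL route for gapped alignments.
- `QR′ = exp(−log₂ QR)` mirrors QR around 1: a pair with QR = x and its
  reciprocal with QR = 1/x get QR′ values that multiply to 1, so one
  threshold covers both orientations of a clipped alignment.
- Multiple alignment rows between the same contig pair are kept as
  independent rows by default (`best_row_per_pair=True` keeps only the
  highest-identity row per pair).

## Query eligibility

Rows whose query exceeds 10 Mb (`max_query_length`) are excluded:
contigs that long are implausible haplotigs, and excluding them as
queries also bounds alignment cost upstream. With
`require_query_not_longer` (default), only the shorter contig of a pair
is purge-eligible; for equal lengths exactly one direction is kept (the
query whose name sorts later), so a reciprocal equal-length pair can
never purge both contigs.

## Cost and its parameters

`Cost = (θ₁M + θ₂D + θ₃F)/(θ₄S)` over the BUSCO class counts of the
retained set, all weights in [0, 1], defaults θ = (1, 1, 0, 1): missing
and duplicated genes are penalised equally, fragmented genes are
ignored, and the single-copy count normalises. `S = 0` returns +inf
rather than raising, so the optimizer can pass through degenerate
regions (e.g. thresholds that purge everything). The per-contig BUSCO
table records, for each contig, the sets of Complete and Fragmented gene
IDs; a gene Duplicated within one contig counts as complete on that
contig, and a gene complete on one retained contig and fragmented on
another counts toward S or D (complete evidence dominates). The lineage
universe size is a required input — it cannot be inferred from the
tables when genes are missing everywhere.

## Hill climbing

Tunable parameters (all per-run, dimensionless except where noted):

| parameter | default | meaning |
|---|---|---|
| `iterations` | 50 000 | total cost evaluations |
| `step_increment` | 0.0001 | step scale; actual step is `step_increment × U(0,1)` per threshold per iteration |
| `plateau_limit` | 50 | consecutive unchanged-cost steps before a random restart |
| `best_x` | 10 | capacity of the unique-candidate store |
| `qr_cap` | 1.00 | restart boundary for QR_T |

All three thresholds are stepped jointly each iteration with independent
uniform draws. Restarts draw each threshold from U(0, 1]; QR_T is capped
at 1.00 like ID_T and Q_T because the symmetric window already covers
ratios above 1, making QR_T > 1 redundant search space. The cost is
evaluated immediately at a restart point, and the plateau counter resets
across a restart, so a perfectly flat cost landscape restarts every
`plateau_limit + 1` evaluations. Iteration 0 always evaluates the
default 0.70/0.70/0.70 point (unless an explicit start is given), which
guarantees the hill-climbed result is never worse than the single-shot
default purge. Retained-set costs are cached, since many threshold
triples collapse to the same purge outcome.

Parallelism is expressed as independent seeded runs merged afterwards
(`merge_runs`), never shared RNG state, so every run is individually
reproducible and the merge is order-independent.

## Unique priority queue

Candidates are deduplicated by retained contig set, keeping the lowest
cost seen (cost ties between identical sets break on the threshold
triple, so store contents are push-order independent). Sets are bucketed
by size before comparison — unequal sizes cannot be equal sets — and
entries stay sorted by cost, so the worst retained score is read from
the tail in O(1) and clearly-worse candidates are rejected with one
comparison. Cost ties between *distinct* sets order by larger retained
set first, then lexicographically by contig names.

Trace costs are reported min-max normalised, `(c − min)/(max − min)`,
computed over the finite costs; +inf entries map to 1 and a constant
trace normalises to all zeros with a warning.

## Synthetic data generator

The fixture generator emulates the three inputs of a real run at toy
scale: primary contigs are i.i.d. random nucleotide strings (default 4
contigs of 6–10 kb); each planted haplotig copies a contiguous span
(default 80%) of a source primary and applies substitutions at a fixed
rate (default 2%, i.e. comfortably within the divergence of a
heterozygous diploid); each primary carries 5 distinct BUSCO genes laid
out in equal windows, inherited by a haplotig when the window midpoint
falls inside the copied span (planting cross-contig duplicates); the
universe is 40 genes, so half are missing from the toy assembly, as in
incomplete real assemblies. Decoy alignments between unrelated primaries
at identity 0.30 exercise the negative path. Divergence is
substitution-only, which keeps the alignment identity analytically exact
(`1 − substitutions/span`) so alignment rows are written without running
an aligner.

What the fixture does *not* emulate — and hence what passing tests do
not show about real data: indels and structural variants (alignment
clipping, QR far from the span ratio), repeat-induced spurious
alignments at high identity, fragmented BUSCO genes, chimeric contigs,
and assemblies large enough for alignment parsing to dominate runtime.
The fixture establishes correctness of the decision rule, the counts and
the optimizer, not field performance.

## Numerical choices and degenerate inputs

- The QR window is inclusive at both ends.
- Alignment rows with an empty target span (R = 0) are rejected with a
  warning; self-alignments are dropped silently.
- N50 uses the `cumulative ≥ total/2` convention; L50 is the 1-based
  rank of the N50 contig; size-sort ties break lexicographically.
- FASTA headers are truncated at the first whitespace and sequences
  upper-cased on read; duplicate headers are an error.
- Problem sizes used by the shipped checks (chosen to make every check a
  matter of seconds): the default 6-contig fixture; a 20³ exhaustive
  threshold grid versus a 20 000-iteration climb for the optimizer
  oracle; 200–1000 randomized instances for the purge-rule, count and
  queue oracles; 5000 iterations in the acceptance script.

## Known limitations

- No coverage-based evidence: a collapsed repeat aligning well to
  another contig can be purged as if it were a haplotig.
- Single-pass purging never reconsiders a reference that was itself
  purged; transitive chains of near-identical contigs may retain more
  than the minimal set.
- PAF identities are conservative (indel bases counted as mismatches).
- The hill climber is a local search with random restarts; on rugged
  cost landscapes the 50 000-iteration default is a budget, not a
  convergence guarantee.
- BUSCO v3 `full_table` TSVs only; v4/v5 JSON outputs are not parsed.
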