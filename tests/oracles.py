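"""Independent brute-force re-implementations used as test oracles.

These deliberately avoid the package's own code paths: the purge oracle
re-derives the QR window from scratch per (contig, record) pair, and the
store oracle recomputes the x-best-unique selection over the whole push
history on every query.
"""

import math


def naive_purged_set(records, thresholds):
    """Per-(contig, record) purge test, recomputing the window each time.

    ``records`` are (query_name, identity, q, qr) tuples; ``thresholds``
    is an (id_t, q_t, qr_t) triple.
    """
    id_t, q_t, qr_t = thresholds
    purged = set()
    contigs = {name for name, _, _, _ in records}
    for contig in contigs:
        for name, ident, q, qr in records:
            if name != contig:
                continue
            qr_prime_t = math.exp(-math.log2(qr_t))
            lo = min(qr_t, qr_prime_t)
            hi = max(qr_t, qr_prime_t)
            if ident >= id_t and q >= q_t and lo <= qr <= hi:
                purged.add(contig)
    return purged


def naive_best_x(pushes, capacity):
    """The x lowest-cost unique candidates from a push history.

    ``pushes`` are (retained frozenset, cost) pairs.  Deduplicate by
    retained set keeping the minimum cost, then order by (cost, larger
    set first, sorted contig names) and truncate.
    """
    best = {}
    for retained, cost in pushes:
        if retained not in best or cost < best[retained]:
            best[retained] = cost
    ranked = sorted(best.items(),
                    key=lambda kv: (kv[1], -len(kv[0]), tuple(sorted(kv[0]))))
    return ranked[:capacity]
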