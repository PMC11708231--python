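"""Numba kernel for bulk site-pattern simulation.

The kernel walks the structured coalescent for five sampled lineages over a
piecewise-constant population structure described by a time-sorted event
list, then emits one polarized pattern per accepted gene tree using exact
size-biased sampling (a tree of total branch length L below the sample MRCA
is accepted with probability L/M and receives a single uniformly placed
mutation).  This is the rare-mutation limit of dropping k ~ Poisson(μL)
mutations per tree and keeps the emitted patterns i.i.d.

Event encoding (arrays of equal length, sorted by time, ties broken by type):
    type 0  ENTER  a = leaf index (0-based), b = population index
    type 1  ADMIX  every lineage in population a moves to b with probability p
    type 2  MERGE  every lineage in population a moves to b
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BIG = 1.0e300


@njit(cache=True)
def _seed(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _one_tree(ev_time, ev_type, ev_a, ev_b, ev_p, lam, lpop, lmask, lbirth,
              emask, elen):
    """Simulate one gene tree; fill edge arrays; return number of edges.

    Returns -1 if the walk failed to coalesce (malformed event list).
    """
    nact = 0
    n_entered = 0
    n_leaves = 0
    for i in range(ev_type.shape[0]):
        if ev_type[i] == 0:
            n_leaves += 1
    nev = ev_time.shape[0]
    iev = 0
    t = 0.0
    nec = 0
    for _ in range(100000):
        te = ev_time[iev] if iev < nev else _BIG
        tot_pairs = 0
        for i in range(nact):
            for j in range(i + 1, nact):
                if lpop[i] == lpop[j]:
                    tot_pairs += 1
        if tot_pairs > 0:
            tc = t + np.random.exponential(1.0 / (lam * tot_pairs))
        else:
            tc = _BIG * 10.0
        if tc < te:
            # choose the k-th same-population pair
            k = int(np.random.random() * tot_pairs)
            if k >= tot_pairs:
                k = tot_pairs - 1
            ii = -1
            jj = -1
            c = 0
            for i in range(nact):
                for j in range(i + 1, nact):
                    if lpop[i] == lpop[j]:
                        if c == k:
                            ii = i
                            jj = j
                        c += 1
            emask[nec] = lmask[ii]
            elen[nec] = tc - lbirth[ii]
            nec += 1
            emask[nec] = lmask[jj]
            elen[nec] = tc - lbirth[jj]
            nec += 1
            lmask[ii] = lmask[ii] | lmask[jj]
            lbirth[ii] = tc
            lpop[jj] = lpop[nact - 1]
            lmask[jj] = lmask[nact - 1]
            lbirth[jj] = lbirth[nact - 1]
            nact -= 1
            t = tc
            if nact == 1 and n_entered == n_leaves:
                return nec
        else:
            if iev >= nev:
                return -1
            ty = ev_type[iev]
            if ty == 0:
                lpop[nact] = ev_b[iev]
                lmask[nact] = 1 << ev_a[iev]
                lbirth[nact] = te
                nact += 1
                n_entered += 1
            elif ty == 1:
                if ev_p[iev] > 0.0:  # beta=0 edges must not perturb the RNG stream
                    for i in range(nact):
                        if lpop[i] == ev_a[iev] and np.random.random() < ev_p[iev]:
                            lpop[i] = ev_b[iev]
            else:
                for i in range(nact):
                    if lpop[i] == ev_a[iev]:
                        lpop[i] = ev_b[iev]
            t = te
            iev += 1
    return -1


@njit(cache=True)
def _sim_pattern_counts(seed, n_patterns, ev_time, ev_type, ev_a, ev_b, ev_p,
                        lam, mask_to_row):
    """Accumulate ``n_patterns`` polarized patterns; return (counts, n_trees)."""
    np.random.seed(seed)
    lpop = np.empty(8, dtype=np.int64)
    lmask = np.empty(8, dtype=np.int64)
    lbirth = np.empty(8, dtype=np.float64)
    emask = np.empty(16, dtype=np.int64)
    elen = np.empty(16, dtype=np.float64)
    counts = np.zeros(15, dtype=np.int64)

    # pilot: estimate mean total length to set the acceptance bound M;
    # P(L > Lbar + 25) < e^-12 for these trees, so the truncation of the
    # size-biased density min(L, M) is negligible.
    lbar = 0.0
    n_pilot = 200
    for _ in range(n_pilot):
        nec = _one_tree(ev_time, ev_type, ev_a, ev_b, ev_p, lam,
                        lpop, lmask, lbirth, emask, elen)
        if nec < 0:
            return counts, -1
        s = 0.0
        for e in range(nec):
            s += elen[e]
        lbar += s
    lbar /= n_pilot
    bound = lbar + 25.0

    got = 0
    n_trees = n_pilot
    while got < n_patterns:
        nec = _one_tree(ev_time, ev_type, ev_a, ev_b, ev_p, lam,
                        lpop, lmask, lbirth, emask, elen)
        n_trees += 1
        if nec < 0:
            return counts, -1
        total = 0.0
        for e in range(nec):
            total += elen[e]
        if np.random.random() * bound >= total:
            continue
        r = np.random.random() * total
        acc = 0.0
        row = -1
        for e in range(nec):
            acc += elen[e]
            if r < acc:
                row = mask_to_row[emask[e]]
                break
        if row < 0:
            row = mask_to_row[emask[nec - 1]]
        if row >= 0:  # full-sample masks (all five) never occur below the MRCA
            counts[row] += 1
            got += 1
    return counts, n_trees
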