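"""Numba kernels for the backward-time coalescent.

The model is passed in as a compiled epoch table (see
:class:`craterdemog.demography.EpochTable`): piecewise exponential deme
sizes, piecewise-constant backward migration rates, and probabilistic
lineage moves (admixture pulses, deme foundings) applied at epoch
boundaries.

One genealogy = one unlinked site.  The per-genealogy bookkeeping tracks,
for every lineage, how many sampled copies from population 1 and 2 it
subtends, so branch lengths can be accumulated directly into joint-SFS
cells without storing trees.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

TIME_CAP = 1.0e15  # generations; exceeding this means lineages are stranded


@njit(cache=True, inline="always", fastmath=True)
def _simulate_tree(
    times, n0, g, mig, mb, mf, mt, mp,
    leaf_deme, leaf_pop,
    c1, c2, birth, members, cnt,
    br_c1, br_c2, br_len, parent, ntime,
):
    """Simulate one genealogy in place.

    Returns (n_branches, ok_flag).  ``br_*`` receive one entry per non-root
    branch (2n - 2 of them); ``parent``/``ntime`` receive the tree topology
    (leaves 0..n-1, internal nodes appended in coalescence order).
    """
    D = n0.shape[1]
    n = leaf_deme.shape[0]
    K = times.shape[0] - 1
    M = mb.shape[0]

    for d in range(D):
        cnt[d] = 0
    for i in range(n):
        d = leaf_deme[i]
        members[d, cnt[d]] = i
        cnt[d] += 1
        if leaf_pop[i] == 0:
            c1[i] = 1
            c2[i] = 0
        else:
            c1[i] = 0
            c2[i] = 1
        birth[i] = 0.0
        parent[i] = -1
        ntime[i] = 0.0

    t = 0.0
    k = 0
    active = n
    next_node = n
    nbr = 0

    # boundary moves attached to epoch 0 (time-zero events)
    for m in range(M):
        if mb[m] == 0:
            fd = mf[m]
            td = mt[m]
            p = mp[m]
            i = cnt[fd] - 1
            while i >= 0:
                if p >= 1.0 or np.random.random() < p:
                    node = members[fd, i]
                    members[td, cnt[td]] = node
                    cnt[td] += 1
                    members[fd, i] = members[fd, cnt[fd] - 1]
                    cnt[fd] -= 1
                i -= 1

    while active > 1:
        if t > TIME_CAP:
            return nbr, 1
        best_dt = np.inf
        best_kind = -1  # 0 = coalescence, 1 = migration
        best_deme = -1
        for d in range(D):
            cd = cnt[d]
            if cd >= 2:
                gd = g[k, d]
                nd = n0[k, d] * math.exp(-gd * (t - times[k]))
                lam = cd * (cd - 1) * 0.25 / nd
                e = np.random.exponential(1.0)
                if gd == 0.0:
                    dt = e / lam
                else:
                    arg = 1.0 + gd * e / lam
                    dt = math.log(arg) / gd if arg > 0.0 else np.inf
                if dt < best_dt:
                    best_dt = dt
                    best_kind = 0
                    best_deme = d
            if cd >= 1:
                mrate = 0.0
                for j in range(D):
                    mrate += mig[k, d, j]
                mrate *= cd
                if mrate > 0.0:
                    dt = np.random.exponential(1.0) / mrate
                    if dt < best_dt:
                        best_dt = dt
                        best_kind = 1
                        best_deme = d

        t_event = t + best_dt
        if k < K - 1 and t_event >= times[k + 1]:
            t = times[k + 1]
            k += 1
            for m in range(M):
                if mb[m] == k:
                    fd = mf[m]
                    td = mt[m]
                    p = mp[m]
                    i = cnt[fd] - 1
                    while i >= 0:
                        if p >= 1.0 or np.random.random() < p:
                            node = members[fd, i]
                            members[td, cnt[td]] = node
                            cnt[td] += 1
                            members[fd, i] = members[fd, cnt[fd] - 1]
                            cnt[fd] -= 1
                        i -= 1
            continue
        if not np.isfinite(t_event):
            return nbr, 1
        t = t_event

        d = best_deme
        cd = cnt[d]
        if best_kind == 0:
            i = np.random.randint(0, cd)
            j = np.random.randint(0, cd - 1)
            if j >= i:
                j += 1
            a = members[d, i]
            b = members[d, j]
            br_c1[nbr] = c1[a]
            br_c2[nbr] = c2[a]
            br_len[nbr] = t - birth[a]
            nbr += 1
            br_c1[nbr] = c1[b]
            br_c2[nbr] = c2[b]
            br_len[nbr] = t - birth[b]
            nbr += 1
            new = next_node
            next_node += 1
            c1[new] = c1[a] + c1[b]
            c2[new] = c2[a] + c2[b]
            birth[new] = t
            parent[a] = new
            parent[b] = new
            parent[new] = -1
            ntime[new] = t
            members[d, i] = new
            members[d, j] = members[d, cd - 1]
            cnt[d] -= 1
            active -= 1
        else:
            # migration: pick lineage, pick destination by row weights
            i = np.random.randint(0, cd)
            node = members[d, i]
            row = 0.0
            for j in range(D):
                row += mig[k, d, j]
            u = np.random.random() * row
            dest = D - 1
            acc = 0.0
            for j in range(D):
                acc += mig[k, d, j]
                if u < acc:
                    dest = j
                    break
            members[dest, cnt[dest]] = node
            cnt[dest] += 1
            members[d, i] = members[d, cd - 1]
            cnt[d] -= 1
    return nbr, 0


@njit(cache=True, fastmath=True)
def branch_sfs_kernel(
    reps, times, n0, g, mig, mb, mf, mt, mp, leaf_deme, leaf_pop, n1, n2, seed
):
    """Accumulate branch lengths into joint-SFS cells over ``reps`` trees.

    Returns (cell_sums flattened (n1+1)*(n2+1), total branch length summed
    over reps, error count).  Cell ``i*(n2+1)+j`` collects the length of
    branches subtending i pop-1 and j pop-2 sample copies (unfolded,
    derived orientation).
    """
    np.random.seed(seed)
    n = leaf_deme.shape[0]
    D = n0.shape[1]
    W = (n1 + 1) * (n2 + 1)
    out = np.zeros(W)
    c1 = np.empty(2 * n - 1, np.int64)
    c2 = np.empty(2 * n - 1, np.int64)
    birth = np.empty(2 * n - 1)
    members = np.empty((D, n), np.int64)
    cnt = np.empty(D, np.int64)
    br_c1 = np.empty(2 * n - 2, np.int64)
    br_c2 = np.empty(2 * n - 2, np.int64)
    br_len = np.empty(2 * n - 2)
    parent = np.empty(2 * n - 1, np.int64)
    ntime = np.empty(2 * n - 1)
    total_len = 0.0
    errors = 0
    for _ in range(reps):
        nbr, err = _simulate_tree(
            times, n0, g, mig, mb, mf, mt, mp, leaf_deme, leaf_pop,
            c1, c2, birth, members, cnt, br_c1, br_c2, br_len, parent, ntime,
        )
        if err != 0:
            errors += 1
            continue
        for b in range(nbr):
            ln = br_len[b]
            out[br_c1[b] * (n2 + 1) + br_c2[b]] += ln
            total_len += ln
    return out, total_len, errors


@njit(cache=True, fastmath=True)
def genealogy_kernel(
    times, n0, g, mig, mb, mf, mt, mp, leaf_deme, leaf_pop, seed
):
    """Simulate one genealogy; returns (parent, node_times, ok)."""
    np.random.seed(seed)
    n = leaf_deme.shape[0]
    D = n0.shape[1]
    c1 = np.empty(2 * n - 1, np.int64)
    c2 = np.empty(2 * n - 1, np.int64)
    birth = np.empty(2 * n - 1)
    members = np.empty((D, n), np.int64)
    cnt = np.empty(D, np.int64)
    br_c1 = np.empty(2 * n - 2, np.int64)
    br_c2 = np.empty(2 * n - 2, np.int64)
    br_len = np.empty(2 * n - 2)
    parent = np.empty(2 * n - 1, np.int64)
    ntime = np.empty(2 * n - 1)
    _, err = _simulate_tree(
        times, n0, g, mig, mb, mf, mt, mp, leaf_deme, leaf_pop,
        c1, c2, birth, members, cnt, br_c1, br_c2, br_len, parent, ntime,
    )
    return parent, ntime, err == 0


@njit(cache=True, fastmath=True)
def site_sfs_kernel(
    n_sites, mu, times, n0, g, mig, mb, mf, mt, mp,
    leaf_deme, leaf_pop, n1, n2, seed,
):
    """Per-site mutation sampling: one genealogy per site, Poisson(mu * L_tree)
    mutations, the site's allelic state taken from one branch drawn with
    probability proportional to its length.

    Returns (unfolded count grid flattened, n_monomorphic, errors).
    """
    np.random.seed(seed)
    n = leaf_deme.shape[0]
    D = n0.shape[1]
    W = (n1 + 1) * (n2 + 1)
    out = np.zeros(W)
    c1 = np.empty(2 * n - 1, np.int64)
    c2 = np.empty(2 * n - 1, np.int64)
    birth = np.empty(2 * n - 1)
    members = np.empty((D, n), np.int64)
    cnt = np.empty(D, np.int64)
    br_c1 = np.empty(2 * n - 2, np.int64)
    br_c2 = np.empty(2 * n - 2, np.int64)
    br_len = np.empty(2 * n - 2)
    parent = np.empty(2 * n - 1, np.int64)
    ntime = np.empty(2 * n - 1)
    n_mono = 0
    errors = 0
    for _ in range(n_sites):
        nbr, err = _simulate_tree(
            times, n0, g, mig, mb, mf, mt, mp, leaf_deme, leaf_pop,
            c1, c2, birth, members, cnt, br_c1, br_c2, br_len, parent, ntime,
        )
        if err != 0:
            errors += 1
            continue
        tbl = 0.0
        for b in range(nbr):
            tbl += br_len[b]
        nmut = np.random.poisson(mu * tbl)
        if nmut == 0:
            n_mono += 1
            continue
        u = np.random.random() * tbl
        acc = 0.0
        chosen = nbr - 1
        for b in range(nbr):
            acc += br_len[b]
            if u < acc:
                chosen = b
                break
        out[br_c1[chosen] * (n2 + 1) + br_c2[chosen]] += 1.0
    return out, n_mono, errors
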