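"""JIT-compiled hot path for exhaustive spiral enumeration.

Same algorithm as the pure-Python DFS in :mod:`zzfullerene.spiral`
(incremental windup over face-size sequences, canonical-form filtering by
unwinding every spiral start), flattened onto integer arrays for numba.  The
pure-Python implementation remains the reference; tests assert both paths
produce identical code lists on small cages.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard wheel on CI images
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _better_spiral_exists(adjmat, nbrs, nbrcnt, deg, nf, ref):
    """True if any spiral start of this dual unwinds to a pentagon tuple
    lexicographically smaller than ``ref`` (i.e. ``ref`` is not canonical)."""
    ordv = np.empty(nf, np.int64)
    used = np.empty(nf, np.uint8)
    c = np.empty(nf, np.int64)
    for f1 in range(nf):
        for i2 in range(nbrcnt[f1]):
            f2 = nbrs[f1, i2]
            for i3 in range(nbrcnt[f1]):
                f3 = nbrs[f1, i3]
                if f3 == f2 or adjmat[f2, f3] == 0:
                    continue
                # -- attempt one unwind from (f1, f2, f3) ------------------
                for k in range(nf):
                    used[k] = 0
                    c[k] = 0
                ordv[0] = f1
                ordv[1] = f2
                used[f1] = 1
                used[f2] = 1
                c[f1] = deg[f1] - 1
                c[f2] = deg[f2] - 1
                better = False
                worse = False
                ri = 0
                for k in range(2):
                    f = ordv[k]
                    if deg[f] == 5:
                        if not better:
                            r = ref[ri]
                            if k + 1 > r:
                                worse = True
                            elif k + 1 < r:
                                better = True
                            ri += 1
                    elif not better and ri < 12 and ref[ri] == k + 1:
                        worse = True
                if worse:
                    continue
                j = 0
                failed = False
                for i in range(2, nf):
                    head = ordv[i - 1]
                    if i == 2:
                        g = f3
                    else:
                        tail = ordv[j]
                        g = -1
                        for t in range(nbrcnt[head]):
                            cand = nbrs[head, t]
                            if used[cand] == 0 and adjmat[tail, cand] != 0:
                                g = cand
                                break
                        if g == -1:
                            failed = True
                            break
                    s = deg[g]
                    k = i + 1
                    if s == 5:
                        if not better:
                            r = ref[ri]
                            if k > r:
                                failed = True
                                break
                            if k < r:
                                better = True
                            ri += 1
                    elif not better and ri < 12 and ref[ri] == k:
                        failed = True
                        break
                    used[g] = 1
                    if i < nf - 1:
                        if c[head] == 0 or j == i - 1:
                            failed = True
                            break
                        ci = s - 1
                        c[head] -= 1
                        tail = ordv[j]
                        if adjmat[g, tail] == 0:
                            failed = True
                            break
                        c[tail] -= 1
                        ci -= 1
                        if c[tail] < 0:
                            failed = True
                            break
                        while c[ordv[j]] == 0:
                            j += 1
                            if j >= i - 1:
                                failed = True
                                break
                            t2 = ordv[j]
                            if adjmat[g, t2] == 0:
                                failed = True
                                break
                            c[t2] -= 1
                            ci -= 1
                            if ci < 0 or c[t2] < 0:
                                failed = True
                                break
                        if failed:
                            break
                        h = i - 1
                        while c[ordv[h]] == 0:
                            h -= 1
                            if h <= j:
                                failed = True
                                break
                            t2 = ordv[h]
                            if adjmat[g, t2] == 0:
                                failed = True
                                break
                            c[t2] -= 1
                            ci -= 1
                            if ci < 0 or c[t2] < 0:
                                failed = True
                                break
                        if failed:
                            break
                        if ci <= 0:
                            failed = True
                            break
                        c[g] = ci
                    else:
                        cnt = 0
                        for idx in range(j, i):
                            t2 = ordv[idx]
                            if c[t2] == 0:
                                continue
                            if c[t2] != 1 or adjmat[g, t2] == 0:
                                failed = True
                                break
                            cnt += 1
                        if failed or cnt != s:
                            failed = True
                            break
                    ordv[i] = g
                if not failed and better:
                    return True
    return False


@njit(cache=True)
def _enumerate_codes_nb(n, limit, out):
    """Iterative DFS windup over face sequences; stores canonical pentagon
    tuples into ``out`` in lexicographic order and returns how many."""
    nf = n // 2 + 2
    last = nf - 1
    c = np.zeros(nf, np.int64)
    partner = np.zeros((nf, 8), np.int64)
    pcount = np.zeros(nf, np.int64)
    sizes = np.zeros(nf, np.int64)
    j_at = np.zeros(nf, np.int64)
    pents_at = np.zeros(nf, np.int64)
    stage = np.zeros(nf, np.int64)
    need = np.zeros(nf, np.int64)
    ref = np.zeros(12, np.int64)
    adjmat = np.zeros((nf, nf), np.uint8)
    nbrs = np.zeros((nf, 7), np.int64)
    nbrcnt = np.zeros(nf, np.int64)
    deg = np.zeros(nf, np.int64)
    found = 0
    pents_at[0] = 12
    i = 0
    while i >= 0:
        if i == last:
            pents_left = pents_at[i]
            if pents_left <= 1:
                s = 6
                if pents_left == 1:
                    s = 5
                j = j_at[i]
                cnt = 0
                ok = True
                for k in range(j, i):
                    if c[k] > 0:
                        if c[k] != 1:
                            ok = False
                            break
                        need[cnt] = k
                        cnt += 1
                if ok and cnt == s:
                    sizes[i] = s
                    # build dual adjacency of the completed cage
                    for a in range(nf):
                        nbrcnt[a] = 0
                        deg[a] = sizes[a]
                        for b in range(nf):
                            adjmat[a, b] = 0
                    for a in range(nf):
                        for t in range(pcount[a]):
                            b = partner[a, t]
                            adjmat[a, b] = 1
                            adjmat[b, a] = 1
                            nbrs[a, nbrcnt[a]] = b
                            nbrcnt[a] += 1
                            nbrs[b, nbrcnt[b]] = a
                            nbrcnt[b] += 1
                    for t in range(cnt):
                        b = need[t]
                        adjmat[i, b] = 1
                        adjmat[b, i] = 1
                        nbrs[i, nbrcnt[i]] = b
                        nbrcnt[i] += 1
                        nbrs[b, nbrcnt[b]] = i
                        nbrcnt[b] += 1
                    ri = 0
                    for k in range(nf):
                        if sizes[k] == 5:
                            ref[ri] = k + 1
                            ri += 1
                    if not _better_spiral_exists(adjmat, nbrs, nbrcnt, deg, nf, ref):
                        for t in range(12):
                            out[found, t] = ref[t]
                        found += 1
                        if found == limit or found == out.shape[0]:
                            return found
            i -= 1
            for t in range(pcount[i]):
                c[partner[i, t]] += 1
            pcount[i] = 0
            c[i] = 0
            continue
        st = stage[i]
        if st >= 2:
            i -= 1
            if i >= 0:
                for t in range(pcount[i]):
                    c[partner[i, t]] += 1
                pcount[i] = 0
                c[i] = 0
            continue
        stage[i] = st + 1
        s = 5 if st == 0 else 6
        pents_left = pents_at[i]
        faces_left = nf - i
        if s == 5:
            if pents_left == 0:
                continue
        elif faces_left <= pents_left:
            continue
        j = j_at[i]
        nj = 0
        if i == 0:
            c[0] = s
        elif i == 1:
            c[1] = s - 1
            c[0] -= 1
            partner[1, 0] = 0
            pcount[1] = 1
        else:
            head = i - 1
            if c[head] == 0 or j == head:
                continue
            ci = s - 1
            npart = 0
            c[head] -= 1
            partner[i, npart] = head
            npart += 1
            c[j] -= 1
            partner[i, npart] = j
            npart += 1
            ci -= 1
            nj = j
            ok = True
            while c[nj] == 0:
                nj += 1
                if nj >= head:
                    ok = False
                    break
                c[nj] -= 1
                partner[i, npart] = nj
                npart += 1
                ci -= 1
                if ci < 0:
                    ok = False
                    break
            if ok:
                h = head
                while c[h] == 0:
                    h -= 1
                    if h <= nj:
                        ok = False
                        break
                    c[h] -= 1
                    partner[i, npart] = h
                    npart += 1
                    ci -= 1
                    if ci < 0:
                        ok = False
                        break
            if not ok or ci <= 0:
                for t in range(npart):
                    c[partner[i, t]] += 1
                continue
            pcount[i] = npart
            c[i] = ci
        sizes[i] = s
        i += 1
        j_at[i] = nj
        pents_at[i] = pents_left - (1 if s == 5 else 0)
        stage[i] = 0
    return found


def enumerate_codes_fast(n: int, limit: int | None = None) -> np.ndarray:
    """Canonical pentagon-position tuples of Cn, lexicographic, as an array."""
    cap = limit if limit is not None else 300000
    out = np.zeros((cap, 12), np.int64)
    found = _enumerate_codes_nb(n, -1 if limit is None else limit, out)
    return out[:found].copy()
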