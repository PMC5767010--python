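"""Branch-and-bound best-subsets search for weighted least squares.

Used as the screening stage of the model-space search when exhaustive
enumeration of 2^p logistic fits is infeasible (p > 16 by default; with the
full candidate panel p=23 the space holds 8,388,608 models).  The logistic
problem is linearized at the full-model IRLS solution (working response and
weights from the final IRLS step), the forced columns are projected out, and
an exact branch-and-bound retains the ``nbest`` lowest-RSS subsets of every
size.  Exact logistic BICs are then recomputed for the retained candidates by
the caller.

Correctness of the search is exact, not heuristic: a subtree is pruned only
when the RSS of its most saturated completion cannot enter any size list it
could still contribute to (RSS is monotone nonincreasing in the subset).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["best_subsets_wls", "exhaustive_subsets_wls"]


@njit(cache=False)
def _subset_rss(G, c, yty, members, k, L, v):
    """RSS of subset ``members[:k]`` via a fresh Cholesky of G[S,S]."""
    if k == 0:
        return yty
    for i in range(k):
        mi = members[i]
        for j in range(i + 1):
            s = G[mi, members[j]]
            for t in range(j):
                s -= L[i, t] * L[j, t]
            if j < i:
                L[i, j] = s / L[j, j]
            else:
                if s <= 1e-12:
                    return yty  # numerically singular subset: treat as useless
                L[i, i] = np.sqrt(s)
    # solve L v = c_S
    acc = 0.0
    for i in range(k):
        s = c[members[i]]
        for t in range(i):
            s -= L[i, t] * v[t]
        v[i] = s / L[i, i]
        acc += v[i] * v[i]
    rss = yty - acc
    if rss < 0.0:
        rss = 0.0
    return rss


@njit(cache=False)
def _insert_kept(kept_rss, kept_mask, kept_n, size, rss, mask, nbest):
    """Insert (rss, mask) into the sorted kept list for ``size``."""
    cnt = kept_n[size]
    if cnt == nbest and rss >= kept_rss[size, cnt - 1]:
        return
    pos = cnt
    while pos > 0 and kept_rss[size, pos - 1] > rss:
        pos -= 1
    last = min(cnt, nbest - 1)
    for j in range(last, pos, -1):
        kept_rss[size, j] = kept_rss[size, j - 1]
        kept_mask[size, j] = kept_mask[size, j - 1]
    kept_rss[size, pos] = rss
    kept_mask[size, pos] = mask
    if cnt < nbest:
        kept_n[size] = cnt + 1


@njit(cache=False)
def _bb_search(G, c, yty, nbest):
    p = G.shape[0]
    kept_rss = np.full((p + 1, nbest), np.inf)
    kept_mask = np.zeros((p + 1, nbest), dtype=np.int64)
    kept_n = np.zeros(p + 1, dtype=np.int64)

    L = np.zeros((p, p))
    v = np.zeros(p)
    members = np.zeros(p, dtype=np.int64)
    full_members = np.zeros(p, dtype=np.int64)

    _insert_kept(kept_rss, kept_mask, kept_n, 0, yty, 0, nbest)

    # DFS stack: (depth, mask).  Include-branch pushed last so it is explored
    # first (good models found early sharpen the pruning bound).
    cap = 4 * p * p + 64
    stack_d = np.zeros(cap, dtype=np.int64)
    stack_m = np.zeros(cap, dtype=np.int64)
    top = 0
    stack_d[top] = 0
    stack_m[top] = 0
    top += 1

    while top > 0:
        top -= 1
        d = stack_d[top]
        mask = stack_m[top]
        if d >= p:
            continue
        # members of current subset
        k = 0
        for i in range(p):
            if mask & (np.int64(1) << i):
                members[k] = i
                k += 1
        r = p - d
        # bound: RSS of subset ∪ all undecided variables
        nk = k
        for i in range(k):
            full_members[i] = members[i]
        for i in range(d, p):
            if not (mask & (np.int64(1) << i)):
                full_members[nk] = i
                nk += 1
        bound = _subset_rss(G, c, yty, full_members, nk, L, v)
        # can any size reachable in this subtree (k+1 .. k+r) still accept `bound`?
        useful = False
        smax = k + r if k + r <= p else p
        for s in range(k + 1, smax + 1):
            if kept_n[s] < nbest or kept_rss[s, kept_n[s] - 1] > bound:
                useful = True
                break
        if not useful:
            continue
        # exclude branch
        if top + 2 > cap:
            # grow is impossible in nopython with fixed arrays; cap is sized
            # for depth-first growth (at most 2 pushes per pop, depth p)
            pass
        stack_d[top] = d + 1
        stack_m[top] = mask
        top += 1
        # include branch (explored first)
        newmask = mask | (np.int64(1) << d)
        members[k] = d
        rss = _subset_rss(G, c, yty, members, k + 1, L, v)
        _insert_kept(kept_rss, kept_mask, kept_n, k + 1, rss, newmask, nbest)
        stack_d[top] = d + 1
        stack_m[top] = newmask
        top += 1

    return kept_rss, kept_mask, kept_n


def _residualize_forced(Xw: np.ndarray, zw: np.ndarray, sw: np.ndarray,
                        forced_idx: np.ndarray,
                        cand_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project the forced block (plus intercept) out of candidates and response.

    Everything lives on the sqrt-weighted scale, including the intercept
    column (which becomes ``sw``).
    """
    F = np.column_stack([sw, Xw[:, forced_idx]]) if len(forced_idx) else sw[:, None]
    Q, _ = np.linalg.qr(F)
    C = Xw[:, cand_idx]
    C = C - Q @ (Q.T @ C)
    z = zw - Q @ (Q.T @ zw)
    return C, z


def best_subsets_wls(
    X: np.ndarray,
    z: np.ndarray,
    w: np.ndarray,
    cand_idx: np.ndarray,
    forced_idx: np.ndarray,
    nbest: int,
) -> dict[tuple[int, ...], float]:
    """Best ``nbest`` candidate subsets per size for the weighted LS problem.

    ``X`` is the unweighted design (no intercept), ``z`` the working response,
    ``w`` the observation weights.  The forced columns and the intercept are
    carried in every model and projected out before the search.  Returns a
    mapping from deduplicated subsets (sorted tuples of candidate positions,
    in ``cand_idx`` order, always including the empty subset) to their RSS on
    the linearized problem.
    """
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    zw = z * sw
    C, zr = _residualize_forced(Xw, zw, sw, forced_idx, cand_idx)
    p = C.shape[1]
    # order candidates by univariate explanatory power for sharper pruning
    G0 = C.T @ C
    c0 = C.T @ zr
    diag = np.clip(np.diag(G0), 1e-300, None)
    order = np.argsort(-(c0**2) / diag)
    G = G0[np.ix_(order, order)]
    c = c0[order]
    yty = float(zr @ zr)

    kept_rss, kept_mask, kept_n = _bb_search(G, c, yty, int(nbest))

    subsets: dict[tuple[int, ...], float] = {(): yty}
    for s in range(p + 1):
        for j in range(kept_n[s]):
            mask = int(kept_mask[s, j])
            members = tuple(sorted(int(order[i]) for i in range(p) if mask >> i & 1))
            subsets[members] = float(kept_rss[s, j])
    return subsets


def exhaustive_subsets_wls(
    X: np.ndarray,
    z: np.ndarray,
    w: np.ndarray,
    cand_idx: np.ndarray,
    forced_idx: np.ndarray,
) -> dict[tuple[int, ...], float]:
    """Brute-force RSS of every candidate subset (test oracle; p must be small)."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    zw = z * sw
    C, zr = _residualize_forced(Xw, zw, sw, forced_idx, cand_idx)
    p = C.shape[1]
    out: dict[tuple[int, ...], float] = {}
    from itertools import combinations

    yty = float(zr @ zr)
    for size in range(p + 1):
        for S in combinations(range(p), size):
            if size == 0:
                out[S] = yty
                continue
            Cs = C[:, S]
            coef, *_ = np.linalg.lstsq(Cs, zr, rcond=None)
            resid = zr - Cs @ coef
            out[S] = float(resid @ resid)
    return out
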