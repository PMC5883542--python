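"""Numba kernels: two-population isolation coalescent with Jukes–Cantor mutation.

Time is measured in per-lineage mutational units (expected substitutions per
site along one lineage), so a population divergence of ``tau`` expected
*pairwise* substitutions/site corresponds to a per-lineage depth ``tau / 2``.
Within a population with mutation parameter theta (= 4N*mu per site) each
lineage pair coalesces at rate ``2 / theta``, giving E[pairwise within-
population diversity] = theta and E[between-population diversity] =
tau + theta_ancestral.

Sequences are encoded A=0, G=1, C=2, T=3 (matching :mod:`sycodiv.distances`).
Mutations fall as a Poisson process on branches; each mutation picks a uniform
site and replaces its base with one of the three alternatives (Jukes–Cantor),
so multiple hits and back mutations occur naturally at finite length.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sim_pair_seqs", "seeded_pair_seqs", "pair_stats", "batch_pair_stats"]


@njit(cache=True)
def _harmonic(n: int) -> float:
    s = 0.0
    for i in range(1, n):
        s += 1.0 / i
    return s


@njit(cache=True)
def sim_pair_seqs(theta_a, theta_b, theta_anc, tau_u, n_a, n_b, L, root_seq, anchor_u):
    """Simulate tip sequences for a two-population isolation model.

    Rows 0..n_a-1 are population A, the rest population B.  ``tau_u`` is the
    divergence time in pairwise substitution units.  ``root_seq``: length-L
    array anchoring the genealogy root to a given ancestral sequence at
    per-lineage depth ``anchor_u`` (a stem branch of max(0, anchor_u - root
    height) is added); pass an empty array for a uniform-random root.
    Uses numba's global RNG: seed beforehand for reproducibility.
    """
    n = n_a + n_b
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    ntime = np.zeros(n_nodes)
    act_a = np.empty(n, dtype=np.int64)
    act_b = np.empty(n, dtype=np.int64)
    for i in range(n_a):
        act_a[i] = i
    for i in range(n_b):
        act_b[i] = n_a + i
    ka, kb = n_a, n_b
    nxt = n
    t = 0.0
    T = tau_u / 2.0
    # phase 1: independent coalescent in each descendant population until T
    while True:
        ra = ka * (ka - 1) / theta_a if ka >= 2 else 0.0
        rb = kb * (kb - 1) / theta_b if kb >= 2 else 0.0
        if ra == 0.0 and rb == 0.0:
            break
        wa = np.random.exponential(1.0 / ra) if ra > 0.0 else np.inf
        wb = np.random.exponential(1.0 / rb) if rb > 0.0 else np.inf
        w = wa if wa <= wb else wb
        if t + w >= T:
            break
        t += w
        if wa <= wb:
            i = np.random.randint(ka)
            j = np.random.randint(ka - 1)
            if j >= i:
                j += 1
            c1, c2 = act_a[i], act_a[j]
            lo, hi = (i, j) if i < j else (j, i)
            act_a[lo] = nxt
            act_a[hi] = act_a[ka - 1]
            ka -= 1
        else:
            i = np.random.randint(kb)
            j = np.random.randint(kb - 1)
            if j >= i:
                j += 1
            c1, c2 = act_b[i], act_b[j]
            lo, hi = (i, j) if i < j else (j, i)
            act_b[lo] = nxt
            act_b[hi] = act_b[kb - 1]
            kb -= 1
        parent[c1] = nxt
        parent[c2] = nxt
        ntime[nxt] = t
        nxt += 1
    # phase 2: merge surviving lineages into the ancestral population
    k = ka + kb
    act = np.empty(k, dtype=np.int64)
    for i in range(ka):
        act[i] = act_a[i]
    for i in range(kb):
        act[ka + i] = act_b[i]
    t = T
    while k > 1:
        rate = k * (k - 1) / theta_anc
        t += np.random.exponential(1.0 / rate)
        i = np.random.randint(k)
        j = np.random.randint(k - 1)
        if j >= i:
            j += 1
        c1, c2 = act[i], act[j]
        parent[c1] = nxt
        parent[c2] = nxt
        ntime[nxt] = t
        lo, hi = (i, j) if i < j else (j, i)
        act[lo] = nxt
        act[hi] = act[k - 1]
        k -= 1
        nxt += 1
    root = n_nodes - 1
    # sequences, root first then pre-order by decreasing node index
    seqs = np.empty((n_nodes, L), dtype=np.uint8)
    if root_seq.shape[0] == L:
        for s in range(L):
            seqs[root, s] = root_seq[s]
        stem = anchor_u - ntime[root]
        if stem > 0.0:
            nmut = np.random.poisson(stem * L)
            for _ in range(nmut):
                pos = np.random.randint(L)
                seqs[root, pos] = (seqs[root, pos] + 1 + np.random.randint(3)) % 4
    else:
        for s in range(L):
            seqs[root, s] = np.random.randint(4)
    for node in range(n_nodes - 2, -1, -1):
        p = parent[node]
        for s in range(L):
            seqs[node, s] = seqs[p, s]
        blen = ntime[p] - ntime[node]
        nmut = np.random.poisson(blen * L)
        for _ in range(nmut):
            pos = np.random.randint(L)
            seqs[node, pos] = (seqs[node, pos] + 1 + np.random.randint(3)) % 4
    return seqs[:n]


@njit(cache=True)
def seeded_pair_seqs(seed, theta_a, theta_b, theta_anc, tau_u, n_a, n_b, L,
                     root_seq, anchor_u):
    """Seed numba's RNG, then run :func:`sim_pair_seqs` (deterministic)."""
    np.random.seed(seed)
    return sim_pair_seqs(theta_a, theta_b, theta_anc, tau_u, n_a, n_b, L,
                         root_seq, anchor_u)


@njit(cache=True)
def pair_stats(seqs, n_a):
    """(pi_between, pi_within_a, pi_within_b, S_a, S_b) from gap-free tip codes."""
    n, L = seqs.shape
    n_b = n - n_a
    pi_wa = 0.0
    npairs_a = 0
    for i in range(n_a):
        for j in range(i + 1, n_a):
            diff = 0
            for s in range(L):
                if seqs[i, s] != seqs[j, s]:
                    diff += 1
            pi_wa += diff / L
            npairs_a += 1
    if npairs_a > 0:
        pi_wa /= npairs_a
    pi_wb = 0.0
    npairs_b = 0
    for i in range(n_a, n):
        for j in range(i + 1, n):
            diff = 0
            for s in range(L):
                if seqs[i, s] != seqs[j, s]:
                    diff += 1
            pi_wb += diff / L
            npairs_b += 1
    if npairs_b > 0:
        pi_wb /= npairs_b
    pi_b = 0.0
    for i in range(n_a):
        for j in range(n_a, n):
            diff = 0
            for s in range(L):
                if seqs[i, s] != seqs[j, s]:
                    diff += 1
            pi_b += diff / L
    pi_b /= n_a * n_b
    S_a = 0
    S_b = 0
    for s in range(L):
        base = seqs[0, s]
        for i in range(1, n_a):
            if seqs[i, s] != base:
                S_a += 1
                break
        base = seqs[n_a, s]
        for i in range(n_a + 1, n):
            if seqs[i, s] != base:
                S_b += 1
                break
    return pi_b, pi_wa, pi_wb, S_a, S_b


@njit(cache=True)
def batch_pair_stats(seeds, theta_a, theta_b, theta_anc, tau_u, n_a, n_b, L):
    """Simulate many pairs and return a (N, 6) summary matrix.

    Columns: pi_between, pi_within_a, pi_within_b, thetaW_a, thetaW_b, pi_net.
    One RNG seed per row: results are independent of batch splitting.
    """
    N = seeds.shape[0]
    out = np.empty((N, 6))
    empty = np.empty(0, dtype=np.uint8)
    for r in range(N):
        np.random.seed(seeds[r])
        seqs = sim_pair_seqs(theta_a[r], theta_b[r], theta_anc[r], tau_u[r],
                             n_a[r], n_b[r], L, empty, 0.0)
        pi_b, pi_wa, pi_wb, S_a, S_b = pair_stats(seqs, n_a[r])
        out[r, 0] = pi_b
        out[r, 1] = pi_wa
        out[r, 2] = pi_wb
        ha = _harmonic(n_a[r])
        hb = _harmonic(n_b[r])
        out[r, 3] = S_a / (ha * L) if ha > 0.0 else 0.0
        out[r, 4] = S_b / (hb * L) if hb > 0.0 else 0.0
        out[r, 5] = pi_b - 0.5 * (pi_wa + pi_wb)
    return out
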