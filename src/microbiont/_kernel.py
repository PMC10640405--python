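"""Numba kernels for the data-augmented MCMC over repertoire histories.

The sampler state is (lambda_gain, lambda_loss, beta) plus a complete
event history: repertoires at every node and time-stamped gain/loss events
on every branch.  Moves:

* multiplicative scaling on lambda_gain / lambda_loss.  Given the history,
  the log density is linear in the rates: per branch,
  ld = -lambda_gain*G - lambda_loss*P + n_gain*log(lambda_gain)
       + n_loss*log(lambda_loss) + E,
  with G the distance-modified gain-rate integral, P the presence-time
  integral and E the summed log distance modifiers of the gain events, so
  rate moves are O(1) using cached per-branch (G, P, n_gain, n_loss);
* beta moves (multiplicative scaling alternating with a reflected-at-zero
  random walk, which mixes near the boundary where the Savage-Dickey
  density estimate lives); G and E depend on beta, so these recompute the
  branch statistics;
* single branch x ASV path redraws: an endpoint-conditioned bridge of the
  neutral two-state chain, proposed by uniformization, accepted by the
  Metropolis-Hastings ratio of the full repertoire-coupled density over
  the neutral proposal density;
* whole-branch sweeps: simultaneous neutral bridges for every ASV on one
  branch, accepted jointly (one density evaluation updates M paths);
* node-state flips (internal nodes and root) with redraws of the paths on
  all incident branches.

Everything is cross-validated in the tests against the reference
implementations in :mod:`microbiont.repertoire` and against exact
small-instance posteriors.

Branch event times are stored *forward* from the rootward end of each
branch.  For the two-state chain with rates (g, l) and mu = g + l the
uniformized jump chain has both rows equal to (l/mu, g/mu), which makes
endpoint-conditioned path sampling exact and cheap: the number of virtual
jumps has a closed-form posterior and intermediate states are i.i.d.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MIN_DIST = 1e-12


# ---------------------------------------------------------------------------
# branch density and its sufficient statistics


@njit(cache=True)
def _eta(j, r, svec, cnt, D, dbar, beta, agg):
    """Distance modifier for gaining ASV j given repertoire bookkeeping."""
    if beta == 0.0 or cnt == 0:
        return 1.0
    if agg == 0:
        dj = svec[j] / cnt
    else:
        dj = 1e300
        for i in range(r.shape[0]):
            if r[i] and D[j, i] < dj:
                dj = D[j, i]
    if dj < _MIN_DIST:
        dj = _MIN_DIST
    return (dbar / dj) ** beta


@njit(cache=True)
def _branch_stats(b, node_state, ev_t, ev_a, ev_g, ev_n,
                  parent, blen, D, dbar, beta, agg, out):
    """Sufficient statistics of the branch path above node b.

    Writes (G, P, n_gain, n_loss, E) into ``out``:
      G = integral of the summed distance modifiers of absent ASVs (so the
          gain-rate integral is lambda_gain * G),
      P = integral of repertoire size (loss integral = lambda_loss * P),
      E = sum of log eta at the gain events.
    Returns -inf in out[4] (E) never; the caller combines these into the
    log density via _ld_from_stats.
    """
    p = parent[b]
    M = D.shape[0]
    r = node_state[p].copy()
    cnt = 0
    svec = np.zeros(M)
    for i in range(M):
        if r[i]:
            cnt += 1
            for j in range(M):
                svec[j] += D[j, i]
    G = 0.0
    P = 0.0
    E = 0.0
    ngain = 0
    nloss = 0
    prev = 0.0
    ne = ev_n[b]
    for e in range(ne + 1):
        tcur = ev_t[b, e] if e < ne else blen[b]
        dt = tcur - prev
        if beta == 0.0 or cnt == 0:
            G += (M - cnt) * dt
        else:
            gsum = 0.0
            for j in range(M):
                if not r[j]:
                    gsum += _eta(j, r, svec, cnt, D, dbar, beta, agg)
            G += gsum * dt
        P += cnt * dt
        if e < ne:
            a = ev_a[b, e]
            if ev_g[b, e]:
                E += np.log(_eta(a, r, svec, cnt, D, dbar, beta, agg))
                ngain += 1
                r[a] = 1
                cnt += 1
                for j in range(M):
                    svec[j] += D[j, a]
            else:
                nloss += 1
                r[a] = 0
                cnt -= 1
                for j in range(M):
                    svec[j] -= D[j, a]
        prev = tcur
    out[0] = G
    out[1] = P
    out[2] = ngain
    out[3] = nloss
    out[4] = E


@njit(cache=True)
def _ld_from_stats(stats, lg, ll):
    """Branch log density from sufficient statistics and the rates."""
    ld = -lg * stats[0] - ll * stats[1] + stats[4]
    if stats[2] > 0:
        ld += stats[2] * np.log(lg)
    if stats[3] > 0:
        ld += stats[3] * np.log(ll)
    return ld


@njit(cache=True)
def _branch_log_density(b, node_state, ev_t, ev_a, ev_g, ev_n,
                        parent, blen, D, dbar, lg, ll, beta, agg):
    """Log density of the full multi-ASV path on the branch above node b."""
    out = np.empty(5)
    _branch_stats(b, node_state, ev_t, ev_a, ev_g, ev_n,
                  parent, blen, D, dbar, beta, agg, out)
    return _ld_from_stats(out, lg, ll)


# ---------------------------------------------------------------------------
# neutral two-state chain: transition probability, path density, bridge


@njit(cache=True)
def _log_pab(a, b, t, g, l):
    """Two-state transition log probability P(a -> b in time t)."""
    mu = g + l
    e = np.exp(-mu * t)
    p1 = g / mu
    pb = p1 if b == 1 else 1.0 - p1
    p = (1.0 - e) * pb
    if a == b:
        p += e
    return np.log(p)


@njit(cache=True)
def _neutral_path_logdens(a, k, times, types, t, g, l):
    """Density of a single-ASV path under the unconditioned neutral chain."""
    ld = 0.0
    cur = a
    prev = 0.0
    for i in range(k):
        rate = g if cur == 0 else l
        ld += -rate * (times[i] - prev) + np.log(rate)
        cur = 1 - cur
        prev = times[i]
    rate = g if cur == 0 else l
    ld -= rate * (t - prev)
    return ld


@njit(cache=True)
def _sample_bridge(a, b, t, g, l, out_times, out_types):
    """Endpoint-conditioned neutral path from state a to b over [0, t].

    Returns the number of *actual* events written to out_times/out_types
    (forward times; type 1 = gain), or -1 on output-capacity overflow.
    """
    mu = g + l
    p1 = g / mu
    e = np.exp(-mu * t)
    pb = p1 if b == 1 else 1.0 - p1
    pab = (1.0 - e) * pb
    if a == b:
        pab += e
    u = np.random.random() * pab
    pois = e  # Poisson(0; mu t)
    acc = pois if a == b else 0.0
    n = 0
    while acc < u and n < 100000:
        n += 1
        pois *= mu * t / n
        acc += pois * pb
    if n == 0:
        return 0
    times = np.sort(np.random.random(n) * t)
    k = 0
    cur = a
    for i in range(n):
        if i == n - 1:
            si = b
        else:
            si = 1 if np.random.random() < p1 else 0
        if si != cur:
            if k >= out_times.shape[0]:
                return -1
            out_times[k] = times[i]
            out_types[k] = si
            k += 1
            cur = si
    return k


# ---------------------------------------------------------------------------
# event-list editing helpers


@njit(cache=True)
def _extract_asv_path(b, j, ev_t, ev_a, ev_g, ev_n, out_times, out_types):
    """Copy ASV j's events on branch b into out arrays; return count."""
    k = 0
    for e in range(ev_n[b]):
        if ev_a[b, e] == j:
            out_times[k] = ev_t[b, e]
            out_types[k] = ev_g[b, e]
            k += 1
    return k


@njit(cache=True)
def _merge_replace(b, j, ev_t, ev_a, ev_g, ev_n, new_k, new_times, new_types,
                   sc_t, sc_a, sc_g, slot):
    """Branch b's events with ASV j's path replaced, written to scratch.

    Returns the new event count, or -1 on capacity overflow.
    """
    cap = ev_t.shape[1]
    k = 0
    ptr = 0
    for e in range(ev_n[b]):
        if ev_a[b, e] == j:
            continue
        while ptr < new_k and new_times[ptr] <= ev_t[b, e]:
            if k >= cap:
                return -1
            sc_t[slot, k] = new_times[ptr]
            sc_a[slot, k] = j
            sc_g[slot, k] = new_types[ptr]
            k += 1
            ptr += 1
        if k >= cap:
            return -1
        sc_t[slot, k] = ev_t[b, e]
        sc_a[slot, k] = ev_a[b, e]
        sc_g[slot, k] = ev_g[b, e]
        k += 1
    while ptr < new_k:
        if k >= cap:
            return -1
        sc_t[slot, k] = new_times[ptr]
        sc_a[slot, k] = j
        sc_g[slot, k] = new_types[ptr]
        k += 1
        ptr += 1
    return k


@njit(cache=True)
def _sort_scratch(sc_t, sc_a, sc_g, slot, k):
    """Insertion-sort scratch slot events by time (k is small)."""
    for i in range(1, k):
        tt = sc_t[slot, i]
        aa = sc_a[slot, i]
        gg = sc_g[slot, i]
        w = i - 1
        while w >= 0 and sc_t[slot, w] > tt:
            sc_t[slot, w + 1] = sc_t[slot, w]
            sc_a[slot, w + 1] = sc_a[slot, w]
            sc_g[slot, w + 1] = sc_g[slot, w]
            w -= 1
        sc_t[slot, w + 1] = tt
        sc_a[slot, w + 1] = aa
        sc_g[slot, w + 1] = gg


@njit(cache=True)
def _copy_from_scratch(b, ev_t, ev_a, ev_g, ev_n, sc_t, sc_a, sc_g, slot, k):
    for e in range(k):
        ev_t[b, e] = sc_t[slot, e]
        ev_a[b, e] = sc_a[slot, e]
        ev_g[b, e] = sc_g[slot, e]
    ev_n[b] = k


@njit(cache=True)
def _scratch_stats(b, node_state, sc_t, sc_a, sc_g, k, slot,
                   parent, blen, D, dbar, beta, agg, out):
    """_branch_stats evaluated on a scratch event list for branch b."""
    p = parent[b]
    M = D.shape[0]
    r = node_state[p].copy()
    cnt = 0
    svec = np.zeros(M)
    for i in range(M):
        if r[i]:
            cnt += 1
            for j in range(M):
                svec[j] += D[j, i]
    G = 0.0
    P = 0.0
    E = 0.0
    ngain = 0
    nloss = 0
    prev = 0.0
    for e in range(k + 1):
        tcur = sc_t[slot, e] if e < k else blen[b]
        dt = tcur - prev
        if beta == 0.0 or cnt == 0:
            G += (M - cnt) * dt
        else:
            gsum = 0.0
            for j in range(M):
                if not r[j]:
                    gsum += _eta(j, r, svec, cnt, D, dbar, beta, agg)
            G += gsum * dt
        P += cnt * dt
        if e < k:
            a = sc_a[slot, e]
            if sc_g[slot, e]:
                E += np.log(_eta(a, r, svec, cnt, D, dbar, beta, agg))
                ngain += 1
                r[a] = 1
                cnt += 1
                for j in range(M):
                    svec[j] += D[j, a]
            else:
                nloss += 1
                r[a] = 0
                cnt -= 1
                for j in range(M):
                    svec[j] -= D[j, a]
        prev = tcur
    out[0] = G
    out[1] = P
    out[2] = ngain
    out[3] = nloss
    out[4] = E


@njit(cache=True)
def _root_logprior(node_state, root, M, lg, ll, pi_mode, pi_value):
    pi = lg / (lg + ll) if pi_mode == 1 else pi_value
    n1 = 0
    for j in range(M):
        if node_state[root, j]:
            n1 += 1
    return n1 * np.log(pi) + (M - n1) * np.log(1.0 - pi)


@njit(cache=True)
def _param_logprior(lg, ll, beta, lam_rate, beta_rate, fix):
    lp = 0.0
    if not fix[0]:
        lp += np.log(lam_rate) - lam_rate * lg
    if not fix[1]:
        lp += np.log(lam_rate) - lam_rate * ll
    if not fix[2]:
        lp += np.log(beta_rate) - beta_rate * beta
    return lp


# ---------------------------------------------------------------------------
# the chain


@njit(cache=True)
def run_chain(parent, blen, root, internal_nodes, branch_nodes,
              children_ptr, children_idx,
              D, dbar, agg,
              init_state,
              lg0, ll0, b0, fix, lam_rate, beta_rate,
              pi_mode, pi_value,
              cycles, thin, seed, prior_only,
              n_sweep_moves, n_hist_moves, n_node_moves,
              scale_step, beta_step, cap,
              slice_branch, slice_tau):
    np.random.seed(seed)
    n_nodes = parent.shape[0]
    n_branch = branch_nodes.shape[0]
    M = D.shape[0]
    n_samples = cycles // thin
    n_slices = slice_branch.shape[0]

    node_state = init_state.copy()
    ev_t = np.zeros((n_nodes, cap))
    ev_a = np.zeros((n_nodes, cap), dtype=np.int64)
    ev_g = np.zeros((n_nodes, cap), dtype=np.uint8)
    ev_n = np.zeros(n_nodes, dtype=np.int64)

    # scratch for proposals (up to 8 branches touched by one move)
    sc_t = np.zeros((8, cap))
    sc_a = np.zeros((8, cap), dtype=np.int64)
    sc_g = np.zeros((8, cap), dtype=np.uint8)
    bt = np.empty(cap)
    btyp = np.empty(cap, dtype=np.uint8)
    bt2 = np.empty(cap)
    btyp2 = np.empty(cap, dtype=np.uint8)
    aff = np.empty(8, dtype=np.int64)
    aff_k = np.empty(8, dtype=np.int64)
    aff_stats = np.empty((8, 5))
    stat_buf = np.empty(5)

    lg, ll, beta = lg0, ll0, b0

    # initialize histories: independent neutral bridges per branch x ASV
    for bi in range(n_branch):
        b = branch_nodes[bi]
        p = parent[b]
        k_all = 0
        for j in range(M):
            k = _sample_bridge(node_state[p, j], node_state[b, j], blen[b],
                               lg, ll, bt, btyp)
            for e in range(k):
                if k_all >= cap:
                    break
                ev_t[b, k_all] = bt[e]
                ev_a[b, k_all] = j
                ev_g[b, k_all] = btyp[e]
                k_all += 1
        for i in range(1, k_all):
            tt = ev_t[b, i]
            aa = ev_a[b, i]
            gg = ev_g[b, i]
            w = i - 1
            while w >= 0 and ev_t[b, w] > tt:
                ev_t[b, w + 1] = ev_t[b, w]
                ev_a[b, w + 1] = ev_a[b, w]
                ev_g[b, w + 1] = ev_g[b, w]
                w -= 1
            ev_t[b, w + 1] = tt
            ev_a[b, w + 1] = aa
            ev_g[b, w + 1] = gg
        ev_n[b] = k_all

    # cached per-branch sufficient statistics (at the current beta)
    branch_stats = np.zeros((n_nodes, 5))
    prop_stats = np.zeros((n_nodes, 5))
    for bi in range(n_branch):
        b = branch_nodes[bi]
        _branch_stats(b, node_state, ev_t, ev_a, ev_g, ev_n,
                      parent, blen, D, dbar, beta, agg, branch_stats[b])

    # outputs
    out_params = np.zeros((n_samples, 3))
    out_loglik = np.zeros((n_samples, 2))  # history logdensity, param logprior
    out_counts = np.zeros((n_samples, 2), dtype=np.int64)
    out_nodes = np.zeros((n_samples, n_nodes, M), dtype=np.uint8)
    out_slices = np.zeros((n_samples, n_slices, M), dtype=np.uint8)
    n_move_types = 6  # lam scale, beta scale, beta walk, sweep, path, node
    accepts = np.zeros(n_move_types, dtype=np.int64)
    proposals = np.zeros(n_move_types, dtype=np.int64)

    s_idx = 0
    for cycle in range(cycles):
        # --- rate scaling moves (O(1) given cached stats) ----------------
        for pidx in range(2):
            if fix[pidx]:
                continue
            proposals[0] += 1
            old = lg if pidx == 0 else ll
            new = old * np.exp(scale_step * (2.0 * np.random.random() - 1.0))
            log_acc = np.log(new / old) - lam_rate * (new - old)
            if not prior_only:
                sG = 0.0
                sP = 0.0
                sng = 0.0
                snl = 0.0
                for bi in range(n_branch):
                    b = branch_nodes[bi]
                    sG += branch_stats[b, 0]
                    sP += branch_stats[b, 1]
                    sng += branch_stats[b, 2]
                    snl += branch_stats[b, 3]
                if pidx == 0:
                    log_acc += -(new - old) * sG + sng * np.log(new / old)
                else:
                    log_acc += -(new - old) * sP + snl * np.log(new / old)
                if pi_mode == 1:
                    nlg = new if pidx == 0 else lg
                    nll = new if pidx == 1 else ll
                    log_acc += _root_logprior(node_state, root, M, nlg, nll,
                                              1, pi_value) \
                        - _root_logprior(node_state, root, M, lg, ll,
                                         1, pi_value)
            if np.log(np.random.random()) < log_acc:
                accepts[0] += 1
                if pidx == 0:
                    lg = new
                else:
                    ll = new

        # --- beta move: scaling and reflected walk on alternate cycles ---
        if not fix[2]:
            walk = cycle % 2 == 1
            proposals[2 if walk else 1] += 1
            if walk:
                nbeta = abs(beta + beta_step * np.random.standard_normal())
                log_acc = -beta_rate * (nbeta - beta)
            else:
                nbeta = beta * np.exp(scale_step *
                                      (2.0 * np.random.random() - 1.0))
                log_acc = np.log(nbeta / beta) - beta_rate * (nbeta - beta)
            if not prior_only:
                for bi in range(n_branch):
                    b = branch_nodes[bi]
                    _branch_stats(b, node_state, ev_t, ev_a, ev_g, ev_n,
                                  parent, blen, D, dbar, nbeta, agg,
                                  prop_stats[b])
                    log_acc += _ld_from_stats(prop_stats[b], lg, ll) \
                        - _ld_from_stats(branch_stats[b], lg, ll)
            if np.log(np.random.random()) < log_acc:
                accepts[2 if walk else 1] += 1
                beta = nbeta
                if not prior_only:
                    for bi in range(n_branch):
                        b = branch_nodes[bi]
                        for q in range(5):
                            branch_stats[b, q] = prop_stats[b, q]

        if not prior_only:
            # --- whole-branch sweeps ------------------------------------
            for _ in range(n_sweep_moves):
                proposals[3] += 1
                b = branch_nodes[np.random.randint(n_branch)]
                p = parent[b]
                log_acc = -_ld_from_stats(branch_stats[b], lg, ll)
                k_all = 0
                ok = True
                for j in range(M):
                    a = node_state[p, j]
                    c = node_state[b, j]
                    k_old = _extract_asv_path(b, j, ev_t, ev_a, ev_g, ev_n,
                                              bt2, btyp2)
                    log_acc += _neutral_path_logdens(a, k_old, bt2, btyp2,
                                                     blen[b], lg, ll)
                    k_new = _sample_bridge(a, c, blen[b], lg, ll, bt, btyp)
                    if k_new < 0 or k_all + k_new > cap:
                        ok = False
                        break
                    log_acc -= _neutral_path_logdens(a, k_new, bt, btyp,
                                                     blen[b], lg, ll)
                    for e in range(k_new):
                        sc_t[0, k_all] = bt[e]
                        sc_a[0, k_all] = j
                        sc_g[0, k_all] = btyp[e]
                        k_all += 1
                if not ok:
                    continue
                _sort_scratch(sc_t, sc_a, sc_g, 0, k_all)
                _scratch_stats(b, node_state, sc_t, sc_a, sc_g, k_all, 0,
                               parent, blen, D, dbar, beta, agg, stat_buf)
                log_acc += _ld_from_stats(stat_buf, lg, ll)
                if np.log(np.random.random()) < log_acc:
                    accepts[3] += 1
                    _copy_from_scratch(b, ev_t, ev_a, ev_g, ev_n,
                                       sc_t, sc_a, sc_g, 0, k_all)
                    for q in range(5):
                        branch_stats[b, q] = stat_buf[q]

            # --- single branch x ASV path redraws -----------------------
            for _ in range(n_hist_moves):
                proposals[4] += 1
                b = branch_nodes[np.random.randint(n_branch)]
                j = np.random.randint(M)
                p = parent[b]
                a = node_state[p, j]
                c = node_state[b, j]
                k_old = _extract_asv_path(b, j, ev_t, ev_a, ev_g, ev_n,
                                          bt2, btyp2)
                old_neutral = _neutral_path_logdens(a, k_old, bt2, btyp2,
                                                    blen[b], lg, ll)
                k_new = _sample_bridge(a, c, blen[b], lg, ll, bt, btyp)
                if k_new < 0:
                    continue
                new_neutral = _neutral_path_logdens(a, k_new, bt, btyp,
                                                    blen[b], lg, ll)
                k_merged = _merge_replace(b, j, ev_t, ev_a, ev_g, ev_n,
                                          k_new, bt, btyp, sc_t, sc_a, sc_g, 0)
                if k_merged < 0:
                    continue
                _scratch_stats(b, node_state, sc_t, sc_a, sc_g, k_merged, 0,
                               parent, blen, D, dbar, beta, agg, stat_buf)
                log_acc = _ld_from_stats(stat_buf, lg, ll) \
                    - _ld_from_stats(branch_stats[b], lg, ll) \
                    + (old_neutral - new_neutral)
                if np.log(np.random.random()) < log_acc:
                    accepts[4] += 1
                    _copy_from_scratch(b, ev_t, ev_a, ev_g, ev_n,
                                       sc_t, sc_a, sc_g, 0, k_merged)
                    for q in range(5):
                        branch_stats[b, q] = stat_buf[q]

            # --- node-state flips with incident path redraws ------------
            for _ in range(n_node_moves):
                proposals[5] += 1
                v = internal_nodes[np.random.randint(internal_nodes.shape[0])]
                j = np.random.randint(M)
                s_old = node_state[v, j]
                s_new = 1 - s_old
                log_acc = 0.0
                n_aff = 0
                ok = True
                if parent[v] >= 0:
                    aff[n_aff] = v
                    n_aff += 1
                for ci in range(children_ptr[v], children_ptr[v + 1]):
                    if n_aff >= 8:
                        ok = False
                        break
                    aff[n_aff] = children_idx[ci]
                    n_aff += 1
                if not ok:
                    continue
                # reverse-proposal terms for the current paths
                for ai in range(n_aff):
                    e = aff[ai]
                    pe = parent[e]
                    a_old = node_state[pe, j]
                    c_old = node_state[e, j]
                    k_old = _extract_asv_path(e, j, ev_t, ev_a, ev_g, ev_n,
                                              bt2, btyp2)
                    log_acc += _neutral_path_logdens(a_old, k_old, bt2, btyp2,
                                                     blen[e], lg, ll)
                    log_acc -= _log_pab(a_old, c_old, blen[e], lg, ll)
                    log_acc -= _ld_from_stats(branch_stats[e], lg, ll)
                if v == root:
                    pi = lg / (lg + ll) if pi_mode == 1 else pi_value
                    if s_new == 1:
                        log_acc += np.log(pi) - np.log(1.0 - pi)
                    else:
                        log_acc += np.log(1.0 - pi) - np.log(pi)
                # flip and propose new paths
                node_state[v, j] = s_new
                for ai in range(n_aff):
                    e = aff[ai]
                    pe = parent[e]
                    a_new = node_state[pe, j]
                    c_new = node_state[e, j]
                    k_new = _sample_bridge(a_new, c_new, blen[e], lg, ll,
                                           bt, btyp)
                    if k_new < 0:
                        ok = False
                        break
                    log_acc -= _neutral_path_logdens(a_new, k_new, bt, btyp,
                                                     blen[e], lg, ll)
                    log_acc += _log_pab(a_new, c_new, blen[e], lg, ll)
                    km = _merge_replace(e, j, ev_t, ev_a, ev_g, ev_n,
                                        k_new, bt, btyp, sc_t, sc_a, sc_g, ai)
                    if km < 0:
                        ok = False
                        break
                    aff_k[ai] = km
                    _scratch_stats(e, node_state, sc_t, sc_a, sc_g, km, ai,
                                   parent, blen, D, dbar, beta, agg,
                                   aff_stats[ai])
                    log_acc += _ld_from_stats(aff_stats[ai], lg, ll)
                if ok and np.log(np.random.random()) < log_acc:
                    accepts[5] += 1
                    for ai in range(n_aff):
                        e = aff[ai]
                        _copy_from_scratch(e, ev_t, ev_a, ev_g, ev_n,
                                           sc_t, sc_a, sc_g, ai, aff_k[ai])
                        for q in range(5):
                            branch_stats[e, q] = aff_stats[ai, q]
                else:
                    node_state[v, j] = s_old

        # --- record -----------------------------------------------------
        if (cycle + 1) % thin == 0:
            out_params[s_idx, 0] = lg
            out_params[s_idx, 1] = ll
            out_params[s_idx, 2] = beta
            hist_ld = _root_logprior(node_state, root, M, lg, ll,
                                     pi_mode, pi_value)
            ng = 0
            nl = 0
            for bi in range(n_branch):
                b = branch_nodes[bi]
                hist_ld += _ld_from_stats(branch_stats[b], lg, ll)
                for e in range(ev_n[b]):
                    if ev_g[b, e]:
                        ng += 1
                    else:
                        nl += 1
            out_loglik[s_idx, 0] = hist_ld
            out_loglik[s_idx, 1] = _param_logprior(lg, ll, beta,
                                                   lam_rate, beta_rate, fix)
            out_counts[s_idx, 0] = ng
            out_counts[s_idx, 1] = nl
            for nd in range(n_nodes):
                for j in range(M):
                    out_nodes[s_idx, nd, j] = node_state[nd, j]
            for si in range(n_slices):
                b = slice_branch[si]
                p = parent[b]
                for j in range(M):
                    out_slices[s_idx, si, j] = node_state[p, j]
                for e in range(ev_n[b]):
                    if ev_t[b, e] <= slice_tau[si]:
                        out_slices[s_idx, si, ev_a[b, e]] = ev_g[b, e]
                    else:
                        break
            s_idx += 1

    return out_params, out_loglik, out_counts, out_nodes, out_slices, \
        accepts, proposals
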