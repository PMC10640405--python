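"""The host-repertoire process: ASV gain/loss along a host phylogeny.

Each host lineage carries a repertoire, the set of ASVs it currently hosts.
Along a branch the repertoire evolves as a continuous-time Markov process:
a present ASV is lost at rate ``lambda_loss``; an absent ASV j is gained at
rate ``lambda_gain * eta(j, R)`` where

    eta(j, R) = (dbar / d(j, R)) ** beta,

d(j, R) is the (mean or min) patristic distance on the ASV tree from j to
the ASVs already in the repertoire R and dbar the mean off-diagonal ASV
distance.  beta >= 0 scales how strongly phylogenetic proximity to the
current repertoire promotes gains; beta = 0 (or an empty repertoire) makes
the process neutral.  At a host split both daughters inherit the parental
repertoire.  Time is in Myr; rates in events/Myr/ASV.

This module holds readable reference implementations: the generative
simulator (exact Gillespie), the augmented-history density targeted by the
MCMC, and two exact-likelihood oracles (a joint 2^M CTMC and the beta = 0
per-ASV pruning factorization) used to validate both the simulator and the
sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .trees import DistanceMatrix, Phylogeny

__all__ = [
    "RepertoireParams",
    "Event",
    "RepertoireHistory",
    "gain_rate",
    "simulate_history",
    "history_log_density",
    "exact_tip_likelihood",
    "independent_pruning_loglik",
    "joint_tip_pattern_distribution",
]

_MAX_JOINT_ASVS = 14  # 2^M joint state space cap for the exact oracle
_MIN_DIST = 1e-12  # guard against zero patristic distances in eta


@dataclass(frozen=True)
class RepertoireParams:
    """Rates of the gain/loss process (events/Myr/ASV) and the distance effect."""

    lambda_gain: float
    lambda_loss: float
    beta: float = 0.0

    def __post_init__(self):
        if self.lambda_gain < 0 or self.lambda_loss < 0:
            raise ValueError("rates must be non-negative")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class Event:
    """A single gain or loss: (age in Myr before present, ASV index, kind)."""

    age: float
    asv: int
    is_gain: bool


def _as_distance_array(D) -> np.ndarray:
    if isinstance(D, DistanceMatrix):
        return D.values
    return np.asarray(D, dtype=float)


def mean_offdiagonal(D) -> float:
    d = _as_distance_array(D)
    n = d.shape[0]
    if n < 2:
        return 1.0
    return float(d[~np.eye(n, dtype=bool)].mean())


def gain_rate(j, repertoire, params: RepertoireParams, D, agg: str = "mean") -> float:
    """Rate (events/Myr) at which ASV ``j`` is gained given repertoire ``R``.

    ``repertoire`` is an iterable of ASV indices or a boolean mask.  Falls
    back to the neutral rate ``lambda_gain`` when the repertoire is empty or
    beta = 0.  Raises if j is already present (a gain must target an absent
    ASV).
    """
    d = _as_distance_array(D)
    mask = np.zeros(d.shape[0], dtype=bool)
    r = np.asarray(repertoire)
    if r.dtype == bool:
        mask = r.copy()
    elif r.size:
        mask[r.astype(int)] = True
    if mask[j]:
        raise ValueError(f"ASV {j} already in repertoire; gain undefined")
    if params.beta == 0.0 or not mask.any():
        return params.lambda_gain
    dists = d[j, mask]
    if agg == "mean":
        djr = dists.mean()
    elif agg == "min":
        djr = dists.min()
    else:
        raise ValueError(f"unknown aggregation {agg!r}")
    djr = max(djr, _MIN_DIST)
    eta = (mean_offdiagonal(d) / djr) ** params.beta
    return params.lambda_gain * eta


@dataclass
class RepertoireHistory:
    """A complete realization of the process on a host tree.

    ``node_states``: (n_nodes, M) boolean, the repertoire at every node.
    ``events``: branch (keyed by child-node index) -> events ordered from
    the rootward end of the branch to the tipward end (decreasing age).
    Applying a branch's events to the parental repertoire must reproduce the
    child's; both daughters of a split start from the parental end-state.
    """

    tree: Phylogeny
    n_asvs: int
    node_states: np.ndarray
    events: dict[int, list[Event]] = field(default_factory=dict)

    def validate(self) -> None:
        ages = self.tree.ages
        for child, evs in self.events.items():
            p = self.tree.parent[child]
            if p < 0:
                raise ValueError("events recorded above the root")
            r = self.node_states[p].copy()
            prev_age = ages[p]
            for i, ev in enumerate(evs):
                if not (ages[child] < ev.age < ages[p]) or ev.age > prev_age:
                    raise ValueError(
                        f"branch {child}, event {i}: age {ev.age} outside/unordered"
                    )
                if ev.is_gain and r[ev.asv]:
                    raise ValueError(f"branch {child}, event {i}: gain of present ASV")
                if not ev.is_gain and not r[ev.asv]:
                    raise ValueError(f"branch {child}, event {i}: loss of absent ASV")
                r[ev.asv] = ev.is_gain
                prev_age = ev.age
            if not np.array_equal(r, self.node_states[child]):
                raise ValueError(f"branch {child}: events do not reach child state")

    def repertoire_at(self, branch: int, age: float) -> np.ndarray:
        """Repertoire on ``branch`` (edge above node ``branch``) at ``age``."""
        ages = self.tree.ages
        p = self.tree.parent[branch]
        if p < 0:
            raise ValueError("root has no branch")
        if not (ages[branch] <= age <= ages[p]):
            raise ValueError("age not on branch")
        r = self.node_states[p].copy()
        for ev in self.events.get(branch, []):
            if ev.age <= age:
                break
            r[ev.asv] = ev.is_gain
        return r

    def tip_matrix(self) -> np.ndarray:
        """(n_tips, M) presence/absence at the tips, in tip_indices order."""
        return self.node_states[self.tree.tip_indices].astype(float)

    def event_counts(self) -> tuple[int, int]:
        gains = sum(ev.is_gain for evs in self.events.values() for ev in evs)
        losses = sum(not ev.is_gain for evs in self.events.values() for ev in evs)
        return gains, losses


def _total_rates(r: np.ndarray, params: RepertoireParams, d: np.ndarray,
                 dbar: float, agg: str) -> tuple[np.ndarray, float]:
    """Per-absent-ASV gain rates and the total loss rate for repertoire r."""
    m = r.size
    gains = np.zeros(m)
    absent = ~r
    if params.beta == 0.0 or not r.any():
        gains[absent] = params.lambda_gain
    else:
        sub = d[np.ix_(absent, r)]
        djr = sub.mean(axis=1) if agg == "mean" else sub.min(axis=1)
        djr = np.maximum(djr, _MIN_DIST)
        gains[absent] = params.lambda_gain * (dbar / djr) ** params.beta
    return gains, params.lambda_loss * float(r.sum())


def simulate_history(
    tree: Phylogeny,
    D,
    params: RepertoireParams,
    root_prob: float = 0.5,
    seed=None,
    agg: str = "mean",
) -> RepertoireHistory:
    """Draw a complete history by exact Gillespie simulation along the tree.

    The root repertoire is independent Bernoulli(``root_prob``) per ASV; on
    each branch, waiting times are exponential in the current total rate
    (resampled after every event), and event identity is chosen
    proportionally to the individual rates.
    """
    if not 0.0 <= root_prob <= 1.0:
        raise ValueError("root_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    d = _as_distance_array(D)
    m = d.shape[0]
    dbar = mean_offdiagonal(d)
    ages = tree.ages
    states = np.zeros((tree.n_nodes, m), dtype=bool)
    states[tree.root] = rng.random(m) < root_prob
    events: dict[int, list[Event]] = {}

    for node in tree._preorder():
        if node == tree.root:
            continue
        p = tree.parent[node]
        r = states[p].copy()
        t_len = ages[p] - ages[node]
        tau = 0.0
        evs: list[Event] = []
        while True:
            gains, loss_tot = _total_rates(r, params, d, dbar, agg)
            total = gains.sum() + loss_tot
            if total <= 0:
                break
            tau += rng.exponential(1.0 / total)
            if tau >= t_len:
                break
            rates = gains.copy()
            rates[r] = params.lambda_loss
            pick = rng.choice(m, p=rates / rates.sum())
            is_gain = not r[pick]
            r[pick] = is_gain
            evs.append(Event(age=ages[p] - tau, asv=int(pick), is_gain=is_gain))
        states[node] = r
        events[node] = evs
    return RepertoireHistory(tree=tree, n_asvs=m, node_states=states, events=events)


def history_log_density(
    history: RepertoireHistory,
    params: RepertoireParams,
    D,
    root_prob: float = 0.5,
    agg: str = "mean",
    validate: bool = True,
) -> float:
    """Log density of a complete history under the process.

    log Bernoulli(root) + per branch: -(total rate) * dt over every constant
    segment, + log(rate of each event at its occurrence time).
    """
    if validate:
        history.validate()
    d = _as_distance_array(D)
    dbar = mean_offdiagonal(d)
    tree = history.tree
    ages = tree.ages
    r0 = history.node_states[tree.root]
    with np.errstate(divide="ignore"):
        ld = float(
            r0.sum() * np.log(root_prob) + (r0.size - r0.sum()) * np.log(1 - root_prob)
        )
    for node in tree._preorder():
        if node == tree.root:
            continue
        p = tree.parent[node]
        r = history.node_states[p].copy()
        prev = ages[p]
        for ev in history.events.get(node, []):
            gains, loss_tot = _total_rates(r, params, d, dbar, agg)
            ld -= (gains.sum() + loss_tot) * (prev - ev.age)
            rate = gains[ev.asv] if ev.is_gain else params.lambda_loss
            ld += np.log(rate)
            r[ev.asv] = ev.is_gain
            prev = ev.age
        gains, loss_tot = _total_rates(r, params, d, dbar, agg)
        ld -= (gains.sum() + loss_tot) * (prev - ages[node])
    return float(ld)


# ---------------------------------------------------------------------------
# exact likelihood oracles


def _joint_generator(params: RepertoireParams, d: np.ndarray, agg: str) -> np.ndarray:
    """Dense generator over the 2^M joint repertoires (single-ASV flips)."""
    m = d.shape[0]
    if m > _MAX_JOINT_ASVS:
        raise ValueError(f"joint CTMC limited to {_MAX_JOINT_ASVS} ASVs, got {m}")
    dbar = mean_offdiagonal(d)
    n = 1 << m
    q = np.zeros((n, n))
    for s in range(n):
        r = np.array([(s >> j) & 1 for j in range(m)], dtype=bool)
        gains, _ = _total_rates(r, params, d, dbar, agg)
        for j in range(m):
            if r[j]:
                q[s, s ^ (1 << j)] = params.lambda_loss
            else:
                q[s, s ^ (1 << j)] = gains[j]
        q[s, s] = -q[s].sum()
    return q


def _root_distribution(m: int, root_prob: float) -> np.ndarray:
    n = 1 << m
    p = np.empty(n)
    for s in range(n):
        k = bin(s).count("1")
        p[s] = root_prob**k * (1 - root_prob) ** (m - k)
    return p


def _tips_as_array(tree: Phylogeny, tips) -> np.ndarray:
    """Coerce tip data to an (n_tips, M) array in tip_indices order."""
    from .tables import InteractionMatrix

    if isinstance(tips, InteractionMatrix):
        order = [tips.hosts.index(lbl) for lbl in tree.tip_labels]
        return tips.values[order]
    return np.asarray(tips, dtype=float)


def _branch_transition_cache(tree: Phylogeny, q: np.ndarray) -> dict[int, np.ndarray]:
    ages = tree.ages
    cache: dict[float, np.ndarray] = {}
    out = {}
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p < 0:
            continue
        t = float(ages[p] - ages[node])
        if t not in cache:
            cache[t] = expm(q * t)
        out[node] = cache[t]
    return out


def exact_tip_likelihood(
    tree: Phylogeny, tips, params: RepertoireParams, D, root_prob: float = 0.5,
    agg: str = "mean",
) -> float:
    """Exact log likelihood of tip repertoires under the joint 2^M CTMC.

    Builds the generator over joint repertoires (single-ASV flips, gains
    distance-modified), prunes with per-branch matrix exponentials, and sums
    over the product-Bernoulli root distribution.  Refuses M > 14.
    """
    d = _as_distance_array(D)
    m = d.shape[0]
    q = _joint_generator(params, d, agg)
    trans = _branch_transition_cache(tree, q)
    tip_arr = _tips_as_array(tree, tips)
    tip_rows = {node: i for i, node in enumerate(tree.tip_indices)}
    n_states = 1 << m

    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node in tip_rows:
            bits = tip_arr[tip_rows[node]]
            s = sum((1 << j) for j in range(m) if bits[j] > 0.5)
            vec = np.zeros(n_states)
            vec[s] = 1.0
        else:
            vec = np.ones(n_states)
            for c in tree.children(node):
                vec = vec * (trans[c] @ partial[c])
        partial[node] = vec
    lik = float(_root_distribution(m, root_prob) @ partial[tree.root])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik))


def independent_pruning_loglik(
    tree: Phylogeny, tips, params: RepertoireParams, root_prob: float = 0.5
) -> float:
    """beta = 0 fast path: per-ASV two-state Felsenstein pruning, summed.

    With no distance effect the ASVs evolve independently, each on the
    two-state chain with rates (lambda_gain, lambda_loss).
    """
    if params.beta != 0.0:
        raise ValueError("independent pruning requires beta = 0")
    g, l = params.lambda_gain, params.lambda_loss
    ages = tree.ages
    tip_arr = _tips_as_array(tree, tips)
    m = tip_arr.shape[1]
    tip_rows = {node: i for i, node in enumerate(tree.tip_indices)}

    def ptrans(t: float) -> np.ndarray:
        mu = g + l
        if mu == 0:
            return np.eye(2)
        e = np.exp(-mu * t)
        p1 = g / mu
        return np.array(
            [[1 - p1 * (1 - e), p1 * (1 - e)], [(1 - p1) * (1 - e), p1 + (1 - p1) * e]]
        )

    total = 0.0
    root_pi = np.array([1 - root_prob, root_prob])
    for j in range(m):
        partial: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node in tip_rows:
                obs = int(tip_arr[tip_rows[node], j] > 0.5)
                vec = np.zeros(2)
                vec[obs] = 1.0
            else:
                vec = np.ones(2)
                for c in tree.children(node):
                    t = float(ages[tree.parent[c]] - ages[c])
                    vec = vec * (ptrans(t) @ partial[c])
            partial[node] = vec
        lik = float(root_pi @ partial[tree.root])
        total += np.log(lik) if lik > 0 else -np.inf
    return float(total)


def joint_tip_pattern_distribution(
    tree: Phylogeny, params: RepertoireParams, D, root_prob: float = 0.5,
    agg: str = "mean",
):
    """Exact distribution over *all* joint tip patterns (tiny trees only).

    Returns (tip_order, probs) where probs[i] is the probability of the
    pattern whose per-tip joint states are the digits of i in base 2^M, most
    significant digit = first tip in ``tip_order``.  Used as the simulator's
    goodness-of-fit oracle.
    """
    d = _as_distance_array(D)
    m = d.shape[0]
    n_states = 1 << m
    n_tips = tree.n_tips
    if n_states**n_tips > 2_000_000:
        raise ValueError("pattern space too large for exact enumeration")
    q = _joint_generator(params, d, agg)
    trans = _branch_transition_cache(tree, q)
    tipset = set(tree.tip_indices)

    # bottom-up tables T[node][s, p] = P(tip pattern p below node | state s)
    def table(node: int) -> tuple[np.ndarray, list[int]]:
        if node in tipset:
            return np.eye(n_states), [node]
        tab = None
        tips_order: list[int] = []
        for c in tree.children(node):
            child_tab, child_tips = table(c)
            msg = trans[c] @ child_tab  # [s, p_child]
            if tab is None:
                tab, tips_order = msg, child_tips
            else:
                tab = np.einsum("sp,sq->spq", tab, msg).reshape(n_states, -1)
                tips_order = tips_order + child_tips
        return tab, tips_order

    tab, tips_order = table(tree.root)
    probs = _root_distribution(m, root_prob) @ tab
    return tips_order, probs
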