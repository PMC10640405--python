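"""Community statistics: alpha diversity, Bray-Curtis, PERMANOVA.

Shannon is reported in nats.  ACE follows the classic frequency-count
estimator with rare cutoff 10 and falls back to bias-corrected Chao1 when
the rare-class coverage is zero (all rare counts singletons).  PERMANOVA is
the permutation pseudo-F test on a distance matrix, with an add-one
permutation p-value; the pairwise variant applies Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import false_discovery_control

__all__ = [
    "shannon",
    "ace",
    "bray_curtis",
    "bray_curtis_matrix",
    "permanova",
    "pairwise_permanova",
    "PermanovaResult",
]


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) over positive counts."""
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or (c < 0).any():
        raise ValueError("counts must be non-negative and non-empty")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def ace(counts, rare_cutoff: int = 10) -> tuple[float, bool]:
    """Abundance-based coverage estimator of richness.

    With F_i the number of taxa observed exactly i times, S_rare the number
    of taxa with 1..cutoff reads, N_rare their total reads and
    C = 1 - F_1/N_rare the rare-class sample coverage:

        S_ACE = S_abund + S_rare/C + (F_1/C) * gamma^2,
        gamma^2 = max[(S_rare/C) * sum i(i-1)F_i / (N_rare (N_rare-1)) - 1, 0].

    When C = 0 (every rare taxon is a singleton) the estimator is undefined
    and the bias-corrected Chao1 value is returned instead.  Returns
    (estimate, chao1_fallback_used).
    """
    c = np.asarray(counts)
    if not np.issubdtype(c.dtype, np.integer):
        if not np.allclose(c, np.round(c)):
            raise ValueError("ACE requires integer counts")
        c = np.round(c).astype(int)
    if (c < 0).any() or (c > 0).sum() == 0:
        raise ValueError("need non-negative counts with at least one positive")
    c = c[c > 0]
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = int(rare.size)
    if s_rare == 0:
        return float(s_abund), False
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    coverage = 1.0 - f1 / n_rare
    if coverage == 0.0:
        # all rare taxa are singletons: bias-corrected Chao1 fallback
        f2 = 0  # by construction here
        s_obs = s_abund + s_rare
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        return float(chao1), True
    freq = np.bincount(rare, minlength=rare_cutoff + 1)
    i = np.arange(rare_cutoff + 1)
    ssum = float((i * (i - 1) * freq).sum())
    gamma2 = 0.0
    if n_rare > 1:
        gamma2 = max((s_rare / coverage) * ssum / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    return float(s_abund + s_rare / coverage + (f1 / coverage) * gamma2), False


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundances")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors all-zero")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(counts) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarities between rows of ``counts``."""
    c = np.asarray(counts, dtype=float)
    n = c.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(c[i], c[j])
    return out


@dataclass
class PermanovaResult:
    """PERMANOVA partition and permutation test outcome."""

    f_statistic: float
    ss_among: float
    ss_within: float
    ss_total: float
    n_permutations: int
    p_value: float
    groups: tuple[str, ...]
    p_adjusted: float | None = None
    notes: dict = field(default_factory=dict)


def _ss_partition(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Total / within sums of squares from squared distances and group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(codes == g)
        if members.size > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(members.size, k=1)].sum() / members.size
    return ss_total, ss_within


def _pseudo_f(d2, codes, n_groups):
    n = d2.shape[0]
    ss_total, ss_within = _ss_partition(d2, codes, n_groups)
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_among > 0 else np.nan, ss_among, ss_within, ss_total
    f = (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_among, ss_within, ss_total


def permanova(dist, labels, n_permutations: int = 999, seed=None) -> PermanovaResult:
    """Permutation MANOVA (pseudo-F) on a distance matrix.

    SS_total = (1/n) sum_{i<j} d_ij^2; SS_within sums the analogous per-group
    terms; F = (SS_among/(g-1)) / (SS_within/(n-g)).  The p-value counts
    permutations with F >= F_obs under the add-one rule
    p = (#exceedances + 1)/(n_permutations + 1).
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    n = d.shape[0]
    if d.shape != (n, n) or labels.size != n:
        raise ValueError("distance matrix / labels shape mismatch")
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    groups = np.unique(labels)
    codes = np.searchsorted(groups, labels)
    if groups.size < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(codes)
    small = [str(groups[g]) for g in np.flatnonzero(counts < 2)]
    if small:
        raise ValueError(f"groups of size 1 not allowed: {small}")
    d2 = d**2
    if not d2.any():
        raise ValueError("all distances zero: F undefined")

    f_obs, ss_among, ss_within, ss_total = _pseudo_f(d2, codes, groups.size)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        f_perm = _pseudo_f(d2, codes[perm], groups.size)[0]
        if f_perm >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return PermanovaResult(
        f_statistic=float(f_obs),
        ss_among=float(ss_among),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
        n_permutations=n_permutations,
        p_value=float(p),
        groups=tuple(str(g) for g in groups),
    )


def pairwise_permanova(
    dist, labels, n_permutations: int = 999, seed=None
) -> list[PermanovaResult]:
    """One PERMANOVA per unordered group pair, BH-adjusted p-values."""
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    results = []
    for a, b in combinations(groups, 2):
        mask = np.isin(labels, [a, b])
        idx = np.flatnonzero(mask)
        sub = d[np.ix_(idx, idx)]
        res = permanova(
            sub, labels[idx], n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        results.append(res)
    raw = np.array([r.p_value for r in results])
    adj = false_discovery_control(raw, method="bh")
    for r, q in zip(results, adj):
        r.p_adjusted = float(min(q, 1.0))
    return results
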