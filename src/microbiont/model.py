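"""Bayesian inference for the host-repertoire gain/loss model.

`HostRepertoireModel` is built from a presence/absence host x ASV matrix, a
dated host phylogeny and an ASV patristic-distance matrix; ``fit`` runs a
data-augmented MCMC (parameters + complete gain/loss histories) and returns
a `HostRepertoireResults` carrying the traces, convergence diagnostics
(Gelman-Rubin PSRF), the Savage-Dickey Bayes factor for the
phylogenetic-distance effect beta = 0, posterior interaction probabilities
at internal nodes and at requested time slices, and event-rate summaries.

Priors: lambda_gain, lambda_loss ~ Exponential(rate), beta ~
Exponential(rate) on [0, inf).  Exponential priors keep the prior density
of beta at the point null closed-form, which the Savage-Dickey ratio needs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import _kernel
from .repertoire import _as_distance_array, mean_offdiagonal
from .tables import InteractionMatrix
from .trees import Phylogeny, lineage_name, lineages_at_time

__all__ = [
    "Priors",
    "ChainConfig",
    "EventRateSummary",
    "HostRepertoireModel",
    "HostRepertoireResults",
    "gelman_psrf",
    "savage_dickey_bf",
    "interpret_bf",
]

PARAM_NAMES = ("lambda_gain", "lambda_loss", "beta")


@dataclass(frozen=True)
class Priors:
    """Exponential prior rates; mean = 1/rate."""

    lambda_rate: float = 10.0
    beta_rate: float = 1.0

    def __post_init__(self):
        if self.lambda_rate <= 0 or self.beta_rate <= 0:
            raise ValueError("prior rates must be positive")

    def beta_density_at_zero(self) -> float:
        return self.beta_rate


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run lengths: cycles, thinning, burn-in fraction, chain count."""

    cycles: int = 150_000
    thinning: int = 500
    burnin: float = 0.10
    chains: int = 3
    seed: int | None = None

    def __post_init__(self):
        if self.cycles % self.thinning != 0:
            raise ValueError("cycles must be divisible by thinning")
        if not 0 <= self.burnin < 1:
            raise ValueError("burn-in fraction must be in [0, 1)")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @property
    def samples_per_chain(self) -> int:
        return self.cycles // self.thinning

    @property
    def retained_per_chain(self) -> int:
        n = self.samples_per_chain
        return n - int(np.floor(self.burnin * n))


@dataclass(frozen=True)
class EventRateSummary:
    """Posterior mean gain/loss event rates under a stated normalization."""

    gains_per_myr: float
    losses_per_myr: float
    normalization: str  # "tree_length" | "root_age"
    basis_myr: float

    @property
    def total_per_myr(self) -> float:
        return self.gains_per_myr + self.losses_per_myr


# ---------------------------------------------------------------------------
# free-standing diagnostics


def gelman_psrf(chains) -> tuple[float, bool]:
    """Gelman-Rubin potential scale reduction factor for >= 2 chains.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance of means times n.  Returns
    (psrf, degenerate); degenerate flags zero within-chain variance.
    """
    arrs = [np.asarray(c, dtype=float) for c in chains]
    if len(arrs) < 2:
        raise ValueError("need at least two chains")
    n = arrs[0].size
    if n < 10 or any(a.size != n for a in arrs):
        raise ValueError("chains must have equal length >= 10")
    means = np.array([a.mean() for a in arrs])
    variances = np.array([a.var(ddof=1) for a in arrs])
    w = variances.mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return (np.inf if b > 0 else 1.0), True
    return float(np.sqrt(((n - 1) / n * w + b / n) / w)), False


def savage_dickey_bf(beta_samples, prior_density_at_zero: float = 1.0,
                     epsilon: float | None = None) -> dict:
    """Savage-Dickey Bayes factor for beta != 0 versus beta = 0.

    BF = prior density at 0 / posterior density at 0, the latter estimated
    by the fraction of posterior samples in [0, eps) divided by eps, with
    eps from a Silverman-type bandwidth rule (reported).  When no sample
    falls in the window the BF is reported as a lower bound and flagged.
    """
    s = np.asarray(beta_samples, dtype=float)
    if s.size == 0:
        raise ValueError("no beta samples")
    n = s.size
    if epsilon is None:
        sd = s.std(ddof=1) if n > 1 else 0.0
        iqr = np.subtract(*np.percentile(s, [75, 25]))
        scale = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
        epsilon = 0.9 * scale * n ** (-0.2) if scale > 0 else 0.0
    if epsilon <= 0:
        epsilon = max(s.mean(), 1e-6) * 0.1  # degenerate trace fallback
    frac = float((s < epsilon).mean())
    if frac == 0.0:
        post0 = (1.0 / (n + 1)) / epsilon
        return {
            "bf": prior_density_at_zero / post0,
            "is_lower_bound": True,
            "epsilon": float(epsilon),
            "posterior_density_at_zero": post0,
            "n_samples": n,
        }
    post0 = frac / epsilon
    return {
        "bf": prior_density_at_zero / post0,
        "is_lower_bound": False,
        "epsilon": float(epsilon),
        "posterior_density_at_zero": post0,
        "n_samples": n,
    }


def interpret_bf(bf: float) -> str:
    """Evidence category for the distance-effect model, by BF band."""
    if bf <= 0:
        raise ValueError("Bayes factor must be positive")
    if bf < 1:
        return "no effect"
    if bf < 10:
        return "weak/positive"
    if bf < 30:
        return "strong"
    if bf < 100:
        return "very strong"
    return "decisive"


# ---------------------------------------------------------------------------
# the model


class HostRepertoireModel:
    """Gain/loss model of host-ASV repertoires on a dated host phylogeny.

    Parameters
    ----------
    tip_matrix : InteractionMatrix or (n_tips, M) array
        Observed presence/absence; rows must match the tree's tips (by label
        for an InteractionMatrix, by tip order for an array).
    host_tree : Phylogeny
        Dated (ultrametric) host tree, branch lengths in Myr.
    asv_distances : DistanceMatrix or (M, M) array
        Patristic distances on the ASV character tree.
    priors : Priors
    root_prob : float or "stationary"
        Root-repertoire Bernoulli probability; "stationary" tracks
        lambda_gain/(lambda_gain+lambda_loss) of the current parameters.
    distance_agg : "mean" or "min"
        How d(j, R) aggregates distances from j to the repertoire.
    """

    def __init__(self, tip_matrix, host_tree: Phylogeny, asv_distances,
                 priors: Priors = Priors(), root_prob="stationary",
                 distance_agg: str = "mean"):
        self.tree = host_tree
        if not host_tree.is_ultrametric:
            raise ValueError("host tree must be dated (ultrametric)")
        d = _as_distance_array(asv_distances)
        if isinstance(tip_matrix, InteractionMatrix):
            order = [tip_matrix.hosts.index(lbl) for lbl in host_tree.tip_labels]
            tips = tip_matrix.values[order]
            self.asv_labels = list(tip_matrix.asvs)
            from .trees import DistanceMatrix

            if isinstance(asv_distances, DistanceMatrix):
                idx = [asv_distances.labels.index(a) for a in tip_matrix.asvs]
                d = asv_distances.values[np.ix_(idx, idx)]
        else:
            tips = np.asarray(tip_matrix, dtype=float)
            self.asv_labels = [f"ASV{j}" for j in range(tips.shape[1])]
        if tips.shape != (host_tree.n_tips, d.shape[0]):
            raise ValueError(
                f"tip matrix shape {tips.shape} does not match "
                f"{host_tree.n_tips} tips x {d.shape[0]} ASVs"
            )
        self.tip_states = tips > 0.5
        self.D = d
        self.dbar = mean_offdiagonal(d)
        self.priors = priors
        self.root_prob = root_prob
        if distance_agg not in ("mean", "min"):
            raise ValueError("distance_agg must be 'mean' or 'min'")
        self.distance_agg = distance_agg

    # -- initialization ----------------------------------------------------
    def _initial_states(self) -> np.ndarray:
        """Majority-rule upward pass seeding internal node repertoires."""
        tree = self.tree
        m = self.D.shape[0]
        states = np.zeros((tree.n_nodes, m), dtype=np.uint8)
        tip_rows = {node: i for i, node in enumerate(tree.tip_indices)}
        for node in tree.postorder():
            if node in tip_rows:
                states[node] = self.tip_states[tip_rows[node]].astype(np.uint8)
            else:
                kids = tree.children(node)
                votes = states[kids].sum(axis=0)
                states[node] = (2 * votes >= len(kids)).astype(np.uint8)
        return states

    def _slice_arrays(self, record_ages):
        """Flatten requested time slices into kernel arrays + lineage names."""
        branches, taus, names, ages_of = [], [], [], []
        ages = self.tree.ages
        for t in record_ages or ():
            lin = lineages_at_time(self.tree, t)
            for b in sorted(lin):
                branches.append(b)
                taus.append(float(ages[self.tree.parent[b]] - t))
                names.append(lineage_name(lin[b]))
                ages_of.append(float(t))
        return (np.array(branches, dtype=np.int64),
                np.array(taus, dtype=float), names, ages_of)

    # -- fitting -----------------------------------------------------------
    def fit(self, config: ChainConfig = ChainConfig(), record_ages=(),
            prior_only: bool = False, fixed: dict | None = None,
            init_params: dict | None = None,
            sweep_moves: int | None = None,
            hist_move_fraction: float = 0.02,
            node_move_fraction: float = 0.05,
            scale_step: float = 0.4, beta_step: float = 0.5,
            event_capacity: int = 4096) -> "HostRepertoireResults":
        """Run ``config.chains`` independent chains; deterministic given seed.

        ``fixed`` maps parameter names to values held constant;
        ``record_ages`` lists slice ages (Myr) at which per-lineage
        repertoires are recorded for ancestral-network reconstruction.
        """
        tree = self.tree
        m = self.D.shape[0]
        parent = tree.parent.astype(np.int64)
        blen = tree.branch_length.astype(float)
        branch_nodes = np.array(
            [i for i in range(tree.n_nodes) if parent[i] >= 0], dtype=np.int64
        )
        tipset = set(tree.tip_indices)
        internal_nodes = np.array(
            [i for i in range(tree.n_nodes) if i not in tipset], dtype=np.int64
        )
        children_ptr = np.zeros(tree.n_nodes + 1, dtype=np.int64)
        children_idx = []
        for i in range(tree.n_nodes):
            kids = tree.children(i)
            children_ptr[i + 1] = children_ptr[i] + len(kids)
            children_idx.extend(kids)
        children_idx = np.array(children_idx, dtype=np.int64)

        fixed = dict(fixed or {})
        fix = np.zeros(3, dtype=np.uint8)
        init = {
            "lambda_gain": 1.0 / self.priors.lambda_rate,
            "lambda_loss": 1.0 / self.priors.lambda_rate,
            "beta": 1.0 / self.priors.beta_rate,
        }
        init.update(init_params or {})
        for name, value in fixed.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
            fix[PARAM_NAMES.index(name)] = 1
            init[name] = float(value)

        pi_mode = 1 if self.root_prob == "stationary" else 0
        pi_value = 0.5 if pi_mode else float(self.root_prob)

        slice_branch, slice_tau, slice_names, slice_ages = \
            self._slice_arrays(record_ages)

        n_sweep = branch_nodes.size if sweep_moves is None else int(sweep_moves)
        n_hist = max(4, round(hist_move_fraction * branch_nodes.size * m))
        n_node = max(4, round(node_move_fraction * internal_nodes.size * m))

        seed_seq = np.random.SeedSequence(config.seed)
        chain_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                       for s in seed_seq.spawn(config.chains)]

        init_state = self._initial_states()
        agg = 0 if self.distance_agg == "mean" else 1
        chains = []
        for c in range(config.chains):
            out = _kernel.run_chain(
                parent, blen, tree.root, internal_nodes, branch_nodes,
                children_ptr, children_idx,
                self.D, self.dbar, agg,
                init_state,
                float(init["lambda_gain"]), float(init["lambda_loss"]),
                float(init["beta"]), fix,
                float(self.priors.lambda_rate), float(self.priors.beta_rate),
                pi_mode, pi_value,
                int(config.cycles), int(config.thinning),
                chain_seeds[c], prior_only,
                int(n_sweep), int(n_hist), int(n_node),
                float(scale_step), float(beta_step), int(event_capacity),
                slice_branch, slice_tau,
            )
            chains.append(out)
        return HostRepertoireResults(
            model=self, config=config, chains_raw=chains,
            slice_names=slice_names, slice_ages=slice_ages,
            fixed=fixed, prior_only=prior_only, chain_seeds=chain_seeds,
        )


class HostRepertoireResults:
    """Posterior draws and diagnostics from :meth:`HostRepertoireModel.fit`."""

    def __init__(self, model, config, chains_raw, slice_names, slice_ages,
                 fixed, prior_only, chain_seeds):
        self.model = model
        self.config = config
        self.fixed = fixed
        self.prior_only = prior_only
        self.chain_seeds = chain_seeds
        self.slice_names = slice_names
        self.slice_ages = slice_ages
        self._params = [c[0] for c in chains_raw]      # (n, 3)
        self._loglik = [c[1] for c in chains_raw]      # (n, 2)
        self._counts = [c[2] for c in chains_raw]      # (n, 2)
        self._nodes = [c[3] for c in chains_raw]       # (n, n_nodes, M)
        self._slices = [c[4] for c in chains_raw]      # (n, n_slices, M)
        self.accepts = [c[5] for c in chains_raw]
        self.proposals = [c[6] for c in chains_raw]
        n = config.samples_per_chain
        self._burn = int(np.floor(config.burnin * n))

    # -- traces ------------------------------------------------------------
    @property
    def n_retained(self) -> int:
        return self.config.retained_per_chain * self.config.chains

    def param_chain(self, name: str, chain: int,
                    include_burnin: bool = False) -> np.ndarray:
        j = PARAM_NAMES.index(name)
        arr = self._params[chain][:, j]
        return arr if include_burnin else arr[self._burn:]

    def posterior(self, name: str, pooled: bool = True,
                  chain: int | None = None) -> np.ndarray:
        if chain is not None:
            return self.param_chain(name, chain)
        if pooled:
            return np.concatenate(
                [self.param_chain(name, c) for c in range(self.config.chains)]
            )
        raise ValueError("specify pooled=True or a chain index")

    def to_frame(self, include_burnin: bool = False) -> pd.DataFrame:
        rows = []
        for c in range(self.config.chains):
            lo = 0 if include_burnin else self._burn
            n = self._params[c].shape[0]
            for i in range(lo, n):
                rows.append({
                    "chain": c,
                    "cycle": (i + 1) * self.config.thinning,
                    "lambda_gain": self._params[c][i, 0],
                    "lambda_loss": self._params[c][i, 1],
                    "beta": self._params[c][i, 2],
                    "log_history_density": self._loglik[c][i, 0],
                    "log_prior": self._loglik[c][i, 1],
                    "n_gains": self._counts[c][i, 0],
                    "n_losses": self._counts[c][i, 1],
                })
        return pd.DataFrame(rows)

    # -- diagnostics -------------------------------------------------------
    def psrf(self, name: str) -> tuple[float, bool]:
        if self.config.chains < 2:
            raise ValueError("PSRF needs >= 2 chains")
        return gelman_psrf(
            [self.param_chain(name, c) for c in range(self.config.chains)]
        )

    def acceptance_rates(self) -> pd.DataFrame:
        labels = ["rate_scale", "beta_scale", "beta_walk", "branch_sweep",
                  "path_redraw", "node_flip"]
        acc = np.sum(self.accepts, axis=0)
        prop = np.sum(self.proposals, axis=0)
        with np.errstate(invalid="ignore"):
            rate = np.where(prop > 0, acc / np.maximum(prop, 1), np.nan)
        return pd.DataFrame({"move": labels, "proposed": prop,
                             "accepted": acc, "rate": rate})

    def credible_interval(self, name: str, level: float = 0.95):
        s = self.posterior(name)
        a = (1 - level) / 2
        return tuple(np.quantile(s, [a, 1 - a]))

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: mean, sd, 95% CI, PSRF per parameter."""
        rows = []
        for name in PARAM_NAMES:
            s = self.posterior(name)
            lo, hi = self.credible_interval(name)
            row = {
                "parameter": name,
                "mean": s.mean(),
                "sd": s.std(ddof=1) if s.size > 1 else 0.0,
                "ci2.5": lo,
                "ci97.5": hi,
                "fixed": name in self.fixed,
            }
            if self.config.chains >= 2 and name not in self.fixed:
                psrf, degen = self.psrf(name)
                row["psrf"] = np.nan if degen else psrf
            else:
                row["psrf"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows).set_index("parameter")

    # -- science outputs ---------------------------------------------------
    def savage_dickey_bf(self, epsilon: float | None = None) -> dict:
        out = savage_dickey_bf(
            self.posterior("beta"),
            prior_density_at_zero=self.model.priors.beta_density_at_zero(),
            epsilon=epsilon,
        )
        out["category"] = interpret_bf(out["bf"])
        return out

    def _pool_slices(self, pooled, chain):
        idx = range(self.config.chains) if chain is None else [chain]
        return np.concatenate([self._slices[c][self._burn:] for c in idx])

    def _pool_nodes(self, chain=None):
        idx = range(self.config.chains) if chain is None else [chain]
        return np.concatenate([self._nodes[c][self._burn:] for c in idx])

    def interaction_probabilities(self, age: float | None = None,
                                  chain: int | None = None) -> pd.DataFrame:
        """Posterior P(lineage hosts ASV): rows lineages, columns ASVs.

        ``age=None`` returns internal-node probabilities (node ancestral
        states); otherwise ``age`` must be one of the fit's recorded slice
        ages.
        """
        asvs = self.model.asv_labels
        if age is None:
            samples = self._pool_nodes(chain)  # (n, n_nodes, M)
            tree = self.model.tree
            tipset = set(tree.tip_indices)
            rows, names = [], []
            for node in range(tree.n_nodes):
                if node in tipset:
                    continue
                rows.append(samples[:, node, :].mean(axis=0))
                names.append(lineage_name(tree.tip_set(node)))
            return pd.DataFrame(rows, index=names, columns=asvs)
        matching = [i for i, a in enumerate(self.slice_ages)
                    if np.isclose(a, age)]
        if not matching:
            raise ValueError(
                f"age {age} not recorded; available: {sorted(set(self.slice_ages))}"
            )
        samples = self._pool_slices(True, chain)
        rows = [samples[:, i, :].mean(axis=0) for i in matching]
        names = [self.slice_names[i] for i in matching]
        return pd.DataFrame(rows, index=names, columns=asvs)

    def tip_probabilities(self, chain: int | None = None) -> pd.DataFrame:
        samples = self._pool_nodes(chain)
        tree = self.model.tree
        rows = [samples[:, node, :].mean(axis=0) for node in tree.tip_indices]
        return pd.DataFrame(rows, index=tree.tip_labels,
                            columns=self.model.asv_labels)

    def event_rate_summary(self, normalization: str = "tree_length",
                           chain: int | None = None) -> EventRateSummary:
        """Posterior mean event rates; events per Myr of tree length (default)
        or per Myr of elapsed time (root age)."""
        if normalization == "tree_length":
            basis = self.model.tree.total_branch_length
        elif normalization == "root_age":
            basis = self.model.tree.root_age
        else:
            raise ValueError("normalization must be 'tree_length' or 'root_age'")
        idx = range(self.config.chains) if chain is None else [chain]
        counts = np.concatenate([self._counts[c][self._burn:] for c in idx])
        return EventRateSummary(
            gains_per_myr=float(counts[:, 0].mean() / basis),
            losses_per_myr=float(counts[:, 1].mean() / basis),
            normalization=normalization,
            basis_myr=float(basis),
        )

    def manifest(self) -> dict:
        return {
            "config": asdict(self.config),
            "priors": asdict(self.model.priors),
            "fixed": self.fixed,
            "prior_only": self.prior_only,
            "chain_seeds": self.chain_seeds,
            "root_prob": self.model.root_prob,
            "distance_agg": self.model.distance_agg,
            "recorded_slice_ages": sorted(set(self.slice_ages)),
            "acceptance": self.acceptance_rates().to_dict("records"),
        }
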