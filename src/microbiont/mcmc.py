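"""Functional surface over the Model/Results MCMC machinery.

Thin wrappers for callers who prefer functions to objects; everything
delegates to :mod:`microbiont.model`.
"""

from __future__ import annotations

from .model import (
    ChainConfig,
    HostRepertoireModel,
    HostRepertoireResults,
    Priors,
    gelman_psrf,
    interpret_bf,
    savage_dickey_bf,
)

__all__ = [
    "run_mcmc",
    "gelman_psrf",
    "savage_dickey_bf",
    "interpret_bf",
    "interaction_probabilities",
    "event_rate_summary",
    "ChainConfig",
    "Priors",
]


def run_mcmc(tip_matrix, host_tree, asv_distances,
             priors: Priors = Priors(), config: ChainConfig = ChainConfig(),
             **fit_kwargs) -> HostRepertoireResults:
    """Fit the gain/loss model; returns the results object (all chains)."""
    model = HostRepertoireModel(tip_matrix, host_tree, asv_distances,
                                priors=priors)
    return model.fit(config=config, **fit_kwargs)


def interaction_probabilities(results: HostRepertoireResults, age=None,
                              chain=None):
    return results.interaction_probabilities(age=age, chain=chain)


def event_rate_summary(results: HostRepertoireResults,
                       normalization: str = "tree_length"):
    return results.event_rate_summary(normalization=normalization)
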