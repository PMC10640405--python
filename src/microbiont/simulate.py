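"""Synthetic study generator with known ground truth.

Emulates a multi-site amplicon survey of gut bacteria across six closely
related leaf-beetle species: a dated six-species host tree with splits
spanning 77 ky to 4 My, a unit-height Yule tree for the pool of dominant
ASVs, host repertoires evolved under the gain/loss process with known
parameters, and per-individual sequencing counts with site structure and a
long tail of rare background ASVs.

Default conditions (see docs/methods.md for the reasoning):

* 6 species sampled at 1-3 sites each, 3-9 individuals per species-site
  (85 samples total); sequencing depth lognormal around 50k reads;
* a 45-ASV dominant pool with gain rate 0.1 and loss rate 0.35
  (/Myr/ASV), giving a stationary repertoire size near 10 of 45 and
  roughly balanced gain and loss event flows, and a distance effect
  beta = 1.5;
* 2000 background ASVs with power-law mean abundances carrying ~30% of
  the reads, so the dominant pool covers ~70% of reads per sample;
* dominant ASVs spread over five bacterial phyla, plus a small set of
  host-derived (mitochondrial/chloroplast) and unassigned ASVs that
  loading is expected to discard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .repertoire import RepertoireHistory, RepertoireParams, simulate_history
from .tables import CountTable, InteractionMatrix
from .trees import Phylogeny, patristic_distances

__all__ = [
    "StudyDesign",
    "preset_host_tree",
    "random_asv_tree",
    "simulate_study",
    "DEFAULT_PARAMS",
    "DEFAULT_ROOT_PROB",
]

#: generator defaults: the study-shaped gain/loss process
DEFAULT_PARAMS = RepertoireParams(lambda_gain=0.1, lambda_loss=0.35, beta=1.5)
#: stationary occupancy of the neutral chain at the default rates (10/45)
DEFAULT_ROOT_PROB = DEFAULT_PARAMS.lambda_gain / (
    DEFAULT_PARAMS.lambda_gain + DEFAULT_PARAMS.lambda_loss
)

PHYLA = ("Proteobacteria", "Bacteroidota", "Actinobacteriota",
         "Firmicutes", "Verrucomicrobiota")
#: dominant-pool phylum mixture, most weight on Proteobacteria
PHYLUM_WEIGHTS = (0.62, 0.12, 0.08, 0.14, 0.04)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design and sequencing model of the synthetic survey."""

    species_sites: dict = field(default_factory=lambda: {
        "calmariensis": {"siteA": 9, "siteB": 7, "siteC": 8},
        "pusilla": {"siteA": 6, "siteB": 5},
        "tenella": {"siteB": 4, "siteD": 5, "siteE": 3},
        "lineola": {"siteD": 7, "siteF": 6},
        "nymphaea": {"siteF": 5, "siteG": 4},
        "sagittariae": {"siteG": 8, "siteH": 5, "siteE": 3},
    })
    depth_meanlog: float = float(np.log(50_000))
    depth_sdlog: float = 0.4
    n_background_asvs: int = 2000
    #: fraction of expected reads carried by the background tail
    tail_mass: float = 0.30
    #: lognormal sd of dominant ASV mean abundances
    dominant_sdlog: float = 1.0
    #: lognormal sd of the per-site, per-ASV multiplicative effect
    site_effect_sd: float = 0.8
    #: per-ASV probability of low-rate contamination of absent dominants
    contamination_rate: float = 0.0
    #: number of host-derived/unassigned ASVs mixed into the background
    n_excluded_taxa: int = 12

    def __post_init__(self):
        for sp, sites in self.species_sites.items():
            if not sites or any(n < 1 for n in sites.values()):
                raise ValueError(f"species {sp!r} needs >= 1 sample per site")
        if self.tail_mass < 0 or self.tail_mass >= 1:
            raise ValueError("tail_mass must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return sum(n for sites in self.species_sites.values()
                   for n in sites.values())

    @property
    def species(self) -> list[str]:
        return sorted(self.species_sites)


def preset_host_tree() -> Phylogeny:
    """The dated six-species host tree used throughout the synthetic study.

    Topology ((sagittariae, nymphaea), (lineola, (tenella, (pusilla,
    calmariensis)))), with the pusilla-calmariensis split at 0.077 Ma, the
    tenella split at 1.0 Ma (five lineages exist at 1 Ma), the lineola and
    sagittariae-nymphaea splits at 2.5 and 2.2 Ma (four lineages at 2 Ma)
    and the root at 4.0 Ma.
    """
    ages = {"root": 4.0, "sn": 2.2, "lin_anc": 2.5, "ten_anc": 1.0,
            "pc": 0.077}
    labels = ["", "", "sagittariae", "nymphaea", "", "lineola", "",
              "tenella", "", "pusilla", "calmariensis"]
    parent = np.array([-1, 0, 1, 1, 0, 4, 4, 6, 6, 8, 8])
    blen = np.array([
        0.0,
        ages["root"] - ages["sn"],
        ages["sn"], ages["sn"],
        ages["root"] - ages["lin_anc"],
        ages["lin_anc"],
        ages["lin_anc"] - ages["ten_anc"],
        ages["ten_anc"],
        ages["ten_anc"] - ages["pc"],
        ages["pc"], ages["pc"],
    ])
    return Phylogeny(parent=parent, branch_length=blen, labels=labels)


def random_asv_tree(n: int, seed=None) -> Phylogeny:
    """Seeded Yule (pure-birth) tree with ``n`` tips, scaled to unit height.

    Stands in for a character-based phylogeny of the dominant ASVs; only
    its patristic distances enter the gain/loss model, and the distance
    modifier is invariant to the overall scale.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    # grow forward in time: each active lineage splits at rate 1
    parent = [-1]
    birth = [0.0]  # time the node was created
    active = [0]
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        pick = active[rng.integers(k)]
        for _ in range(2):
            parent.append(pick)
            birth.append(t)
            active.append(len(parent) - 1)
        active.remove(pick)
        if len(active) == n:
            break
    t_end = t + rng.exponential(1.0 / n)  # tips extend past the last split
    parent = np.array(parent)
    birth = np.array(birth)
    n_nodes = parent.size
    is_tip = np.ones(n_nodes, dtype=bool)
    is_tip[parent[parent >= 0]] = False
    blen = np.zeros(n_nodes)
    for i in range(n_nodes):
        if parent[i] >= 0:
            end = t_end if is_tip[i] else birth[np.flatnonzero(parent == i)[0]]
            blen[i] = end - birth[i]
    height = t_end - birth[1]  # root's daughters are born at the root split
    blen /= height  # unit height
    labels = ["" for _ in range(n_nodes)]
    tip_ids = np.flatnonzero(is_tip)
    for rank, i in enumerate(tip_ids):
        labels[i] = f"ASV{rank + 1:03d}"
    return Phylogeny(parent=parent, branch_length=blen, labels=labels)


def _taxonomy(dominant: list[str], background: list[str],
              n_excluded: int, rng) -> pd.DataFrame:
    rows = {}
    for i, asv in enumerate(dominant):
        ph = rng.choice(len(PHYLA), p=PHYLUM_WEIGHTS)
        rows[asv] = (PHYLA[ph], f"class_{PHYLA[ph][:4]}", f"genus_{i % 17}")
    for i, asv in enumerate(background):
        if i < n_excluded:
            kind = ("mitochondria", "chloroplast", "unassigned")[i % 3]
            if kind == "mitochondria":
                rows[asv] = ("Proteobacteria", "mitochondria", "unassigned")
            elif kind == "chloroplast":
                rows[asv] = ("Cyanobacteria", "chloroplast", "unassigned")
            else:
                rows[asv] = ("unassigned", "unassigned", "unassigned")
        else:
            ph = rng.choice(len(PHYLA), p=PHYLUM_WEIGHTS)
            rows[asv] = (PHYLA[ph], f"class_{PHYLA[ph][:4]}",
                         f"genus_{i % 31}")
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["phylum", "class", "genus"])
    df.index.name = "asv"
    return df


def simulate_study(design: StudyDesign | None = None,
                   host_tree: Phylogeny | None = None,
                   asv_tree: Phylogeny | None = None,
                   params: RepertoireParams = DEFAULT_PARAMS,
                   root_prob: float = DEFAULT_ROOT_PROB,
                   seed=None):
    """Generate a complete synthetic survey.

    Returns (CountTable, true RepertoireHistory, true InteractionMatrix,
    manifest dict).  Dominant-pool repertoires evolve on the host tree;
    present dominants receive lognormal mean abundances scaled by per-site
    lognormal effects; background ASVs receive power-law means carrying
    ``design.tail_mass`` of the expected reads; counts are multinomial at
    lognormal depth.  Fully deterministic for a given seed.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    host_tree = host_tree or preset_host_tree()
    asv_tree = asv_tree or random_asv_tree(45, seed=rng.integers(2**31 - 1))
    D = patristic_distances(asv_tree)
    dominant = list(D.labels)
    m = len(dominant)

    history = simulate_history(host_tree, D, params, root_prob,
                               seed=rng.integers(2**31 - 1))
    tip_states = history.tip_matrix()  # (n_tips, M) in tip_indices order
    tip_labels = host_tree.tip_labels
    truth = InteractionMatrix(hosts=tip_labels, asvs=dominant,
                              values=tip_states)

    background = [f"bg{i + 1:04d}" for i in range(design.n_background_asvs)]
    taxonomy = _taxonomy(dominant, background, design.n_excluded_taxa, rng)

    # per-species mean abundances of present dominant ASVs (lognormal);
    # scaled so the background tail carries `tail_mass` of expected reads
    dom_means = {}
    for si, sp in enumerate(tip_labels):
        present = tip_states[si] > 0.5
        mu = np.zeros(m)
        mu[present] = rng.lognormal(0.0, design.dominant_sdlog,
                                    size=int(present.sum()))
        if design.contamination_rate > 0:
            absent = ~present
            leak = rng.random(m) < design.contamination_rate
            mu[absent & leak] = 1e-3 * rng.lognormal(0.0, 0.5,
                                                     size=int((absent & leak).sum()))
        dom_means[sp] = mu
    # flat-ish power law: many rare taxa, none rivalling a dominant ASV
    ranks = np.arange(1, design.n_background_asvs + 1)
    bg_means = ranks ** -0.8
    mean_dom_total = np.mean([mu.sum() for mu in dom_means.values()])
    # the per-site lognormal multiplier inflates expected dominant mass by
    # exp(sd^2/2); fold that in so `tail_mass` is the realized read share
    site_inflation = float(np.exp(design.site_effect_sd**2 / 2))
    if design.tail_mass > 0 and mean_dom_total > 0:
        bg_means *= (design.tail_mass / (1 - design.tail_mass)) \
            * mean_dom_total * site_inflation / bg_means.sum()

    sites = sorted({s for v in design.species_sites.values() for s in v})
    site_effects = {s: rng.lognormal(0.0, design.site_effect_sd, size=m)
                    for s in sites}

    sample_ids, counts, meta_rows = [], [], []
    for sp in design.species:
        if sp not in tip_labels:
            raise ValueError(f"design species {sp!r} not on the host tree")
        for site, n_ind in sorted(design.species_sites[sp].items()):
            for i in range(n_ind):
                sid = f"{sp}_{site}_{i + 1}"
                mu = np.concatenate([
                    dom_means[sp] * site_effects[site], bg_means,
                ])
                depth = int(rng.lognormal(design.depth_meanlog,
                                          design.depth_sdlog))
                p = mu / mu.sum()
                counts.append(rng.multinomial(depth, p))
                sample_ids.append(sid)
                meta_rows.append({"sample": sid, "species": sp, "site": site})

    count_df = pd.DataFrame(np.array(counts), index=sample_ids,
                            columns=dominant + background)
    count_df.index.name = "sample"
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    table = CountTable(counts=count_df, metadata=metadata, taxonomy=taxonomy)

    manifest = {
        "seed": seed,
        "params": {"lambda_gain": params.lambda_gain,
                   "lambda_loss": params.lambda_loss, "beta": params.beta},
        "root_prob": root_prob,
        "n_dominant": m,
        "n_background": design.n_background_asvs,
        "n_samples": design.n_samples,
        "true_events": dict(zip(("gains", "losses"),
                                history.event_counts())),
        "asv_tree_newick": asv_tree.to_newick(),
        "host_tree_newick": host_tree.to_newick(),
        # true per-species mean abundances of the dominant pool, for
        # selection-recovery checks ("truly dominant" = top-k true means)
        "true_mean_abundance": {sp: [float(x) for x in mu]
                                for sp, mu in dom_means.items()},
    }
    return table, history, truth, manifest
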