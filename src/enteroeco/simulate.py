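"""Synthetic gut-community generators.

Everything the pipeline assumes about real data has a generative
counterpart here, so the whole artifact is exercisable offline:

* Dirichlet-multinomial mixtures with driver genera boosted per cluster
  (planted enterotype structure);
* Yule phylogenies whose tips are drawn into communities either at
  random or from within one subclade (planted assembly signal);
* metacommunities obeying the Sloan occurrence-abundance relationship at
  a known migration rate;
* host metadata (season, altitude, body temperature, RMR, mass) with
  planted enterotype-conditional effects.

All generators are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import skbio
import yaml
from scipy import stats
from skbio import TreeNode

from .containers import AbundanceTable, ConfigError
from .io import derive_metadata

__all__ = [
    "ScenarioConfig",
    "load_preset",
    "simulate_enterotype_dataset",
    "simulate_phylogeny_communities",
    "simulate_neutral_dataset",
    "simulate_host_physiology",
    "yule_tree",
]

# per-enterotype physiology templates (plateau-pika scale: rectal
# temperature in deg C, RMR in mL CO2/min, mass in grams); entry i is the
# mean for cluster label i+1, cycled when K exceeds the template length
_BODY_TEMP_TEMPLATE = (39.6, 38.9, 39.5, 39.2)
_RMR_TEMPLATE = (3.2, 2.7, 3.1, 2.9)
_MASS_TEMPLATE = (152.0, 170.0, 160.0, 158.0)
# P(warm | enterotype): cluster 1 is the warm-season type, cluster 2 the
# cold-season type, later clusters are season-generalists
_WARM_PROB_TEMPLATE = (0.95, 0.15, 0.45, 0.5)
# P(high altitude | enterotype)
_HIGH_PROB_TEMPLATE = (0.55, 0.5, 0.35, 0.5)


def _cycle(template, k):
    return tuple(template[i % len(template)] for i in range(k))


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study scenario.

    The defaults describe the bacterial-like desk-scale scenario: 60
    samples, 50 genera, three enterotypes each dominated by one driver
    genus boosted 8x, rarefied depth 10^4.
    """

    n_samples: int = 60
    n_taxa: int = 50
    n_clusters: int = 3
    n_drivers: int = 2
    driver_boost: float = 8.0
    base_concentration: float = 40.0
    depth: int = 10_000
    cluster_probs: tuple | None = None
    # phylogeny / assembly scenario
    tree_birth_rate: float = 1.0
    assembly_scenario: str = "random"
    richness_per_sample: int = 10
    # neutral metacommunity
    neutral_m: float = 0.1
    neutral_N: int = 1000
    logseries_shape: float = 0.999
    # host metadata effects (per-enterotype means; None -> templates)
    body_temp_means: tuple | None = None
    body_temp_sd: float = 0.5
    rmr_means: tuple | None = None
    rmr_sd: float = 0.5
    mass_means: tuple | None = None
    mass_sd: float = 12.0
    season_probs: tuple | None = None        # per cluster: (P(warm), P(cold))
    altitude_high_probs: tuple | None = None  # per cluster: P(high)

    def __post_init__(self) -> None:
        k = self.n_clusters
        if k < 1 or self.n_taxa < 1 or self.n_samples < 1:
            raise ConfigError("counts must be positive")
        if k > self.n_taxa:
            raise ConfigError("n_clusters cannot exceed n_taxa")
        if self.driver_boost < 1:
            raise ConfigError("driver_boost must be >= 1")
        if self.assembly_scenario not in ("random", "clustered"):
            raise ConfigError(f"unknown assembly scenario {self.assembly_scenario!r}")
        if not (0 < self.neutral_m <= 1):
            raise ConfigError("neutral_m must lie in (0, 1]")
        for sd in (self.body_temp_sd, self.rmr_sd, self.mass_sd):
            if sd <= 0:
                raise ConfigError("effect standard deviations must be positive")
        if self.cluster_probs is None:
            self.cluster_probs = tuple(1.0 / k for _ in range(k))
        self.cluster_probs = tuple(float(x) for x in self.cluster_probs)
        if len(self.cluster_probs) != k or abs(sum(self.cluster_probs) - 1) > 1e-9:
            raise ConfigError("cluster_probs must have length K and sum to 1")
        if self.body_temp_means is None:
            self.body_temp_means = _cycle(_BODY_TEMP_TEMPLATE, k)
        if self.rmr_means is None:
            self.rmr_means = _cycle(_RMR_TEMPLATE, k)
        if self.mass_means is None:
            self.mass_means = _cycle(_MASS_TEMPLATE, k)
        if self.season_probs is None:
            warm = _cycle(_WARM_PROB_TEMPLATE, k)
            self.season_probs = tuple((w, 1.0 - w) for w in warm)
        self.season_probs = tuple(tuple(float(x) for x in row)
                                  for row in self.season_probs)
        for row in self.season_probs:
            if len(row) != 2 or abs(sum(row) - 1) > 1e-9 or min(row) < 0:
                raise ConfigError("season_probs rows must be (P(warm), P(cold)) "
                                  "summing to 1")
        if self.altitude_high_probs is None:
            self.altitude_high_probs = _cycle(_HIGH_PROB_TEMPLATE, k)
        for p in self.altitude_high_probs:
            if not 0 <= p <= 1:
                raise ConfigError("altitude_high_probs must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def load_preset(name: str) -> ScenarioConfig:
    """Load a shipped scenario preset ('bacterial_like' or 'fungal_like')."""
    ref = importlib.resources.files("enteroeco") / "presets" / f"{name}.yaml"
    if not ref.is_file():
        raise ConfigError(f"no preset named {name!r}")
    return ScenarioConfig.from_dict(yaml.safe_load(ref.read_text()) or {})


# ---------------------------------------------------------------------------
# enterotype-structured tables
# ---------------------------------------------------------------------------

def simulate_enterotype_dataset(cfg: ScenarioConfig, seed: int = 0):
    """Draw a counts table from a Dirichlet-multinomial mixture with
    planted driver genera, plus true labels and host metadata.

    Cluster c's Dirichlet parameters are the shared base concentrations
    with that cluster's driver genera multiplied by ``driver_boost``.
    Drivers are the K x n_drivers highest-weight genera, so each
    enterotype is dominated by an already-abundant genus, one per
    cluster.

    Returns (AbundanceTable[counts], labels: Series sample -> 1..K,
    metadata DataFrame).
    """
    rng = np.random.default_rng(seed)
    k, t = cfg.n_clusters, cfg.n_taxa
    weights = rng.lognormal(0.0, 1.0, size=t)
    weights /= weights.sum()
    base_alpha = cfg.base_concentration * weights
    rank = np.argsort(weights)[::-1]
    drivers = {c + 1: [int(rank[c * cfg.n_drivers + j])
                       for j in range(cfg.n_drivers)] for c in range(k)}
    alphas = []
    for c in range(k):
        a = base_alpha.copy()
        a[drivers[c + 1]] *= cfg.driver_boost
        alphas.append(a)
    labels = rng.choice(np.arange(1, k + 1), size=cfg.n_samples,
                        p=cfg.cluster_probs)
    counts = np.empty((cfg.n_samples, t), dtype=np.int64)
    for i, lab in enumerate(labels):
        comp = rng.dirichlet(alphas[lab - 1])
        counts[i] = rng.multinomial(cfg.depth, comp)
    sample_ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    taxon_ids = [f"G{j + 1:03d}" for j in range(t)]
    table = AbundanceTable(
        pd.DataFrame(counts, index=sample_ids, columns=taxon_ids), kind="counts")
    labels = pd.Series(labels, index=sample_ids, name="enterotype")
    metadata = simulate_host_physiology(labels, cfg, seed=seed + 1)
    return table, labels, metadata


# ---------------------------------------------------------------------------
# phylogenies and assembly scenarios
# ---------------------------------------------------------------------------

def yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> TreeNode:
    """Pure-birth (Yule) tree with ``n_tips`` labelled tips T1..Tn."""
    if n_tips < 2:
        raise ConfigError("a Yule tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    t = 0.0
    root = TreeNode()
    root.length = 0.0
    birth_time = {id(root): 0.0}
    active = [root]
    while len(active) < n_tips:
        n = len(active)
        t += rng.exponential(1.0 / (birth_rate * n))
        i = int(rng.integers(n))
        parent = active.pop(i)
        parent.length = t - birth_time[id(parent)]
        children = [TreeNode(), TreeNode()]
        parent.extend(children)
        for ch in children:
            birth_time[id(ch)] = t
        active.extend(children)
    # run the last generation forward to the present
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for i, node in enumerate(active):
        node.length = t - birth_time[id(node)]
        node.name = f"T{i + 1}"
    root.length = 0.0
    return root


def simulate_phylogeny_communities(cfg: ScenarioConfig, seed: int = 0):
    """Sample presence communities from a Yule phylogeny.

    ``random`` scenario: each sample's taxa are a uniform draw of
    ``richness_per_sample`` tips. ``clustered``: each sample draws its
    taxa from one randomly chosen non-root subclade holding at least
    twice the per-sample richness. Counts are uniform (presence = 1).

    Returns (tree, AbundanceTable[counts]).
    """
    if cfg.n_taxa < 8:
        raise ConfigError("assembly simulation needs at least 8 taxa")
    if cfg.richness_per_sample < 2:
        raise ConfigError("richness_per_sample must be at least 2")
    rng = np.random.default_rng(seed)
    tree = yule_tree(cfg.n_taxa, cfg.tree_birth_rate, seed=seed)
    tips = [tip.name for tip in tree.tips()]
    r = cfg.richness_per_sample
    if cfg.assembly_scenario == "clustered":
        # minimal qualifying subclades: at least 2x the per-sample richness
        # but no qualifying child clade, i.e. the tightest clades that can
        # host a community — these carry the strongest clustering signal
        qualifying = {}
        for node in tree.non_tips(include_self=False):
            clade_tips = [tip.name for tip in node.tips()]
            if len(clade_tips) >= 2 * r and len(clade_tips) < len(tips):
                qualifying[id(node)] = (node, clade_tips)
        clades = []
        for node, clade_tips in qualifying.values():
            if not any(id(ch) in qualifying for ch in node.children):
                clades.append(clade_tips)
        if not clades:
            raise ConfigError(
                "no non-root subclade holds 2x the per-sample richness; "
                "increase n_taxa or lower richness_per_sample")
    presence = np.zeros((cfg.n_samples, len(tips)), dtype=np.int64)
    tip_index = {name: j for j, name in enumerate(tips)}
    for i in range(cfg.n_samples):
        if cfg.assembly_scenario == "random":
            chosen = rng.choice(len(tips), size=r, replace=False)
            presence[i, chosen] = 1
        else:
            clade = clades[int(rng.integers(len(clades)))]
            chosen = rng.choice(len(clade), size=r, replace=False)
            for c in chosen:
                presence[i, tip_index[clade[int(c)]]] = 1
    sample_ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    table = AbundanceTable(
        pd.DataFrame(presence, index=sample_ids, columns=tips), kind="counts")
    return tree, table


# ---------------------------------------------------------------------------
# neutral metacommunities
# ---------------------------------------------------------------------------

def simulate_neutral_dataset(m: float = 0.1, N: int = 1000, n_taxa: int = 500,
                             n_samples: int = 100,
                             logseries_shape: float = 0.999,
                             count_model: str = "censored",
                             seed: int = 0):
    """Communities obeying the Sloan neutral occurrence-abundance law.

    Metacommunity relative abundances come from a normalised log-series;
    each sample's per-taxon relative abundance x is drawn from the
    neutral stationary distribution Beta(N*m*p, N*m*(1-p)).

    ``count_model`` controls how the Beta draw is realised as reads:

    * ``"censored"`` (default): reads = N*x for x above the detection
      limit 1/N, else 0. Presence then follows exactly the occupancy law
      the Sloan fit inverts (a taxon is detected iff its relative
      abundance clears the detection limit), making parameter recovery a
      clean round trip. Reads are real-valued.
    * ``"binomial"``: integer counts = Binomial(N, x). The resampling
      layer smooths occupancy near the detection limit, which inflates a
      naively fitted migration rate by ~20-40%; offered for realism
      studies, not for recovery oracles.

    Returns (AbundanceTable[counts], truth dict with the planted m, N, p).
    """
    if not (0 < m <= 1):
        raise ConfigError("m must lie in (0, 1]")
    if N < 100:
        raise ConfigError("N must be at least 100")
    if count_model not in ("censored", "binomial"):
        raise ConfigError(f"unknown count_model {count_model!r}")
    rng = np.random.default_rng(seed)
    abund = stats.logser.rvs(logseries_shape, size=n_taxa, random_state=rng)
    p = abund / abund.sum()
    a = N * m * p
    b = N * m * (1.0 - p)
    x = rng.beta(a[None, :].repeat(n_samples, axis=0),
                 b[None, :].repeat(n_samples, axis=0))
    if count_model == "binomial":
        counts = rng.binomial(N, x)
    else:
        counts = np.where(x > 1.0 / N, N * x, 0.0)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    taxon_ids = [f"A{j + 1:04d}" for j in range(n_taxa)]
    table = AbundanceTable(
        pd.DataFrame(counts, index=sample_ids, columns=taxon_ids), kind="counts")
    return table, {"m": float(m), "N": int(N), "p": p}


# ---------------------------------------------------------------------------
# host metadata
# ---------------------------------------------------------------------------

def simulate_host_physiology(labels: pd.Series, cfg: ScenarioConfig,
                             seed: int = 0) -> pd.DataFrame:
    """Draw host metadata conditional on enterotype labels.

    Body temperature, RMR and mass are Normal(mu_enterotype, sd); season
    and altitude class follow the per-enterotype probability rows of the
    config; altitude in metres is uniform within the class band (the
    high/low boundary sits at 3,900 m).
    """
    rng = np.random.default_rng(seed)
    k = cfg.n_clusters
    lab = labels.to_numpy()
    if lab.min() < 1 or lab.max() > k:
        raise ConfigError("labels must lie in 1..n_clusters")
    idx = lab - 1
    temp = rng.normal(np.asarray(cfg.body_temp_means)[idx], cfg.body_temp_sd)
    rmr = rng.normal(np.asarray(cfg.rmr_means)[idx], cfg.rmr_sd)
    mass = rng.normal(np.asarray(cfg.mass_means)[idx], cfg.mass_sd)
    warm_p = np.array([row[0] for row in cfg.season_probs])[idx]
    season = np.where(rng.random(len(lab)) < warm_p, "warm", "cold")
    high_p = np.asarray(cfg.altitude_high_probs)[idx]
    is_high = rng.random(len(lab)) < high_p
    altitude = np.where(is_high,
                        rng.uniform(3901.0, 4800.0, len(lab)),
                        rng.uniform(3100.0, 3900.0, len(lab)))
    sex = rng.choice(["F", "M"], size=len(lab))
    df = pd.DataFrame({
        "sample_id": labels.index,
        "season": season,
        "altitude_m": np.round(altitude, 0),
        "sex": sex,
        "body_temp_C": np.round(temp, 2),
        "rmr": np.round(np.clip(rmr, 0.1, None), 3),
        "mass_g": np.round(np.clip(mass, 50.0, None), 1),
    })
    return derive_metadata(df)
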