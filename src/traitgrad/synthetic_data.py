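"""Synthetic grassland scenarios: phylogenies, traits and community tables
with the statistical structure the analysis pipeline assumes.

The default scenario emulates a temperate-grassland survey: 76 species on
an ultrametric tree, 27 plots split between two habitat types across three
sites, abundances as the fraction of 10 quadrats occupied, log-scale traits
whose within-community (alpha) component is phylogenetically conserved
while habitat affinity carries no phylogenetic signal, intraspecific
variation tracking the community trait gradient with slope b_s of about 1,
and ~2% of species-plot occurrences left unmeasured.

The intraspecific slope b_s is generated mechanistically: plants respond
plastically to their plot's environment, and b_s_true fixes the share of
the community-mean trait gradient carried by that shared plastic response
(the remainder is species turnover).  See :func:`attach_traits` for the
construction; recovering b_s_true cleanly requires communities where the
gradient is well identified (see the calibration notes in the package
documentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .phylo import Node, Phylogeny
from .trait_gradient import OccurrenceTable

__all__ = [
    "ScenarioConfig",
    "simulate_tree",
    "simulate_bm_traits",
    "assign_habitat_affinity",
    "assemble_communities",
    "attach_traits",
    "generate_scenario",
    "write_scenario",
    "slope_calibration_config",
    "DEFAULT_TRAITS",
]

DEFAULT_TRAITS = [
    "height", "sla", "leaf_size", "leaf_thickness", "leaf_tissue_density",
    "srl", "root_tissue_density", "root_diameter",
]


@dataclass
class ScenarioConfig:
    """Parameters of a simulated grassland survey."""

    n_species: int = 76
    n_plots: int = 27
    n_habitats: int = 2
    n_quadrats: int = 10
    birth_rate: float = 1.0          # Yule speciation rate (1/My, nominal)
    bm_rate: float = 1.0             # BM rate of the alpha component
    alpha_sd: float = 1.0            # SD of the alpha component (log10 units)
    alpha_signal: bool = True        # BM on the tree vs tip-shuffled
    habitat_signal: bool = False     # phylogenetic signal in affinity
    niche_breadth: float = 0.5       # Gaussian niche width on affinity scale
    detectability: float = 0.12      # median per-quadrat occupancy at optimum
    dominance_sd: float = 1.0        # lognormal SD of species commonness
    habitat_separation: float = 1.2  # distance between habitat centres
    env_jitter_sd: float = 0.15      # plot-level environmental noise
    beta_coef: float = 0.1           # base-trait response to habitat affinity
    gradient_sd: float = 0.3         # SD of the plastic plot gradient (log10)
    b_s_true: float = 1.0            # intraspecific slope along the gradient
    noise_sd: float = 0.25           # residual SD among individual plants
    plants_per_occurrence: int = 1   # collected plants per species per plot
    missing_fraction: float = 0.02   # occurrences left unmeasured
    trait_names: List[str] = field(default_factory=lambda: list(DEFAULT_TRAITS))
    species_level_traits: List[str] = field(default_factory=lambda: ["height"])
    seed: int = 0

    def __post_init__(self):
        for name in ("n_species", "n_plots", "n_habitats", "n_quadrats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.missing_fraction <= 1:
            raise ValueError("missing_fraction must be in [0, 1]")
        if self.niche_breadth <= 0:
            raise ValueError("niche_breadth must be positive")


# ---------------------------------------------------------------------------
# Trees and traits
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> Phylogeny:
    """Ultrametric Yule (pure-birth) tree with tips sp0001, sp0002, ...

    Waiting times between speciation events are exponential with rate
    (number of lineages) x birth_rate; the lineage that splits is uniform.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    rng = np.random.default_rng(seed)
    root = Node()
    t = 0.0
    active: List[tuple] = []  # (node, birth_time)
    for _ in range(2):
        active.append((root.add_child(Node()), 0.0))
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        node, birth = active.pop(idx)
        node.length = t - birth
        active.append((node.add_child(Node()), t))
        active.append((node.add_child(Node()), t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    labels = iter(f"sp{i+1:04d}" for i in range(n_tips))
    # label in deterministic (preorder) position order, not split order
    tree = Phylogeny(root, validate=False)
    for node, birth in active:
        node.length = t - birth
    for node in tree.preorder():
        if node.is_tip:
            node.label = next(labels)
    tree.validate()
    return tree


def simulate_bm_traits(tree: Phylogeny, rate: float, root_value: float = 0.0,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None
                       ) -> Dict[str, float]:
    """Brownian motion along the tree: Gaussian increments with variance
    rate x branch length, accumulated root to tip."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    values: Dict[int, float] = {id(tree.root): float(root_value)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        bl = node.length or 0.0
        values[id(node)] = values[id(node.parent)] + \
            rng.normal(0.0, np.sqrt(rate * bl))
    return {t.label: values[id(t)] for t in tree.tips()}


def assign_habitat_affinity(tree: Phylogeny, signal: bool, seed: int
                            ) -> Dict[str, float]:
    """Species habitat affinities on [-1, 1].

    A BM trait is simulated on the tree and rank-rescaled to an even grid on
    [-1, 1].  With ``signal=False`` the values are then shuffled across tips,
    which keeps the marginal distribution but severs the link to the tree.
    """
    rng = np.random.default_rng(seed)
    bm = simulate_bm_traits(tree, rate=1.0, rng=rng)
    labels = list(bm)
    vals = np.array([bm[s] for s in labels])
    n = len(vals)
    grid = -1.0 + 2.0 * (np.argsort(np.argsort(vals)) + 0.5) / n
    if not signal:
        grid = rng.permutation(grid)
    return dict(zip(labels, grid))


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

def _plot_layout(cfg: ScenarioConfig) -> pd.DataFrame:
    """Plots in contiguous habitat blocks, split into sites within habitat."""
    plots = [f"plot{i+1:02d}" for i in range(cfg.n_plots)]
    habitats = [f"habitat{(i * cfg.n_habitats) // cfg.n_plots + 1}"
                for i in range(cfg.n_plots)]
    # ~9 plots per site, numbered within habitat
    sites = []
    counters: Dict[str, int] = {}
    for h in habitats:
        k = counters.get(h, 0)
        sites.append(f"site_{h}_{k // 9 + 1}")
        counters[h] = k + 1
    return pd.DataFrame({"plot": plots, "site": sites, "habitat": habitats})


def _habitat_centres(cfg: ScenarioConfig) -> Dict[str, float]:
    span = cfg.habitat_separation
    if cfg.n_habitats == 1:
        return {"habitat1": 0.0}
    centres = np.linspace(-span / 2, span / 2, cfg.n_habitats)
    return {f"habitat{i+1}": float(c) for i, c in enumerate(centres)}


def assemble_communities(affinity: Dict[str, float], cfg: ScenarioConfig,
                         seed: int) -> OccurrenceTable:
    """Assemble plot-by-species occupancies from habitat filtering.

    Each plot gets an environment e_p (its habitat centre plus jitter); a
    species occupies each quadrat independently with probability
    d_s x exp(-(affinity - e_p)^2 / (2 breadth^2)), where the per-species
    commonness d_s is lognormal around ``detectability`` (capped at 1) —
    a few dominant species recur in most plots, many are rare, as in real
    species-abundance distributions.  Abundance is the fraction of occupied
    quadrats.  Plots that end up empty are redrawn.
    """
    rng = np.random.default_rng(seed)
    layout = _plot_layout(cfg)
    centres = _habitat_centres(cfg)
    species = sorted(affinity)
    aff = np.array([affinity[s] for s in species])
    commonness = np.minimum(
        1.0, cfg.detectability
        * rng.lognormal(0.0, cfg.dominance_sd, size=len(species)))

    rows = []
    env = {}
    for _, prow in layout.iterrows():
        plot = prow["plot"]
        for _attempt in range(1000):
            e = centres[prow["habitat"]] + rng.normal(0.0, cfg.env_jitter_sd)
            p_quadrat = commonness * np.exp(
                -(aff - e) ** 2 / (2.0 * cfg.niche_breadth ** 2))
            occupied = rng.binomial(cfg.n_quadrats, p_quadrat)
            if occupied.sum() > 0:
                break
        else:  # pragma: no cover - pathological configs only
            raise RuntimeError(f"could not populate plot {plot}")
        env[plot] = e
        for s, q in zip(species, occupied):
            if q > 0:
                rows.append({"species": s, "plot": plot,
                             "abundance": q / cfg.n_quadrats})
    occurrences = pd.DataFrame(rows)
    layout = layout.assign(environment=layout["plot"].map(env))
    plants = pd.DataFrame(
        columns=["plant_id", "species", "plot", "site", "imputed"]
        + list(cfg.trait_names))
    return OccurrenceTable(occurrences, plants, layout,
                           trait_names=list(cfg.trait_names))


def attach_traits(occ: OccurrenceTable, tree: Phylogeny, cfg: ScenarioConfig,
                  seed: int, affinity: Optional[Dict[str, float]] = None
                  ) -> OccurrenceTable:
    """Attach per-plant log-scale trait values to an occurrence table.

    Species base value = alpha component (BM on the tree, or tip-shuffled
    when ``cfg.alpha_signal`` is off) + beta_coef x habitat affinity.  On
    top of the base, every plant responds plastically to its plot's
    environment (standardised to u_p), and ``b_s_true`` sets the ratio of
    that shared plastic shift to the total community-mean shift along the
    gradient — the quantity the intraspecific slope b_s estimates.  The
    community-mean shift is plasticity plus species-turnover; writing
    kappa for the turnover trend of plot-mean base values on u (measured
    inside the generator from the realised composition), a plant of
    species s in plot p gets

        t = base_s + c * u_p + noise,   c = kappa * b / (1 - b),

    so the total gradient is (kappa + c) u = kappa/(1-b) u and the plastic
    share is exactly b.  The case b = 1 means the gradient is carried by
    plasticity alone (turnover contributes nothing new along it); there c
    is set directly to ``gradient_sd`` and the tracking ratio is 1 by
    construction, for any c.  Traits listed in
    ``cfg.species_level_traits`` are species constants (one value
    everywhere, no plasticity or noise).  A ``missing_fraction`` of
    occurrences is left unmeasured.
    """
    rng = np.random.default_rng(seed)
    species_in_occ = occ.occurrences["species"].unique()
    tipset = set(tree.tip_labels)
    if not set(species_in_occ) <= tipset:
        raise ValueError("occurrence table contains species not in the tree")
    if affinity is None:
        affinity = {s: 0.0 for s in tipset}

    out = occ.copy()
    o = out.occurrences
    plot_site = out.plot_info.set_index("plot")["site"]

    # choose unmeasured occurrences once, shared across traits
    n_occ = len(o)
    n_missing = int(round(cfg.missing_fraction * n_occ))
    missing_idx = set(rng.choice(n_occ, size=n_missing, replace=False)
                      ) if n_missing else set()

    plant_rows: List[Dict] = []
    for i, (_, row) in enumerate(o.iterrows()):
        if i in missing_idx:
            continue
        for j in range(cfg.plants_per_occurrence):
            plant_rows.append({
                "plant_id": f"pl_{i+1:05d}_{j+1}", "species": row["species"],
                "plot": row["plot"], "site": plot_site[row["plot"]],
                "imputed": False,
            })
    plants = pd.DataFrame(plant_rows)

    # standardised plot environment u_p, the axis plants respond to
    if "environment" in out.plot_info.columns:
        env = out.plot_info.set_index("plot")["environment"]
    else:
        env = pd.Series(0.0, index=out.plot_info["plot"])
    ec = env - env.mean()
    u_plot = (ec / ec.std() if ec.std() > 0
              else pd.Series(0.0, index=env.index))

    def turnover_trend(base: Dict[str, float]) -> float:
        """OLS slope of abundance-weighted plot-mean base values on u."""
        ob = o.assign(value=o["species"].map(base))
        pb = (ob["abundance"] * ob["value"]).groupby(ob["plot"]).sum() / \
            ob.groupby("plot")["abundance"].sum()
        u = u_plot.loc[pb.index].to_numpy(float)
        if np.ptp(u) == 0:
            return 0.0
        uc = u - u.mean()
        return float(uc @ (pb.to_numpy(float) - pb.mean()) / (uc @ uc))

    for trait in cfg.trait_names:
        alpha = simulate_bm_traits(tree, rate=cfg.bm_rate, rng=rng)
        if not cfg.alpha_signal:
            labels = list(alpha)
            vals = rng.permutation([alpha[s] for s in labels])
            alpha = dict(zip(labels, vals))
        # standardise the BM component, then scale to alpha_sd so every
        # trait sits on a common, configurable scale
        av = np.array(list(alpha.values()))
        mu, sd = av.mean(), av.std()
        alpha = {s: cfg.alpha_sd * (v - mu) / sd if sd > 0 else 0.0
                 for s, v in alpha.items()}
        base = {s: alpha[s] + cfg.beta_coef * affinity[s]
                for s in tree.tip_labels}

        if trait in cfg.species_level_traits:
            plants[trait] = plants["species"].map(base)
            continue

        b = cfg.b_s_true
        if b == 1.0:
            # slope 1 means the gradient is pure shared plasticity: remove
            # the turnover trend from the base values (residualise species
            # against their mean gradient position), then respond at
            # gradient_sd
            og = o.assign(u=o["plot"].map(u_plot))
            u_species = (og["abundance"] * og["u"]).groupby(
                og["species"]).sum() / og.groupby("species")["abundance"].sum()
            for _ in range(20):
                kappa = turnover_trend(base)
                if abs(kappa) < 1e-12:
                    break
                rho = turnover_trend(u_species.to_dict())
                step = kappa / rho if abs(rho) > 1e-9 else kappa
                base = {s: v - step * u_species.get(s, 0.0)
                        for s, v in base.items()}
            c = cfg.gradient_sd
        else:
            c = turnover_trend(base) * b / (1.0 - b)
        plants[trait] = (plants["species"].map(base)
                         + c * plants["plot"].map(u_plot)
                         + rng.normal(0.0, cfg.noise_sd, size=len(plants)))

    out.plants = plants
    return out


def generate_scenario(cfg: Optional[ScenarioConfig] = None,
                      **overrides) -> Dict[str, object]:
    """Run the whole generator: tree, affinities, communities, traits.

    Returns a dict with keys tree, affinity, table, config; all randomness
    derives from ``cfg.seed``.
    """
    if cfg is None:
        cfg = ScenarioConfig(**overrides)
    elif overrides:
        cfg = ScenarioConfig(**{**asdict(cfg), **overrides})
    rng = np.random.default_rng(cfg.seed)
    seeds = [int(s) for s in rng.integers(2 ** 31, size=4)]
    tree = simulate_tree(cfg.n_species, seed=seeds[0],
                         birth_rate=cfg.birth_rate)
    affinity = assign_habitat_affinity(tree, signal=cfg.habitat_signal,
                                       seed=seeds[1])
    table = assemble_communities(affinity, cfg, seed=seeds[2])
    table = attach_traits(table, tree, cfg, seed=seeds[3], affinity=affinity)
    return {"tree": tree, "affinity": affinity, "table": table, "config": cfg}


def slope_calibration_config(b_s_true: float, seed: int) -> ScenarioConfig:
    """Scenario in which the intraspecific slope is cleanly identified.

    Estimating b_s regresses plant values on realised community means, so
    recovery requires the community trait gradient to dominate the plot
    means.  This configuration narrows the among-species baseline spread
    (``alpha_sd`` 0.1), strengthens the turnover signal (``beta_coef``
    0.6), samples three plants per occurrence (averaging the plot means'
    sampling noise without muting the per-plant residuals that give the
    slope estimates their spread), and keeps communities rich
    (``detectability`` 0.25, mild dominance).  Under b_s_true = 1 the
    one-sample t-test of the slopes against 1 then rejects at close to its
    nominal level, and for b_s_true < 1 the mean slope recovers the
    parameter.
    """
    return ScenarioConfig(
        b_s_true=b_s_true, alpha_sd=0.1, beta_coef=0.6,
        plants_per_occurrence=3, detectability=0.25, dominance_sd=0.5,
        noise_sd=0.3, env_jitter_sd=0.3, seed=seed)


def write_scenario(scenario: Dict[str, object], out_dir) -> Dict[str, str]:
    """Write a generated scenario in the formats the pipeline ingests.

    Emits tree.nwk, community.csv (plot, species, abundance fraction),
    traits.csv (plant_id, species, plot, site, raw-scale trait columns;
    ingest re-applies log10) and plots.csv (plot, site, habitat).
    """
    from pathlib import Path

    from .phylo import write_newick_file

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table: OccurrenceTable = scenario["table"]
    cfg: ScenarioConfig = scenario["config"]
    write_newick_file(scenario["tree"], out / "tree.nwk")
    table.occurrences[["plot", "species", "abundance"]].to_csv(
        out / "community.csv", index=False)
    plants = table.plants.drop(columns=["imputed"]).copy()
    for t in cfg.trait_names:
        plants[t] = np.power(10.0, plants[t])
    plants.to_csv(out / "traits.csv", index=False)
    table.plot_info[["plot", "site", "habitat"]].to_csv(
        out / "plots.csv", index=False)
    return {"tree": str(out / "tree.nwk"),
            "community": str(out / "community.csv"),
            "traits": str(out / "traits.csv"),
            "plots": str(out / "plots.csv")}
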