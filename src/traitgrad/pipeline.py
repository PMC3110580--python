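"""End-to-end analysis pipeline: ingest, impute, trait-gradient partition,
ordination, and comparative tests, emitting summary tables and a run log.

Outputs (written under ``RunConfig.out_dir``):

* ``trait_summary.csv``    — per trait: plot-mean vs NMDS axis-1 r and P,
  b_s mean/sd/t-test P, % trait variance within species.
* ``correlations_<component>.csv`` — square trait-by-trait matrix per
  component (alpha, beta, total): ahistorical r below the diagonal, PIC r
  above; ``correlations_long.csv`` carries the P-values.
* ``signal.csv``           — per component x trait: Blomberg's K,
  permutation P, and the variance in species means explained by the
  component.
* ``habitat_signal.csv``   — signal test of species habitat affinities
  (NMDS axis-1 species scores).
* ``species_components_<trait>.csv`` / ``plot_means.csv`` — the underlying
  per-species and per-plot trait-gradient quantities.
* ``run_log.json``         — seeds, imputation/drop records, contrast count
  and diagnostics, stress.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import comparative, ordination, phylo, trait_gradient

__all__ = ["RunConfig", "validate_inputs", "run_full_analysis"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    tree: str
    community: str
    traits: str
    out_dir: str
    plots: Optional[str] = None
    trait_list: Optional[List[str]] = None
    species_level_traits: List[str] = field(default_factory=lambda: ["height"])
    n_perm: int = 999
    n_starts: int = 20
    n_mc_runs: int = 0            # Monte-Carlo stress test runs (0 = skip)
    min_plots: int = 3
    seed: int = 0
    branch_lengths: str = "equal"  # "equal" or "dated"
    root_age: float = phylo.DEFAULT_ROOT_AGE
    holm: bool = False
    weighted_variance: bool = False

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.branch_lengths not in ("equal", "dated"):
            raise ValueError("branch_lengths must be 'equal' or 'dated'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


def validate_inputs(cfg: RunConfig) -> Dict[str, object]:
    """Cross-check species names among tree, community and trait tables.

    Report-only: returns a dict with per-source species sets, fatal
    mismatches (community species missing from the tree), and the count of
    unmeasured occurrences.
    """
    tree = phylo.read_newick_file(cfg.tree)
    occ = trait_gradient.load_tables(cfg.community, cfg.traits, cfg.plots,
                                     trait_names=cfg.trait_list)
    tree_sp = set(tree.tip_labels)
    comm_sp = set(occ.occurrences["species"])
    trait_sp = set(occ.plants["species"])
    measured_pairs = set(zip(occ.plants["species"], occ.plants["plot"]))
    unmeasured = [
        (s, p) for s, p in zip(occ.occurrences["species"],
                               occ.occurrences["plot"])
        if (s, p) not in measured_pairs
    ]
    fatal = sorted(comm_sp - tree_sp)
    return {
        "n_tree_species": len(tree_sp),
        "n_community_species": len(comm_sp),
        "n_trait_species": len(trait_sp),
        "community_not_in_tree": fatal,
        "trait_not_in_community": sorted(trait_sp - comm_sp),
        "tree_not_in_community": sorted(tree_sp - comm_sp),
        "n_unmeasured_occurrences": len(unmeasured),
        "unmeasured_fraction": (len(unmeasured) / len(occ.occurrences)
                                if len(occ.occurrences) else 0.0),
        "fatal": bool(fatal),
    }


def _holm(pvals: pd.Series) -> pd.Series:
    order = pvals.sort_values().index
    m = len(order)
    adj, running = {}, 0.0
    for i, key in enumerate(order):
        running = max(running, (m - i) * pvals[key])
        adj[key] = min(1.0, running)
    return pd.Series(adj)[pvals.index]


def run_full_analysis(cfg: RunConfig) -> Dict[str, object]:
    """Run the full pipeline and write the output bundle.

    Returns a dict of the in-memory results (DataFrames and the run log).
    """
    report = validate_inputs(cfg)
    if report["fatal"]:
        raise ValueError("community species missing from tree: "
                         f"{report['community_not_in_tree']}")

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    seeds = {
        "polytomy": int(rng.integers(2 ** 31)),
        "nmds": int(rng.integers(2 ** 31)),
        "montecarlo": int(rng.integers(2 ** 31)),
        "signal_base": int(rng.integers(2 ** 31)),
    }
    log: Dict[str, object] = {"seeds": seeds, "config": asdict(cfg)}

    # -- ingest and impute -------------------------------------------------
    tree_full = phylo.read_newick_file(cfg.tree)
    occ = trait_gradient.load_tables(cfg.community, cfg.traits, cfg.plots,
                                     trait_names=cfg.trait_list)
    traits = list(occ.trait_names)
    occ, imp_log = trait_gradient.impute_missing_traits(occ)
    log["imputation"] = imp_log.to_dict(orient="records")

    # -- comparative tree --------------------------------------------------
    species = occ.species
    tree = phylo.prune_to_tips(tree_full, species)
    tree = phylo.resolve_polytomies(tree, seed=seeds["polytomy"])
    if cfg.branch_lengths == "equal":
        ctree = phylo.set_equal_branch_lengths(tree, 1.0)
    else:
        ctree = tree
    log["n_species_analysed"] = len(species)
    log["n_contrasts"] = len(species) - 1

    # -- ordination --------------------------------------------------------
    comm_wide = (occ.occurrences
                 .pivot(index="plot", columns="species", values="abundance")
                 .fillna(0.0).sort_index())
    dis = ordination.bray_curtis(comm_wide)
    ord_res = ordination.nmds(dis, k=2, n_starts=cfg.n_starts,
                              seed=seeds["nmds"])
    ordination.species_scores(ord_res, comm_wide)
    habitats = occ.plot_info.set_index("plot")["habitat"]
    hab_levels = list(dict.fromkeys(occ.plot_info["habitat"]))
    indicator = habitats.map({h: i for i, h in enumerate(hab_levels)})
    ordination.orient_axes(
        ord_res, indicator.astype(float) if indicator.nunique() > 1 else None)
    log["nmds_stress"] = ord_res.stress
    if cfg.n_mc_runs > 0:
        mc = ordination.stress_montecarlo(
            comm_wide, k=2, n_runs=cfg.n_mc_runs, seed=seeds["montecarlo"],
            n_starts=min(cfg.n_starts, 5))
        ord_res.montecarlo_p = mc["P"]
        log["stress_montecarlo"] = mc

    # -- trait gradient per trait -----------------------------------------
    tg: Dict[str, trait_gradient.TraitGradientResult] = {}
    slopes: Dict[str, pd.Series] = {}
    varparts: Dict[str, Dict[str, float]] = {}
    plot_means = pd.DataFrame(index=comm_wide.index)
    for trait in traits:
        res = trait_gradient.trait_gradient_analysis(occ, trait)
        tg[trait] = res
        plot_means[trait] = res.plots["p_bar"]
        res.species.to_csv(out_dir / f"species_components_{trait}.csv")
        if trait in cfg.species_level_traits:
            continue
        slopes[trait], _ = trait_gradient.intraspecific_slope(
            occ, trait, min_plots=cfg.min_plots, result=res)
        varparts[trait] = trait_gradient.variance_partition(
            occ, trait, weighted=cfg.weighted_variance)
    plot_means.to_csv(out_dir / "plot_means.csv")

    # -- trait summary table (Table-1 layout) ------------------------------
    env = ordination.trait_env_correlation(
        ord_res.plot_scores["axis1"], plot_means)
    rows = []
    for trait in traits:
        row = {"trait": trait,
               "env_r": env.loc[trait, "r"], "env_P": env.loc[trait, "P"]}
        if trait in slopes and len(slopes[trait]) >= 2:
            bs = trait_gradient.test_bs(slopes[trait])
            row.update({"bs_mean": bs["mean"], "bs_sd": bs["sd"],
                        "bs_P": bs["P"], "bs_n": bs["n"]})
        if trait in varparts:
            row["within_species_pct"] = \
                100.0 * varparts[trait]["fraction_within_species"]
            row["within_plot_pct"] = \
                100.0 * varparts[trait]["fraction_within_plots"]
        rows.append(row)
    trait_summary = pd.DataFrame(rows).set_index("trait")
    trait_summary.to_csv(out_dir / "trait_summary.csv")

    # -- comparative: correlations and signal ------------------------------
    components = {
        "alpha": {t: tg[t].species["alpha"].to_dict() for t in traits},
        "beta": {t: tg[t].species["beta"].to_dict() for t in traits},
        "total": {t: tg[t].species["t_bar"].to_dict() for t in traits},
    }
    contrast_cache: Dict[tuple, comparative.ContrastSet] = {}

    def contrasts(component: str, trait: str) -> comparative.ContrastSet:
        key = (component, trait)
        if key not in contrast_cache:
            contrast_cache[key] = comparative.independent_contrasts(
                ctree, components[component][trait])
        return contrast_cache[key]

    long_rows = []
    for comp, cmaps in components.items():
        mat = pd.DataFrame(np.nan, index=traits, columns=traits)
        for i, ti in enumerate(traits):
            for j, tj in enumerate(traits):
                if i == j:
                    continue
                if i > j:  # below diagonal: ahistorical
                    res = comparative.correlation_ahistorical(
                        cmaps[ti], cmaps[tj])
                    method = "ahistorical"
                else:      # above diagonal: PIC
                    res = comparative.correlation_pic(
                        contrasts(comp, ti), contrasts(comp, tj))
                    method = "pic"
                mat.loc[ti, tj] = res["r"]
                long_rows.append({"component": comp, "trait_x": ti,
                                  "trait_y": tj, "method": method,
                                  "r": res["r"], "P": res["P"]})
        mat.to_csv(out_dir / f"correlations_{comp}.csv")
    correlations_long = pd.DataFrame(long_rows)
    if cfg.holm:
        for (comp, method), grp in correlations_long.groupby(
                ["component", "method"]):
            # each unordered pair tested once per method
            correlations_long.loc[grp.index, "P_holm"] = \
                _holm(grp["P"]).to_numpy()
    correlations_long.to_csv(out_dir / "correlations_long.csv", index=False)

    sig_rows = []
    for ci, (comp, cmaps) in enumerate(components.items()):
        for tj, trait in enumerate(traits):
            sig = comparative.signal_test(
                ctree, cmaps[trait], n_perm=cfg.n_perm,
                seed=seeds["signal_base"] + 1000 * ci + tj)
            row = {"component": comp, "trait": trait, "K": sig.K, "P": sig.P}
            if comp in ("alpha", "beta"):
                r2 = trait_gradient.component_r2(tg[trait])
                row["r2"] = r2[f"r2_{comp}"]
            sig_rows.append(row)
    signal = pd.DataFrame(sig_rows)
    signal.to_csv(out_dir / "signal.csv", index=False)

    # -- habitat affinity signal ------------------------------------------
    affinity = ord_res.species_scores["axis1"].to_dict()
    hab_sig = comparative.signal_test(
        ctree, affinity, n_perm=cfg.n_perm,
        seed=seeds["signal_base"] + 99_000)
    pd.DataFrame([{"K": hab_sig.K, "P": hab_sig.P,
                   "n_permutations": hab_sig.n_permutations}]
                 ).to_csv(out_dir / "habitat_signal.csv", index=False)

    # -- diagnostics and log ----------------------------------------------
    diag = comparative.contrast_diagnostics(contrasts("total", traits[0]))
    log["contrast_diagnostics"] = diag
    with open(out_dir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, default=str)

    return {
        "trait_summary": trait_summary,
        "correlations_long": correlations_long,
        "signal": signal,
        "habitat_signal": hab_sig,
        "ordination": ord_res,
        "trait_gradient": tg,
        "log": log,
    }
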