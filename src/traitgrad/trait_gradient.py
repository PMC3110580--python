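"""Trait-gradient analysis: partitioning species trait values into
within-community (alpha) and among-community (beta) components.

The central data object is the :class:`OccurrenceTable`: a long-format table
of species-by-plot occurrences with quadrat-frequency abundances, plus
individual-plant trait measurements on the log10 scale.  Writing t_sp for
the trait value of species s in plot p and a_sp for its abundance,

    t_bar_s = sum_p a_sp t_sp / sum_p a_sp        (species mean trait)
    p_bar_p = sum_s a_sp t_sp / sum_s a_sp        (community mean trait)
    beta_s  = sum_p a_sp p_bar_p / sum_p a_sp     (among-community component)
    alpha_s = t_bar_s - beta_s                    (within-community component)

so that alpha_s + beta_s = t_bar_s by construction.  The intraspecific
slope b_s is the OLS slope of a species' plant-level trait values against
p_bar_p over the plots it occupies; if within-species variation tracks the
community gradient one-for-one, b_s = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OccurrenceTable",
    "TraitGradientResult",
    "derive_traits",
    "impute_missing_traits",
    "trait_gradient_analysis",
    "intraspecific_slope",
    "test_bs",
    "variance_partition",
    "component_r2",
    "load_tables",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceTable:
    """Species-by-plot occurrences with per-plant trait measurements.

    ``occurrences``: columns (species, plot, abundance), abundance the
    fraction of quadrats occupied, in (0, 1]; absence = no row.
    ``plants``: columns (plant_id, species, plot, site, imputed, <traits>),
    trait values on the log10 scale.  ``plot_info``: columns
    (plot, site, habitat).
    """

    occurrences: pd.DataFrame
    plants: pd.DataFrame
    plot_info: pd.DataFrame
    trait_names: List[str] = field(default_factory=list)

    def __post_init__(self):
        occ = self.occurrences
        if occ.duplicated(["species", "plot"]).any():
            raise ValueError("duplicate (species, plot) occurrence rows")
        ab = occ["abundance"].to_numpy(float)
        if (ab <= 0).any():
            raise ValueError("abundances must be positive (absence = no row)")
        if (ab > 1 + 1e-12).any():
            raise ValueError("abundances must be fractions in (0, 1]")
        if "imputed" not in self.plants.columns:
            self.plants = self.plants.assign(imputed=False)
        for t in self.trait_names:
            vals = self.plants[t].to_numpy(float)
            if np.isinf(vals).any():
                raise ValueError(f"non-finite values in trait {t!r}")

    @property
    def species(self) -> List[str]:
        return sorted(self.occurrences["species"].unique())

    @property
    def plots(self) -> List[str]:
        return sorted(self.occurrences["plot"].astype(str).unique())

    def tsp(self, trait: str, include_imputed: bool = True) -> pd.DataFrame:
        """Per-(species, plot) trait values: mean over individual plants.

        Returns columns (species, plot, value, n_plants, measured) for every
        occurrence that has at least one plant record for the trait.
        """
        pl = self.plants
        if not include_imputed:
            pl = pl[~pl["imputed"]]
        pl = pl.dropna(subset=[trait])
        if pl.empty:
            return pd.DataFrame(
                columns=["species", "plot", "value", "n_plants", "measured"])
        grp = pl.groupby(["species", "plot"], sort=True)
        agg = grp.agg(value=(trait, "mean"),
                      n_plants=(trait, "size"),
                      measured=("imputed", lambda s: bool((~s).any())))
        return agg.reset_index()

    def copy(self) -> "OccurrenceTable":
        return OccurrenceTable(self.occurrences.copy(), self.plants.copy(),
                               self.plot_info.copy(), list(self.trait_names))


@dataclass
class TraitGradientResult:
    """Per-species and per-plot output of trait-gradient analysis."""

    trait: str
    species: pd.DataFrame  # index species: t_bar, beta, alpha, n_occupied_plots
    plots: pd.DataFrame    # index plot: p_bar, total_abundance
    variance_fractions: Optional[Dict[str, float]] = None

    def check_identity(self, tol: float = 1e-10) -> float:
        err = (self.species["alpha"] + self.species["beta"]
               - self.species["t_bar"]).abs().max()
        if err > tol:
            raise AssertionError(f"alpha + beta != t_bar (max |err| = {err})")
        return float(err)


# ---------------------------------------------------------------------------
# Trait derivation from raw field measures
# ---------------------------------------------------------------------------

def derive_traits(raw: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Derive functional traits from raw per-plant measures.

    Expects columns (where available): leaf_area_cm2, leaf_mass_g,
    leaf_thickness_mm, root_length_m, root_volume_mm3, root_mass_g,
    root_diameter_mm.  Returns (derived, invalid_log) where derived holds
    SLA (cm^2/g), leaf tissue density (mg/mm^3, leaf volume = area x
    thickness), leaf size (cm^2), leaf thickness (mm), SRL (m/g), root
    tissue density (mg/mm^3) and root diameter (mm), all on the raw (not
    log) scale.  Rows with non-positive masses or volumes are dropped and
    listed in the log.
    """
    raw = raw.copy()
    bad_mask = pd.Series(False, index=raw.index)
    reasons = pd.Series("", index=raw.index)
    for col in ("leaf_mass_g", "root_mass_g", "root_volume_mm3"):
        if col in raw.columns:
            bad = raw[col].notna() & (raw[col] <= 0)
            reasons[bad & ~bad_mask] = f"non-positive {col}"
            bad_mask |= bad
    invalid = raw.loc[bad_mask].copy()
    invalid["reason"] = reasons[bad_mask]
    ok = raw.loc[~bad_mask]

    out = pd.DataFrame(index=ok.index)
    for col in ("plant_id", "species", "plot", "site"):
        if col in ok.columns:
            out[col] = ok[col]
    if {"leaf_area_cm2", "leaf_mass_g"} <= set(ok.columns):
        out["sla"] = ok["leaf_area_cm2"] / ok["leaf_mass_g"]
    if "leaf_area_cm2" in ok.columns:
        out["leaf_size"] = ok["leaf_area_cm2"]
    if "leaf_thickness_mm" in ok.columns:
        out["leaf_thickness"] = ok["leaf_thickness_mm"]
    if {"leaf_area_cm2", "leaf_thickness_mm", "leaf_mass_g"} <= set(ok.columns):
        # leaf volume = area x thickness; cm^2 x mm = 100 mm^3; mass g -> mg
        volume_mm3 = ok["leaf_area_cm2"] * 100.0 * ok["leaf_thickness_mm"]
        out["leaf_tissue_density"] = ok["leaf_mass_g"] * 1000.0 / volume_mm3
    if {"root_length_m", "root_mass_g"} <= set(ok.columns):
        out["srl"] = ok["root_length_m"] / ok["root_mass_g"]
    if {"root_mass_g", "root_volume_mm3"} <= set(ok.columns):
        out["root_tissue_density"] = ok["root_mass_g"] * 1000.0 / ok["root_volume_mm3"]
    if "root_diameter_mm" in ok.columns:
        out["root_diameter"] = ok["root_diameter_mm"]
    return out, invalid


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_missing_traits(occ: OccurrenceTable
                          ) -> Tuple[OccurrenceTable, pd.DataFrame]:
    """Fill unmeasured (species, plot, trait) cells with the species' mean
    from other plots at the same site.

    Occurrences of a species at a site where it was never measured are
    dropped; species never measured anywhere are removed entirely.  Returns
    the completed table and a log DataFrame with one row per action
    (action in {"imputed", "dropped_occurrence", "dropped_species"}).
    """
    out = occ.copy()
    log_rows: List[Dict] = []

    plot_site = out.plot_info.set_index("plot")["site"]
    occs = out.occurrences.copy()
    occs["site"] = occs["plot"].map(plot_site)

    measured = out.plants[~out.plants["imputed"]]
    measured_species = set(measured["species"].unique())

    # species with no measurements at all
    for sp in sorted(set(occs["species"]) - measured_species):
        log_rows.append({"action": "dropped_species", "species": sp,
                         "plot": "", "trait": "", "value": np.nan})
    occs = occs[occs["species"].isin(measured_species)]

    # species x site coverage
    msite = measured.merge(plot_site.rename("site_m"), left_on="plot",
                           right_index=True, how="left")
    covered = set(zip(msite["species"], msite["site_m"]))
    drop_mask = [
        (sp, st) not in covered
        for sp, st in zip(occs["species"], occs["site"])
    ]
    for _, row in occs.loc[drop_mask].iterrows():
        log_rows.append({"action": "dropped_occurrence",
                         "species": row["species"], "plot": row["plot"],
                         "trait": "", "value": np.nan})
    occs = occs.loc[[not m for m in drop_mask]]

    # impute per trait: occurrence cells with no plant value for that trait
    site_means = {}
    for trait in out.trait_names:
        mm = msite.dropna(subset=[trait])
        site_means[trait] = mm.groupby(["species", "site_m"])[trait].mean()

    new_rows: List[Dict] = []
    have = {
        trait: set(zip(g["species"], g["plot"]))
        for trait, g in ((t, out.plants.dropna(subset=[t]))
                         for t in out.trait_names)
    }
    counter = 0
    for _, row in occs.iterrows():
        sp, plot, site = row["species"], row["plot"], row["site"]
        fill = {}
        for trait in out.trait_names:
            if (sp, plot) in have[trait]:
                continue
            key = (sp, site)
            if key in site_means[trait].index:
                fill[trait] = float(site_means[trait].loc[key])
                log_rows.append({"action": "imputed", "species": sp,
                                 "plot": plot, "trait": trait,
                                 "value": fill[trait]})
        if fill:
            counter += 1
            rec = {"plant_id": f"imputed_{counter:04d}", "species": sp,
                   "plot": plot, "site": site, "imputed": True}
            rec.update({t: fill.get(t, np.nan) for t in out.trait_names})
            new_rows.append(rec)

    if new_rows:
        out.plants = pd.concat(
            [out.plants, pd.DataFrame(new_rows)], ignore_index=True)
    out.occurrences = occs.drop(columns=["site"]).reset_index(drop=True)
    # drop plant records for removed occurrences/species
    keep = set(zip(out.occurrences["species"], out.occurrences["plot"]))
    out.plants = out.plants[
        [pair in keep for pair in zip(out.plants["species"], out.plants["plot"])]
    ].reset_index(drop=True)
    log = pd.DataFrame(
        log_rows, columns=["action", "species", "plot", "trait", "value"])
    return out, log


# ---------------------------------------------------------------------------
# The alpha/beta partition
# ---------------------------------------------------------------------------

def trait_gradient_analysis(occ: OccurrenceTable, trait: str
                            ) -> TraitGradientResult:
    """Partition species trait values into alpha and beta components."""
    tsp = occ.tsp(trait)
    d = occ.occurrences.merge(tsp, on=["species", "plot"], how="inner")
    if d.empty:
        raise ValueError(f"no trait values for {trait!r}")
    missing = len(occ.occurrences) - len(d)
    if missing:
        raise ValueError(
            f"{missing} occurrences lack a value for {trait!r}; "
            "run impute_missing_traits first")

    d["aw"] = d["abundance"]
    tot = d.groupby("plot")["aw"].transform("sum")
    if (tot <= 0).any():
        raise ValueError("plot with zero total abundance")
    pbar = (d["aw"] * d["value"]).groupby(d["plot"]).sum() / \
        d.groupby("plot")["aw"].sum()
    plots = pd.DataFrame({
        "p_bar": pbar,
        "total_abundance": d.groupby("plot")["aw"].sum(),
    })
    plots.index.name = "plot"

    d["p_bar"] = d["plot"].map(pbar)
    g = d.groupby("species")
    asum = g["aw"].sum()
    t_bar = (d["aw"] * d["value"]).groupby(d["species"]).sum() / asum
    beta = (d["aw"] * d["p_bar"]).groupby(d["species"]).sum() / asum
    species = pd.DataFrame({
        "t_bar": t_bar,
        "beta": beta,
        "alpha": t_bar - beta,
        "n_occupied_plots": g["plot"].nunique(),
    })
    species.index.name = "species"
    res = TraitGradientResult(trait=trait, species=species, plots=plots)
    res.check_identity()
    return res


def intraspecific_slope(occ: OccurrenceTable, trait: str,
                        min_plots: int = 3,
                        result: Optional[TraitGradientResult] = None,
                        ) -> Tuple[pd.Series, pd.DataFrame]:
    """Per-species OLS slope b_s of plant trait values against p_bar_p.

    Only species measured (not imputed) in at least ``min_plots`` plots are
    eligible.  Uses individual plant values, so multiple plants per plot all
    contribute.  Returns (slopes, log) where the log lists excluded species
    and the reason.
    """
    if result is None:
        result = trait_gradient_analysis(occ, trait)
    pbar = result.plots["p_bar"]
    plants = occ.plants[~occ.plants["imputed"]].dropna(subset=[trait])
    slopes: Dict[str, float] = {}
    log_rows: List[Dict] = []
    for sp, grp in plants.groupby("species", sort=True):
        n_plots = grp["plot"].nunique()
        if n_plots < min_plots:
            log_rows.append({"species": sp, "reason": "too_few_plots",
                             "n_plots": n_plots})
            continue
        x = grp["plot"].map(pbar).to_numpy(float)
        y = grp[trait].to_numpy(float)
        if np.ptp(x) == 0:
            log_rows.append({"species": sp, "reason": "no_gradient_variance",
                             "n_plots": n_plots})
            continue
        xc = x - x.mean()
        slopes[sp] = float(xc @ (y - y.mean()) / (xc @ xc))
    return (pd.Series(slopes, name="b_s", dtype=float),
            pd.DataFrame(log_rows, columns=["species", "reason", "n_plots"]))


def test_bs(slopes: Iterable[float]) -> Dict[str, float]:
    """One-sample two-sided t-test of the b_s values against 1."""
    arr = np.asarray([s for s in slopes if math.isfinite(s)], dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two finite slopes")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance among slopes")
    t, p = stats.ttest_1samp(arr, popmean=1.0)
    return {"mean": float(arr.mean()), "sd": float(sd), "t": float(t),
            "df": int(arr.size - 1), "P": float(p), "n": int(arr.size)}


# ---------------------------------------------------------------------------
# Variance decompositions
# ---------------------------------------------------------------------------

def _ss_fractions(values: np.ndarray, groups: np.ndarray,
                  weights: Optional[np.ndarray] = None
                  ) -> Tuple[float, float]:
    """(among-group, within-group) fractions of the total sum of squares."""
    if weights is None:
        weights = np.ones_like(values)
    wsum = weights.sum()
    grand = (weights * values).sum() / wsum
    total = (weights * (values - grand) ** 2).sum()
    if total == 0:
        return 0.0, 0.0
    df = pd.DataFrame({"v": values, "g": groups, "w": weights})
    gm = df.groupby("g").apply(
        lambda s: (s["w"] * s["v"]).sum() / s["w"].sum(),
        include_groups=False)
    gw = df.groupby("g")["w"].sum()
    among = float((gw * (gm - grand) ** 2).sum())
    return among / total, 1.0 - among / total


def variance_partition(occ: OccurrenceTable, trait: str,
                       weighted: bool = False) -> Dict[str, float]:
    """Decompose trait variance among vs within plots, and within vs among
    species.

    The plot decomposition operates on occurrence-level t_sp values (one per
    species-plot pair); the species decomposition on individual plants.
    Unweighted sums of squares by default; ``weighted=True`` weights the
    plot decomposition by abundance.
    """
    tsp = occ.tsp(trait)
    if tsp["plot"].nunique() < 2 or tsp["species"].nunique() < 2:
        raise ValueError("need at least two plots and two species")
    w = None
    if weighted:
        merged = tsp.merge(occ.occurrences, on=["species", "plot"])
        w = merged["abundance"].to_numpy(float)
        tsp = merged
    among_plot, within_plot = _ss_fractions(
        tsp["value"].to_numpy(float), tsp["plot"].to_numpy(), w)

    plants = occ.plants[~occ.plants["imputed"]].dropna(subset=[trait])
    among_sp, within_sp = _ss_fractions(
        plants[trait].to_numpy(float), plants["species"].to_numpy())
    return {
        "fraction_among_plots": among_plot,
        "fraction_within_plots": within_plot,
        "fraction_among_species": among_sp,
        "fraction_within_species": within_sp,
    }


def component_r2(res: TraitGradientResult) -> Dict[str, float]:
    """Variance in species mean trait values explained by each component
    (squared Pearson correlation of t_bar with alpha and with beta)."""
    sp = res.species
    if len(sp) < 3:
        raise ValueError("need at least three species")
    out = {}
    for comp in ("alpha", "beta"):
        x = sp[comp].to_numpy(float)
        y = sp["t_bar"].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[f"r2_{comp}"] = 0.0
            out[f"r2_{comp}_degenerate"] = True
        else:
            out[f"r2_{comp}"] = float(np.corrcoef(x, y)[0, 1] ** 2)
    return out


# ---------------------------------------------------------------------------
# CSV ingest
# ---------------------------------------------------------------------------

def load_tables(community_csv, traits_csv, plots_csv=None,
                trait_names: Optional[List[str]] = None) -> OccurrenceTable:
    """Read the community and trait CSVs into an :class:`OccurrenceTable`.

    Community CSV: columns (plot, species, abundance); abundance may be a
    fraction in (0, 1] or a percentage in (0, 100] (divided by 100 when any
    value exceeds 1).  Traits CSV: (plant_id, species, plot, site, <traits>)
    with raw positive trait values, log10-transformed at ingest.  Optional
    plots CSV: (plot, site, habitat).
    """
    occ = pd.read_csv(community_csv)
    occ = occ.rename(columns=str.lower)[["plot", "species", "abundance"]]
    if (occ["abundance"] > 1).any():
        occ["abundance"] = occ["abundance"] / 100.0

    plants = pd.read_csv(traits_csv).rename(columns=str.lower)
    meta_cols = [c for c in ("plant_id", "species", "plot", "site")
                 if c in plants.columns]
    if trait_names is None:
        trait_names = [c for c in plants.columns if c not in meta_cols]
    for t in trait_names:
        vals = plants[t]
        if (vals.dropna() <= 0).any():
            raise ValueError(f"trait {t!r} has non-positive values; "
                             "log10 transform undefined")
        plants[t] = np.log10(vals)
    plants["imputed"] = False

    if plots_csv is not None:
        plot_info = pd.read_csv(plots_csv).rename(columns=str.lower)
    else:
        sites = (plants[["plot", "site"]].drop_duplicates()
                 if "site" in plants.columns
                 else pd.DataFrame({"plot": occ["plot"].unique(),
                                    "site": "site1"}))
        plot_info = sites.assign(habitat="unknown")
    plot_info = plot_info.drop_duplicates("plot").reset_index(drop=True)
    return OccurrenceTable(occ, plants, plot_info, list(trait_names))
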