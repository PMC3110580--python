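"""Community ordination: Bray-Curtis dissimilarities, non-metric
multidimensional scaling (NMDS), a Monte-Carlo stress test, and plot-mean
trait vs axis-1 correlations.

Stress is Kruskal stress-1 multiplied by 100 (so 8.7 means stress-1 =
0.087).  Axis orientation in NMDS is arbitrary; :func:`orient_axes` fixes
the sign so increasing axis-1 scores track a supplied habitat indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

__all__ = [
    "OrdinationResult",
    "bray_curtis",
    "nmds",
    "species_scores",
    "orient_axes",
    "stress_montecarlo",
    "trait_env_correlation",
]


@dataclass
class OrdinationResult:
    """NMDS configuration: plot scores, optional species scores, stress."""

    plot_scores: pd.DataFrame             # plots x k axes
    stress: float                         # Kruskal stress-1 x 100
    k: int
    n_starts: int
    seed: int
    species_scores: Optional[pd.DataFrame] = None
    montecarlo_p: Optional[float] = None
    metadata: Dict = field(default_factory=dict)


def bray_curtis(community: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity among the rows (plots) of an abundance
    matrix: d(p,q) = 1 - 2 sum_s min(a_sp, a_sq) / (sum_s a_sp + sum_s a_sq).
    """
    x = community.to_numpy(float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    if (x.sum(axis=1) == 0).any():
        empty = community.index[x.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero plots: {empty}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=community.index, columns=community.index)


def _pcoa_coords(dm: np.ndarray, k: int) -> np.ndarray:
    """Classical scaling (PCoA) coordinates, used as a deterministic
    NMDS start alongside the random ones."""
    n = len(dm)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


def nmds(d: pd.DataFrame, k: int = 2, n_starts: int = 20, seed: int = 0,
         max_iter: int = 300) -> OrdinationResult:
    """Non-metric MDS of a dissimilarity matrix; deterministic per seed.

    Runs ``n_starts`` random SMACOF starts plus one start initialised from
    classical scaling (PCoA), and keeps the lowest-stress configuration.
    """
    n = len(d)
    if k >= n:
        raise ValueError("k must be smaller than the number of plots")
    dm = d.to_numpy(float)
    with warnings.catch_warnings():
        # scikit-learn is renaming the MDS metric/dissimilarity/init
        # parameters; the classic spelling still works and stays seeded
        warnings.simplefilter("ignore", FutureWarning)
        model = MDS(n_components=k, metric=False,
                    dissimilarity="precomputed", n_init=n_starts,
                    random_state=int(seed) % (2 ** 32), max_iter=max_iter,
                    normalized_stress=True, eps=1e-9)
        coords = model.fit_transform(dm)
        stress = float(model.stress_)
        pinit = MDS(n_components=k, metric=False,
                    dissimilarity="precomputed", n_init=1,
                    random_state=int(seed) % (2 ** 32), max_iter=max_iter,
                    normalized_stress=True, eps=1e-9)
        pcoords = pinit.fit_transform(dm, init=_pcoa_coords(dm, k))
        if float(pinit.stress_) < stress:
            coords, stress = pcoords, float(pinit.stress_)
    scores = pd.DataFrame(coords, index=d.index,
                          columns=[f"axis{i+1}" for i in range(k)])
    return OrdinationResult(plot_scores=scores, stress=stress * 100.0,
                            k=k, n_starts=n_starts, seed=seed)


def species_scores(res: OrdinationResult, community: pd.DataFrame
                   ) -> pd.DataFrame:
    """Species scores as abundance-weighted averages of plot scores.

    A species confined to one plot lands exactly on that plot's score.
    ``community`` is plots x species, aligned to the ordination's plots.
    """
    comm = community.loc[res.plot_scores.index]
    a = comm.to_numpy(float)
    totals = a.sum(axis=0)
    if (totals == 0).any():
        comm = comm.loc[:, totals > 0]
        a = comm.to_numpy(float)
        totals = a.sum(axis=0)
    w = a / totals
    scores = pd.DataFrame(w.T @ res.plot_scores.to_numpy(float),
                          index=comm.columns,
                          columns=res.plot_scores.columns)
    res.species_scores = scores
    return scores


def orient_axes(res: OrdinationResult,
                habitat_indicator: Optional[pd.Series] = None) -> OrdinationResult:
    """Fix the arbitrary axis signs.

    If a habitat indicator (numeric, indexed by plot) is given, axis 1 is
    flipped so its correlation with the indicator is non-negative; other
    axes (and axis 1 without an indicator) are flipped so the first plot in
    lexicographic order has a non-negative score.
    """
    scores = res.plot_scores
    order = scores.index.sort_values()
    for j, col in enumerate(scores.columns):
        flip = False
        if j == 0 and habitat_indicator is not None:
            ind = habitat_indicator.reindex(scores.index).to_numpy(float)
            r = np.corrcoef(scores[col].to_numpy(float), ind)[0, 1]
            flip = bool(r < 0)
        else:
            flip = bool(scores.loc[order[0], col] < 0)
        if flip:
            res.plot_scores[col] = -scores[col]
            if res.species_scores is not None:
                res.species_scores[col] = -res.species_scores[col]
    return res


def stress_montecarlo(community: pd.DataFrame, k: int = 2,
                      n_runs: int = 999, seed: int = 0,
                      n_starts: int = 5, max_iter: int = 150) -> Dict[str, float]:
    """Monte-Carlo test of NMDS stress.

    The null shuffles each species' abundance vector independently across
    plots (preserving per-species occupancy frequencies) and re-runs the
    ordination; P = (#{null stress <= observed} + 1) / (n_runs + 1).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    observed = nmds(bray_curtis(community), k=k, n_starts=n_starts,
                    seed=int(rng.integers(2 ** 31)), max_iter=max_iter).stress
    x = community.to_numpy(float)
    count = 0
    for _ in range(n_runs):
        shuffled = np.column_stack(
            [rng.permutation(x[:, j]) for j in range(x.shape[1])])
        keep = shuffled.sum(axis=1) > 0
        null_comm = pd.DataFrame(shuffled[keep])
        s = nmds(bray_curtis(null_comm), k=k, n_starts=n_starts,
                 seed=int(rng.integers(2 ** 31)), max_iter=max_iter).stress
        if s <= observed:
            count += 1
    p = (count + 1) / (n_runs + 1)
    return {"stress": observed, "P": p, "n_runs": n_runs}


def trait_env_correlation(axis_scores: pd.Series,
                          plot_means: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each trait's plot means with axis-1 scores."""
    plots = axis_scores.index.intersection(plot_means.index)
    if len(plots) < 3:
        raise ValueError("need at least three plots")
    x = axis_scores.loc[plots].to_numpy(float)
    rows = []
    for trait in plot_means.columns:
        y = plot_means.loc[plots, trait].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"zero variance for trait {trait!r}")
        r, p = stats.pearsonr(x, y)
        rows.append({"trait": trait, "r": float(r), "P": float(p),
                     "n": len(plots)})
    return pd.DataFrame(rows).set_index("trait")
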