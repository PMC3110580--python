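"""Phylogenetic comparative statistics: independent contrasts, contrast
diagnostics, ahistorical and through-origin contrast correlations, and
Blomberg's K with a tip-shuffle permutation test.

The contrast recursion (Felsenstein pruning) is expressed as a linear
operator on tip values: for a fixed bifurcating tree every raw contrast is
a fixed linear combination of tip values, so the whole contrast vector is
``L @ x``.  Building ``L`` once makes tip-shuffle permutation tests a
single matrix product.  The same recursion yields the phylogenetic
(GLS) mean, its variance, and the quadratic form (x - a)' C^-1 (x - a)
without ever inverting the covariance matrix; these are exactly the
quantities Blomberg's K needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats

from .phylo import Phylogeny

__all__ = [
    "ContrastSet",
    "SignalResult",
    "independent_contrasts",
    "contrast_diagnostics",
    "correlation_ahistorical",
    "correlation_pic",
    "blomberg_k",
    "signal_test",
]

ZERO_LENGTH_FLOOR = 1e-8  # applied to zero-length edges from polytomy resolution


@dataclass
class ContrastSet:
    """Standardized independent contrasts, one per internal node."""

    node_ids: List[str]
    contrasts: np.ndarray      # raw contrasts
    sds: np.ndarray            # expected standard deviations
    tip_labels: List[str]

    @property
    def standardized(self) -> np.ndarray:
        return self.contrasts / self.sds

    @property
    def n(self) -> int:
        return len(self.contrasts)


@dataclass
class SignalResult:
    """Blomberg's K with its tip-shuffle permutation P-value."""

    K: float
    P: float
    n_permutations: int
    observed_statistic: float  # variance of standardized contrasts
    seed: int


@dataclass
class _PruningOperator:
    """Precomputed linear algebra of the contrast recursion on one tree."""

    tip_labels: List[str]
    node_ids: List[str]
    L: np.ndarray              # (n-1, n): raw contrasts = L @ x
    variances: np.ndarray      # (n-1,): expected contrast variances
    root_weights: np.ndarray   # (n,): GLS mean = root_weights @ x
    root_variance: float       # var of the GLS mean = 1 / (1' C^-1 1)
    trace_c: float             # tr(C) = sum of root-to-tip distances

    @property
    def L_std(self) -> np.ndarray:
        return self.L / np.sqrt(self.variances)[:, None]


def _build_operator(tree: Phylogeny) -> _PruningOperator:
    if not tree.is_bifurcating():
        raise ValueError("contrasts need a bifurcating tree; "
                         "resolve polytomies first")
    tips = tree.tips()
    n = len(tips)
    if n < 2:
        raise ValueError("need at least two tips")
    index = {t.label: k for k, t in enumerate(tips)}

    rows: List[np.ndarray] = []
    variances: List[float] = []
    node_ids: List[str] = []
    state: Dict[int, Tuple[np.ndarray, float]] = {}  # id -> (weights, adj bl)

    def edge_length(node) -> float:
        bl = node.length
        if bl is None:
            raise ValueError(f"missing branch length at {node.label!r}")
        return max(float(bl), ZERO_LENGTH_FLOOR)

    counter = 0
    for node in tree.postorder():
        if node.is_tip:
            w = np.zeros(n)
            w[index[node.label]] = 1.0
            bl = 0.0 if node is tree.root else edge_length(node)
            state[id(node)] = (w, bl)
            continue
        (wi, bi), (wj, bj) = (state.pop(id(c)) for c in node.children)
        rows.append(wi - wj)
        variances.append(bi + bj)
        counter += 1
        node_ids.append(node.label or f"node{counter}")
        w = (wi / bi + wj / bj) / (1.0 / bi + 1.0 / bj)
        extra = bi * bj / (bi + bj)
        bl = extra if node is tree.root else edge_length(node) + extra
        state[id(node)] = (w, bl)

    root_w, root_var = state[id(tree.root)]
    depths = tree.depths()
    trace_c = sum(depths[id(t)] for t in tips)
    return _PruningOperator(
        tip_labels=[t.label for t in tips], node_ids=node_ids,
        L=np.array(rows), variances=np.array(variances),
        root_weights=root_w, root_variance=root_var, trace_c=trace_c)


def _trait_vector(op: _PruningOperator, trait: Dict[str, float]) -> np.ndarray:
    missing = set(op.tip_labels) - set(trait)
    extra = set(trait) - set(op.tip_labels)
    if missing or extra:
        raise ValueError(
            f"tip/trait mismatch: missing {sorted(missing)}, "
            f"extra {sorted(extra)}")
    x = np.array([float(trait[t]) for t in op.tip_labels])
    if not np.isfinite(x).all():
        raise ValueError("non-finite trait values")
    return x


# ---------------------------------------------------------------------------
# Contrasts and their correlations
# ---------------------------------------------------------------------------

def independent_contrasts(tree: Phylogeny, trait: Dict[str, float]
                          ) -> ContrastSet:
    """Felsenstein's independent contrasts on a bifurcating tree.

    The trait map must cover exactly the tip set.  Zero-length edges (from
    polytomy resolution) are floored at ``ZERO_LENGTH_FLOOR`` so contrast
    variances stay positive.
    """
    op = _build_operator(tree)
    x = _trait_vector(op, trait)
    return ContrastSet(node_ids=op.node_ids, contrasts=op.L @ x,
                       sds=np.sqrt(op.variances), tip_labels=op.tip_labels)


def contrast_diagnostics(cs: ContrastSet) -> Dict[str, object]:
    """Correlation of |standardized contrast| with its expected SD.

    A branch-length transform is adequate when this correlation is
    indistinguishable from zero.  On a star-like tree all SDs are equal and
    the statistic is undefined (``applicable=False``).
    """
    if cs.n < 3:
        raise ValueError("need at least three contrasts")
    if np.ptp(cs.sds) == 0:
        return {"r": None, "P": None, "applicable": False}
    r, p = stats.pearsonr(np.abs(cs.standardized), cs.sds)
    return {"r": float(r), "P": float(p), "applicable": True}


def correlation_ahistorical(x: Dict[str, float], y: Dict[str, float]
                            ) -> Dict[str, float]:
    """Ordinary Pearson correlation over the shared species."""
    shared = sorted(set(x) & set(y))
    if len(shared) < 3:
        raise ValueError("need at least three shared species")
    xv = np.array([x[s] for s in shared], dtype=float)
    yv = np.array([y[s] for s in shared], dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(xv, yv)
    return {"r": float(r), "P": float(p), "n": len(shared)}


def correlation_pic(cx: ContrastSet, cy: ContrastSet) -> Dict[str, float]:
    """Through-origin correlation of two sets of standardized contrasts.

    r = sum(cx*cy) / sqrt(sum(cx^2) sum(cy^2)); the regression through the
    origin estimates one parameter, so df = N - 1; two-sided P from the
    t transform of r.
    """
    if cx.node_ids != cy.node_ids:
        raise ValueError("contrast sets come from different trees")
    a, b = cx.standardized, cy.standardized
    sa, sb = float(a @ a), float(b @ b)
    if sa == 0 or sb == 0:
        raise ValueError("all-zero contrasts")
    r = float(a @ b) / np.sqrt(sa * sb)
    df = cx.n - 1
    if df < 1:
        raise ValueError("need at least two contrasts")
    r_clip = min(max(r, -1.0), 1.0)
    if abs(r_clip) == 1.0:
        p = 0.0
    else:
        t = r_clip * np.sqrt(df) / np.sqrt(1.0 - r_clip ** 2)
        p = 2.0 * stats.t.sf(abs(t), df)
    return {"r": r, "P": float(p), "df": df}


# ---------------------------------------------------------------------------
# Phylogenetic signal
# ---------------------------------------------------------------------------

def _k_from_operator(op: _PruningOperator, x: np.ndarray) -> float:
    n = len(x)
    a_hat = float(op.root_weights @ x)
    dev = x - a_hat
    mse0 = float(dev @ dev) / (n - 1)
    contrasts = op.L @ x
    # sum of squared standardized raw contrasts = (x-a)' C^-1 (x-a)
    q = float(np.sum(contrasts ** 2 / op.variances))
    mse = q / (n - 1)
    if mse == 0:
        raise ValueError("constant trait: K undefined")
    expected = (op.trace_c - n * op.root_variance) / (n - 1)
    return (mse0 / mse) / expected


def _quadratic_forms(tree: Phylogeny, x: np.ndarray,
                     tip_index: Dict[str, int]) -> Tuple[float, float, float]:
    """(x'C^-1 x, 1'C^-1 x, 1'C^-1 1) by Gaussian elimination up the tree.

    Works on arbitrary (also multifurcating) trees without forming C.  At
    each node the children's (value, effective branch) pairs are pooled
    with weights 1/b; the discarded residual contributes to the quadratic
    form.  Cross terms come from running the recursion jointly on x and 1.
    """
    state: Dict[int, Tuple[float, float, float]] = {}  # id -> (vx, v1, b)
    qxx = q1x = q11 = 0.0
    for node in tree.postorder():
        if node.is_tip:
            bl = max(float(node.length), ZERO_LENGTH_FLOOR) \
                if node is not tree.root else 0.0
            state[id(node)] = (x[tip_index[node.label]], 1.0, bl)
            continue
        vs = [state.pop(id(c)) for c in node.children]
        s1 = sum(1.0 / b for _, _, b in vs)
        sx = sum(v / b for v, _, b in vs)
        so = sum(o / b for _, o, b in vs)
        qxx += sum(v * v / b for v, _, b in vs) - sx * sx / s1
        q11 += sum(o * o / b for _, o, b in vs) - so * so / s1
        q1x += sum(v * o / b for v, o, b in vs) - sx * so / s1
        if node is tree.root:
            b = 1.0 / s1
        else:
            b = max(float(node.length), ZERO_LENGTH_FLOOR) + 1.0 / s1
        state[id(node)] = (sx / s1, so / s1, b)
    vx, v1, b = state[id(tree.root)]
    qxx += vx * vx / b
    q11 += v1 * v1 / b
    q1x += vx * v1 / b
    return qxx, q1x, q11


def blomberg_k(tree: Phylogeny, trait: Dict[str, float]) -> float:
    """Blomberg's K: observed vs Brownian-expected partitioning of trait
    variance on the tree.

    K = 1 under Brownian motion; K < 1 means less resemblance among
    relatives than Brownian motion predicts; K = 1 exactly on a star
    phylogeny.  With phylogenetic mean a = (1'C^-1 x)/(1'C^-1 1),

        K = [MSE0 / MSE] / [(tr(C) - n/(1'C^-1 1)) / (n - 1)],

    MSE0 = (x-a)'(x-a)/(n-1), MSE = (x-a)'C^-1(x-a)/(n-1).  The quadratic
    forms are accumulated by a pruning-style elimination pass, so the
    covariance matrix is never built or inverted and multifurcating trees
    are handled directly.
    """
    n = tree.n_tips
    if n < 3:
        raise ValueError("need at least three tips")
    tips = tree.tips()
    tip_index = {t.label: k for k, t in enumerate(tips)}
    missing = set(tip_index) - set(trait)
    extra = set(trait) - set(tip_index)
    if missing or extra:
        raise ValueError(f"tip/trait mismatch: missing {sorted(missing)}, "
                         f"extra {sorted(extra)}")
    x = np.array([float(trait[t.label]) for t in tips])
    qxx, q1x, q11 = _quadratic_forms(tree, x, tip_index)
    a_hat = q1x / q11
    dev = x - a_hat
    mse0 = float(dev @ dev) / (n - 1)
    mse = (qxx - q1x ** 2 / q11) / (n - 1)
    if mse <= 0:
        raise ValueError("constant trait: K undefined")
    depths = tree.depths()
    trace_c = sum(depths[id(t)] for t in tips)
    expected = (trace_c - n / q11) / (n - 1)
    return (mse0 / mse) / expected


def signal_test(tree: Phylogeny, trait: Dict[str, float],
                n_perm: int = 999, seed: int = 0) -> SignalResult:
    """Permutation test for phylogenetic signal.

    The observed statistic is the variance of the standardized contrasts;
    strong signal makes contrasts small relative to their Brownian SDs.  The
    null distribution shuffles trait values across tips ``n_perm`` times and
    P = (#{null <= observed} + 1) / (n_perm + 1).  K is reported alongside.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    op = _build_operator(tree)
    x = _trait_vector(op, trait)
    lstd = op.L_std
    observed = float(np.var(lstd @ x, ddof=1))
    rng = np.random.default_rng(seed)
    perms = np.empty((len(x), n_perm))
    for j in range(n_perm):
        perms[:, j] = rng.permutation(x)
    null = np.var(lstd @ perms, axis=0, ddof=1)
    p = (int(np.sum(null <= observed)) + 1) / (n_perm + 1)
    return SignalResult(K=_k_from_operator(op, x), P=float(p),
                        n_permutations=n_perm,
                        observed_statistic=observed, seed=seed)
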