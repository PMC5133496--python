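"""Signed weighted coexpression networks and module detection.

The construction follows the weighted-network recipe: a robust pairwise
correlation (biweight midcorrelation), a signed soft-threshold adjacency
``a_lk = |0.5 + 0.5 * cor(x_l, x_k)|**gamma``, topological overlap, and
average-linkage hierarchical clustering of the topological-overlap
dissimilarity with an adaptive tree cut.  Each module is summarized by its
eigengene, the first principal component of the standardized expression of
its genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkError",
    "ModulePartition",
    "Eigengene",
    "bicor_matrix",
    "signed_adjacency",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "module_eigengenes",
    "network_modules",
    "GREY",
]

logger = logging.getLogger(__name__)

GREY = "grey"


class NetworkError(ValueError):
    pass


@dataclass
class ModulePartition:
    """Probe-to-module labels; ``"grey"`` marks unassigned probes.

    Non-grey labels are ``module1``, ``module2``, ... in decreasing module
    size.
    """

    labels: pd.Series  # index: probe ids, values: labels

    def module_ids(self) -> list[str]:
        sizes = self.labels[self.labels != GREY].value_counts()
        return sorted(sizes.index, key=lambda m: (-sizes[m], m))

    def genes(self, module_id: str) -> list[str]:
        return list(self.labels.index[self.labels == module_id])

    def n_modules(self) -> int:
        return len(self.module_ids())

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("module_label").rename_axis("probe_id").reset_index()


@dataclass
class Eigengene:
    """First-PC summary of a gene set: per-sample scores, unit variance."""

    gene_set: list[str]
    scores: pd.Series = field(repr=False)  # index: sample ids
    variance_explained: float


# ---------------------------------------------------------------------------
# Correlation and adjacency
# ---------------------------------------------------------------------------

def _bicor_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized row vectors whose inner products give bicor.

    Rows with zero MAD (or zero variance) fall back to the Pearson form
    (mean-centered); the returned mask flags those rows.
    """
    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    fallback = (mad.ravel() == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
        w = np.where(np.isfinite(u), (1.0 - u**2) ** 2 * (np.abs(u) < 1.0), 0.0)
    V = w * dev
    # Pearson fallback rows: plain mean-centering
    if fallback.any():
        C = X[fallback] - X[fallback].mean(axis=1, keepdims=True)
        V[fallback] = C
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    degenerate = norms.ravel() == 0
    norms[degenerate] = 1.0
    return V / norms, fallback


def bicor_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise biweight midcorrelation of probes (rows of ``expr``).

    Each probe is centered on its median and scaled by 9 * MAD; points at
    or beyond 9 MADs get zero weight, points near the median weight close
    to one (Tukey biweight).  Probes with zero MAD are computed as Pearson
    for all their pairs (logged).  Values are clipped to [-1, 1] with unit
    diagonal; constant probes correlate 0 with everything.
    """
    if expr.shape[1] < 4:
        raise NetworkError("need at least 4 samples for correlation")
    X = expr.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise NetworkError("expression contains non-finite values; impute first")
    V, fallback = _bicor_rows(X)
    if fallback.any():
        logger.warning("bicor: %d probe(s) with zero MAD fell back to Pearson",
                       int(fallback.sum()))
    C = np.clip(V @ V.T, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    flat = X.std(axis=1) < 1e-14
    if flat.any():
        C[flat, :] = 0.0
        C[:, flat] = 0.0
        np.fill_diagonal(C, 1.0)
        warnings.warn(f"{int(flat.sum())} constant probe(s) assigned zero correlation")
    return pd.DataFrame(C, index=expr.index, columns=expr.index)


def signed_adjacency(cor: pd.DataFrame | np.ndarray, gamma: float):
    """Signed soft-threshold adjacency ``|0.5 + 0.5 * cor|**gamma``.

    Anti-correlated probes map near 0, perfectly correlated near 1; gamma
    sharpens the contrast without a hard cutoff.  Diagonal is 1.
    """
    if gamma <= 0:
        raise NetworkError("gamma must be positive")
    arr = cor.to_numpy() if isinstance(cor, pd.DataFrame) else np.asarray(cor, float)
    A = np.abs(0.5 + 0.5 * arr) ** gamma
    np.fill_diagonal(A, 1.0)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(A, index=cor.index, columns=cor.columns)
    return A


def _scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log regression of the connectivity histogram.

    Scale-free topology shows a straight, decreasing log-frequency vs
    log-connectivity relation; the sign of the slope is folded into the
    returned statistic (negative slope => positive fit index).
    """
    k = connectivity
    if np.ptp(k) < 1e-12:
        raise NetworkError("degenerate connectivity: all nodes identical")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freqs, means = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        freqs.append(sel.sum())
        means.append(k[sel].mean())
    x = np.log10(np.maximum(np.asarray(means, float), 1e-12))
    y = np.log10(np.asarray(freqs, float))
    if len(x) < 3 or np.ptp(x) < 1e-12:
        return 0.0
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -np.sign(slope) * r2


def pick_soft_threshold(
    cor: pd.DataFrame | np.ndarray,
    candidates: Sequence[float] = tuple(range(2, 21, 2)),
    rsq_target: float = 0.8,
) -> float:
    """Choose the soft-threshold exponent by approximate scale-free fit.

    Returns the smallest candidate whose signed scale-free fit index
    reaches ``rsq_target``; when none qualifies, the candidate with the
    largest index.
    """
    if len(candidates) < 2:
        if len(candidates) == 1:
            return float(candidates[0])
        raise NetworkError("need at least one candidate gamma")
    fits = []
    for g in candidates:
        A = signed_adjacency(cor, g)
        arr = A.to_numpy() if isinstance(A, pd.DataFrame) else A
        k = arr.sum(axis=1) - 1.0
        fits.append(_scale_free_fit(k))
    for g, r2 in zip(candidates, fits):
        if r2 >= rsq_target:
            return float(g)
    return float(candidates[int(np.argmax(fits))])


def tom_similarity(adj: pd.DataFrame | np.ndarray):
    """Topological overlap: similarity crediting shared neighbors.

    ``TOM_lk = (sum_m a_lm a_mk + a_lk) / (min(k_l, k_k) + 1 - a_lk)``
    with connectivities ``k_l = sum_{m != l} a_lm``; diagonal 1.
    """
    arr = adj.to_numpy() if isinstance(adj, pd.DataFrame) else np.asarray(adj, float)
    A = arr.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    num = A @ A + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore"):
        T = num / den
    T = np.clip(T, 0.0, 1.0)
    np.fill_diagonal(T, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(T, index=adj.index, columns=adj.columns)
    return T


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def detect_modules(
    dissim: pd.DataFrame | np.ndarray,
    min_module_size: int = 30,
    cut_frac: float = 0.98,
    cohesion: float = 0.5,
    probe_ids: Sequence[str] | None = None,
) -> ModulePartition:
    """Average-linkage clustering with a dynamic-hybrid-style tree cut.

    Module *cores* are the maximal dendrogram branches of at least
    ``min_module_size`` probes that finish merging below an adaptive
    height ``h_low + cohesion * (h_cut - h_low)``, where ``h_low`` is the
    5th percentile of all merge heights (the tightest real structure in
    this tree), ``h_cut = cut_frac * tree_height``, and ``cohesion`` in
    (0, 1) is the split-sensitivity knob — larger values admit weaker,
    less separated cores.  Anchoring the threshold to the tree's own
    merge-height range makes the cut scale-free: it behaves the same for
    strongly and weakly correlated data.

    Because average linkage chains peripheral members onto a core one at
    a time, a second, PAM-like stage assigns each leftover probe to the
    core with the smallest mean dissimilarity, provided that mean is
    below the core's assignment radius — 60 % of the way from the core's
    internal mean dissimilarity to the overall background mean, i.e. the
    probe is clearly closer to the module than to an average probe.
    Everything else is ``grey``.  Labels are ``module1`` (largest),
    ``module2``, ...
    """
    if isinstance(dissim, pd.DataFrame):
        ids = list(dissim.index)
        D = dissim.to_numpy(dtype=float)
    else:
        D = np.asarray(dissim, dtype=float)
        ids = list(probe_ids) if probe_ids is not None else [
            f"p{i}" for i in range(D.shape[0])
        ]
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise NetworkError("dissimilarity must be square symmetric")
    grey_all = pd.Series(GREY, index=pd.Index(ids, name="probe_id"))
    if n < min_module_size:
        warnings.warn("fewer probes than min_module_size: all probes grey")
        return ModulePartition(grey_all)
    if not 0 < cohesion < 1:
        raise NetworkError("cohesion must be in (0, 1)")
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    heights = Z[:, 2]
    tree_height = float(heights[-1]) if len(heights) else 0.0
    if tree_height <= 0:
        warnings.warn("flat dendrogram: all probes grey")
        return ModulePartition(grey_all)
    h_cut = cut_frac * tree_height
    h_low = float(np.percentile(heights, 5.0))
    core_height = h_low + cohesion * max(h_cut - h_low, 0.0)
    overall = float(D[np.triu_indices(n, 1)].mean())

    # leaves of each internal node, iteratively (avoid recursion limits)
    n_nodes = 2 * n - 1
    members: list[list[int]] = [[i] for i in range(n)] + [None] * (n - 1)
    for m in range(n - 1):
        a, b = int(Z[m, 0]), int(Z[m, 1])
        members[n + m] = members[a] + members[b]
    node_height = np.concatenate([np.zeros(n), heights])

    # maximal branches below the core height seed the modules; a core
    # nucleus may be smaller than the final minimum module size
    core_min = max(4, min_module_size // 8)
    cores: list[list[int]] = []
    stack = [n_nodes - 1]
    while stack:
        node = stack.pop()
        idx = members[node]
        if len(idx) < core_min:
            continue
        if node_height[node] <= core_height:
            cores.append(idx)
            continue
        if node >= n:
            m = node - n
            stack.append(int(Z[m, 0]))
            stack.append(int(Z[m, 1]))

    def _intra(idx: list[int]) -> float:
        return float(D[np.ix_(idx, idx)].sum() / (len(idx) * (len(idx) - 1)))

    # merge fragmented nuclei of one module: two cores fuse when the mean
    # dissimilarity between them is inside either one's assignment radius
    def _radius(idx: list[int]) -> float:
        return _intra(idx) + 0.6 * (overall - _intra(idx))

    merged = True
    while merged and len(cores) > 1:
        merged = False
        for i in range(len(cores)):
            for j in range(i + 1, len(cores)):
                between = float(D[np.ix_(cores[i], cores[j])].mean())
                if between <= max(_radius(cores[i]), _radius(cores[j])):
                    cores[i] = cores[i] + cores[j]
                    del cores[j]
                    merged = True
                    break
            if merged:
                break

    labels = np.full(n, GREY, dtype=object)
    if cores:
        # PAM-like stage: pull chained peripheral probes into their core
        assigned = np.zeros(n, dtype=bool)
        for idx in cores:
            assigned[idx] = True
        radius = np.array([_radius(idx) for idx in cores])
        free = np.flatnonzero(~assigned)
        if free.size:
            avg = np.stack([
                D[np.ix_(free, idx)].mean(axis=1) for idx in cores
            ])  # cores x free
            best = np.argmin(avg, axis=0)
            ok = avg[best, np.arange(free.size)] <= radius[best]
            for j, c, keep in zip(free, best, ok):
                if keep:
                    cores[c] = cores[c] + [int(j)]
        cores = [c for c in cores if len(c) >= min_module_size]
        order = sorted(
            range(len(cores)),
            key=lambda i: (-len(cores[i]), min(ids[j] for j in cores[i])),
        )
        for rank, mi in enumerate(order, start=1):
            for j in cores[mi]:
                labels[j] = f"module{rank}"
    return ModulePartition(pd.Series(labels, index=pd.Index(ids, name="probe_id")))


# ---------------------------------------------------------------------------
# Eigengenes
# ---------------------------------------------------------------------------

def module_eigengene(expr: pd.DataFrame, gene_set: Sequence[str]) -> Eigengene:
    """First principal component of the standardized expression of a set.

    Probes are standardized across samples (mean 0, sd 1); the leading
    left-singular direction of the samples-by-genes block gives the
    per-sample scores, rescaled to unit variance.  ``variance_explained``
    is the leading eigenvalue's share.  The score sign is fixed so that it
    correlates positively with the per-sample mean of the standardized
    block.
    """
    gene_set = list(gene_set)
    missing = [g for g in gene_set if g not in expr.index]
    if missing:
        raise NetworkError(f"genes absent from expression: {missing[:5]}")
    block = expr.loc[gene_set].to_numpy(dtype=float)
    sd = block.std(axis=1, ddof=1)
    keep = sd > 1e-12
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} zero-variance gene(s) dropped "
                      "from eigengene computation")
        block = block[keep]
        gene_set = [g for g, k in zip(gene_set, keep) if k]
    if len(gene_set) < 2:
        raise NetworkError("gene set collapsed below 2 usable genes")
    Z = (block - block.mean(axis=1, keepdims=True)) / block.std(
        axis=1, ddof=1, keepdims=True
    )
    # samples x genes
    U, s, _ = np.linalg.svd(Z.T, full_matrices=False)
    scores = U[:, 0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    mean_profile = Z.mean(axis=0)
    if np.dot(scores, mean_profile) < 0:
        scores = -scores
    scores = scores / scores.std(ddof=1)
    return Eigengene(
        gene_set=gene_set,
        scores=pd.Series(scores, index=expr.columns, name="eigengene"),
        variance_explained=var_explained,
    )


def module_eigengenes(
    expr: pd.DataFrame, partition: ModulePartition
) -> dict[str, Eigengene]:
    """Eigengene for every non-grey module of a partition."""
    return {
        m: module_eigengene(expr, partition.genes(m))
        for m in partition.module_ids()
    }


def network_modules(
    expr: pd.DataFrame,
    gamma: float = 6.0,
    min_module_size: int = 30,
    dissimilarity: str = "tom",
    cohesion: float = 0.5,
) -> ModulePartition:
    """Convenience chain: bicor -> signed adjacency -> TOM -> modules."""
    cor = bicor_matrix(expr)
    adj = signed_adjacency(cor, gamma)
    if dissimilarity == "tom":
        sim = tom_similarity(adj)
    elif dissimilarity == "adjacency":
        sim = adj
    else:
        raise NetworkError("dissimilarity must be 'tom' or 'adjacency'")
    return detect_modules(1.0 - sim, min_module_size=min_module_size,
                          cohesion=cohesion)
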