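"""Weighted co-expression network construction and module detection.

The construction follows the weighted correlation-network recipe: a soft-
thresholded correlation adjacency (unsigned ``|r|**beta`` or signed
``((1+r)/2)**beta``), topological overlap similarity, average-linkage
hierarchical clustering of ``1 - TOM``, a static branch cut, size
filtering, and iterative merging of modules with highly correlated
eigengenes.  The module eigengene is the first principal component of the
per-gene standardized module submatrix, unit-variance scaled and
sign-oriented so that it correlates positively with the module's mean
standardized expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16, 18, 20)

__all__ = [
    "CoexpressionNetwork",
    "ModulePartition",
    "pick_soft_threshold",
    "build_adjacency",
    "compute_tom",
    "detect_modules",
    "module_eigengene",
    "build_network",
    "export_edge_list",
    "scale_free_fit",
    "UNASSIGNED",
]


@dataclass
class CoexpressionNetwork:
    """A weighted gene co-expression network (adjacency and TOM)."""

    gene_ids: list[str]
    adjacency: np.ndarray
    tom: np.ndarray | None
    power: float
    signed: bool

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"gene(s) not in network: {', '.join(missing[:5])}")
        return np.array([lookup[g] for g in genes])


@dataclass
class ModulePartition:
    """Assignment of genes to labelled modules plus per-module eigengenes.

    Labels are ``"M1"``, ``"M2"``, ... ordered by decreasing module size,
    plus :data:`UNASSIGNED` for genes in no module.  ``eigengenes`` is a
    samples x modules DataFrame (absent when detection ran without
    expression data); ``dendrogram`` is the scipy linkage matrix.
    """

    assignment: pd.Series
    eigengenes: pd.DataFrame | None = None
    dendrogram: np.ndarray | None = None

    @property
    def module_labels(self) -> list[str]:
        return [l for l in self.assignment.unique() if l != UNASSIGNED]

    def genes_in(self, label: str) -> list[str]:
        return list(self.assignment.index[self.assignment == label])

    def sizes(self) -> pd.Series:
        counts = self.assignment[self.assignment != UNASSIGNED].value_counts()
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.assignment.index, "module_label": self.assignment.to_numpy()}
        )


def _correlation(x: ExpressionMatrix) -> np.ndarray:
    v = x.values
    sd = v.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(x.gene_ids, sd) if s == 0]
        raise ValueError(f"zero-variance gene(s): {', '.join(bad[:5])} (filter before networking)")
    c = np.corrcoef(v)
    np.clip(c, -1.0, 1.0, out=c)
    return c


def build_adjacency(x: ExpressionMatrix, power: float, signed: bool = False) -> np.ndarray:
    """Soft-thresholded correlation adjacency with unit diagonal."""
    if power < 1:
        raise ValueError(f"power must be >= 1, got {power}")
    c = _correlation(x)
    if signed:
        a = ((1.0 + c) / 2.0) ** power
    else:
        a = np.abs(c) ** power
    np.fill_diagonal(a, 1.0)
    return a


def compute_tom(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    ``tom_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu a_uj`` over ``u != i, j`` and ``k_i`` the
    connectivity of gene i (off-diagonal row sum); ``tom_ii = 1``.
    """
    a = np.array(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # includes u=i and u=j terms, both zero since diag(a)=0
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return tom


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit: R^2 and slope of log10 p(k) on log10 k.

    Connectivities are binned into ``n_bins`` equal-width bins; empty bins
    are dropped.  Returns ``(r_squared, slope)``.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.digitize(k, edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    fit = linregress(xs, ys)
    return float(fit.rvalue**2), float(fit.slope)


def pick_soft_threshold(
    x: ExpressionMatrix,
    candidate_powers: Sequence[float] = DEFAULT_POWERS,
    signed: bool = False,
    rsq_target: float = 0.85,
) -> float:
    """Choose the smallest power reaching scale-free fit R^2 >= target.

    The slope of the fit must be negative for a power to qualify; if no
    candidate reaches the target, the power maximizing R^2 is returned with
    a warning.
    """
    if len(candidate_powers) == 0:
        raise ValueError("candidate_powers must be non-empty")
    if x.shape[1] < 8:
        logger.warning("fewer than 8 samples (%d): power selection is unreliable", x.shape[1])
    fits = []
    for beta in candidate_powers:
        a = build_adjacency(x, beta, signed=signed)
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        rsq, slope = scale_free_fit(k)
        fits.append((beta, rsq, slope))
    for beta, rsq, slope in fits:
        if rsq >= rsq_target and slope < 0:
            return float(beta)
    best = max(fits, key=lambda f: f[1])
    logger.warning(
        "no candidate power reached scale-free R^2 >= %.2f; falling back to "
        "power %s (R^2 = %.3f)", rsq_target, best[0], best[1],
    )
    return float(best[0])


def module_eigengene(x: ExpressionMatrix, genes: Sequence[str]) -> pd.Series:
    """First principal component of the standardized module submatrix.

    Scaled to unit variance and sign-oriented so that its correlation with
    the mean standardized module expression is non-negative.  Zero-variance
    genes are excluded with a warning.
    """
    if len(genes) == 0:
        raise ValueError("module gene set is empty")
    sub = x.subset_genes(genes)
    v = sub.values
    sd = v.std(axis=1, ddof=1)
    if (sd == 0).any():
        keep = sd > 0
        logger.warning("excluding %d zero-variance gene(s) from eigengene", int((~keep).sum()))
        if not keep.any():
            raise ValueError("all module genes have zero variance")
        v = v[keep]
        sd = sd[keep]
    z = (v - v.mean(axis=1, keepdims=True)) / sd[:, None]
    # first right singular vector of the genes x samples standardized matrix
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    ev = vt[0]
    ev_sd = ev.std(ddof=1)
    if ev_sd == 0:
        raise ValueError("degenerate eigengene (zero variance)")
    ev = ev / ev_sd
    mean_profile = z.mean(axis=0)
    if np.dot(ev - ev.mean(), mean_profile - mean_profile.mean()) < 0:
        ev = -ev
    return pd.Series(ev, index=sub.sample_ids, name="eigengene")


def _relabel_by_size(groups: dict[str, list[str]], all_genes: Sequence[str]) -> pd.Series:
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    assignment = pd.Series(UNASSIGNED, index=list(all_genes), dtype=object)
    for rank, (_, genes) in enumerate(ordered, start=1):
        assignment.loc[genes] = f"M{rank}"
    return assignment


def detect_modules(
    tom: np.ndarray,
    gene_ids: Sequence[str] | None = None,
    expression: ExpressionMatrix | None = None,
    min_module_size: int = 30,
    cut_height: float = 0.95,
    merge_height: float = 0.25,
) -> ModulePartition:
    """Detect modules from a TOM by average-linkage clustering of 1 - TOM.

    A static branch cut at ``cut_height`` defines candidate clusters;
    clusters below ``min_module_size`` become unassigned.  When
    ``expression`` is supplied, modules whose eigengene correlation is at
    least ``1 - merge_height`` are merged iteratively and per-module
    eigengenes are returned.
    """
    if min_module_size < 3:
        raise ValueError(f"min_module_size must be >= 3, got {min_module_size}")
    if expression is not None and gene_ids is None:
        gene_ids = expression.gene_ids
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(tom.shape[0])]
    if len(gene_ids) != tom.shape[0]:
        raise ValueError("gene_ids length does not match TOM")

    dist = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.clip((dist + dist.T) / 2.0, 0.0, None), checks=False)
    z = linkage(condensed, method="average")
    flat = fcluster(z, t=cut_height, criterion="distance")

    groups: dict[str, list[str]] = {}
    for cluster_id in np.unique(flat):
        members = [gene_ids[i] for i in np.flatnonzero(flat == cluster_id)]
        if len(members) >= min_module_size:
            groups[f"c{cluster_id}"] = members

    if expression is not None and len(groups) >= 2:
        groups = _merge_correlated(groups, expression, merge_height)

    assignment = _relabel_by_size(groups, gene_ids)
    eigengenes = None
    if expression is not None:
        labels = [l for l in sorted(assignment.unique(), key=_label_key) if l != UNASSIGNED]
        if labels:
            eigengenes = pd.DataFrame(
                {
                    lab: module_eigengene(expression, list(assignment.index[assignment == lab]))
                    for lab in labels
                }
            )
    return ModulePartition(assignment=assignment, eigengenes=eigengenes, dendrogram=z)


def _label_key(label: str):
    return (0, int(label[1:])) if label.startswith("M") and label[1:].isdigit() else (1, label)


def _merge_correlated(
    groups: dict[str, list[str]], expression: ExpressionMatrix, merge_height: float
) -> dict[str, list[str]]:
    threshold = 1.0 - merge_height
    groups = {k: list(v) for k, v in groups.items()}
    while len(groups) >= 2:
        keys = sorted(groups)
        mes = pd.DataFrame({k: module_eigengene(expression, groups[k]) for k in keys})
        corr = mes.corr().to_numpy()
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < threshold:
            break
        a, b = keys[i], keys[j]
        groups[a] = groups[a] + groups.pop(b)
    return groups


def export_edge_list(
    net: CoexpressionNetwork,
    path,
    threshold: float = 0.5,
    max_edges: int = 200_000,
) -> int:
    """Write gene pairs with adjacency >= threshold as a TSV edge list.

    The threshold bounds the file size; the strongest ``max_edges`` pairs
    are kept if the threshold still admits more.  Returns the number of
    edges written.
    """
    a = net.adjacency
    iu, ju = np.triu_indices(a.shape[0], k=1)
    keep = a[iu, ju] >= threshold
    iu, ju = iu[keep], ju[keep]
    order = np.argsort(-a[iu, ju], kind="stable")[:max_edges]
    iu, ju = iu[order], ju[order]
    rows = pd.DataFrame(
        {
            "gene_i": [net.gene_ids[i] for i in iu],
            "gene_j": [net.gene_ids[j] for j in ju],
            "adjacency": a[iu, ju],
            "tom": net.tom[iu, ju] if net.tom is not None else np.nan,
        }
    )
    rows.to_csv(path, sep="\t", index=False)
    return len(rows)


def build_network(
    x: ExpressionMatrix,
    power: float | None = None,
    signed: bool = False,
    with_tom: bool = True,
) -> CoexpressionNetwork:
    """Convenience constructor: pick power if unset, build adjacency (+TOM)."""
    if power is None:
        power = pick_soft_threshold(x, signed=signed)
    adjacency = build_adjacency(x, power, signed=signed)
    tom = compute_tom(adjacency) if with_tom else None
    return CoexpressionNetwork(
        gene_ids=x.gene_ids, adjacency=adjacency, tom=tom, power=float(power), signed=signed
    )
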