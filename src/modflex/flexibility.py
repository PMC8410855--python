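"""Modular flexibility: instantiate a reference module's gene set in each
response stratum's network, measure the topological distance D to the
reference, and regress D (and edge count) on the stratum phenotype.

The instantiated module is the binary graph on the module's genes with an
edge wherever the stratum network's adjacency reaches a threshold
``tau_g``.  By default ``tau_g`` is anchored so the *reference* stratum's
instantiation is a complete graph (density 1), a reproducible calibration;
an explicit value can be supplied instead.

The global topological distance D between two instantiations is the
Euclidean norm of the difference of bounded feature vectors
``(density, clustering coefficient, CPL/2 clipped to [0,1],
mean degree / (n-1))``.  D is a pseudometric: non-negative, symmetric,
zero for identical graphs, and satisfies the triangle inequality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import linregress

from .modgraph import TopologyFeatures, topology_features
from .network import CoexpressionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "FlexibilityProfile",
    "RegressionFit",
    "instantiate_module",
    "reference_threshold",
    "feature_vector",
    "d_value",
    "flexibility_profiles",
    "flexibility_regression",
]


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n_points": self.n_points,
        }


@dataclass
class FlexibilityProfile:
    """One stratum's instantiation of the reference module."""

    stratum: str
    mean_delta_af: float
    graph: nx.Graph
    features: TopologyFeatures
    d_value: float

    @property
    def n_edges(self) -> int:
        return self.features.n_edges


def reference_threshold(net: CoexpressionNetwork, genes: list[str]) -> float:
    """Adjacency threshold making the module's instantiation complete.

    The minimum off-diagonal adjacency among the module's genes in the
    reference network: binarizing at this value reproduces a density-1
    (complete) reference module.
    """
    idx = net.gene_index(genes)
    if idx.size < 2:
        raise ValueError("need >= 2 module genes for a threshold")
    sub = net.adjacency[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].min())


def instantiate_module(genes: list[str], stratum_net: CoexpressionNetwork, tau_g: float) -> nx.Graph:
    """Binary graph on the module genes: edge iff stratum adjacency >= tau_g."""
    if len(genes) < 2:
        raise ValueError(f"need >= 2 module genes present, got {len(genes)}")
    idx = stratum_net.gene_index(genes)
    sub = stratum_net.adjacency[np.ix_(idx, idx)]
    g = nx.Graph()
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    for i, j in zip(iu, ju):
        if sub[i, j] >= tau_g:
            g.add_edge(genes[i], genes[j])
    return g


def feature_vector(features: TopologyFeatures) -> np.ndarray:
    """Bounded topology summary (density, clustering, CPL/2, normalized mean degree).

    Each component lies in [0, 1].  An edgeless graph has no defined CPL;
    its CPL component is set to 1 (maximally distant).
    """
    n = features.n_nodes
    mean_degree = 2.0 * features.n_edges / n if n else 0.0
    cpl = features.characteristic_path_length
    cpl_component = 1.0 if not np.isfinite(cpl) else min(cpl / 2.0, 1.0)
    return np.array(
        [
            features.density,
            features.clustering_coefficient,
            cpl_component,
            mean_degree / (n - 1) if n > 1 else 0.0,
        ]
    )


def d_value(features_a: TopologyFeatures, features_b: TopologyFeatures) -> float:
    """Euclidean distance between the two graphs' bounded feature vectors."""
    return float(np.linalg.norm(feature_vector(features_a) - feature_vector(features_b)))


def flexibility_profiles(
    genes: list[str],
    stratum_nets: dict[str, CoexpressionNetwork],
    stratum_delta_af: dict[str, float],
    reference: str,
    tau_g: float | None = None,
) -> list[FlexibilityProfile]:
    """Instantiate the module in every stratum and score D versus the reference.

    ``tau_g=None`` applies the reference-complete calibration
    (:func:`reference_threshold` on the reference stratum's network).
    """
    if reference not in stratum_nets:
        raise KeyError(f"reference stratum {reference!r} has no network")
    if tau_g is None:
        tau_g = reference_threshold(stratum_nets[reference], genes)
    ref_graph = instantiate_module(genes, stratum_nets[reference], tau_g)
    ref_features = topology_features(ref_graph)
    profiles = []
    for name, net in stratum_nets.items():
        g = instantiate_module(genes, net, tau_g)
        feats = topology_features(g)
        profiles.append(
            FlexibilityProfile(
                stratum=name,
                mean_delta_af=float(stratum_delta_af[name]),
                graph=g,
                features=feats,
                d_value=d_value(feats, ref_features),
            )
        )
    return profiles


def profiles_table(profiles: list[FlexibilityProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stratum": p.stratum,
                "mean_delta_af": p.mean_delta_af,
                "n_nodes": p.features.n_nodes,
                "n_edges": p.features.n_edges,
                "density": p.features.density,
                "cpl": p.features.characteristic_path_length,
                "clustering": p.features.clustering_coefficient,
                "d_value": p.d_value,
            }
            for p in profiles
        ]
    )


def flexibility_regression(
    profiles: list[FlexibilityProfile],
) -> tuple[RegressionFit, RegressionFit]:
    """OLS of D on stratum mean delta-AF, and of edge count on the same.

    Returns ``(fit_d, fit_edges)`` with slope, intercept, r^2 and two-sided
    slope p-value each.  Requires >= 3 strata and a non-constant predictor.
    """
    if len(profiles) < 3:
        raise ValueError(f"need >= 3 strata for regression, got {len(profiles)}")
    x = np.array([p.mean_delta_af for p in profiles], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("stratum mean delta-AF is constant; regression undefined")

    def _fit(y: np.ndarray) -> RegressionFit:
        res = linregress(x, y)
        return RegressionFit(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            p_value=float(res.pvalue),
            n_points=len(x),
        )

    fit_d = _fit(np.array([p.d_value for p in profiles], dtype=float))
    fit_edges = _fit(np.array([p.n_edges for p in profiles], dtype=float))
    return fit_d, fit_edges
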