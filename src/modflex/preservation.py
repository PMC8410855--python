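"""Permutation-based module preservation (Z_summary) and DEM calling.

For each reference module, three statistics are evaluated in the test
network: the mean within-module adjacency (density branch), and two
connectivity-branch statistics, the correlation of intramodular
connectivity and the correlation of within-module adjacency entries
between the reference and test networks.  Each observed statistic is
standardized against B random gene sets of the same size drawn from the
shared gene universe, giving permutation Z scores.  The composite is

    z_density      = Z(mean adjacency)
    z_connectivity = median(Z(cor kIM), Z(cor adj))
    z_summary      = (z_density + z_connectivity) / 2

A module with ``z_summary < 0`` (strictly) is a differentially expressed
module (DEM): its co-expression structure in the test network is weaker
than that of random gene sets, i.e. the module has been disrupted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import CoexpressionNetwork, ModulePartition, UNASSIGNED

logger = logging.getLogger(__name__)

MIN_MODULE_SIZE = 4

__all__ = ["PreservationResult", "preservation_z", "preservation_table"]


class DegenerateNullError(RuntimeError):
    """Raised when a permutation null has zero spread (Z undefined)."""


@dataclass
class PreservationResult:
    module_label: str
    size: int
    z_density: float
    z_connectivity: float
    z_summary: float
    mean_adjacency: float
    cor_kim: float
    cor_adj: float
    n_permutations: int

    @property
    def is_dem(self) -> bool:
        return self.z_summary < 0.0


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(np.dot(a, b) / (na * nb))


def _module_stats(ref: np.ndarray, test: np.ndarray, idx: np.ndarray) -> tuple[float, float, float]:
    """(mean test adjacency, cor kIM ref/test, cor adjacency ref/test) for a gene set."""
    m = idx.size
    sub_ref = ref[np.ix_(idx, idx)]
    sub_test = test[np.ix_(idx, idx)]
    iu = np.triu_indices(m, k=1)
    off_ref = sub_ref[iu]
    off_test = sub_test[iu]
    mean_adj = float(off_test.mean())
    kim_ref = sub_ref.sum(axis=1) - np.diag(sub_ref)
    kim_test = sub_test.sum(axis=1) - np.diag(sub_test)
    return mean_adj, _pearson(kim_ref, kim_test), _pearson(off_ref, off_test)


def preservation_z(
    ref_net: CoexpressionNetwork,
    test_net: CoexpressionNetwork,
    partition: ModulePartition,
    n_permutations: int = 100,
    seed: int | None = 0,
) -> list[PreservationResult]:
    """Composite permutation preservation Z statistics per module.

    Both networks must share the same gene universe (same identifiers, same
    order).  Random null sets are drawn without replacement from that
    universe and may overlap the module.  Modules smaller than 4 genes are
    skipped with a warning.
    """
    if ref_net.gene_ids != test_net.gene_ids:
        raise ValueError("reference and test networks must share the same gene universe")
    if n_permutations < 50:
        raise ValueError(f"need at least 50 permutations, got {n_permutations}")
    rng = np.random.default_rng(seed)
    universe = np.arange(len(ref_net.gene_ids))
    lookup = {g: i for i, g in enumerate(ref_net.gene_ids)}
    ref = ref_net.adjacency
    test = test_net.adjacency

    results: list[PreservationResult] = []
    for label in partition.module_labels:
        genes = partition.genes_in(label)
        genes = [g for g in genes if g in lookup]
        m = len(genes)
        if m < MIN_MODULE_SIZE:
            logger.warning("module %s has %d gene(s) in the universe (<%d); skipped",
                           label, m, MIN_MODULE_SIZE)
            continue
        idx = np.array([lookup[g] for g in genes])
        obs = np.array(_module_stats(ref, test, idx))
        null = np.empty((n_permutations, 3))
        for b in range(n_permutations):
            rand_idx = rng.choice(universe, size=m, replace=False)
            null[b] = _module_stats(ref, test, rand_idx)
        mu = np.nanmean(null, axis=0)
        sd = np.nanstd(null, axis=0, ddof=1)
        if np.any(sd == 0) or np.any(~np.isfinite(sd)):
            raise DegenerateNullError(
                f"permutation null for module {label} has zero/undefined spread; "
                "increase n_permutations or check for a degenerate network"
            )
        z = (obs - mu) / sd
        z_density = float(z[0])
        z_connectivity = float(np.median(z[1:3]))
        results.append(
            PreservationResult(
                module_label=label,
                size=m,
                z_density=z_density,
                z_connectivity=z_connectivity,
                z_summary=(z_density + z_connectivity) / 2.0,
                mean_adjacency=float(obs[0]),
                cor_kim=float(obs[1]),
                cor_adj=float(obs[2]),
                n_permutations=n_permutations,
            )
        )
    return results


def preservation_table(results: list[PreservationResult]) -> pd.DataFrame:
    """Tabulate preservation results (one row per module)."""
    return pd.DataFrame(
        [
            {
                "module_label": r.module_label,
                "size": r.size,
                "z_density": r.z_density,
                "z_connectivity": r.z_connectivity,
                "z_summary": r.z_summary,
                "is_dem": r.is_dem,
            }
            for r in results
        ]
    )
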