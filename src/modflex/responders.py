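"""Responder stratification, module-trait correlation and selection of the
most effective therapeutic module (METM).

Treated subjects are stratified by their phenotype change delta-AF (change
in the Seattle Angina Questionnaire angina-frequency score at Day 30 from
baseline): best effect (dAF >= 40), mild effect (40 > dAF >= 20), no
effect (dAF < 20).  Within a stratum, a module is a *significant* DEM when
the Pearson correlation of its eigengene with delta-AF satisfies
|r| >= 0.3 and p < 0.05; the METM is the significant module with the
highest |r| (ties broken by smaller p, then by label).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .network import CoexpressionNetwork, ModulePartition

logger = logging.getLogger(__name__)

R_THRESHOLD = 0.3
P_THRESHOLD = 0.05

#: default strata: (name, lower bound inclusive, upper bound exclusive)
DEFAULT_BINS: tuple[tuple[str, float, float], ...] = (
    ("best", 40.0, float("inf")),
    ("mild", 20.0, 40.0),
    ("none", float("-inf"), 20.0),
)

__all__ = [
    "ResponseStratum",
    "stratify",
    "module_trait_correlation",
    "select_metm",
    "gene_stats",
    "hub_genes",
    "DEFAULT_BINS",
]


@dataclass
class ResponseStratum:
    """A half-open delta-AF interval [lo, hi) with its member subjects."""

    name: str
    lo: float
    hi: float
    subjects: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.subjects)

    def contains(self, value: float) -> bool:
        return self.lo <= value < self.hi


def stratify(
    meta: pd.DataFrame,
    bins: tuple[tuple[str, float, float], ...] = DEFAULT_BINS,
    arm: str = "DHI",
) -> list[ResponseStratum]:
    """Assign every treated subject to exactly one delta-AF stratum.

    Bins are half-open, lower-inclusive intervals and must not overlap.
    Raises if a treated subject lacks delta-AF or falls in no bin.
    """
    strata = [ResponseStratum(name, float(lo), float(hi)) for name, lo, hi in bins]
    for a, b in zip(sorted(strata, key=lambda s: s.lo), sorted(strata, key=lambda s: s.lo)[1:]):
        if b.lo < a.hi:
            raise ValueError(f"strata '{a.name}' and '{b.name}' overlap")
    sub = meta[meta["arm"] == arm][["subject_id", "delta_af"]].drop_duplicates("subject_id")
    if sub["delta_af"].isna().any():
        missing = sub.loc[sub["delta_af"].isna(), "subject_id"]
        raise ValueError(f"delta_af missing for treated subject(s): {', '.join(missing[:5])}")
    for _, row in sub.iterrows():
        hits = [s for s in strata if s.contains(row["delta_af"])]
        if len(hits) != 1:
            raise ValueError(
                f"subject {row['subject_id']} (delta_af={row['delta_af']}) matched "
                f"{len(hits)} strata"
            )
        hits[0].subjects.append(row["subject_id"])
    return strata


def module_trait_correlation(eigengenes: pd.DataFrame, delta_af: pd.Series) -> pd.DataFrame:
    """Pearson r (with two-sided t-based p) of each module eigengene with delta-AF.

    ``eigengenes`` is samples/subjects x modules; ``delta_af`` must cover
    its index.  Modules with a constant eigengene are excluded with a
    warning.  Significance flag: |r| >= 0.3 and p < 0.05.
    """
    missing = [s for s in eigengenes.index if s not in delta_af.index]
    if missing:
        raise ValueError(f"delta_af missing for: {', '.join(map(str, missing[:5]))}")
    y = delta_af.loc[eigengenes.index].to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")
    rows = []
    for label in eigengenes.columns:
        v = eigengenes[label].to_numpy(dtype=float)
        if v.std() == 0 or y.std() == 0:
            logger.warning("constant eigengene or trait for module %s; excluded", label)
            continue
        r, p = stats.pearsonr(v, y)
        rows.append(
            {
                "module_label": label,
                "r": float(r),
                "p_value": float(p),
                "n": n,
                "is_significant": bool(abs(r) >= R_THRESHOLD and p < P_THRESHOLD),
            }
        )
    return pd.DataFrame(rows, columns=["module_label", "r", "p_value", "n", "is_significant"])


def select_metm(correlations: pd.DataFrame) -> str | None:
    """The most effective therapeutic module among significant correlations.

    Highest |r|, ties broken by smaller p, then by module label; ``None``
    when no module is significant (or the table is empty).
    """
    if len(correlations) == 0:
        logger.warning("no module-trait correlations supplied; METM undefined")
        return None
    sig = correlations[correlations["is_significant"]]
    if len(sig) == 0:
        return None
    ranked = sig.assign(abs_r=sig["r"].abs()).sort_values(
        by=["abs_r", "p_value", "module_label"], ascending=[False, True, True]
    )
    return str(ranked.iloc[0]["module_label"])


def gene_stats(
    x: ExpressionMatrix,
    eigengene: pd.Series,
    delta_af: pd.Series,
    module_label: str = "",
) -> pd.DataFrame:
    """Per-gene gene significance (GS) and module membership (MM).

    GS = |cor(expression, delta-AF)|; MM = cor(expression, eigengene), both
    over the matrix's samples.  Zero-variance genes are excluded with a
    warning.
    """
    samples = x.sample_ids
    y = delta_af.loc[samples].to_numpy(dtype=float)
    e = eigengene.loc[samples].to_numpy(dtype=float)
    v = x.values
    sd = v.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("excluding %d zero-variance gene(s) from GS/MM", int((~keep).sum()))
    vs = v[keep] - v[keep].mean(axis=1, keepdims=True)
    norm = np.linalg.norm(vs, axis=1)

    def _cor_with(t: np.ndarray) -> np.ndarray:
        tc = t - t.mean()
        tn = np.linalg.norm(tc)
        if tn == 0:
            return np.full(vs.shape[0], np.nan)
        return (vs @ tc) / (norm * tn)

    gs = np.abs(_cor_with(y))
    mm = _cor_with(e)
    genes = [g for g, k in zip(x.gene_ids, keep) if k]
    return pd.DataFrame(
        {
            "gene_id": genes,
            "gene_significance": gs,
            "module_membership": mm,
            "module_label": module_label,
        }
    )


def hub_genes(
    network: CoexpressionNetwork, partition: ModulePartition, label: str, k: int = 5
) -> list[str]:
    """Top-k module genes by intramodular connectivity (within-module adjacency row sum)."""
    genes = partition.genes_in(label)
    idx = network.gene_index(genes)
    sub = network.adjacency[np.ix_(idx, idx)]
    kim = sub.sum(axis=1) - np.diag(sub)
    order = np.argsort(-kim, kind="stable")
    return [genes[i] for i in order[:k]]
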