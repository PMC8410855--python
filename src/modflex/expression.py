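"""Expression-matrix and metadata I/O, preprocessing, DEG calling and
gene-trait correlation.

All expression values are assumed to be on a log2-like scale, so a mean
difference of ``d`` between two groups corresponds to a fold change of
``2**d``.  Differentially expressed genes (DEGs) are called with the
unadjusted rule p < 0.05 and fold change >= 1.5 (or <= 1/1.5); an optional
Benjamini-Hochberg adjustment can be switched on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEG_P_THRESHOLD = 0.05
DEG_FC_THRESHOLD = 1.5

REQUIRED_METADATA_COLUMNS = ("sample_id", "subject_id", "arm", "timepoint")

__all__ = [
    "ExpressionMatrix",
    "FormatError",
    "ContrastError",
    "read_expression",
    "read_metadata",
    "validate_metadata",
    "filter_variance",
    "call_degs",
    "gene_trait_correlation",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


class ContrastError(ValueError):
    """Raised when a DEG contrast is degenerate (e.g. an empty side)."""


@dataclass
class ExpressionMatrix:
    """A genes x samples log-scale expression matrix.

    Wraps a :class:`pandas.DataFrame` with gene identifiers as the index and
    sample identifiers as columns.  Construction validates uniqueness of
    identifiers and finiteness of values; genes containing missing values
    are dropped (with a logged count).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise FormatError("empty expression matrix")
        dup_genes = df.index[df.index.duplicated()].unique()
        if len(dup_genes):
            raise FormatError(f"duplicate gene identifier(s): {', '.join(map(str, dup_genes[:5]))}")
        dup_samples = df.columns[df.columns.duplicated()].unique()
        if len(dup_samples):
            raise FormatError(
                f"duplicate sample identifier(s): {', '.join(map(str, dup_samples[:5]))}"
            )
        non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        if non_numeric:
            raise FormatError(f"non-numeric values in column(s): {', '.join(map(str, non_numeric[:5]))}")
        n_missing = int(df.isna().any(axis=1).sum())
        if n_missing:
            logger.warning("dropping %d gene(s) with missing values", n_missing)
            self.data = df.dropna(axis=0)
            if self.data.shape[0] == 0:
                raise FormatError("all genes dropped due to missing values")
        if not np.isfinite(self.data.to_numpy()).all():
            bad = self.data.index[~np.isfinite(self.data).all(axis=1)]
            raise FormatError(f"non-finite values in gene(s): {', '.join(map(str, bad[:5]))}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"gene(s) not present: {', '.join(missing[:5])}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"sample(s) not present: {', '.join(missing[:5])}")
        return ExpressionMatrix(self.data[list(samples)])

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (gene-ID first column, sample header)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty expression file: {path}") from exc
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad_rows = df.index[coerced.isna() & df[col].notna()]
            raise FormatError(
                f"non-numeric cell(s) in column '{col}'"
                + (f", row '{bad_rows[0]}'" if len(bad_rows) else "")
            )
    return ExpressionMatrix(df)


def validate_metadata(meta: pd.DataFrame, expression: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Validate a sample-metadata table (and, optionally, its match to a matrix)."""
    missing_cols = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"metadata missing column(s): {', '.join(missing_cols)}")
    dup = meta["sample_id"][meta["sample_id"].duplicated()].unique()
    if len(dup):
        raise FormatError(f"duplicate sample_id(s) in metadata: {', '.join(map(str, dup[:5]))}")
    if expression is not None:
        absent = set(expression.sample_ids) - set(meta["sample_id"])
        if absent:
            raise FormatError(
                f"expression sample(s) missing from metadata: {', '.join(sorted(absent)[:5])}"
            )
    return meta


def read_metadata(path: str | Path, expression: ExpressionMatrix | None = None) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    return validate_metadata(meta, expression)


def filter_variance(x: ExpressionMatrix, top_n: int) -> ExpressionMatrix:
    """Retain the ``top_n`` most variable genes.

    Order is stable under ties: variance descending, then gene id ascending.
    """
    if top_n <= 0:
        raise ValueError(f"top_n must be positive, got {top_n}")
    if top_n > x.shape[0]:
        raise ValueError(f"top_n ({top_n}) exceeds gene count ({x.shape[0]})")
    var = x.data.var(axis=1, ddof=1)
    order = sorted(x.gene_ids, key=lambda g: (-var[g], g))
    return x.subset_genes(order[:top_n])


def _group_samples(meta: pd.DataFrame, arm: str | None = None, timepoint: str | None = None) -> list[str]:
    mask = pd.Series(True, index=meta.index)
    if arm is not None:
        mask &= meta["arm"] == arm
    if timepoint is not None:
        mask &= meta["timepoint"] == timepoint
    return list(meta.loc[mask, "sample_id"])


def call_degs(
    x: ExpressionMatrix,
    meta: pd.DataFrame,
    contrast: str = "arm_at_timepoint",
    *,
    arms: tuple[str, str] = ("DHI", "control"),
    arm: str = "DHI",
    timepoint: str = "Day30",
    timepoints: tuple[str, str] = ("Day0", "Day30"),
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-gene differential-expression test.

    ``contrast="arm_at_timepoint"`` compares ``arms[0]`` vs ``arms[1]`` at
    ``timepoint`` with a two-sided Welch t-test.  ``contrast="within_arm"``
    compares ``timepoints[1]`` vs ``timepoints[0]`` within ``arm`` with a
    paired t-test over subjects present at both timepoints.

    Returns a DataFrame with columns gene_id, log2_fold_change, fold_change,
    p_value, direction and is_deg.  ``is_deg`` requires p < 0.05 and fold
    change >= 1.5 (boundary inclusive) or <= 1/1.5; with ``adjust="bh"`` a
    Benjamini-Hochberg adjusted p-value is used instead of the raw one.
    """
    meta = validate_metadata(meta, x)
    meta = meta[meta["sample_id"].isin(x.sample_ids)]
    if contrast == "arm_at_timepoint":
        s1 = _group_samples(meta, arm=arms[0], timepoint=timepoint)
        s2 = _group_samples(meta, arm=arms[1], timepoint=timepoint)
        if len(s1) < 2 or len(s2) < 2:
            raise ContrastError(
                f"contrast {arms[0]} vs {arms[1]} at {timepoint} needs >=2 samples per side "
                f"(got {len(s1)} and {len(s2)})"
            )
        g1 = x.subset_samples(s1).values
        g2 = x.subset_samples(s2).values
        res = stats.ttest_ind(g1, g2, axis=1, equal_var=False)
        lfc = g1.mean(axis=1) - g2.mean(axis=1)
        pvals = res.pvalue
    elif contrast == "within_arm":
        sub = meta[meta["arm"] == arm]
        wide = sub.pivot_table(index="subject_id", columns="timepoint", values="sample_id", aggfunc="first")
        tp0, tp1 = timepoints
        if tp0 not in wide.columns or tp1 not in wide.columns:
            raise ContrastError(f"timepoint(s) {timepoints} absent for arm {arm}")
        paired = wide.dropna(subset=[tp0, tp1])
        if len(paired) < 2:
            raise ContrastError(f"within-arm contrast needs >=2 paired subjects (got {len(paired)})")
        g0 = x.subset_samples(list(paired[tp0])).values
        g1 = x.subset_samples(list(paired[tp1])).values
        res = stats.ttest_rel(g1, g0, axis=1)
        lfc = (g1 - g0).mean(axis=1)
        pvals = res.pvalue
        if np.isnan(pvals).all():
            raise ContrastError("paired contrast degenerate: all per-gene differences constant")
    else:
        raise ValueError(f"unknown contrast kind: {contrast!r}")

    pvals = np.asarray(pvals, dtype=float)
    fc = 2.0 ** np.abs(lfc)
    p_for_call = pvals
    out = pd.DataFrame(
        {
            "gene_id": x.gene_ids,
            "log2_fold_change": lfc,
            "fold_change": fc,
            "p_value": pvals,
            "direction": np.where(lfc > 0, "up", "down"),
        }
    )
    if adjust is not None:
        if adjust != "bh":
            raise ValueError(f"unknown adjustment: {adjust!r}")
        ok = np.isfinite(pvals)
        padj = np.full_like(pvals, np.nan)
        padj[ok] = stats.false_discovery_control(pvals[ok], method="bh")
        out["p_adjusted"] = padj
        p_for_call = padj
    with np.errstate(invalid="ignore"):
        out["is_deg"] = (p_for_call < DEG_P_THRESHOLD) & (fc >= DEG_FC_THRESHOLD)
    out["is_deg"] = out["is_deg"].fillna(False).astype(bool)
    return out


def gene_trait_correlation(x: ExpressionMatrix, trait: pd.Series | np.ndarray) -> pd.DataFrame:
    """Per-gene Pearson correlation with a trait, with two-sided t-based p.

    ``trait`` must be aligned to the matrix samples (a Series indexed by
    sample id, or an array in sample order); at least 3 samples required.
    Zero-variance genes (or a zero-variance trait) yield NaN with a warning.
    """
    if isinstance(trait, pd.Series):
        missing = [s for s in x.sample_ids if s not in trait.index]
        if missing:
            raise ValueError(f"trait missing for sample(s): {', '.join(missing[:5])}")
        t = trait.loc[x.sample_ids].to_numpy(dtype=float)
    else:
        t = np.asarray(trait, dtype=float)
        if t.shape[0] != x.shape[1]:
            raise ValueError("trait length does not match sample count")
    n = t.shape[0]
    if n < 3:
        raise ValueError(f"need >=3 samples for correlation, got {n}")
    v = x.values
    ts = t - t.mean()
    t_sd = ts.std(ddof=1)
    vs = v - v.mean(axis=1, keepdims=True)
    g_sd = vs.std(axis=1, ddof=1)
    if t_sd == 0:
        logger.warning("trait has zero variance; all correlations undefined")
        r = np.full(v.shape[0], np.nan)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (vs @ ts) / ((n - 1) * g_sd * t_sd)
        n_bad = int((g_sd == 0).sum())
        if n_bad:
            logger.warning("%d zero-variance gene(s): correlation undefined", n_bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return pd.DataFrame({"gene_id": x.gene_ids, "r": r, "p_value": p})
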