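"""Proteome-wide relative-abundance normalization and gene-group shift analysis.

Quantitative proteomics (TMT-style relative quantification against a
wild-type reference) is summarized per gene as the log relative protein
abundance (LRPA), Y_i = log10(A_i^strain / A_i^wt), then standardized
per strain into z-scores

    z_i = (Y_i - <Y>) / sd(Y)

so proteome profiles of different strains/conditions are directly
comparable.  Inter-proteome similarity is Pearson correlation on z-scores
over the shared quantified genes; coordinated regulation of functional and
regulatory gene classes is screened with two-sample Kolmogorov-Smirnov tests
between naive and evolved z-value sets, with the direction of change taken
from the group mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneGroupSet",
    "GroupShiftResult",
    "lrpa",
    "zscore_proteome",
    "proteome_correlation",
    "group_shift_analysis",
    "correlation_panel",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneGroupSet:
    """Named gene groups (functional/regulatory classes); membership may overlap."""

    groups: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for name, members in self.groups.items():
            if not members:
                raise ValueError(f"gene group {name!r} is empty")

    def __iter__(self):
        return iter(self.groups.items())

    def __contains__(self, name: str) -> bool:
        return name in self.groups

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneGroupSet":
        """Build from a two-column (group_id, gene_id) table."""
        grouped = df.groupby(df.columns[0])[df.columns[1]].apply(tuple)
        return cls(groups=dict(grouped))


@dataclass(frozen=True)
class GroupShiftResult:
    group: str
    n_pre: int
    n_post: int
    mean_z_pre: float
    mean_z_post: float
    direction: str  # "up" | "down"
    D: float
    p: float
    significant: bool


def lrpa(rel_abundance: pd.DataFrame) -> pd.DataFrame:
    """Log10 relative protein abundance; zeros and missing become missing.

    Genes undetected in the wild-type reference (relative abundance
    unavailable or zero) cannot contribute and are logged as dropped.
    """
    rel = rel_abundance.astype(float)
    if ((rel < 0) & rel.notna()).any().any():
        raise ValueError("relative abundances must be non-negative")
    positive = rel > 0
    n_dropped = int((rel.notna() & ~positive).sum().sum())
    if n_dropped:
        logger.info("lrpa: %d zero entries mapped to missing", n_dropped)
    y = pd.DataFrame(
        np.where(positive, np.log10(rel.where(positive)), np.nan),
        index=rel.index,
        columns=rel.columns,
    )
    for col in y.columns:
        if y[col].isna().all():
            raise ValueError(f"strain {col!r} has no usable abundances")
    return y


def zscore_proteome(y: pd.DataFrame, min_genes: int = 3) -> pd.DataFrame:
    """Per-strain standardization of LRPA (sample sd, n-1); missing preserved."""
    z = y.astype(float).copy()
    for col in z.columns:
        vals = z[col].dropna()
        if len(vals) < min_genes:
            raise ValueError(f"strain {col!r} has fewer than {min_genes} quantified genes")
        sd = vals.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"strain {col!r} has zero spread; z-scores undefined")
        z[col] = (z[col] - vals.mean()) / sd
    return z


def proteome_correlation(z_a: pd.Series, z_b: pd.Series, method: str = "pearson") -> dict:
    """Correlation between two proteome z-score profiles over shared genes."""
    shared = pd.concat([z_a, z_b], axis=1, join="inner").dropna()
    n = len(shared)
    if n < 3:
        raise ValueError(f"only {n} shared quantified genes (< 3)")
    x, y = shared.iloc[:, 0].to_numpy(), shared.iloc[:, 1].to_numpy()
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return {"r": float(r), "p": float(p), "n": n}


def group_shift_analysis(
    z_pre: pd.Series,
    z_post: pd.Series,
    groups: GeneGroupSet,
    alpha: float = 0.01,
    min_size: int = 5,
    exact_max_n: int = 25,
) -> list[GroupShiftResult]:
    """Kolmogorov-Smirnov screen for gene groups shifted between conditions.

    For each group, the sets of z-values of its member genes in the pre and
    post proteomes are compared by a two-sample KS test (exact p when the
    smaller set has at most ``exact_max_n`` genes, asymptotic otherwise);
    the direction of change is the sign of the group-mean difference.
    Groups resolving to fewer than ``min_size`` genes in either condition
    are skipped with a logged reason.
    """
    results: list[GroupShiftResult] = []
    for name, members in groups:
        idx = [g for g in members if g in z_pre.index and g in z_post.index]
        pre = z_pre.loc[idx].dropna().to_numpy(dtype=float)
        post = z_post.loc[idx].dropna().to_numpy(dtype=float)
        if len(pre) < min_size or len(post) < min_size:
            logger.info(
                "group %s skipped: %d/%d genes with data (< %d)",
                name, len(pre), len(post), min_size,
            )
            continue
        method = "exact" if min(len(pre), len(post)) <= exact_max_n else "asymp"
        ks = stats.ks_2samp(pre, post, method=method)
        mean_pre, mean_post = float(pre.mean()), float(post.mean())
        results.append(
            GroupShiftResult(
                group=name,
                n_pre=len(pre),
                n_post=len(post),
                mean_z_pre=mean_pre,
                mean_z_post=mean_post,
                direction="up" if mean_post > mean_pre else "down",
                D=float(ks.statistic),
                p=float(ks.pvalue),
                significant=bool(ks.pvalue < alpha),
            )
        )
    if not results:
        logger.warning("no gene group resolved to >= %d genes", min_size)
    return results


def shifts_to_frame(results: list[GroupShiftResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def correlation_panel(
    z: pd.DataFrame, labels: list[str] | None = None, method: str = "pearson"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise proteome correlations among the given z-score columns.

    Returns (r, p) matrices ordered as given.
    """
    cols = list(z.columns) if labels is None else labels
    if len(cols) < 2:
        raise ValueError("need at least 2 proteome columns")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            res = proteome_correlation(z[ci], z[cj], method=method)
            r.loc[ci, cj] = r.loc[cj, ci] = res["r"]
            p.loc[ci, cj] = p.loc[cj, ci] = res["p"]
    return r, p
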