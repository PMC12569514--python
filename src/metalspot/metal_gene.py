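"""Transcriptome-wide metal-gene correlation screen.

Counts are normalized to 10 000 per spot and log1p-transformed; every gene is
then Spearman-correlated against an element's Gi* z-score vector across
spots.  Multiplicity is controlled by Bonferroni at family level α = 0.05
over G, the number of genes tested, and the top-k (default 150) genes per
element are extracted as three ranked lists — positive ρ, negative ρ, and by
magnitude — for downstream over-representation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TARGET_SUM = 10_000.0


@dataclass
class CorrelationResult:
    """Per-gene Spearman screen against one element's Gi* z vector."""

    element: str
    table: pd.DataFrame       # index gene: rho, p_raw, p_bonf, significant
    n_genes: int              # G, the Bonferroni family size
    n_spots: int
    alpha: float = 0.05

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_genes


@dataclass
class TopGeneSets:
    """Ranked ≤k gene lists per element: positive, negative, magnitude."""

    element: str
    positive: list[str]
    negative: list[str]
    magnitude: list[str]
    k: int = 150


def normalize_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each spot to 10 000 total counts, then log1p.

    Spots with zero total counts are dropped with a warning — they carry no
    expression information and would divide by zero.
    """
    arr = counts.to_numpy(dtype=np.float64)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = arr.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("excluding %d spots with zero total counts", int(empty.sum()))
        counts = counts.loc[~empty]
        arr = arr[~empty]
        totals = totals[~empty]
    scaled = arr * (TARGET_SUM / totals[:, None])
    return pd.DataFrame(np.log1p(scaled), index=counts.index, columns=counts.columns)


def _spearman_vs_vector(mat: np.ndarray, vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Spearman ρ and two-sided t-approximation p against vec.

    Average ranks for ties (matching scipy.stats.spearmanr); constant columns
    return NaN ρ and p = 1.
    """
    n = len(vec)
    r_vec = stats.rankdata(vec)
    r_mat = stats.rankdata(mat, axis=0)
    rv = r_vec - r_vec.mean()
    rm = r_mat - r_mat.mean(axis=0)
    denom = np.sqrt((rm**2).sum(axis=0) * (rv**2).sum())
    const = denom == 0
    denom[const] = 1.0
    rho = (rm * rv[:, None]).sum(axis=0) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), 0.0, p)        # |rho| == 1 -> t = inf -> p = 0
    rho[const] = np.nan
    p[const] = 1.0
    return rho, p


def correlate_genes(
    normalized: pd.DataFrame,
    gi_z: pd.DataFrame,
    element: str,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Spearman screen of every gene against one element's Gi* z-scores.

    The Bonferroni family size G is the number of genes submitted to the
    screen (constant genes receive p = 1 and can never be significant, so
    including them in G is conservative only).
    """
    if element not in gi_z.columns:
        raise KeyError(f"element {element!r} not in Gi* table")
    shared = normalized.index.intersection(gi_z.index)
    if len(shared) < 10:
        raise ValueError("need at least 10 shared spots for the screen")
    expr = normalized.loc[shared]
    z = gi_z.loc[shared, element].to_numpy(dtype=float)
    rho, p_raw = _spearman_vs_vector(expr.to_numpy(dtype=float), z)
    G = expr.shape[1]
    p_bonf = np.minimum(1.0, p_raw * G)
    table = pd.DataFrame(
        {
            "rho": rho,
            "p_raw": p_raw,
            "p_bonf": p_bonf,
            "significant": p_raw < alpha / G,
        },
        index=pd.Index(expr.columns, name="gene"),
    )
    return CorrelationResult(element, table, n_genes=G, n_spots=len(shared), alpha=alpha)


def select_top_genes(cr: CorrelationResult, k: int = 150) -> TopGeneSets:
    """Top-k significant genes per direction, ranked by adjusted p.

    Ties in adjusted p break toward larger |ρ|, then gene name.  Only genes
    passing the Bonferroni threshold are eligible, so a list may be shorter
    than k (logged).
    """
    t = cr.table
    eligible = t[t["significant"] & t["rho"].notna()].reset_index()
    eligible["abs_rho"] = eligible["rho"].abs()
    eligible = eligible.sort_values(
        by=["p_bonf", "abs_rho", "gene"], ascending=[True, False, True]
    )

    def take(sub: pd.DataFrame) -> list[str]:
        genes = sub["gene"].tolist()[:k]
        if len(genes) < k:
            logger.info(
                "%s: only %d of %d requested genes pass Bonferroni",
                cr.element, len(genes), k,
            )
        return genes

    return TopGeneSets(
        element=cr.element,
        positive=take(eligible[eligible["rho"] > 0]),
        negative=take(eligible[eligible["rho"] < 0]),
        magnitude=take(eligible),
        k=k,
    )


def volcano_table(cr: CorrelationResult) -> pd.DataFrame:
    """Per-gene (ρ, −log10 p_raw, significance) rows for volcano plotting."""
    p = np.maximum(cr.table["p_raw"].to_numpy(), 1e-300)
    return pd.DataFrame(
        {
            "gene": cr.table.index,
            "rho": cr.table["rho"].to_numpy(),
            "neg_log10_p": -np.log10(p),
            "significant": cr.table["significant"].to_numpy(),
        }
    )
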