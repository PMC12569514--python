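"""Associate elemental hotspot scores with tissue architecture and cell types.

Architecture association is a one-way linear model per element (Gi* z-score ~
architecture) whose estimated marginal means are the model-implied group
means; all pairwise contrasts carry Tukey-adjusted p-values.  Cell-type
association is a Spearman correlation matrix between deconvolved proportions
and Gi* z-scores, hierarchically clustered for display.  Sparse pathologist
annotations are completed beforehand by k-nearest-neighbour label
propagation over the spot lattice.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import statsmodels.api as sm
from scipy.spatial import cKDTree
from scipy.stats import spearmanr, studentized_range

from .elemental_io import SpotLayout

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class ArchitectureModelResult:
    """Per-element EMMs, pairwise contrasts, and a display-ready matrix.

    ``emm``: (element, group) → mean, se, n.  ``contrasts``: one row per
    ordered pair with delta = EMM(a) − EMM(b), pooled-SE t, residual df and
    Tukey-adjusted p.  ``zscored_emm`` is the EMM matrix z-scored per element
    row — for heatmaps only; statistics are computed on unscaled values.
    """

    emm: pd.DataFrame
    contrasts: pd.DataFrame
    zscored_emm: pd.DataFrame


@dataclass
class CellTypeCorrMatrix:
    rho: pd.DataFrame            # cell types × elements
    p: pd.DataFrame
    row_order: list[int] = field(default_factory=list)
    col_order: list[int] = field(default_factory=list)


def propagate_labels(
    labels: pd.Series,
    spots: SpotLayout,
    k: int = 4,
    max_iter: int = 50,
) -> pd.Series:
    """Fill unassigned architecture labels by iterative k-NN majority vote.

    At each pass every unassigned spot takes the majority label among its
    ``k`` nearest spots that currently hold one; ties break lexicographically
    by label name.  Iteration stops at a fixed point or ``max_iter``; spots
    still out of reach keep the label ``"unassigned"`` (warned).  Missing
    values (NaN or "unassigned") count as unassigned.
    """
    out = labels.reindex(spots.spot_ids)
    out = out.where(~out.isin([UNASSIGNED, ""]), other=np.nan)
    if out.notna().sum() == 0:
        raise ValueError("label propagation needs at least one labelled spot")

    coords = spots.coords
    tree = cKDTree(coords)
    kq = min(k + 1, len(coords))
    _, knn = tree.query(coords, k=kq)
    knn = np.atleast_2d(knn)[:, 1:]          # drop self

    assigned = out.notna().to_numpy()
    label_arr = out.to_numpy(dtype=object)
    for _ in range(max_iter):
        todo = np.nonzero(~assigned)[0]
        if len(todo) == 0:
            break
        changed = False
        new_labels = label_arr.copy()
        for i in todo:
            votes = [label_arr[j] for j in knn[i] if assigned[j]]
            if not votes:
                continue
            counts: dict[str, int] = {}
            for v in votes:
                counts[v] = counts.get(v, 0) + 1
            best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            new_labels[i] = best
            changed = True
        if not changed:
            break
        assigned = np.array([isinstance(v, str) for v in new_labels])
        label_arr = new_labels

    n_left = int((~assigned).sum())
    if n_left:
        warnings.warn(f"{n_left} spots remain unassigned after propagation")
        label_arr[~assigned] = UNASSIGNED
    return pd.Series(label_arr, index=spots.spot_ids, name="label")


def fit_architecture_model(
    gi_z: pd.DataFrame, labels: pd.Series
) -> ArchitectureModelResult:
    """One-way OLS of Gi* z on architecture, EMMs and Tukey contrasts.

    In the one-way design the estimated marginal mean of a group equals its
    arithmetic mean; standard errors use the pooled residual variance.  The
    Tukey adjustment evaluates the studentized-range distribution at
    q = |t|·√2 with the number of groups and the residual df.
    """
    lab = labels.reindex(gi_z.index)
    keep = lab.notna() & (lab != UNASSIGNED)
    lab = lab[keep]
    data = gi_z.loc[keep.index[keep]]
    groups = sorted(lab.unique())
    sizes = lab.value_counts()
    if len(groups) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 architecture groups with >= 2 spots each")

    dummies = pd.get_dummies(lab, dtype=float)[groups]
    emm_rows, contrast_rows = [], []
    for elem in data.columns:
        y = data[elem].to_numpy(dtype=float)
        model = sm.OLS(y, dummies.to_numpy()).fit()   # cell-means coding
        means = dict(zip(groups, model.params))
        df_resid = int(model.df_resid)
        mse = float(model.mse_resid)
        if mse <= (1e-12 * max(1.0, float(np.abs(y).max()))) ** 2:
            mse = 0.0                                 # groups fit exactly
        for g in groups:
            n_g = int(sizes[g])
            emm_rows.append(
                {
                    "element": elem,
                    "group": g,
                    "emm": means[g],
                    "se": np.sqrt(mse / n_g),
                    "n": n_g,
                }
            )
        for a, b in itertools.permutations(groups, 2):
            delta = means[a] - means[b]
            se = np.sqrt(mse * (1 / sizes[a] + 1 / sizes[b]))
            t = delta / se if se > 0 else 0.0
            if se > 0:
                p_adj = float(
                    studentized_range.sf(abs(t) * np.sqrt(2.0), len(groups), df_resid)
                )
            else:
                p_adj = 1.0
            contrast_rows.append(
                {
                    "element": elem,
                    "group_a": a,
                    "group_b": b,
                    "delta": delta,
                    "t": t,
                    "df": df_resid,
                    "p_tukey": min(p_adj, 1.0),
                }
            )

    emm = pd.DataFrame(emm_rows)
    contrasts = pd.DataFrame(contrast_rows)
    wide = emm.pivot(index="element", columns="group", values="emm")
    mu = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=0).replace(0.0, 1.0)
    zscored = wide.sub(mu, axis=0).div(sd, axis=0)
    return ArchitectureModelResult(emm, contrasts, zscored)


def celltype_metal_correlation(
    props: pd.DataFrame, gi_z: pd.DataFrame
) -> CellTypeCorrMatrix:
    """Spearman ρ/p between every cell-type proportion and element Gi* z.

    Computed over the shared spot index; a constant column yields a missing ρ
    with p = 1.  Row/column dendrogram orders come from average-linkage
    clustering of the completed matrix.
    """
    shared = props.index.intersection(gi_z.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared spots")
    pr = props.loc[shared]
    gz = gi_z.loc[shared]
    rho = pd.DataFrame(index=pr.columns, columns=gz.columns, dtype=float)
    pval = pd.DataFrame(1.0, index=pr.columns, columns=gz.columns, dtype=float)
    for ct in pr.columns:
        for el in gz.columns:
            a, b = pr[ct].to_numpy(), gz[el].to_numpy()
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                rho.loc[ct, el] = np.nan
                pval.loc[ct, el] = 1.0
                continue
            r, p = spearmanr(a, b)
            rho.loc[ct, el] = r
            pval.loc[ct, el] = p
    filled = rho.fillna(0.0)
    row_order = cluster_matrix(filled.to_numpy())
    col_order = cluster_matrix(filled.to_numpy().T)
    return CellTypeCorrMatrix(rho, pval, row_order, col_order)


def cluster_matrix(matrix: np.ndarray) -> list[int]:
    """Deterministic leaf order from average-linkage Euclidean clustering of
    rows.  A single row is the identity order."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if matrix.shape[0] < 2:
        return list(range(matrix.shape[0]))
    link = sch.linkage(matrix, method="average", metric="euclidean")
    return [int(i) for i in sch.leaves_list(link)]
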