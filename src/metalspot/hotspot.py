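"""Getis-Ord Gi* hotspot statistics on the spot lattice.

The Gi* statistic compares the sum of a variable over a spot's neighbourhood
(including the spot itself) with the expectation under spatial randomness:

    z_i = (sum_j w_ij x_j - xbar * W_i) /
          (S * sqrt((n * sum_j w_ij^2 - W_i^2) / (n - 1)))

with binary weights w_ij = 1 for spots within a fixed radius (self included),
W_i their count, and xbar / S the global mean and population standard
deviation over all n spots.  Positive z marks a hotspot of locally elevated
abundance, negative z a coldspot.  Inference is two-sided, either from the
normal approximation or by conditional permutation (hold x_i, permute the
rest).  No multiple-testing adjustment is applied to the spot-level z-scores;
they serve as a spatially smoothed abundance feature downstream, not as a
per-spot discovery procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.spatial import cKDTree
from scipy.stats import norm

from .elemental_io import SpotLayout

logger = logging.getLogger(__name__)


@dataclass
class NeighborGraph:
    """Distance-band neighbourhood with binary weights; every spot neighbours
    itself (the Gi-star convention)."""

    weights: scipy.sparse.csr_matrix     # (n, n) binary, symmetric, diag = 1
    radius_um: float
    spot_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def neighbor_lists(self) -> list[np.ndarray]:
        w = self.weights
        return [w.indices[w.indptr[i]:w.indptr[i + 1]] for i in range(self.n)]


def build_neighbors(spots: SpotLayout, radius_um: float = 100.0) -> NeighborGraph:
    """Binary distance-band weights: w_ij = 1 iff d(i, j) <= radius_um.

    The default 100 µm captures the centre-to-centre pitch of adjacent
    Visium spots, so an interior spot of a square lattice neighbours itself
    plus its 4-adjacent spots.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    coords = spots.coords
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=radius_um, output_type="ndarray")
    n = len(coords)
    ii = np.concatenate([pairs[:, 0], pairs[:, 1], np.arange(n)])
    jj = np.concatenate([pairs[:, 1], pairs[:, 0], np.arange(n)])
    w = scipy.sparse.csr_matrix(
        (np.ones(len(ii)), (ii, jj)), shape=(n, n), dtype=np.float64
    )
    return NeighborGraph(w, radius_um=radius_um, spot_ids=spots.spot_ids)


def gi_star(values: np.ndarray, graph: NeighborGraph) -> tuple[np.ndarray, np.ndarray]:
    """Gi* z-score and two-sided analytic p-value per spot.

    Degenerate cases return (0, 1): a constant field (S = 0), or a spot whose
    neighbourhood spans all spots (the variance term vanishes).
    """
    x = np.asarray(values, dtype=np.float64)
    n = graph.n
    if len(x) != n:
        raise ValueError(f"{len(x)} values for {n} spots")
    if n < 2:
        raise ValueError("Gi* needs at least 2 spots")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")

    xbar = x.mean()
    s = x.std(ddof=0)                       # population std, canonical Gi*
    if s <= 1e-12 * max(1.0, float(np.abs(x).max())):
        s = 0.0                             # constant up to rounding
    wi = np.asarray(graph.weights.sum(axis=1)).ravel()
    wi2 = wi                                 # binary weights: sum w^2 = sum w
    lag = graph.weights @ x
    var_term = (n * wi2 - wi**2) / (n - 1)

    z = np.zeros(n)
    ok = (s > 0) & (var_term > 0)
    z[ok] = (lag[ok] - xbar * wi[ok]) / (s * np.sqrt(var_term[ok]))
    p = np.ones(n)
    p[ok] = 2.0 * norm.sf(np.abs(z[ok]))
    np.clip(p, np.finfo(float).tiny, 1.0, out=p)
    return z, p


def gi_star_permutation(
    values: np.ndarray,
    graph: NeighborGraph,
    n_perm: int = 999,
    seed: int = 0,
) -> np.ndarray:
    """Conditional-permutation p-values for Gi*.

    For each spot the focal value stays fixed while the remaining values are
    permuted over the other spots; p = (1 + #{|z_perm| >= |z_obs|}) /
    (1 + n_perm).  Because a permutation leaves the global mean and standard
    deviation unchanged, only the local sum is resampled.  Deterministic
    given ``seed``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = np.asarray(values, dtype=np.float64)
    n = graph.n
    z_obs, _ = gi_star(x, graph)

    xbar = x.mean()
    s = x.std(ddof=0)
    if s <= 1e-12 * max(1.0, float(np.abs(x).max())):
        return np.ones(n)
    wi = np.asarray(graph.weights.sum(axis=1)).ravel()
    var_term = (n * wi - wi**2) / (n - 1)
    neigh = graph.neighbor_lists()
    k_list = np.array([len(nb) - 1 for nb in neigh])   # neighbours minus self
    k_max = int(k_list.max())

    rng = np.random.default_rng(seed)
    # one bank of index-permutations into "the other n-1 spots", shared
    # across spots (the standard conditional-randomization device)
    if k_max > 0:
        keys = rng.random((n_perm, n - 1))
        idx_bank = np.argpartition(keys, k_max - 1, axis=1)[:, :k_max]

    all_ids = np.arange(n)
    p = np.ones(n)
    for i in range(n):
        k = int(k_list[i])
        denom = s * np.sqrt(var_term[i]) if var_term[i] > 0 else 0.0
        if denom == 0.0:
            continue
        others = np.delete(all_ids, i)
        if k == 0:
            lag_perm = np.full(n_perm, x[i])
        else:
            sampled = x[others][idx_bank[:, :k]]
            lag_perm = x[i] + sampled.sum(axis=1)
        z_perm = (lag_perm - xbar * wi[i]) / denom
        p[i] = (1.0 + np.count_nonzero(np.abs(z_perm) >= abs(z_obs[i]))) / (1.0 + n_perm)
    return p


def gi_star_table(
    spot_values: pd.DataFrame,
    graph: NeighborGraph,
    n_perm: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run Gi* per element column; long table (spot_id, element, z, p...).

    ``spot_values`` rows must align with the graph's spot order.
    """
    if len(spot_values) != graph.n:
        raise ValueError("spot table does not match neighbour graph size")
    frames = []
    for elem in spot_values.columns:
        z, p = gi_star(spot_values[elem].to_numpy(), graph)
        df = pd.DataFrame(
            {
                "spot_id": spot_values.index,
                "element": elem,
                "z": z,
                "p_analytic": p,
            }
        )
        if n_perm is not None:
            df["p_perm"] = gi_star_permutation(
                spot_values[elem].to_numpy(), graph, n_perm=n_perm, seed=seed
            )
            df["n_perm"] = n_perm
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def gi_z_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long Gi* table to spots × elements z-scores."""
    wide = table.pivot(index="spot_id", columns="element", values="z")
    wide.columns.name = None
    order = table["spot_id"].drop_duplicates()
    return wide.loc[order]
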