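"""Landmark homography from map pixels to the whole-slide µm frame, and
pixel → spot aggregation.

The elemental map and the spatial-transcriptomics slide come from serial
sections imaged on different instruments; manually picked fiducial pairs
(``(px_x, px_y) → (um_x, um_y)``) anchor a planar projective transform
between the two frames.  Estimation is the normalized direct linear transform
refined by reprojection least squares.  Aggregation then assigns every
in-mask pixel whose transformed centre lies within the capture radius of its
nearest spot centre, and averages the pseudo-log intensities per spot.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.spatial import cKDTree
from skimage.transform import estimate_transform

from .elemental_io import ElementalMap, SpotLayout
from .preprocess import TissueMask, pseudo_log

logger = logging.getLogger(__name__)


@dataclass
class LandmarkSet:
    """Fiducial correspondences: source in map pixels, target in WSI µm."""

    src_px: np.ndarray    # (n, 2) = (px_x, px_y)
    dst_um: np.ndarray    # (n, 2) = (um_x, um_y)

    def __post_init__(self) -> None:
        self.src_px = np.asarray(self.src_px, dtype=float)
        self.dst_um = np.asarray(self.dst_um, dtype=float)
        if self.src_px.shape != self.dst_um.shape or self.src_px.ndim != 2:
            raise ValueError("source and target must be matching (n, 2) arrays")
        if len(self.src_px) < 4:
            raise ValueError("homography estimation needs >= 4 landmark pairs")
        if len(np.unique(self.src_px, axis=0)) != len(self.src_px):
            raise ValueError("duplicate source landmarks")

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "LandmarkSet":
        return cls(df[["px_x", "px_y"]].to_numpy(), df[["um_x", "um_y"]].to_numpy())

    def __len__(self) -> int:
        return len(self.src_px)


@dataclass
class Homography:
    """3×3 projective transform, normalized so H[2,2] = 1."""

    H: np.ndarray
    rmse: float = 0.0

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if self.H.shape != (3, 3):
            raise ValueError("H must be 3x3")
        if abs(np.linalg.det(self.H)) < 1e-12:
            raise ValueError("homography is singular")
        self.H = self.H / self.H[2, 2]

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.H))

    def hash(self) -> str:
        return hashlib.sha256(np.round(self.H, 10).tobytes()).hexdigest()[:16]


@dataclass
class SpotElementMatrix:
    """Spots × elements aggregated pseudo-log abundances."""

    values: pd.DataFrame          # index spot_id, columns elements
    pixel_count: pd.Series        # per retained spot
    provenance: dict = field(default_factory=dict)


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def transform_points(h: Homography, pts: np.ndarray) -> np.ndarray:
    """Apply the homography: homogeneous multiply then perspective divide."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    ones = np.ones((len(pts), 1))
    hom = np.hstack([pts, ones]) @ h.H.T
    w = hom[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise ValueError("point maps to infinity under this homography")
    return hom[:, :2] / w[:, None]


def estimate_homography(lm: LandmarkSet, refine: bool = True) -> Homography:
    """Fit the map-px → WSI-µm homography from fiducial pairs.

    Normalized DLT (least squares over all pairs) seeds a Levenberg-Marquardt
    refinement of the 8 free parameters against reprojection residuals.  The
    reported RMSE is in target (µm) units.
    """
    if _collinear(lm.src_px):
        raise ValueError("source landmarks are collinear; homography is degenerate")
    tform = estimate_transform("projective", lm.src_px, lm.dst_um)
    H0 = np.asarray(tform.params, dtype=float)
    if not np.all(np.isfinite(H0)) or abs(np.linalg.det(H0)) < 1e-12:
        raise ValueError("degenerate landmark configuration")
    H0 = H0 / H0[2, 2]

    if refine:
        def residuals(p: np.ndarray) -> np.ndarray:
            H = np.append(p, 1.0).reshape(3, 3)
            hom = np.hstack([lm.src_px, np.ones((len(lm), 1))]) @ H.T
            proj = hom[:, :2] / hom[:, 2:3]
            return (proj - lm.dst_um).ravel()

        sol = scipy.optimize.least_squares(
            residuals, H0.ravel()[:8], method="lm", xtol=1e-15, ftol=1e-15
        )
        H = np.append(sol.x, 1.0).reshape(3, 3)
    else:
        H = H0

    h = Homography(H)
    proj = transform_points(h, lm.src_px)
    h.rmse = float(np.sqrt(np.mean(np.sum((proj - lm.dst_um) ** 2, axis=1))))
    return h


def aggregate_to_spots(
    emap: ElementalMap,
    mask: TissueMask,
    spots: SpotLayout,
    h: Homography,
    min_pixels: int = 5,
    radius_um: float | None = None,
    transform: str = "pseudo_log",
) -> SpotElementMatrix:
    """Aggregate per-pixel intensities onto capture spots.

    Each in-mask pixel centre ``(x=col, y=row)`` is mapped through ``h`` to
    the µm frame and assigned to its nearest spot centre iff the distance is
    within ``radius_um`` (default: spot diameter / 2, i.e. the capture
    radius).  The spot value per element is the mean of the assigned pixels'
    pseudo-log intensities — the transform is applied per pixel *before*
    averaging so single hot pixels cannot dominate a spot.  Spots with fewer
    than ``min_pixels`` assigned pixels are dropped (logged).
    """
    if radius_um is None:
        radius_um = spots.diameter_um / 2.0
    rows, cols = np.nonzero(mask.mask)
    if len(rows) == 0:
        raise ValueError("tissue mask is empty")
    px_xy = np.column_stack([cols.astype(float), rows.astype(float)])
    um_xy = transform_points(h, px_xy)

    tree = cKDTree(spots.coords)
    dist, nearest = tree.query(um_xy)
    keep = dist <= radius_um
    if not keep.any():
        raise ValueError("no pixel falls within the capture radius of any spot")

    if transform == "pseudo_log":
        intens = pseudo_log(emap.data[:, rows, cols])
    elif transform == "none":
        intens = emap.data[:, rows, cols].astype(np.float64)
    else:
        raise ValueError(f"unknown transform {transform!r}")

    n_spots = len(spots)
    assign = nearest[keep]
    counts = np.bincount(assign, minlength=n_spots)
    sums = np.zeros((n_spots, len(emap.channels)))
    for ci in range(len(emap.channels)):
        sums[:, ci] = np.bincount(assign, weights=intens[ci, keep], minlength=n_spots)

    retained = counts >= max(min_pixels, 1)
    n_dropped = int((~retained & (counts > 0)).sum())
    if n_dropped:
        logger.info("dropped %d spots with < %d assigned pixels", n_dropped, min_pixels)
    if not retained.any():
        raise ValueError("no spot retained after the min_pixels rule")

    ids = np.asarray(spots.spot_ids)[retained]
    values = pd.DataFrame(
        sums[retained] / counts[retained, None],
        index=pd.Index(ids, name="spot_id"),
        columns=list(emap.channels),
    )
    pixel_count = pd.Series(counts[retained], index=values.index, name="pixel_count")
    return SpotElementMatrix(
        values,
        pixel_count,
        provenance={
            "homography": h.hash(),
            "radius_um": radius_um,
            "min_pixels": min_pixels,
            "transform": transform,
            "rule": "pixel assigned to nearest centre iff distance <= radius",
        },
    )
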