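"""Elemental-map cleanup.

Laser-ablation maps carry three characteristic defects before any statistics
can be trusted: off-tissue background, directional stripe artifacts along the
ablation raster, and washout of labile metals at tissue margins.  This module
detects tissue (Gaussian smoothing + quantile threshold + binary
opening/closing on the channel-sum image), removes stripes (edge enhancement
by Perona-Malik anisotropic diffusion, probabilistic Hough line detection
restricted to near-axis angles, then a perpendicular-window median in-fill),
erodes the mask inward to discard washout margins, and applies the pseudo-log
(log1p) intensity transform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
from skimage.draw import line as draw_line
from skimage.measure import label as cc_label
from skimage.morphology import disk
from skimage.transform import probabilistic_hough_line

from .elemental_io import ElementalMap

logger = logging.getLogger(__name__)


@dataclass
class TissueMask:
    mask: np.ndarray                      # boolean grid, map shape
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class StripeReport:
    """Outcome of stripe detection/correction.

    ``detected_lines`` holds ``(angle_deg, offset_px, support_px)`` per
    accepted Hough segment: the segment's angle to the horizontal axis, its
    mean row (near-horizontal) or column (near-vertical) offset, and its
    length in pixels.
    """

    detected_lines: list[tuple[float, float, int]]
    stripe_mask: np.ndarray
    corrected: bool
    params: dict = field(default_factory=dict)


def detect_tissue(
    emap: ElementalMap,
    threshold_quantile: float = 0.5,
    sigma_px: float = 2.0,
    open_radius_px: int = 2,
    close_radius_px: int = 2,
    min_area_px: int = 64,
) -> TissueMask:
    """Segment tissue from background on the channel-sum image.

    The summed abundance is Gaussian-filtered (outlier damping), thresholded
    at a quantile of the smoothed values, cleaned by binary opening then
    closing, and reduced to connected components of at least ``min_area_px``.
    """
    if not 0.0 < threshold_quantile < 1.0:
        raise ValueError("threshold_quantile must be in (0, 1)")
    total = emap.channel_sum().astype(np.float64)
    smooth = scipy.ndimage.gaussian_filter(total, sigma=sigma_px)
    thr = float(np.quantile(smooth, threshold_quantile))
    raw = smooth > thr
    if open_radius_px > 0:
        raw = scipy.ndimage.binary_opening(raw, structure=disk(open_radius_px))
    if close_radius_px > 0:
        raw = scipy.ndimage.binary_closing(raw, structure=disk(close_radius_px))
    labels, n = cc_label(raw, return_num=True)
    mask = np.zeros_like(raw)
    for comp in range(1, n + 1):
        sel = labels == comp
        if int(sel.sum()) >= min_area_px:
            mask |= sel
    if not mask.any():
        raise ValueError("no tissue detected")
    return TissueMask(
        mask,
        provenance={
            "threshold_quantile": threshold_quantile,
            "threshold_value": thr,
            "sigma_px": sigma_px,
            "open_radius_px": open_radius_px,
            "close_radius_px": close_radius_px,
            "min_area_px": min_area_px,
            "erosion_depth_px": 0,
        },
    )


def _perona_malik(img: np.ndarray, n_iter: int, kappa: float, dt: float = 0.2) -> np.ndarray:
    """Edge-preserving smoothing (exponential conduction coefficient)."""
    u = img.astype(np.float64).copy()
    for _ in range(n_iter):
        dn = np.roll(u, -1, axis=0) - u
        ds = np.roll(u, 1, axis=0) - u
        de = np.roll(u, -1, axis=1) - u
        dw = np.roll(u, 1, axis=1) - u
        # no flux across the image border
        dn[-1, :] = 0; ds[0, :] = 0; de[:, -1] = 0; dw[:, 0] = 0
        cn = np.exp(-((dn / kappa) ** 2))
        cs = np.exp(-((ds / kappa) ** 2))
        ce = np.exp(-((de / kappa) ** 2))
        cw = np.exp(-((dw / kappa) ** 2))
        u += dt * (cn * dn + cs * ds + ce * de + cw * dw)
    return u


def remove_stripes(
    emap: ElementalMap,
    mask: TissueMask,
    diffusion_iters: int = 10,
    diffusion_kappa: float = 0.5,
    hough_threshold: int = 10,
    min_line_len_px: int = 40,
    line_gap_px: int = 4,
    angle_tol_deg: float = 5.0,
    edge_quantile: float = 0.98,
    edge_exclude_border_px: int = 3,
    stripe_halfwidth_px: int = 2,
    median_window_px: int = 7,
    seed: int = 0,
) -> tuple[ElementalMap, StripeReport]:
    """Detect and in-fill directional stripe artifacts.

    The channel-sum is diffused anisotropically so stripe edges stay sharp
    while texture smooths out; the gradient magnitude is binarised at
    ``edge_quantile`` and fed to a probabilistic Hough transform restricted to
    within ``angle_tol_deg`` of the raster axes.  Accepted segments, dilated
    to ``stripe_halfwidth_px``, form the stripe mask; stripe pixels are
    replaced per channel by the median of non-stripe pixels in a window of
    ``median_window_px`` perpendicular to the stripe.  Pixels outside the
    stripe mask are returned untouched; with no detection the input map is
    returned unchanged (``corrected=False``).
    """
    if not mask.mask.any():
        raise ValueError("tissue mask is empty")
    total = emap.channel_sum().astype(np.float64)
    scale = float(total[mask.mask].std()) or 1.0
    diffused = _perona_malik(total / scale, diffusion_iters, diffusion_kappa)
    gy, gx = np.gradient(diffused)
    grad = np.hypot(gx, gy)
    # the tissue outline is itself a strong edge; exclude a thin boundary
    # ring so it neither dominates the gradient quantile nor seeds lines
    interior = mask.mask
    if edge_exclude_border_px > 0:
        interior = scipy.ndimage.binary_erosion(
            mask.mask, iterations=edge_exclude_border_px
        )
    if not interior.any():
        interior = mask.mask
    grad[~interior] = 0.0
    thr = np.quantile(grad[interior], edge_quantile)
    edges = grad > thr

    tol = math.radians(angle_tol_deg)
    # skimage convention: theta is the line-normal angle; horizontal lines
    # have vertical normals (±pi/2), vertical lines have theta ~ 0.
    thetas = np.concatenate([
        np.linspace(-tol, tol, 21),
        np.linspace(np.pi / 2 - tol, np.pi / 2, 11),
        np.linspace(-np.pi / 2, -np.pi / 2 + tol, 11),
    ])
    segments = probabilistic_hough_line(
        edges,
        threshold=hough_threshold,
        line_length=min_line_len_px,
        line_gap=line_gap_px,
        theta=thetas,
        rng=seed,
    )

    detected: list[tuple[float, float, int]] = []
    stripe_mask = np.zeros(emap.shape, dtype=bool)
    horizontal_at: list[bool] = []
    for (x0, y0), (x1, y1) in segments:
        ang = math.degrees(math.atan2(y1 - y0, x1 - x0))
        ang_to_axis = min(abs(ang) % 180, 180 - abs(ang) % 180)
        horizontal = ang_to_axis <= angle_tol_deg
        vertical = abs(ang_to_axis - 90) <= angle_tol_deg
        if not (horizontal or vertical):
            continue
        offset = (y0 + y1) / 2.0 if horizontal else (x0 + x1) / 2.0
        support = int(math.hypot(x1 - x0, y1 - y0)) + 1
        # an ablation stripe runs the full raster line: extrapolate the
        # detected segment to the grid borders along its own direction
        nrow_, ncol_ = emap.shape
        if horizontal:
            slope = (y1 - y0) / (x1 - x0) if x1 != x0 else 0.0
            ya = int(round(y0 + slope * (0 - x0)))
            yb = int(round(y0 + slope * (ncol_ - 1 - x0)))
            ya = int(np.clip(ya, 0, nrow_ - 1))
            yb = int(np.clip(yb, 0, nrow_ - 1))
            rr, cc = draw_line(ya, 0, yb, ncol_ - 1)
        else:
            slope = (x1 - x0) / (y1 - y0) if y1 != y0 else 0.0
            xa = int(round(x0 + slope * (0 - y0)))
            xb = int(round(x0 + slope * (nrow_ - 1 - y0)))
            xa = int(np.clip(xa, 0, ncol_ - 1))
            xb = int(np.clip(xb, 0, ncol_ - 1))
            rr, cc = draw_line(0, xa, nrow_ - 1, xb)
        seg_mask = np.zeros_like(stripe_mask)
        seg_mask[rr, cc] = True
        seg_mask = scipy.ndimage.binary_dilation(
            seg_mask, iterations=stripe_halfwidth_px
        )
        stripe_mask |= seg_mask
        detected.append((ang, float(offset), support))
        horizontal_at.append(horizontal)

    stripe_mask &= mask.mask
    if not detected or not stripe_mask.any():
        report = StripeReport([], np.zeros(emap.shape, bool), corrected=False)
        return ElementalMap(
            list(emap.channels), emap.data.copy(), emap.pixel_size_um, emap.frame
        ), report

    mostly_horizontal = sum(horizontal_at) >= len(horizontal_at) / 2
    corrected = emap.data.copy()
    half = median_window_px // 2
    rows_idx, cols_idx = np.nonzero(stripe_mask)
    nrow, ncol = emap.shape
    for ci in range(corrected.shape[0]):
        grid = corrected[ci]
        filled = grid.copy()
        for r, c in zip(rows_idx, cols_idx):
            # widen the perpendicular window until it reaches clean pixels
            # (a dilated stripe band can exceed the nominal window)
            w = half
            limit = nrow if mostly_horizontal else ncol
            while w < limit:
                if mostly_horizontal:    # window runs perpendicular: down the column
                    lo, hi = max(r - w, 0), min(r + w + 1, nrow)
                    window = grid[lo:hi, c]
                    keep = ~stripe_mask[lo:hi, c]
                else:
                    lo, hi = max(c - w, 0), min(c + w + 1, ncol)
                    window = grid[r, lo:hi]
                    keep = ~stripe_mask[r, lo:hi]
                if keep.any():
                    filled[r, c] = np.median(window[keep])
                    break
                w *= 2
        corrected[ci] = filled

    report = StripeReport(
        detected,
        stripe_mask,
        corrected=True,
        params={
            "diffusion_iters": diffusion_iters,
            "diffusion_kappa": diffusion_kappa,
            "hough_threshold": hough_threshold,
            "min_line_len_px": min_line_len_px,
            "angle_tol_deg": angle_tol_deg,
            "stripe_halfwidth_px": stripe_halfwidth_px,
            "median_window_px": median_window_px,
            "infill": "perpendicular-window median",
        },
    )
    out = ElementalMap(list(emap.channels), corrected, emap.pixel_size_um, emap.frame)
    return out, report


def erode_edges(mask: TissueMask, depth_px: int) -> TissueMask:
    """Erode the tissue mask inward by ``depth_px`` to drop washout margins.

    Uses the 4-connected cross structuring element iterated ``depth_px``
    times (an L1 ball of that radius).  Depth 0 is the identity; an erosion
    that empties the mask raises.
    """
    if depth_px < 0:
        raise ValueError("depth_px must be >= 0")
    if depth_px == 0:
        eroded = mask.mask.copy()
    else:
        eroded = scipy.ndimage.binary_erosion(mask.mask, iterations=depth_px)
    if not eroded.any():
        raise ValueError(f"erosion by {depth_px} px emptied the tissue mask")
    prov = dict(mask.provenance)
    prov["erosion_depth_px"] = prov.get("erosion_depth_px", 0) + depth_px
    return TissueMask(eroded, provenance=prov)


def pseudo_log(values: np.ndarray) -> np.ndarray:
    """log1p transform for nonnegative abundances; 0 maps to 0.

    Damps extreme intensities (single hot pixels from particulates or
    interference) while remaining monotone and defined at zero.
    """
    arr = np.asarray(values, dtype=np.float64)
    if (arr < 0).any():
        raise ValueError("pseudo_log requires nonnegative input")
    return np.log1p(arr)
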