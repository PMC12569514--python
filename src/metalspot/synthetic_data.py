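"""Paired synthetic elemental maps and spot transcriptomics with planted truth.

No patient data accompany this workflow, so every downstream stage is
exercised against a generator that emulates the acquisition: a tissue section
with four architecture regions, per-element intensity fields on a 5 µm pixel
grid (region means + a Gaussian random field + localized hotspot blobs),
directional stripe and edge-washout artifacts injected into a separate
"as-acquired" copy, a square 100 µm-pitch lattice of 55 µm capture spots, a
known pixel→µm homography with sampled fiducials, negative-binomial gene
counts whose log-means are coupled to standardized spot-level element values
for a planted subset of genes, and Dirichlet cell-type proportions with
region- and element-coupled concentration parameters.

Everything planted — stripe rows, blob positions, the homography, gene and
cell-type couplings with their target Spearman correlations — is recorded in
``SyntheticDataset.truth`` so recovery can be tested stage by stage.

The coupling field in the config may be given either as a log-link slope or
as a target Spearman correlation; in the latter case the slope is calibrated
per gene by a seeded Monte-Carlo bisection of the negative-binomial link
against the realized element field.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import scipy.ndimage
from scipy.stats import spearmanr

from . import coregister, elemental_io
from .elemental_io import ElementalMap, SpotLayout
from .preprocess import TissueMask

logger = logging.getLogger(__name__)

REGIONS = ("tumor", "interface", "muscularis", "serosa")
CELL_TYPES = ("Epithelial", "Mesenchymal", "TCell", "Macrophage", "Endothelial")


def _default_region_seeds() -> dict[str, tuple[float, float]]:
    # Voronoi seeds as (row_frac, col_frac); deliberately asymmetric so the
    # region boundaries run oblique to the raster axes and cannot be mistaken
    # for ablation stripes by the near-axis line detector
    return {
        "tumor": (0.28, 0.30),
        "interface": (0.34, 0.72),
        "muscularis": (0.72, 0.22),
        "serosa": (0.68, 0.78),
    }


def _default_region_element_means() -> dict[str, dict[str, float]]:
    # Cu enriched in tumor: the canonical planted scenario for end-to-end
    # recovery (region ordering + coupled gene program)
    means = {r: {"Cu": 3.0, "Fe": 3.0, "Zn": 3.0, "Mn": 3.0} for r in REGIONS}
    means["tumor"]["Cu"] = 6.0
    return means


def _default_celltype_alphas() -> dict[str, list[float]]:
    return {
        "tumor": [8.0, 2.0, 2.0, 2.0, 1.0],
        "interface": [4.0, 4.0, 3.0, 2.0, 1.0],
        "muscularis": [1.0, 6.0, 2.0, 2.0, 1.0],
        "serosa": [2.0, 5.0, 2.0, 2.0, 2.0],
    }


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 5 µm pixels, 55 µm spots at 100 µm pitch,
    four architecture regions, a Cu-enriched tumor with a Cu hotspot blob,
    and ten genes per element coupled at target Spearman ρ = 0.5."""

    grid_shape: tuple[int, int] = (400, 400)
    pixel_size_um: float = 5.0
    spot_pitch_um: float = 100.0
    spot_diameter_um: float = 55.0
    n_genes: int = 400
    n_coupled_genes_per_element: int = 10
    coupling_target_rho: float | None = 0.5
    coupling_strength: float | None = None      # direct log-link slope override
    nb_dispersion: float = 0.5
    elements: tuple[str, ...] = ("Cu", "Fe", "Zn", "Mn")
    region_seeds: dict = dc_field(default_factory=_default_region_seeds)
    region_element_means: dict = dc_field(default_factory=_default_region_element_means)
    celltype_alphas: dict = dc_field(default_factory=_default_celltype_alphas)
    celltype_element_coupling: list = dc_field(
        default_factory=lambda: [("Macrophage", "Cu", 0.8)]
    )
    hotspot_blobs: list = dc_field(
        default_factory=lambda: [("Cu", (120, 120), 25, 4.0)]
    )
    stripe_spec: list = dc_field(default_factory=lambda: [(60, 0.5), (280, 0.4)])
    washout_depth_px: int = 3
    washout_fraction: float = 0.5
    grf_sigma: float = 0.5                      # random-field amplitude
    grf_length_scale_px: float = 10.0
    background_sigma: float = 0.02
    tissue_margin_px: int = 20
    true_homography: np.ndarray = dc_field(
        default_factory=lambda: np.array(
            [[5.0, 0.0, 30.0], [0.0, 5.0, 20.0], [0.0, 0.0, 1.0]]
        )
    )
    n_landmarks: int = 30
    landmark_noise_um: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.spot_diameter_um < self.spot_pitch_um:
            raise ValueError("spot_diameter_um must be smaller than spot_pitch_um")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for row, att in self.stripe_spec:
            if not 0 <= att < 1:
                raise ValueError("stripe attenuation must be in [0, 1)")
            if not 0 <= row < self.grid_shape[0]:
                raise ValueError(f"stripe row {row} outside grid")
        n_coupled = self.n_coupled_genes_per_element * len(self.elements)
        if n_coupled > self.n_genes:
            raise ValueError(
                f"{n_coupled} coupled genes exceed n_genes = {self.n_genes}"
            )
        H = np.asarray(self.true_homography, dtype=float)
        if H.shape != (3, 3) or abs(np.linalg.det(H)) < 1e-12:
            raise ValueError("true_homography must be an invertible 3x3 matrix")
        nr, nc = self.grid_shape
        for elem, (r, c), radius, _amp in self.hotspot_blobs:
            if elem not in self.elements:
                raise ValueError(f"blob element {elem!r} not simulated")
            if not (0 <= r < nr and 0 <= c < nc):
                raise ValueError(f"blob centre {(r, c)} outside grid")
            if radius <= 0:
                raise ValueError("blob radius must be positive")
        if not 0 <= self.washout_fraction < 1:
            raise ValueError("washout_fraction must be in [0, 1)")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    elemental_artifact: ElementalMap
    elemental_clean: ElementalMap
    tissue_mask_truth: np.ndarray
    spots: SpotLayout
    counts: pd.DataFrame               # spots × genes, integer
    labels: pd.Series                  # spot → region
    cell_props: pd.DataFrame           # spots × cell types, rows on simplex
    spot_element_values: pd.DataFrame  # clean aggregated pseudo-log values
    landmarks: pd.DataFrame            # px_x, px_y, um_x, um_y
    truth: dict


# ---------------------------------------------------------------------------
# building blocks


def sample_negative_binomial(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draws with mean ``mu`` and variance ``mu + dispersion * mu**2``."""
    mu = np.asarray(mu, dtype=np.float64)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p, size=mu.shape)


def gaussian_random_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    length_scale_px: float,
    sigma: float,
) -> np.ndarray:
    """White noise convolved with an isotropic Gaussian kernel, rescaled to
    standard deviation ``sigma``."""
    white = rng.standard_normal(shape)
    smooth = scipy.ndimage.gaussian_filter(white, sigma=length_scale_px)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return smooth * sigma


def calibrate_coupling_slope(
    target_rho: float,
    baseline_mean: float,
    dispersion: float,
    z: np.ndarray,
    rng: np.random.Generator,
    n_reps: int = 25,
    max_slope: float = 4.0,
    n_iter: int = 14,
) -> float:
    """Find the log-link slope whose NB counts reach ``target_rho`` Spearman
    correlation with the covariate ``z``, by Monte-Carlo bisection.

    The attainable correlation is monotone in the slope magnitude, so
    bisection on [0, max_slope] converges; the sign of the target carries
    over to the slope.
    """
    if target_rho == 0:
        return 0.0
    sign = np.sign(target_rho)
    goal = abs(target_rho)

    def mean_rho(slope: float) -> float:
        vals = []
        for _ in range(n_reps):
            mu = baseline_mean * np.exp(slope * z)
            counts = sample_negative_binomial(rng, mu, dispersion)
            if np.ptp(counts) == 0:
                vals.append(0.0)
            else:
                vals.append(spearmanr(counts, z)[0])
        return float(np.mean(vals))

    lo, hi = 0.0, max_slope
    if mean_rho(hi) < goal:
        logger.warning(
            "target rho %.2f unattainable at baseline %.2f; using max slope",
            target_rho, baseline_mean,
        )
        return sign * hi
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if mean_rho(mid) < goal:
            lo = mid
        else:
            hi = mid
    return sign * 0.5 * (lo + hi)


def simulate_coupled_counts(
    rng: np.random.Generator,
    baselines: np.ndarray,
    dispersion: float,
    couplings: dict[int, tuple[float, np.ndarray]] | None = None,
    n_spots: int | None = None,
) -> np.ndarray:
    """Spot × gene NB counts; ``couplings`` maps gene index → (slope, z).

    Uncoupled genes are flat at their baseline mean.  Used both by the full
    image-backed generator and directly for spot-level operating-
    characteristic studies (null screens, power checks).
    """
    couplings = couplings or {}
    if n_spots is None:
        if not couplings:
            raise ValueError("n_spots required when no couplings are given")
        n_spots = len(next(iter(couplings.values()))[1])
    G = len(baselines)
    log_mu = np.tile(np.log(baselines), (n_spots, 1))
    for gi, (slope, z) in couplings.items():
        log_mu[:, gi] += slope * z
    return sample_negative_binomial(rng, np.exp(log_mu), dispersion)


# ---------------------------------------------------------------------------
# full dataset


def _tissue_ellipse(shape: tuple[int, int], margin_px: int) -> np.ndarray:
    nr, nc = shape
    rr, cc = np.mgrid[0:nr, 0:nc]
    cy, cx = (nr - 1) / 2.0, (nc - 1) / 2.0
    ay, ax = nr / 2.0 - margin_px, nc / 2.0 - margin_px
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def _region_labels(config: SimulationConfig) -> np.ndarray:
    """Per-pixel region index (Voronoi over the configured seeds)."""
    nr, nc = config.grid_shape
    names = list(config.region_seeds)
    seeds = np.array(
        [(rf * nr, cf * nc) for rf, cf in config.region_seeds.values()]
    )
    rr, cc = np.mgrid[0:nr, 0:nc]
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1).reshape(nr, nc), names


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full paired dataset; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    nr, nc = config.grid_shape
    elements = list(config.elements)

    tissue = _tissue_ellipse(config.grid_shape, config.tissue_margin_px)
    region_idx, region_names = _region_labels(config)

    # --- element fields: region mean + GRF + blobs, clipped nonnegative
    clean = np.zeros((len(elements), nr, nc), dtype=np.float64)
    rr, cc = np.mgrid[0:nr, 0:nc]
    for ei, elem in enumerate(elements):
        means = np.array(
            [config.region_element_means[r].get(elem, 0.0) for r in region_names]
        )
        f = means[region_idx].astype(np.float64)
        f += gaussian_random_field(
            rng, config.grid_shape, config.grf_length_scale_px, config.grf_sigma
        )
        for b_elem, (br, bc), radius, amp in config.hotspot_blobs:
            if b_elem != elem:
                continue
            d2 = (rr - br) ** 2 + (cc - bc) ** 2
            f += amp * np.exp(-d2 / (2.0 * (radius / 2.0) ** 2))
        f[~tissue] = 0.0
        f += np.abs(rng.normal(0.0, config.background_sigma, size=f.shape))
        clean[ei] = np.clip(f, 0.0, None)

    # --- artifact-injected copy: multiplicative row stripes + edge washout
    artifact = clean.copy()
    for row, att in config.stripe_spec:
        artifact[:, row, :] *= 1.0 - att
    if config.washout_depth_px > 0 and config.washout_fraction > 0:
        interior = scipy.ndimage.binary_erosion(
            tissue, iterations=config.washout_depth_px
        )
        band = tissue & ~interior
        artifact[:, band] *= 1.0 - config.washout_fraction

    emap_clean = ElementalMap(elements, clean, config.pixel_size_um)
    emap_artifact = ElementalMap(elements, artifact, config.pixel_size_um)

    # --- spot lattice in the µm frame, clipped to tissue
    H = coregister.Homography(np.asarray(config.true_homography, dtype=float))
    corners_px = np.array([[0, 0], [nc - 1, 0], [0, nr - 1], [nc - 1, nr - 1]], float)
    corners_um = coregister.transform_points(H, corners_px)
    x_lo, y_lo = corners_um.min(axis=0)
    x_hi, y_hi = corners_um.max(axis=0)
    xs = np.arange(x_lo, x_hi + 1e-9, config.spot_pitch_um)
    ys = np.arange(y_lo, y_hi + 1e-9, config.spot_pitch_um)
    gx, gy = np.meshgrid(xs, ys)
    centers_um = np.column_stack([gx.ravel(), gy.ravel()])
    centers_px = coregister.transform_points(H.inverse(), centers_um)
    col_i = np.round(centers_px[:, 0]).astype(int)
    row_i = np.round(centers_px[:, 1]).astype(int)
    inside = (
        (row_i >= 0) & (row_i < nr) & (col_i >= 0) & (col_i < nc)
    )
    inside[inside] &= tissue[row_i[inside], col_i[inside]]
    centers_um = centers_um[inside]
    spot_ids = [f"s{i:04d}" for i in range(len(centers_um))]
    spots = SpotLayout(
        pd.DataFrame(
            {"spot_id": spot_ids, "x_um": centers_um[:, 0], "y_um": centers_um[:, 1]}
        ),
        diameter_um=config.spot_diameter_um,
        pitch_um=config.spot_pitch_um,
    )

    # --- per-spot labels and clean aggregated element values
    spot_px = coregister.transform_points(H.inverse(), centers_um)
    lab_idx = region_idx[
        np.round(spot_px[:, 1]).astype(int), np.round(spot_px[:, 0]).astype(int)
    ]
    labels = pd.Series(
        [region_names[i] for i in lab_idx], index=spot_ids, name="label"
    )

    sem = coregister.aggregate_to_spots(
        emap_clean, TissueMask(tissue), spots, H, min_pixels=1
    )
    if len(sem.values) < len(spot_ids):
        # a rim spot can sit on tissue yet capture no pixel; drop it outright
        keep_ids = sem.values.index.tolist()
        keep_mask = np.isin(spot_ids, keep_ids)
        spots = SpotLayout(
            spots.table[keep_mask].reset_index(drop=True),
            diameter_um=config.spot_diameter_um,
            pitch_um=config.spot_pitch_um,
        )
        spot_ids = spots.spot_ids
        labels = labels.loc[spot_ids]
    spot_vals = sem.values.reindex(spot_ids)

    # --- gene programme: baselines + calibrated couplings on standardized
    #     clean spot-level element values
    baselines = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes) + 0.2
    gene_names = [f"G{i:04d}" for i in range(config.n_genes)]
    z_by_elem = {}
    for elem in elements:
        v = spot_vals[elem].to_numpy()
        z_by_elem[elem] = (v - v.mean()) / (v.std() or 1.0)

    couplings: dict[int, tuple[float, np.ndarray]] = {}
    truth_couplings = []
    gi = 0
    calib_rng = np.random.default_rng(rng.integers(2**31))
    for elem in elements:
        for _ in range(config.n_coupled_genes_per_element):
            if config.coupling_strength is not None:
                slope = config.coupling_strength
                target = None
            else:
                slope = calibrate_coupling_slope(
                    config.coupling_target_rho,
                    baselines[gi],
                    config.nb_dispersion,
                    z_by_elem[elem],
                    calib_rng,
                )
                target = config.coupling_target_rho
            couplings[gi] = (slope, z_by_elem[elem])
            truth_couplings.append(
                {
                    "gene": gene_names[gi],
                    "element": elem,
                    "target_spearman": target,
                    "slope": float(slope),
                }
            )
            gi += 1

    counts_arr = simulate_coupled_counts(
        rng, baselines, config.nb_dispersion, couplings, n_spots=len(spots)
    )
    counts = pd.DataFrame(
        counts_arr, index=pd.Index(spot_ids, name="spot_id"), columns=gene_names
    )

    # --- cell-type proportions: region alphas, element-modulated
    alphas = np.array(
        [config.celltype_alphas[labels.iloc[s]] for s in range(len(spots))],
        dtype=np.float64,
    )
    ct_index = {ct: i for i, ct in enumerate(CELL_TYPES)}
    for ct, elem, strength in config.celltype_element_coupling:
        alphas[:, ct_index[ct]] *= np.exp(strength * z_by_elem[elem])
    props = np.vstack([rng.dirichlet(a) for a in alphas])
    cell_props = pd.DataFrame(
        props, index=pd.Index(spot_ids, name="spot_id"), columns=list(CELL_TYPES)
    )

    # --- fiducial landmarks through the true homography
    lm_px = np.column_stack(
        [
            rng.uniform(0, nc - 1, size=config.n_landmarks),
            rng.uniform(0, nr - 1, size=config.n_landmarks),
        ]
    )
    lm_um = coregister.transform_points(H, lm_px)
    if config.landmark_noise_um > 0:
        lm_um = lm_um + rng.normal(0, config.landmark_noise_um, size=lm_um.shape)
    landmarks = pd.DataFrame(
        {
            "px_x": lm_px[:, 0],
            "px_y": lm_px[:, 1],
            "um_x": lm_um[:, 0],
            "um_y": lm_um[:, 1],
        }
    )

    truth = {
        "couplings": truth_couplings,
        "coupled_genes_by_element": {
            elem: [
                c["gene"] for c in truth_couplings if c["element"] == elem
            ]
            for elem in elements
        },
        "stripe_rows": [list(s) for s in config.stripe_spec],
        "blobs": [
            {"element": e, "center_px": list(c), "radius_px": r, "amplitude": a}
            for e, c, r, a in config.hotspot_blobs
        ],
        "true_homography": np.asarray(config.true_homography, float).tolist(),
        "region_seeds": {k: list(v) for k, v in config.region_seeds.items()},
        "celltype_element_coupling": [
            list(t) for t in config.celltype_element_coupling
        ],
        "washout": {
            "depth_px": config.washout_depth_px,
            "fraction": config.washout_fraction,
        },
    }

    return SyntheticDataset(
        config=config,
        elemental_artifact=emap_artifact,
        elemental_clean=emap_clean,
        tissue_mask_truth=tissue,
        spots=spots,
        counts=counts,
        labels=labels,
        cell_props=cell_props,
        spot_element_values=spot_vals,
        landmarks=landmarks,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Serialize every modality; returns a manifest {modality: filename}.

    All tables round-trip losslessly through the readers in
    :mod:`metalspot.elemental_io`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def put(key: str, name: str) -> Path:
        manifest[key] = name
        return outdir / name

    elemental_io.write_elemental_tiff(put("elemental", "elemental.tiff"), ds.elemental_artifact)
    elemental_io.write_elemental_tiff(
        put("elemental_clean", "elemental_clean.tiff"), ds.elemental_clean
    )
    iio.imwrite(
        put("tissue_mask", "tissue_mask.png"),
        (ds.tissue_mask_truth.astype(np.uint8) * 255),
    )
    elemental_io.write_mtx_expression(
        ds.counts,
        put("counts", "counts.mtx"),
        put("features", "features.tsv"),
        put("barcodes", "barcodes.tsv"),
    )
    ds.spots.table.to_csv(put("spots", "spots.csv"), index=False)
    ds.labels.rename_axis("spot_id").reset_index().to_csv(
        put("labels", "labels.csv"), index=False
    )
    ds.cell_props.to_csv(put("cellprops", "cellprops.csv"))
    ds.landmarks.to_csv(put("landmarks", "landmarks.csv"), index=False)
    with open(put("truth", "truth.json"), "w") as fh:
        json.dump(ds.truth, fh, indent=1)
    return manifest
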