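"""End-to-end orchestration: simulate → preprocess → coregister → hotspot →
association → metal-gene screen → enrichment, from a single YAML config.

Every stage communicates only through serialized artifacts in the output
directory, so any stage can be rerun from files.  A single global seed fans
out to per-stage seeds by stable hashing of the stage name, which keeps a
stage's randomness fixed when other stages are added or re-ordered.  The run
ends with a manifest mapping every artifact to its SHA-256 hash; a rerun
with the same config and seed reproduces all tabular outputs bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    association,
    coregister,
    elemental_io,
    enrichment,
    hotspot,
    metal_gene,
    preprocess,
    synthetic_data,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    outdir: str = "mst_run"
    seed: int = 0
    simulation: dict = field(default_factory=dict)    # SimulationConfig overrides
    element_deny: list = field(default_factory=list)
    # threshold_quantile approximates the background fraction of the frame;
    # the default synthetic tissue ellipse covers ~64% of the grid
    tissue: dict = field(
        default_factory=lambda: {
            "threshold_quantile": 0.35,
            "sigma_px": 2.0,
            "open_radius_px": 2,
            "close_radius_px": 2,
            "min_area_px": 64,
        }
    )
    stripes: dict = field(
        default_factory=lambda: {
            "diffusion_iters": 10,
            "hough_threshold": 10,
            "min_line_len_px": 40,
        }
    )
    erosion_depth_px: int = 3
    aggregation: dict = field(default_factory=lambda: {"min_pixels": 5})
    hotspot: dict = field(
        default_factory=lambda: {"radius_um": 100.0, "n_perm": 199}
    )
    label_propagation: dict = field(default_factory=lambda: {"k": 4})
    screen: dict = field(default_factory=lambda: {"alpha": 0.05, "top_k": 150})
    genesets: dict = field(
        default_factory=lambda: {"gmt": None, "n_decoy_sets": 20}
    )
    figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: crc32 of 'stage:global_seed', kept below 2^31."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def run_all(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the manifest dict.

    A stage failure aborts with the stage name in the raised error; artifacts
    written by earlier stages stay on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "config"
    try:
        # ------------------------------------------------ simulate + write
        stage = "simulate"
        sim_cfg = synthetic_data.SimulationConfig(
            seed=stage_seed(config.seed, "simulate"), **config.simulation
        )
        ds = synthetic_data.simulate_dataset(sim_cfg)
        data_dir = out / "data"
        data_manifest = synthetic_data.write_dataset(ds, data_dir)
        artifacts += [data_dir / v for v in data_manifest.values()]

        # ------------------------------------------------ load from files
        stage = "load"
        emap = elemental_io.read_elemental_tiff(
            data_dir / "elemental.tiff", pixel_size_um=sim_cfg.pixel_size_um
        )
        spots = elemental_io.read_spots_csv(
            data_dir / "spots.csv",
            diameter_um=sim_cfg.spot_diameter_um,
            pitch_um=sim_cfg.spot_pitch_um,
        )
        labels = elemental_io.read_labels_csv(data_dir / "labels.csv")
        cell_props = elemental_io.read_cellprops_csv(data_dir / "cellprops.csv")
        counts = elemental_io.read_mtx_expression(
            data_dir / "counts.mtx",
            data_dir / "features.tsv",
            data_dir / "barcodes.tsv",
            spots=spots,
        )
        landmarks = coregister.LandmarkSet.from_table(
            elemental_io.read_landmarks_csv(data_dir / "landmarks.csv")
        )
        if config.element_deny:
            emap = elemental_io.apply_element_filter(emap, config.element_deny)

        # ------------------------------------------------ preprocess
        stage = "preprocess"
        mask = preprocess.detect_tissue(emap, **config.tissue)
        emap_clean, stripe_report = preprocess.remove_stripes(
            emap, mask, seed=stage_seed(config.seed, "stripes"), **config.stripes
        )
        mask = preprocess.erode_edges(mask, config.erosion_depth_px)
        elemental_io.write_elemental_tiff(out / "elemental_corrected.tiff", emap_clean)
        import imageio.v3 as iio

        iio.imwrite(out / "tissue_mask.png", mask.mask.astype(np.uint8) * 255)
        with open(out / "stripe_report.json", "w") as fh:
            json.dump(
                {
                    "corrected": stripe_report.corrected,
                    "detected_lines": stripe_report.detected_lines,
                    "n_stripe_pixels": int(stripe_report.stripe_mask.sum()),
                    "params": stripe_report.params,
                    "mask_provenance": mask.provenance,
                },
                fh,
                indent=1,
            )
        artifacts += [
            out / "elemental_corrected.tiff",
            out / "tissue_mask.png",
            out / "stripe_report.json",
        ]

        # ------------------------------------------------ coregister
        stage = "coregister"
        h = coregister.estimate_homography(landmarks)
        with open(out / "homography.json", "w") as fh:
            json.dump({"H": h.H.tolist(), "rmse": h.rmse}, fh, indent=1)
        sem = coregister.aggregate_to_spots(
            emap_clean, mask, spots, h, **config.aggregation
        )
        sem_out = sem.values.copy()
        sem_out["pixel_count"] = sem.pixel_count
        _write_tsv(sem_out, out / "spot_elements.tsv", index=True)
        artifacts += [out / "homography.json", out / "spot_elements.tsv"]

        # ------------------------------------------------ hotspot
        stage = "hotspot"
        kept = spots.table["spot_id"].isin(sem.values.index).to_numpy()
        spots_kept = elemental_io.SpotLayout(
            spots.table[kept].reset_index(drop=True),
            diameter_um=spots.diameter_um,
            pitch_um=spots.pitch_um,
        )
        graph = hotspot.build_neighbors(
            spots_kept, radius_um=config.hotspot["radius_um"]
        )
        gi_table = hotspot.gi_star_table(
            sem.values.loc[spots_kept.spot_ids],
            graph,
            n_perm=config.hotspot.get("n_perm"),
            seed=stage_seed(config.seed, "hotspot"),
        )
        _write_tsv(gi_table, out / "gistar.tsv")
        artifacts.append(out / "gistar.tsv")
        gi_z = hotspot.gi_z_wide(gi_table)

        # ------------------------------------------------ association
        stage = "association"
        full_labels = association.propagate_labels(
            labels, spots_kept, k=config.label_propagation["k"]
        )
        arch = association.fit_architecture_model(gi_z, full_labels)
        _write_tsv(arch.emm, out / "emm.tsv")
        _write_tsv(arch.contrasts, out / "contrasts.tsv")
        ct = association.celltype_metal_correlation(cell_props, gi_z)
        _write_tsv(ct.rho, out / "celltype_corr.tsv", index=True)
        with open(out / "dendrogram_orders.json", "w") as fh:
            json.dump({"rows": ct.row_order, "cols": ct.col_order}, fh)
        artifacts += [
            out / "emm.tsv",
            out / "contrasts.tsv",
            out / "celltype_corr.tsv",
            out / "dendrogram_orders.json",
        ]

        # ------------------------------------------------ metal-gene screen
        stage = "metal_gene"
        normalized = metal_gene.normalize_expression(counts)
        alpha = config.screen["alpha"]
        top_k = config.screen["top_k"]
        corr_frames = []
        top_by_element: dict[str, metal_gene.TopGeneSets] = {}
        universe = list(normalized.columns)
        for elem in gi_z.columns:
            cr = metal_gene.correlate_genes(normalized, gi_z, elem, alpha=alpha)
            tgs = metal_gene.select_top_genes(cr, k=top_k)
            top_by_element[elem] = tgs
            tab = cr.table.reset_index()
            tab.insert(1, "element", elem)
            corr_frames.append(tab)
            for direction in ("positive", "negative", "magnitude"):
                path = out / f"topgenes_{elem}_{direction[:3]}.txt"
                path.write_text("\n".join(getattr(tgs, direction)) + "\n")
                artifacts.append(path)
        _write_tsv(pd.concat(corr_frames, ignore_index=True), out / "correlations.tsv")
        artifacts.append(out / "correlations.tsv")

        # ------------------------------------------------ enrichment
        stage = "enrichment"
        if config.genesets.get("gmt"):
            collection = enrichment.read_gmt(config.genesets["gmt"])
        else:
            collection = _truth_geneset_collection(
                data_dir / "truth.json",
                universe,
                n_decoys=config.genesets.get("n_decoy_sets", 20),
                seed=stage_seed(config.seed, "genesets"),
            )
            enrichment.write_gmt(collection, out / "genesets.gmt")
            artifacts.append(out / "genesets.gmt")
        enrich_tables = {}
        for elem, tgs in top_by_element.items():
            if not tgs.positive:
                logger.info("no significant positive genes for %s; skipping ORA", elem)
                continue
            res = enrichment.ora(tgs.positive, universe, collection)
            enrich_tables[elem] = res
            path = out / f"enrichment_{elem}_{collection.name}.tsv"
            _write_tsv(res, path)
            artifacts.append(path)

        if config.figures:
            stage = "figures"
            _make_figures(out, gi_z, full_labels, arch, ct, corr_frames)

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "artifacts": {
                str(p.relative_to(out)): _sha256(p) for p in artifacts if p.exists()
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def _truth_geneset_collection(
    truth_path: Path, universe: list[str], n_decoys: int, seed: int
) -> enrichment.GeneSetCollection:
    """Planted per-element gene programmes plus seeded decoy sets.

    Stands in for a curated pathway GMT when the run is fully synthetic: each
    planted coupling programme is one set, and ``n_decoys`` same-sized random
    draws from the tested universe act as negative controls.
    """
    with open(truth_path) as fh:
        truth = json.load(fh)
    sets: dict[str, list[str]] = {}
    for elem, genes in truth["coupled_genes_by_element"].items():
        if genes:
            sets[f"planted_{elem}"] = [g.upper() for g in genes]
    size = max((len(v) for v in sets.values()), default=10)
    rng = np.random.default_rng(seed)
    uni = np.array([g.upper() for g in universe])
    for i in range(n_decoys):
        sets[f"decoy_{i:02d}"] = list(rng.choice(uni, size=size, replace=False))
    return enrichment.GeneSetCollection("synthetic_truth", sets)


def _make_figures(out, gi_z, labels, arch, ct, corr_frames) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    elem = gi_z.columns[0]
    fig, ax = plt.subplots(figsize=(5, 4))
    lab = labels.reindex(gi_z.index)
    groups = sorted(lab.dropna().unique())
    ax.boxplot(
        [gi_z.loc[lab == g, elem] for g in groups], tick_labels=groups
    )
    ax.set_ylabel(f"Gi* z ({elem})")
    fig.tight_layout()
    fig.savefig(out / "boxplot_architecture.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    mat = ct.rho.fillna(0.0).to_numpy()[np.ix_(ct.row_order, ct.col_order)]
    im = ax.imshow(mat, cmap="coolwarm", vmin=-1, vmax=1)
    ax.set_xticks(range(len(ct.col_order)))
    ax.set_xticklabels([ct.rho.columns[i] for i in ct.col_order], rotation=90)
    ax.set_yticks(range(len(ct.row_order)))
    ax.set_yticklabels([ct.rho.index[i] for i in ct.row_order])
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(out / "celltype_heatmap.png", dpi=120)
    plt.close(fig)

    vt = corr_frames[0]
    fig, ax = plt.subplots(figsize=(5, 4))
    p = np.maximum(vt["p_raw"].to_numpy(), 1e-300)
    ax.scatter(vt["rho"], -np.log10(p), s=6, c=vt["significant"].map({True: "crimson", False: "grey"}))
    ax.set_xlabel("Spearman rho")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(out / "volcano.png", dpi=120)
    plt.close(fig)
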