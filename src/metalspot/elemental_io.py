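"""Readers and writers for elemental maps and the tabular spatial-omics inputs.

Conventions
-----------
Pixel coordinates are 0-based ``(row, col)`` with the origin at the top-left of
the map.  A pixel's physical position is ``x = col * pixel_size_um``,
``y = row * pixel_size_um``.  Elemental intensities are stored as 32-bit
floats; gene counts as integers.  Multi-channel elemental maps travel as
multi-page TIFF stacks, one page per element with the element name in the page
description.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import tifffile

logger = logging.getLogger(__name__)

MAP_PX = "map_px"
WSI_UM = "wsi_um"


@dataclass
class ElementalMap:
    """Per-isotope 2D intensity grids sharing one pixel geometry.

    Attributes
    ----------
    channels : list of str
        Ordered element names, one per grid.
    data : ndarray, shape (n_channels, rows, cols), float32
        Nonnegative intensities.
    pixel_size_um : float
        Edge length of a pixel in micrometres.
    frame : str
        Coordinate frame of the grid, ``"map_px"`` or ``"wsi_um"``.
    """

    channels: list[str]
    data: np.ndarray
    pixel_size_um: float
    frame: str = MAP_PX

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, rows, cols)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} grids"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        neg = int((self.data < 0).sum())
        if neg:
            logger.warning("clipping %d negative intensities to 0", neg)
            self.data = np.clip(self.data, 0.0, None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    def channel_sum(self) -> np.ndarray:
        """Total abundance across channels, the basis for tissue detection."""
        return self.data.sum(axis=0)


@dataclass
class SpotLayout:
    """Capture-spot centres in the whole-slide µm frame.

    ``table`` has columns ``spot_id, x_um, y_um``; ``diameter_um`` is the
    capture diameter (55 µm for Visium) and ``pitch_um`` the centre-to-centre
    distance between adjacent spots (~100 µm).
    """

    table: pd.DataFrame
    diameter_um: float = 55.0
    pitch_um: float = 100.0

    def __post_init__(self) -> None:
        required = {"spot_id", "x_um", "y_um"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"spot table missing columns: {sorted(missing)}")
        if self.table["spot_id"].duplicated().any():
            raise ValueError("spot_ids are not unique")
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")
        self.table = self.table.reset_index(drop=True)

    @property
    def spot_ids(self) -> list[str]:
        return self.table["spot_id"].tolist()

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x_um", "y_um"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


def write_elemental_tiff(path: str | Path, emap: ElementalMap) -> Path:
    """Write one TIFF page per channel, channel name in the page description."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for name, grid in zip(emap.channels, emap.data):
            tif.write(
                grid.astype(np.float32),
                description=name,
                metadata=None,
                contiguous=False,
            )
    return path


def read_elemental_tiff(path: str | Path, pixel_size_um: float = 5.0) -> ElementalMap:
    """Load a multi-page TIFF stack as an :class:`ElementalMap`.

    Channel order follows page order; each page must carry the element name in
    its description tag.  Pages of differing shape, or missing names, raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    channels: list[str] = []
    grids: list[np.ndarray] = []
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) < 1:
            raise ValueError(f"{path}: no pages")
        for i, page in enumerate(tif.pages):
            name = (page.description or "").strip()
            if not name:
                raise ValueError(f"{path}: page {i} has no element name")
            channels.append(name)
            grids.append(page.asarray())
    shapes = {g.shape for g in grids}
    if len(shapes) > 1:
        raise ValueError(f"{path}: pages differ in shape: {sorted(shapes)}")
    return ElementalMap(channels, np.stack(grids), pixel_size_um=pixel_size_um)


def apply_element_filter(emap: ElementalMap, deny: list[str]) -> ElementalMap:
    """Drop denied channels (order preserved); absent names are ignored.

    Post-hoc exclusion of unreliable or confounded isotopes is routine in
    elemental imaging; the deny-list travels in the pipeline config.
    """
    deny_set = set(deny)
    absent = deny_set - set(emap.channels)
    if absent:
        logger.info("deny-list names not present, ignored: %s", sorted(absent))
    keep = [i for i, c in enumerate(emap.channels) if c not in deny_set]
    if not keep:
        raise ValueError("element filter denies every channel")
    return ElementalMap(
        [emap.channels[i] for i in keep],
        emap.data[keep],
        pixel_size_um=emap.pixel_size_um,
        frame=emap.frame,
    )


# ---------------------------------------------------------------------------
# Tabular inputs


def read_spots_csv(path: str | Path, diameter_um: float = 55.0, pitch_um: float = 100.0) -> SpotLayout:
    table = pd.read_csv(path, dtype={"spot_id": str})
    return SpotLayout(table, diameter_um=diameter_um, pitch_um=pitch_um)


def read_labels_csv(path: str | Path) -> pd.Series:
    """Spot → architecture label, indexed by spot_id."""
    df = pd.read_csv(path, dtype=str)
    if not {"spot_id", "label"} <= set(df.columns):
        raise ValueError("labels CSV needs spot_id,label columns")
    return df.set_index("spot_id")["label"]

def read_cellprops_csv(path: str | Path) -> pd.DataFrame:
    """Spot × cell-type proportion table (rows on the probability simplex)."""
    df = pd.read_csv(path, dtype={"spot_id": str}).set_index("spot_id")
    return df.astype(float)


def read_landmarks_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"px_x", "px_y", "um_x", "um_y"}
    if not need <= set(df.columns):
        raise ValueError(f"landmarks CSV needs columns {sorted(need)}")
    return df.astype(float)


def read_mtx_expression(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    spots: SpotLayout | None = None,
) -> pd.DataFrame:
    """Read a genes × spots MTX triplet into a dense spots × genes count frame.

    If ``spots`` is given, rows are reordered to the layout's spot order; a
    barcode missing from the layout (or vice versa) is an error that names the
    offenders.
    """
    mat = scipy.io.mmread(str(mtx_path))
    genes = pd.read_csv(features_path, header=None, sep="\t")[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, header=None, sep="\t")[0].astype(str).tolist()
    dense = np.asarray(scipy.sparse.coo_matrix(mat).todense())
    if dense.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix is {dense.shape}, expected ({len(genes)}, {len(barcodes)})"
        )
    counts = pd.DataFrame(dense.T, index=pd.Index(barcodes, name="spot_id"), columns=genes)
    counts = counts.round().astype(np.int64)
    if spots is not None:
        want = spots.spot_ids
        unknown = sorted(set(barcodes) - set(want))
        missing = sorted(set(want) - set(barcodes))
        if unknown or missing:
            raise ValueError(
                f"barcode/spot mismatch: unknown barcodes {unknown[:5]}, "
                f"spots without counts {missing[:5]}"
            )
        counts = counts.loc[want]
    return counts


def write_mtx_expression(
    counts: pd.DataFrame, mtx_path: str | Path, features_path: str | Path, barcodes_path: str | Path
) -> None:
    """Write a spots × genes frame as a genes × spots integer MTX triplet."""
    sparse = scipy.sparse.coo_matrix(counts.to_numpy().T)
    scipy.io.mmwrite(str(mtx_path), sparse, field="integer")
    pd.Series(counts.columns).to_csv(features_path, header=False, index=False, sep="\t")
    pd.Series(counts.index).to_csv(barcodes_path, header=False, index=False, sep="\t")
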