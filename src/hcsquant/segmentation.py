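"""Per-cell nucleus and ER segmentation from DAPI and GRP94 staining.

The nucleus pipeline is deliberately classical: median background
subtraction, global Otsu threshold, hole filling, and a distance-transform
watershed to split touching nuclei, followed by area gating in um^2. Cells
are then delineated by a seeded watershed on the ER channel restricted to
the ER-positive region, so each cell's "ER mask" is the GRP94-positive
territory assigned to its nucleus, minus the nucleus itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import relabel_sequential, watershed

from .io import ChannelImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabelMap:
    """Integer label image (0 = background) with its physical pixel size."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.min() < 0:
            raise ValueError("labels must be a 2D non-negative integer grid")
        object.__setattr__(self, "labels", lab.astype(np.int32))

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class CellRecord:
    """One segmented cell: disjoint nucleus and ER pixel index sets."""

    cell_id: int
    nucleus_idx: np.ndarray = field(repr=False)
    er_idx: np.ndarray = field(repr=False)
    shape: tuple[int, int] = (0, 0)
    pixel_size_um: float = 1.0
    touches_border: bool = False

    def __post_init__(self):
        if len(self.nucleus_idx) and len(self.er_idx):
            if np.intersect1d(self.nucleus_idx, self.er_idx).size:
                raise ValueError(
                    f"cell {self.cell_id}: nucleus and ER masks overlap"
                )

    @property
    def nucleus_area_um2(self) -> float:
        return len(self.nucleus_idx) * self.pixel_size_um**2

    @property
    def er_area_um2(self) -> float:
        return len(self.er_idx) * self.pixel_size_um**2

    def nucleus_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool).ravel()
        m[self.nucleus_idx] = True
        return m.reshape(self.shape)

    def er_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool).ravel()
        m[self.er_idx] = True
        return m.reshape(self.shape)


def _background_subtract(img: np.ndarray) -> np.ndarray:
    return np.clip(img - np.median(img), 0.0, None)


def _otsu_mask(img: np.ndarray) -> np.ndarray:
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    return img > threshold_otsu(img)


def segment_nuclei(
    dapi: ChannelImage,
    min_area_um2: float = 40.0,
    max_area_um2: float = 400.0,
    declump_min_distance_um: float = 6.0,
    connectivity: int = 2,
) -> LabelMap:
    """Segment nuclei from the DAPI channel.

    Otsu threshold on the background-subtracted image, hole filling, then a
    distance-transform watershed with maxima at least
    ``declump_min_distance_um`` apart to separate touching nuclei. Objects
    outside [min_area_um2, max_area_um2] are removed; labels are relabeled
    sequentially. A blank image yields an empty map, not an error.
    """
    px = dapi.pixel_size_um
    img = _background_subtract(dapi.pixels)
    mask = _otsu_mask(img)
    if not mask.any():
        return LabelMap(np.zeros(img.shape, dtype=np.int32), px)
    mask = ndi.binary_fill_holes(mask)

    distance = ndi.distance_transform_edt(mask)
    min_dist_px = max(1, int(round(declump_min_distance_um / px)))
    peak_idx = peak_local_max(
        distance, min_distance=min_dist_px, labels=cc_label(mask, connectivity=connectivity)
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peak_idx, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers = cc_label(mask, connectivity=connectivity)
    labels = watershed(-distance, markers=markers, mask=mask)

    min_px = min_area_um2 / px**2
    max_px = max_area_um2 / px**2
    counts = np.bincount(labels.ravel())
    bad = np.flatnonzero((counts < min_px) | (counts > max_px))
    labels[np.isin(labels, bad[bad > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return LabelMap(labels, px)


def segment_cells(
    er: ChannelImage,
    nuclei: LabelMap,
    exclude_border_cells: bool = True,
) -> tuple[LabelMap, list[CellRecord]]:
    """Partition the GRP94-positive region among nuclei and build cells.

    The ER-positive region (Otsu on the background-subtracted ER channel,
    union the nuclei so every nucleus is inside its cell) is divided by a
    watershed seeded from the nucleus labels. Per cell, the ER pixel set is
    the assigned ER-positive territory minus its nucleus. Nuclei left with
    no ER pixels are dropped (counted in the log). ``touches_border`` marks
    cells with any pixel on the image edge; such cells are flagged here and
    excluded from scoring downstream when requested.
    """
    if er.shape != nuclei.labels.shape:
        raise ValueError("ER image and nucleus label map shapes differ")
    px = er.pixel_size_um
    img = _background_subtract(er.pixels)
    er_positive = _otsu_mask(img)
    region = er_positive | (nuclei.labels > 0)
    cells = watershed(-img, markers=nuclei.labels, mask=region)

    records: list[CellRecord] = []
    dropped = 0
    border = np.zeros(er.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    out_labels = np.zeros(er.shape, dtype=np.int32)
    for cid in nuclei.ids():
        cell_mask = cells == cid
        nuc_mask = nuclei.labels == cid
        er_mask = cell_mask & er_positive & ~nuc_mask
        if not er_mask.any():
            dropped += 1
            continue
        touches = bool((cell_mask & border).any())
        rec = CellRecord(
            cell_id=int(cid),
            nucleus_idx=np.flatnonzero(nuc_mask),
            er_idx=np.flatnonzero(er_mask),
            shape=er.shape,
            pixel_size_um=px,
            touches_border=touches,
        )
        if exclude_border_cells and touches:
            continue
        records.append(rec)
        out_labels[cell_mask] = cid
    if dropped:
        logger.warning("%d nuclei dropped for lack of surrounding ER signal", dropped)
    return LabelMap(out_labels, px), records
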