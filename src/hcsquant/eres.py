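"""ER exit-site (ERES) detection and within-object colocalization.

An ERES is operationally a punctum positive for both the COPII outer-coat
marker Sec31A and the scaffold Sec16. The two channels are multiplied after
per-channel median background subtraction (clamped at zero) so that only
double-positive pixels are non-zero, objects are found by automatic (Otsu)
thresholding with intensity-based declumping, gated to equivalent diameters
of 0.167-1.67 um, and the original (unprocessed) channels are then measured
inside each object. Colocalization is a pixelwise Pearson correlation over
a cell's pooled ERES pixels, computed per z-slice and aggregated per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

from .io import ChannelImage, ConfigurationError
from .segmentation import LabelMap

logger = logging.getLogger(__name__)

MEASURED_CHANNELS = ("sec31a", "sec16", "atf6", "er")


@dataclass
class ERESObject:
    """One Sec31A x Sec16 double-positive punctum."""

    object_id: int
    slice_index: int
    pixel_idx: np.ndarray = dc_field(repr=False, default=None)
    shape: tuple[int, int] = (0, 0)
    centroid_rc: tuple[float, float] = (0.0, 0.0)
    equivalent_diameter_um: float = 0.0
    cell_id: int = 0          # 0 = unassigned / background
    mean_intensity: dict = dc_field(default_factory=dict)


@dataclass
class CellCorrelation:
    cell_id: int
    r_per_slice: list[float]
    n_pixels_used: int
    n_eres: int

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.r_per_slice))

    @property
    def sd_r(self) -> float:
        return float(np.std(self.r_per_slice, ddof=1)) if len(self.r_per_slice) > 1 else 0.0


def product_image(sec31a: ChannelImage, sec16: ChannelImage) -> ChannelImage:
    """Pixelwise Sec31A x Sec16 product after median background subtraction.

    Each channel has its median subtracted and negatives clamped to zero
    before multiplying, so the product is non-zero only where both channels
    carry above-background fluorescence.
    """
    if sec31a.shape != sec16.shape:
        raise ValueError("Sec31A and Sec16 images have different shapes")
    a = np.clip(sec31a.pixels - np.median(sec31a.pixels), 0.0, None)
    b = np.clip(sec16.pixels - np.median(sec16.pixels), 0.0, None)
    return ChannelImage(
        pixels=a * b,
        pixel_size_um=sec31a.pixel_size_um,
        channel="product",
        slice_index=sec31a.slice_index,
        well_id=sec31a.well_id,
        field_id=sec31a.field_id,
    )


def detect_eres(
    product: ChannelImage,
    d_min_um: float = 0.167,
    d_max_um: float = 1.67,
    threshold_method: str = "otsu",
    declump_min_distance_px: int = 3,
    declump_smooth_sigma_px: float | None = None,
    footprint_fraction: float = 0.25,
) -> list[ERESObject]:
    """Detect size-gated puncta on the product image.

    Detection: automatic global threshold, connected components, and an
    intensity-maxima seeded watershed to split clumped puncta (seeds are
    found on a lightly smoothed copy, sigma defaulting to a quarter of the
    upper diameter gate, so pixel noise cannot shatter one punctum into
    several fragments).

    Sizing: each object's footprint is re-measured at ``footprint_fraction``
    of its own peak in the product image. The default 0.25 is the
    single-channel half-maximum — the product of two like spots squares the
    profile — so the reported equivalent diameter estimates the punctum's
    FWHM on the channel scale, independent of where the global threshold
    happened to fall. Objects whose footprints coincide (a noise-split
    punctum) are merged. The [d_min_um, d_max_um] gate applies to these
    calibrated diameters.
    """
    px = product.pixel_size_um
    if d_min_um / px < 1.0:
        raise ValueError("d_min_um spans < 1 pixel at this pixel size")
    img = product.pixels
    if img.max() <= 0:
        return []
    if threshold_method == "otsu":
        thr = threshold_otsu(img)
    elif threshold_method == "mean":
        thr = img.mean()
    else:
        raise ConfigurationError(f"unknown threshold method {threshold_method!r}")
    mask = img > thr
    if not mask.any():
        return []

    components = cc_label(mask, connectivity=2)
    if declump_smooth_sigma_px is None:
        declump_smooth_sigma_px = 0.25 * d_max_um / px
    seed_img = ndi.gaussian_filter(img, declump_smooth_sigma_px)
    # intensity maxima as declumping seeds; a connected plateau of tied
    # maxima (e.g. a saturated or flat-topped spot) collapses to one seed so
    # uniform objects are never fragmented
    size = 2 * declump_min_distance_px + 1
    maxima = (seed_img == ndi.maximum_filter(seed_img, size=size)) & mask
    markers, n_markers = ndi.label(maxima)
    labels = (
        watershed(-seed_img, markers=markers, mask=mask) if n_markers else components
    )

    objects = []
    seen: set = set()
    oid = 0
    for prop in regionprops(labels):
        coords = prop.coords
        in_obj = seed_img[coords[:, 0], coords[:, 1]]
        seed_rc = coords[int(in_obj.argmax())]
        peak = img[seed_rc[0], seed_rc[1]]
        if peak <= 0:
            continue
        footprint = _grow_footprint(
            img, seed_rc, footprint_fraction * peak, prop, pad=8
        )
        key = (int(footprint.min()), int(footprint.size))
        if key in seen:  # same punctum reached from a second (noise) seed
            continue
        seen.add(key)
        d_um = 2.0 * np.sqrt(footprint.size / np.pi) * px
        if not (d_min_um <= d_um <= d_max_um):
            continue
        oid += 1
        rows, cols = np.unravel_index(footprint, img.shape)
        objects.append(
            ERESObject(
                object_id=oid,
                slice_index=product.slice_index,
                pixel_idx=footprint,
                shape=img.shape,
                centroid_rc=(float(rows.mean()), float(cols.mean())),
                equivalent_diameter_um=float(d_um),
            )
        )
    assert all(d_min_um <= o.equivalent_diameter_um <= d_max_um for o in objects)
    return objects


def _grow_footprint(img, seed_rc, level, prop, pad: int = 8) -> np.ndarray:
    """Raveled indices of the connected region >= ``level`` around the seed,
    searched in a window around the object's bounding box."""
    minr, minc, maxr, maxc = prop.bbox
    extra = max(pad, int(2 * prop.equivalent_diameter_area))
    r0, c0 = max(0, minr - extra), max(0, minc - extra)
    r1 = min(img.shape[0], maxr + extra)
    c1 = min(img.shape[1], maxc + extra)
    local = img[r0:r1, c0:c1] >= level
    lab, _ = ndi.label(local, structure=np.ones((3, 3), dtype=int))
    comp = lab == lab[seed_rc[0] - r0, seed_rc[1] - c0]
    rows, cols = np.nonzero(comp)
    return np.sort((rows + r0) * img.shape[1] + (cols + c0))


def assign_to_cells(objects: list[ERESObject], cells: LabelMap) -> list[ERESObject]:
    """Attach each object to the cell containing its centroid (0 = none)."""
    lab = cells.labels
    for obj in objects:
        r, c = (int(round(x)) for x in obj.centroid_rc)
        r = min(max(r, 0), lab.shape[0] - 1)
        c = min(max(c, 0), lab.shape[1] - 1)
        obj.cell_id = int(lab[r, c])
    return objects


def measure_eres(
    objects: list[ERESObject], channels: dict[str, ChannelImage]
) -> list[ERESObject]:
    """Fill per-object mean intensities from the original channels."""
    missing = [c for c in MEASURED_CHANNELS if c in channels] or None
    if missing is None:
        raise ConfigurationError("no measurable channels supplied")
    flats = {name: ch.pixels.ravel() for name, ch in channels.items()}
    for obj in objects:
        obj.mean_intensity = {
            name: float(flat[obj.pixel_idx].mean()) for name, flat in flats.items()
        }
    return objects


def correlate_within_eres(
    objects: list[ERESObject],
    channel_a: ChannelImage,
    channel_b: ChannelImage,
    mode: str = "pooled",
    min_pixels: int = 3,
) -> float | None:
    """Pearson correlation of two channels over a cell's ERES pixels.

    ``pooled`` concatenates the pixels of all supplied objects (one cell,
    one slice) into a single pair of vectors; ``per_object`` averages the
    per-object correlations instead (small spots make this noisy, hence not
    the default). Returns None when fewer than ``min_pixels`` pixels are
    available or either channel is constant on them — callers count such
    skipped slices.
    """
    if not objects:
        return None
    a_flat = channel_a.pixels.ravel()
    b_flat = channel_b.pixels.ravel()

    def pearson(idx):
        a, b = a_flat[idx], b_flat[idx]
        if idx.size < min_pixels or a.std() == 0 or b.std() == 0:
            return None
        return float(np.corrcoef(a, b)[0, 1])

    if mode == "pooled":
        return pearson(np.concatenate([o.pixel_idx for o in objects]))
    if mode == "per_object":
        rs = [r for r in (pearson(o.pixel_idx) for o in objects) if r is not None]
        return float(np.mean(rs)) if rs else None
    raise ValueError(f"unknown correlation mode {mode!r}")


def aggregate_correlations(
    r_by_cell_slice: dict[int, list[float | None]],
) -> list[CellCorrelation]:
    """Per-cell mean and SD of the per-slice correlations.

    ``r_by_cell_slice`` maps cell_id -> per-slice r values (None for
    undefined slices, which are skipped and counted); cells with no valid
    slice are excluded with a logged count.
    """
    out = []
    excluded = 0
    for cell_id, rs in sorted(r_by_cell_slice.items()):
        valid = [r for r in rs if r is not None]
        if not valid:
            excluded += 1
            continue
        out.append(
            CellCorrelation(
                cell_id=cell_id, r_per_slice=valid, n_pixels_used=0, n_eres=0
            )
        )
    if excluded:
        logger.warning("%d cells excluded with no valid correlation slice", excluded)
    return out


def treatment_correlation_table(
    cell_correlations: dict[str, list[CellCorrelation]],
) -> pd.DataFrame:
    """Treatment-level table of per-cell mean r (the quantity plotted per
    condition), plus the experiment-level mean of per-cell means."""
    rows = []
    for treatment, cells in cell_correlations.items():
        means = np.array([c.mean_r for c in cells])
        rows.append(
            {
                "treatment": treatment,
                "n_cells": len(cells),
                "mean_r": float(means.mean()),
                "sd_r": float(means.std(ddof=1)) if len(means) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def count_eres_per_cell(objects: list[ERESObject]) -> pd.DataFrame:
    """Number of retained ERES per cell (summed over slices; cell 0, i.e.
    unassigned objects, excluded)."""
    counts: dict[int, int] = {}
    for obj in objects:
        if obj.cell_id == 0:
            continue
        counts[obj.cell_id] = counts.get(obj.cell_id, 0) + 1
    return pd.DataFrame(
        [{"cell_id": k, "n_eres": v} for k, v in sorted(counts.items())]
    )


def analyze_eres_field(
    channels_by_slice: dict[int, dict[str, ChannelImage]],
    cells: LabelMap,
    d_min_um: float = 0.167,
    d_max_um: float = 1.67,
    channel_pair: tuple[str, str] = ("atf6", "sec31a"),
    mode: str = "pooled",
) -> tuple[list[ERESObject], list[CellCorrelation]]:
    """Run the full per-field ERES pipeline slice by slice.

    For each z-slice: product mask, detection, size gate, cell assignment,
    intensity measurement, and per-cell pooled correlation of
    ``channel_pair`` (GFP-ATF6 vs. Sec31A by default); correlations are then
    aggregated across slices per cell.
    """
    all_objects: list[ERESObject] = []
    r_by_cell: dict[int, list[float | None]] = {}
    for z in sorted(channels_by_slice):
        chans = channels_by_slice[z]
        prod = product_image(chans["sec31a"], chans["sec16"])
        objs = detect_eres(prod, d_min_um=d_min_um, d_max_um=d_max_um)
        assign_to_cells(objs, cells)
        measure_eres(objs, chans)
        all_objects.extend(objs)
        by_cell: dict[int, list[ERESObject]] = {}
        for o in objs:
            if o.cell_id:
                by_cell.setdefault(o.cell_id, []).append(o)
        for cid, objs_c in by_cell.items():
            r = correlate_within_eres(
                objs_c, chans[channel_pair[0]], chans[channel_pair[1]], mode=mode
            )
            r_by_cell.setdefault(cid, []).append(r)
    return all_objects, aggregate_correlations(r_by_cell)
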