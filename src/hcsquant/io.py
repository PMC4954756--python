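"""Reading and writing of multichannel microscopy fields and result tables.

Conventions used throughout the package:

* images are row-major 2D arrays, origin top-left, pixel centers at integer
  coordinates;
* all physical sizes are in micrometers, converted via ``pixel_size_um``;
* intensities are held as float64 regardless of the on-disk bit depth
  (the downstream statistics are ratio- and correlation-based, so the
  integer scale of the camera is irrelevant).
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

#: channel identities the pipeline knows about. "product" is the derived
#: Sec31A x Sec16 channel created by the colocalization stage.
CHANNELS = ("dapi", "er", "atf6", "sec31a", "sec16", "golgi", "product")

WELL_ROLES = ("unstressed_control", "stressed_control", "test")


class ConfigurationError(ValueError):
    """A required configuration entry is missing or inconsistent."""


class FormatError(ValueError):
    """An input file violates the expected image format contract."""


@dataclass(frozen=True)
class ChannelImage:
    """One 2D fluorescence slice of one channel of one field."""

    pixels: np.ndarray
    pixel_size_um: float
    channel: str
    slice_index: int = 0
    well_id: str = ""
    field_id: int = 0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise FormatError(f"pixels must be 2D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise FormatError("pixel intensities must be finite")
        if px.min() < 0:
            raise FormatError("pixel intensities must be non-negative")
        if not (self.pixel_size_um > 0):
            raise FormatError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.channel not in CHANNELS:
            raise ConfigurationError(
                f"unknown channel {self.channel!r}; expected one of {CHANNELS}"
            )
        if self.slice_index < 0:
            raise FormatError("slice_index must be >= 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class WellInfo:
    role: str
    treatment: str = ""
    replicate_group: str = ""

    def __post_init__(self):
        if self.role not in WELL_ROLES:
            raise ConfigurationError(
                f"unknown well role {self.role!r}; expected one of {WELL_ROLES}"
            )


@dataclass
class PlateLayout:
    """Mapping of well ids to assay roles (controls vs. test compounds)."""

    wells: dict[str, WellInfo] = field(default_factory=dict)

    def wells_with_role(self, role: str) -> list[str]:
        return sorted(w for w, info in self.wells.items() if info.role == role)

    def require_controls(self) -> None:
        """Threshold derivation needs at least one well pair of controls."""
        for role in ("unstressed_control", "stressed_control"):
            if not self.wells_with_role(role):
                raise ConfigurationError(f"plate layout has no {role} well")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlateLayout":
        wells = {}
        for well_id, info in d.items():
            if well_id in wells:
                raise ConfigurationError(f"duplicate well id {well_id!r}")
            if isinstance(info, str):
                info = {"role": info}
            wells[str(well_id)] = WellInfo(
                role=info["role"],
                treatment=info.get("treatment", ""),
                replicate_group=info.get("replicate_group", ""),
            )
        return cls(wells)

    @classmethod
    def from_yaml(cls, path) -> "PlateLayout":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "wells" in doc:
            doc = doc["wells"]
        return cls.from_dict(doc)


def load_config(path) -> dict:
    """Load a YAML analysis config, merged over the package defaults."""
    from .config import default_config, merge_config

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(default_config(), user)


def _ome_pixel_size(tf: tifffile.TiffFile) -> float | None:
    xml = tf.ome_metadata
    if not xml:
        return None
    m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', xml)
    return float(m.group(1)) if m else None


def read_field(
    path,
    config: Mapping,
    well_id: str = "",
    field_id: int = 0,
) -> list[ChannelImage]:
    """Read one multichannel (optionally multi-slice) TIFF field.

    ``config`` must contain ``channels`` (ordered channel names matching the
    file's channel axis) and may contain ``pixel_size_um`` which, when set,
    overrides any OME metadata (a warning is logged if both are present and
    disagree).

    Returns one :class:`ChannelImage` per channel per z-slice, intensities
    preserved bit-exactly (as float64).
    """
    channels: Sequence[str] = config["channels"]
    if not channels:
        raise ConfigurationError("config['channels'] is empty")

    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta_px = _ome_pixel_size(tf)

    override = config.get("pixel_size_um")
    if override is not None:
        if meta_px is not None and not np.isclose(meta_px, override):
            logger.warning(
                "pixel size override %.4g um takes precedence over file metadata %.4g um (%s)",
                override, meta_px, path,
            )
        pixel_size = float(override)
    elif meta_px is not None:
        pixel_size = meta_px
    else:
        raise ConfigurationError(
            f"no pixel size in {path} metadata and no config override"
        )
    if pixel_size <= 0:
        raise FormatError(f"non-positive pixel size {pixel_size}")

    # Normalize to (Z, C, Y, X). Unknown axis labels ('Q', 'S', 'I') of the
    # right length are taken as the channel axis.
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        ax0 = axes[0] if axes else "?"
        if ax0 == "C" or (ax0 not in "ZT" and data.shape[0] == len(channels)):
            data = data[None, :]
        else:  # leading axis is z/time
            data = data[:, None]
            if len(channels) != 1:
                raise ConfigurationError(
                    f"{path}: file has 1 channel axis entry but config lists "
                    f"{len(channels)} channels"
                )
    elif data.ndim == 4:
        if axes.startswith("CZ"):
            data = np.swapaxes(data, 0, 1)
    else:
        raise FormatError(f"unsupported TIFF dimensionality {data.ndim}")

    n_slices, n_chan = data.shape[:2]
    if n_chan != len(channels):
        raise ConfigurationError(
            f"{path}: file has {n_chan} channels, config maps {len(channels)}"
        )

    images = []
    for z in range(n_slices):
        for c, name in enumerate(channels):
            images.append(
                ChannelImage(
                    pixels=data[z, c],
                    pixel_size_um=pixel_size,
                    channel=name,
                    slice_index=z,
                    well_id=well_id,
                    field_id=field_id,
                )
            )
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise FormatError(f"{path}: channels have mismatched shapes {shapes}")
    return images


def write_field(images: Sequence[ChannelImage], path) -> None:
    """Write a field as an OME-TIFF with axes ZCYX.

    Integer-valued data that fits in 16 bits is stored as uint16 so a
    write-then-read round trip is lossless; anything else is float32.
    """
    slices = sorted({im.slice_index for im in images})
    chans = []
    for im in images:
        if im.channel not in chans:
            chans.append(im.channel)
    shape = images[0].shape
    px = images[0].pixel_size_um
    stack = np.zeros((len(slices), len(chans)) + shape, dtype=np.float64)
    for im in images:
        if im.shape != shape or im.pixel_size_um != px:
            raise FormatError("all channels of one field must share shape and pixel size")
        stack[slices.index(im.slice_index), chans.index(im.channel)] = im.pixels
    if np.all(stack == np.round(stack)) and stack.max() < 2**16:
        stack = stack.astype(np.uint16)
    else:
        stack = stack.astype(np.float32)
    # content-derived UUID keeps same-seed plate outputs byte-identical
    digest = hashlib.md5(stack.tobytes()).hexdigest()
    uuid = (
        f"urn:uuid:{digest[:8]}-{digest[8:12]}-{digest[12:16]}-"
        f"{digest[16:20]}-{digest[20:32]}"
    )
    tifffile.imwrite(
        str(path),
        stack,
        ome=True,
        metadata={
            "axes": "ZCYX",
            "UUID": uuid,
            "PhysicalSizeX": px,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": px,
            "PhysicalSizeYUnit": "µm",
            "Channel": {"Name": chans},
        },
    )


def write_labels(labels: np.ndarray, path) -> None:
    """Write a label map as a 16-bit label TIFF."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= 2**16:
        raise FormatError("labels must fit in uint16")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def write_table(rows, path) -> None:
    """Write tabular results as CSV with stable column names.

    Accepts a DataFrame, a sequence of dataclasses, or a sequence of dicts.
    Floats keep >= 10 significant digits. An empty sequence of dataclasses
    yields a header-only file when a prototype row type cannot be inferred;
    pass a DataFrame with columns for a guaranteed header.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        records = [asdict(r) if is_dataclass(r) else dict(r) for r in rows]
        df = pd.DataFrame.from_records(records)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
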