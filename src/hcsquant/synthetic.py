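"""Synthetic multichannel fluorescence fields with known ground truth.

The generator emulates the statistical structure of the two imaging assays
the pipeline quantifies:

* a *translocation* scene: U2-OS-like cells rendered as a nuclear disk
  (DAPI) inside an ER annulus (GRP94), with an ATF6 channel whose signal is
  split between nucleus and ER so that the per-cell mean nuclear : mean ER
  ratio equals a known ``true_ratio`` drawn from a lognormal mixture of
  "inactive" (ER-retained) and "activated" (nuclear) cells;
* an *ERES* scene: diffraction-limited puncta rendered as 2D Gaussian spots
  (FWHM = nominal diameter) in the Sec31A and Sec16 channels with a
  controllable co-occurrence fraction, and an ATF6 channel whose pixel
  values inside double-positive puncta are mixed with the Sec31A profile so
  that their within-puncta Pearson correlation has a set expectation
  ``target_rho`` (Gaussian copula mixing).

Photon (Poisson) shot noise and additive Gaussian read noise are applied
last and can be disabled, in which case the construction identities (exact
ratio, exact correlation at rho = +/-1, exact counts) hold to rounding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ChannelImage, PlateLayout, write_field, write_table

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class GenerationError(RuntimeError):
    """Raised when a scene cannot be realized (e.g. infeasible cell density)."""


@dataclass(frozen=True)
class RatioParams:
    """Lognormal parameters of the per-cell true nuclear:ER ratio.

    ``inactive_mean`` / ``active_mean`` are the medians of the two mixture
    components; ``lognormal_sd`` is the standard deviation of log-ratio.
    """

    inactive_mean: float = 0.8
    active_mean: float = 2.5
    lognormal_sd: float = 0.25


@dataclass(frozen=True)
class EresParams:
    n_puncta_per_cell: int = 15
    diameter_range_um: tuple[float, float] = (0.3, 1.4)
    coloc_fraction: float = 0.8
    target_rho: float = 0.5
    n_slices: int = 1
    peak_intensity: float = 200.0
    peak_cv: float = 0.25           # lognormal CV of per-punctum peak
    atf6_mean: float = 150.0
    atf6_sd: float = 30.0
    min_separation_um: float = 1.2


@dataclass(frozen=True)
class NoiseParams:
    """photon_scale = expected photons per intensity unit (None/0 = no shot
    noise); read_sd = additive Gaussian read noise, intensity units."""

    photon_scale: float | None = 1.0
    read_sd: float = 2.0

    @property
    def enabled(self) -> bool:
        return bool(self.photon_scale) or self.read_sd > 0


@dataclass(frozen=True)
class SceneSpec:
    field_shape_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.8
    n_cells: int = 8
    activated_fraction: float = 0.02
    ratio_params: RatioParams = field(default_factory=RatioParams)
    nucleus_diameter_um: float = 12.0
    cell_diameter_um: float = 26.0
    eres: EresParams = field(default_factory=EresParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0
    # rendering intensities (camera units before noise)
    background: float = 5.0
    dapi_intensity: float = 300.0
    er_intensity: float = 200.0
    atf6_er_intensity: float = 100.0

    def __post_init__(self):
        if not 0.0 <= self.activated_fraction <= 1.0:
            raise ValueError("activated_fraction must be in [0, 1]")
        if not 0.0 <= self.eres.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if not -1.0 <= self.eres.target_rho <= 1.0:
            raise ValueError("target_rho must be in [-1, 1]")
        if not self.nucleus_diameter_um < self.cell_diameter_um:
            raise ValueError("nucleus_diameter_um must be < cell_diameter_um")


def translocation_scene(**overrides) -> SceneSpec:
    """Default scene for the 20x nuclear-translocation assay (0.8 um/px)."""
    return SceneSpec(**overrides)


def eres_scene(**overrides) -> SceneSpec:
    """Default scene for the 100x ERES assay (0.11 um/px, 1-2 cells/field)."""
    defaults = dict(
        field_shape_px=(512, 512),
        pixel_size_um=0.11,
        n_cells=2,
        nucleus_diameter_um=10.0,
        cell_diameter_um=22.0,
    )
    defaults.update(overrides)
    return SceneSpec(**defaults)


@dataclass
class CellTruth:
    cell_id: int
    activated: bool
    true_ratio: float
    center_rc: tuple[float, float]
    border: bool = False


@dataclass
class PunctumTruth:
    punctum_id: int
    cell_id: int
    slice_index: int
    center_rc: tuple[float, float]
    diameter_um: float
    in_both_channels: bool
    pixel_idx: np.ndarray = field(repr=False, default=None)


@dataclass
class GroundTruth:
    """Everything the generator knows about a field, for oracle-based tests."""

    cells: list[CellTruth]
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    puncta: list[PunctumTruth] = field(default_factory=list)
    target_rho: float | None = None
    pixel_size_um: float = 1.0

    def nucleus_mask(self, cell_id: int) -> np.ndarray:
        return self.nucleus_labels == cell_id

    def er_mask(self, cell_id: int) -> np.ndarray:
        return (self.cell_labels == cell_id) & (self.nucleus_labels != cell_id)

    def activated_fraction(self) -> float:
        return float(np.mean([c.activated for c in self.cells]))


# ---------------------------------------------------------------------------
# building blocks


def _place_cells(
    rng: np.random.Generator,
    shape: tuple[int, int],
    radius_px: float,
    n: int,
    max_attempts_per_cell: int = 2000,
) -> np.ndarray:
    """Non-overlapping cell centers, fully inside the field, by rejection."""
    lo = radius_px + 1
    hi_r, hi_c = shape[0] - radius_px - 1, shape[1] - radius_px - 1
    if hi_r <= lo or hi_c <= lo:
        raise GenerationError("cell diameter exceeds the field")
    centers: list[tuple[float, float]] = []
    for _ in range(n):
        for _attempt in range(max_attempts_per_cell):
            r = rng.uniform(lo, hi_r)
            c = rng.uniform(lo, hi_c)
            if all((r - r0) ** 2 + (c - c0) ** 2 >= (2 * radius_px + 2) ** 2
                   for r0, c0 in centers):
                centers.append((r, c))
                break
        else:
            raise GenerationError(
                f"could not place cell {len(centers) + 1}/{n}; density infeasible"
            )
    return np.array(centers)


def _disk_mask(shape, center, radius_px) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def sample_activation(rng, n_cells: int, activated_fraction: float) -> np.ndarray:
    return rng.random(n_cells) < activated_fraction


def sample_true_ratios(rng, activated: np.ndarray, params: RatioParams) -> np.ndarray:
    """Per-cell true nuclear:ER ratios: lognormal around the component median."""
    medians = np.where(activated, params.active_mean, params.inactive_mean)
    return medians * np.exp(params.lognormal_sd * rng.standard_normal(len(activated)))


def sample_well_ratios(
    rng, n_cells: int, activated_fraction: float, params: RatioParams
) -> tuple[np.ndarray, np.ndarray]:
    """Fast statistical path: draw the per-cell ratio population of one well
    directly from the same mixture the image renderer uses."""
    activated = sample_activation(rng, n_cells, activated_fraction)
    return sample_true_ratios(rng, activated, params), activated


def apply_noise(pixels: np.ndarray, noise: NoiseParams, rng) -> np.ndarray:
    out = np.asarray(pixels, dtype=np.float64)
    if noise.photon_scale:
        out = rng.poisson(out * noise.photon_scale) / noise.photon_scale
    if noise.read_sd > 0:
        out = out + rng.normal(0.0, noise.read_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def noise_for_snr(
    foreground: float, background: float, snr: float, read_sd: float = 0.0
) -> NoiseParams:
    """Noise parameters giving (fg - bg) / sigma(fg) = snr at intensity fg."""
    sd_target = (foreground - background) / snr
    var_shot = sd_target**2 - read_sd**2
    if var_shot <= 0:
        raise ValueError("read_sd alone already exceeds the target noise")
    return NoiseParams(photon_scale=foreground / var_shot, read_sd=read_sd)


#: spot support radius in sigmas; exp(-2.146^2 / 2) ~ 0.1, i.e. the rendered
#: Gaussian is truncated at 10% of peak so well-separated puncta in
#: different channels never overlap in the product image
SPOT_CUTOFF_SIGMA = np.sqrt(2.0 * np.log(10.0))


def _add_gaussian_spot(img, center, sigma_px, amplitude):
    half = max(2, int(np.ceil(SPOT_CUTOFF_SIGMA * sigma_px)) + 1)
    r0, c0 = int(round(center[0])), int(round(center[1]))
    rlo, rhi = max(0, r0 - half), min(img.shape[0], r0 + half + 1)
    clo, chi = max(0, c0 - half), min(img.shape[1], c0 + half + 1)
    rr = np.arange(rlo, rhi)[:, None] - center[0]
    cc = np.arange(clo, chi)[None, :] - center[1]
    d2 = rr**2 + cc**2
    spot = amplitude * np.exp(-d2 / (2.0 * sigma_px**2))
    spot[d2 > (SPOT_CUTOFF_SIGMA * sigma_px) ** 2] = 0.0
    img[rlo:rhi, clo:chi] += spot


# ---------------------------------------------------------------------------
# field generators


def _base_cells(spec: SceneSpec, rng):
    shape = spec.field_shape_px
    cell_r = spec.cell_diameter_um / 2 / spec.pixel_size_um
    nuc_r = spec.nucleus_diameter_um / 2 / spec.pixel_size_um
    centers = _place_cells(rng, shape, cell_r, spec.n_cells)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)
    for i, ctr in enumerate(centers, start=1):
        cell_labels[_disk_mask(shape, ctr, cell_r)] = i
        nucleus_labels[_disk_mask(shape, ctr, nuc_r)] = i
    return centers, nucleus_labels, cell_labels


def generate_translocation_field(
    spec: SceneSpec, well_id: str = "", field_id: int = 0
) -> tuple[list[ChannelImage], GroundTruth]:
    """Render one DAPI / ER / ATF6 field with known per-cell activation.

    Before noise, the mean ATF6 intensity over the true nucleus mask divided
    by the mean over the true ER mask equals each cell's ``true_ratio``
    exactly (the ATF6 background is confined to outside the cells).
    """
    rng = np.random.default_rng(spec.seed)
    centers, nucleus_labels, cell_labels = _base_cells(spec, rng)
    shape = spec.field_shape_px

    activated = sample_activation(rng, spec.n_cells, spec.activated_fraction)
    ratios = sample_true_ratios(rng, activated, spec.ratio_params)

    dapi = np.full(shape, spec.background, dtype=np.float64)
    er = np.full(shape, spec.background, dtype=np.float64)
    atf6 = np.full(shape, 2.0, dtype=np.float64)

    # mild multiplicative ER texture; the ATF6 channel stays exact so the
    # ratio construction identity holds without noise
    texture = np.exp(0.15 * rng.standard_normal(shape))

    cells = []
    for i, ctr in enumerate(centers, start=1):
        nuc = nucleus_labels == i
        ermask = (cell_labels == i) & ~nuc
        dapi[nuc] = spec.dapi_intensity
        er[ermask] = spec.er_intensity * texture[ermask]
        er[nuc] = spec.background
        atf6[ermask] = spec.atf6_er_intensity
        atf6[nuc] = spec.atf6_er_intensity * ratios[i - 1]
        cells.append(
            CellTruth(
                cell_id=i,
                activated=bool(activated[i - 1]),
                true_ratio=float(ratios[i - 1]),
                center_rc=tuple(ctr),
                border=False,
            )
        )

    channels = {"dapi": dapi, "er": er, "atf6": atf6}
    images = []
    for name, img in channels.items():
        if spec.noise.enabled:
            img = apply_noise(img, spec.noise, rng)
        images.append(
            ChannelImage(
                pixels=img,
                pixel_size_um=spec.pixel_size_um,
                channel=name,
                well_id=well_id,
                field_id=field_id,
            )
        )
    truth = GroundTruth(
        cells=cells,
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        pixel_size_um=spec.pixel_size_um,
    )
    return images, truth


def _place_puncta_in_cell(rng, center, nuc_r, cell_r, n, min_sep_px, diam_px, shape):
    """Punctum centers inside the ER annulus, mutually separated; a full
    diameter of clearance from the annulus edges keeps puncta of adjacent
    cells from overlapping in any channel."""
    placed = []
    pad = max(diam_px) + 1
    for _ in range(n):
        for _attempt in range(4000):
            rad = rng.uniform(nuc_r + pad, cell_r - pad)
            ang = rng.uniform(0, 2 * np.pi)
            r = center[0] + rad * np.sin(ang)
            c = center[1] + rad * np.cos(ang)
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                continue
            if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep_px**2 for r0, c0 in placed):
                placed.append((r, c))
                break
        else:
            raise GenerationError("could not place puncta; density infeasible")
    return placed


def generate_eres_field(
    spec: SceneSpec, well_id: str = "", field_id: int = 0
) -> tuple[list[ChannelImage], GroundTruth]:
    """Render Sec31A / Sec16 / ATF6 (plus DAPI and ER) slices with planted
    puncta.

    A punctum marked ``in_both_channels`` is rendered in Sec31A and Sec16 at
    the same position; otherwise it appears in exactly one of the two. The
    ATF6 values inside double-positive puncta are built per cell from the
    standardized clean Sec31A profile z and an independent normal deviate n
    as ``atf6 = mu + sd * (rho z + sqrt(1 - rho^2) n)``, so the pooled
    within-puncta Pearson correlation with Sec31A has expectation rho and is
    exactly +/-1 at rho = +/-1 with noise off.
    """
    p = spec.eres
    rng = np.random.default_rng(spec.seed)
    centers, nucleus_labels, cell_labels = _base_cells(spec, rng)
    shape = spec.field_shape_px
    px = spec.pixel_size_um
    cell_r = spec.cell_diameter_um / 2 / px
    nuc_r = spec.nucleus_diameter_um / 2 / px
    min_sep_px = p.min_separation_um / px

    images: list[ChannelImage] = []
    puncta: list[PunctumTruth] = []
    pid = 0
    for z in range(p.n_slices):
        sec31a = np.full(shape, spec.background, dtype=np.float64)
        sec16 = np.full(shape, spec.background, dtype=np.float64)
        atf6 = np.full(shape, 2.0, dtype=np.float64)
        dapi = np.full(shape, spec.background, dtype=np.float64)
        er = np.full(shape, spec.background, dtype=np.float64)
        for i in range(1, spec.n_cells + 1):
            dapi[nucleus_labels == i] = spec.dapi_intensity
            ermask = (cell_labels == i) & (nucleus_labels != i)
            er[ermask] = spec.er_intensity
            atf6[ermask] = 30.0

        sec31a_clean = np.zeros(shape)
        for ci, ctr in enumerate(centers, start=1):
            diam_um = rng.uniform(*p.diameter_range_um, size=p.n_puncta_per_cell)
            diam_px = diam_um / px
            if np.any(diam_px < 2.0):
                raise GenerationError("punctum diameter below 2 px; unresolvable")
            pos = _place_puncta_in_cell(
                rng, ctr, nuc_r, cell_r, p.n_puncta_per_cell,
                max(min_sep_px, diam_px.max() * 2.0), diam_px, shape,
            )
            cell_puncta = []
            for k, (center_rc, d_um) in enumerate(zip(pos, diam_um)):
                pid += 1
                u = rng.random()
                in_both = u < p.coloc_fraction
                only31 = (not in_both) and rng.random() < 0.5
                sigma = (d_um / px) * FWHM_TO_SIGMA
                amp = p.peak_intensity * np.exp(
                    p.peak_cv * rng.standard_normal()
                )
                # truth pixel set: the half-max (FWHM) disk, i.e. a disk of
                # the punctum's nominal diameter
                mask = _disk_mask(shape, center_rc, d_um / px / 2.0)
                pt = PunctumTruth(
                    punctum_id=pid,
                    cell_id=ci,
                    slice_index=z,
                    center_rc=center_rc,
                    diameter_um=float(d_um),
                    in_both_channels=bool(in_both),
                    pixel_idx=np.flatnonzero(mask),
                )
                puncta.append(pt)
                if in_both or only31:
                    _add_gaussian_spot(sec31a, center_rc, sigma, amp)
                    _add_gaussian_spot(sec31a_clean, center_rc, sigma, amp)
                if in_both or not only31:
                    _add_gaussian_spot(sec16, center_rc, sigma, amp)
                if in_both:
                    cell_puncta.append(pt)
            # Gaussian copula mixing, pooled over the cell's double-positive
            # puncta so the per-cell pooled Pearson has expectation rho
            if cell_puncta:
                idx = np.concatenate([pt.pixel_idx for pt in cell_puncta])
                s = sec31a_clean.ravel()[idx]
                zscore = (s - s.mean()) / s.std() if s.std() > 0 else np.zeros_like(s)
                rho = p.target_rho
                mix = rho * zscore
                if abs(rho) < 1.0:
                    mix = mix + np.sqrt(1 - rho**2) * rng.standard_normal(len(idx))
                vals = p.atf6_mean + p.atf6_sd * mix
                flat = atf6.ravel()
                flat[idx] = np.clip(vals, 0.0, None)
                atf6 = flat.reshape(shape)

        for name, img in (
            ("dapi", dapi), ("er", er), ("atf6", atf6),
            ("sec31a", sec31a), ("sec16", sec16),
        ):
            if spec.noise.enabled:
                img = apply_noise(img, spec.noise, rng)
            images.append(
                ChannelImage(
                    pixels=img,
                    pixel_size_um=px,
                    channel=name,
                    slice_index=z,
                    well_id=well_id,
                    field_id=field_id,
                )
            )

    cells = [
        CellTruth(
            cell_id=i, activated=False, true_ratio=float("nan"),
            center_rc=tuple(centers[i - 1]),
        )
        for i in range(1, spec.n_cells + 1)
    ]
    truth = GroundTruth(
        cells=cells,
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        puncta=puncta,
        target_rho=p.target_rho,
        pixel_size_um=px,
    )
    return images, truth


def generate_field(spec: SceneSpec, kind: str = "translocation", **kw):
    if kind == "translocation":
        return generate_translocation_field(spec, **kw)
    if kind == "eres":
        return generate_eres_field(spec, **kw)
    raise ValueError(f"unknown scene kind {kind!r}")


# ---------------------------------------------------------------------------
# plates


def generate_plate(
    layout: PlateLayout,
    scenes: dict[str, SceneSpec],
    out_dir,
    seed: int,
    fields_per_well: int = 1,
    kind: str = "translocation",
) -> Path:
    """Write one or more synthetic fields per well plus a master truth CSV.

    Fully reproducible from ``seed``: per-field seeds are derived with a
    ``SeedSequence`` keyed on the well and field indices.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(scenes) - set(layout.wells)
    if unknown:
        raise ValueError(f"scene wells not in layout: {sorted(unknown)}")
    rows = []
    written = set()
    for wi, well_id in enumerate(sorted(scenes)):
        for f in range(fields_per_well):
            child = int(
                np.random.SeedSequence(entropy=seed, spawn_key=(wi, f))
                .generate_state(1)[0] % (2**31)
            )
            spec = dataclasses.replace(scenes[well_id], seed=child)
            images, truth = generate_field(spec, kind, well_id=well_id, field_id=f)
            path = out_dir / f"{well_id}_f{f:02d}.ome.tif"
            if path in written:
                raise ValueError(f"duplicate field output {path}")
            written.add(path)
            write_field(images, path)
            for cell in truth.cells:
                rows.append(
                    {
                        "well_id": well_id,
                        "field_id": f,
                        "role": layout.wells[well_id].role,
                        "cell_id": cell.cell_id,
                        "activated": cell.activated,
                        "true_ratio": cell.true_ratio,
                        "border": cell.border,
                    }
                )
    truth_path = out_dir / "truth.csv"
    write_table(pd.DataFrame(rows), truth_path)
    return out_dir
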