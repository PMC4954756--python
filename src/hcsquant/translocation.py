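"""Nuclear-translocation scoring: the screening statistic of the assay.

Per cell, the mean ATF6-channel intensity over the nucleus mask is divided
by the mean over the ER mask. A plate-adaptive activation threshold is the
minimum ratio greater than 1 at which the stressed-control well's ratio
histogram rises above the unstressed control's. Percent activation per well
is the percentage of cells strictly above that threshold, and test wells
are called hits when their percent activation falls more than three
standard deviations below the mean of the stressed-control wells.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ChannelImage, PlateLayout
from .segmentation import CellRecord

logger = logging.getLogger(__name__)


class ThresholdDerivationError(RuntimeError):
    """No qualifying histogram bin: the stressed control failed to separate."""


@dataclass(frozen=True)
class CellRatio:
    cell_id: int
    well_id: str
    nuclear_mean: float
    er_mean: float

    @property
    def ratio(self) -> float:
        return self.nuclear_mean / self.er_mean


@dataclass(frozen=True)
class PlateThreshold:
    value: float
    bin_width: float
    derived_from: tuple[str, str] = ("", "")

    def __post_init__(self):
        if not self.value > 1.0:
            raise ValueError("activation threshold must be > 1")


@dataclass(frozen=True)
class WellActivation:
    well_id: str
    n_cells: int
    percent_activation: float
    role: str = "test"


@dataclass(frozen=True)
class HitCall:
    well_id: str
    is_hit: bool
    percent_activation: float
    control_mean: float
    control_sd: float
    z_like: float


def score_cells(atf6: ChannelImage, cells: list[CellRecord]) -> list[CellRatio]:
    """Per-cell mean ATF6 intensity over the exact nucleus and ER masks.

    Cells whose ER mean is not positive cannot produce a ratio and are
    dropped with a logged count.
    """
    flat = atf6.pixels.ravel()
    out = []
    dropped = 0
    for cell in cells:
        nuclear_mean = float(flat[cell.nucleus_idx].mean())
        er_mean = float(flat[cell.er_idx].mean())
        if er_mean <= 0:
            dropped += 1
            continue
        out.append(
            CellRatio(
                cell_id=cell.cell_id,
                well_id=atf6.well_id,
                nuclear_mean=nuclear_mean,
                er_mean=er_mean,
            )
        )
    if dropped:
        logger.warning("%d cells dropped with non-positive ER mean", dropped)
    return out


def _as_ratio_array(ratios) -> np.ndarray:
    vals = np.asarray(
        [r.ratio if isinstance(r, CellRatio) else float(r) for r in ratios]
    )
    if vals.size == 0:
        raise ValueError("empty ratio list")
    return vals


def _bin_counts(vals: np.ndarray, bin_width: float, n_bins: int) -> np.ndarray:
    # right-closed bins (lo, lo + w] anchored at 0: a ratio exactly on a bin
    # edge belongs to the lower bin, mirroring the strict ">" threshold rule
    idx = np.ceil(vals / bin_width).astype(int) - 1
    return np.bincount(np.clip(idx, 0, n_bins - 1), minlength=n_bins).astype(float)


def derive_threshold(
    stressed,
    unstressed,
    bin_width: float = 0.05,
    count_mode: str = "frequency",
    run_length: int = 3,
    wells: tuple[str, str] = ("stressed", "unstressed"),
) -> PlateThreshold:
    """Plate-adaptive activation threshold from a stressed/unstressed pair.

    Both ratio populations are histogrammed on common bins of width
    ``bin_width`` anchored at 0 (bin membership: floor(ratio / bin_width)).
    In ``frequency`` mode counts are normalized by each population's size,
    making the rule invariant to unequal well populations; ``raw`` compares
    plain counts. The threshold is the lower edge of the lowest bin whose
    left edge exceeds 1 in which the stressed curve is strictly above the
    unstressed one, provided the next ``run_length - 1`` bins do not
    contradict it (stressed >= unstressed), which guards against single-bin
    sampling artifacts. Set ``run_length=1`` to disable the guard.
    """
    s = _as_ratio_array(stressed)
    u = _as_ratio_array(unstressed)
    if count_mode not in ("frequency", "raw"):
        raise ValueError("count_mode must be 'frequency' or 'raw'")
    n_bins = int(np.ceil(max(s.max(), u.max()) / bin_width)) + 1
    cs = _bin_counts(s, bin_width, n_bins)
    cu = _bin_counts(u, bin_width, n_bins)
    if count_mode == "frequency":
        cs = cs / s.size
        cu = cu / u.size
    # pad so run guards past the last bin see empty (non-contradicting) bins
    pad = max(0, run_length - 1)
    cs = np.concatenate([cs, np.zeros(pad)])
    cu = np.concatenate([cu, np.zeros(pad)])
    for i in range(n_bins):
        edge = i * bin_width
        if edge <= 1.0 * (1.0 + 1e-9):
            continue
        if cs[i] > cu[i] and np.all(cs[i + 1 : i + run_length] >= cu[i + 1 : i + run_length]):
            return PlateThreshold(value=edge, bin_width=bin_width, derived_from=wells)
    raise ThresholdDerivationError(
        f"no ratio bin > 1 where stressed ({wells[0]}) exceeds unstressed "
        f"({wells[1]}); stressed control may have failed"
    )


def percent_activation(
    ratios,
    threshold: PlateThreshold,
    well_id: str = "",
    role: str = "test",
    min_cells: int = 50,
) -> WellActivation:
    """Percentage of a well's cells with ratio strictly above the threshold."""
    vals = _as_ratio_array(ratios)
    if vals.size < min_cells:
        logger.warning(
            "well %s has %d cells (< %d); percent activation is noisy",
            well_id, vals.size, min_cells,
        )
    pct = 100.0 * float(np.mean(vals > threshold.value))
    if not well_id and isinstance(next(iter(ratios)), CellRatio):
        well_id = next(iter(ratios)).well_id
    return WellActivation(
        well_id=well_id, n_cells=int(vals.size), percent_activation=pct, role=role
    )


def call_hits(
    wells: list[WellActivation],
    layout: PlateLayout,
    sd_multiplier: float = 3.0,
) -> list[HitCall]:
    """Flag test wells suppressed below mean - 3 SD of stressed controls.

    The control mean and sample standard deviation (n-1 denominator) are
    computed over the plate's stressed-control wells; at least two are
    required. Strict inequality: a well exactly at the boundary is not a
    hit.
    """
    by_id = {w.well_id: w for w in wells}
    control_ids = [
        w for w in layout.wells_with_role("stressed_control") if w in by_id
    ]
    if len(control_ids) < 2:
        raise ValueError(
            f"need >= 2 stressed-control wells for the SD rule, got {len(control_ids)}"
        )
    control = np.array([by_id[w].percent_activation for w in control_ids])
    mean = float(control.mean())
    sd = float(control.std(ddof=1))
    calls = []
    for w in wells:
        role = layout.wells[w.well_id].role if w.well_id in layout.wells else w.role
        if role != "test":
            continue
        z_like = (mean - w.percent_activation) / sd if sd > 0 else np.inf
        calls.append(
            HitCall(
                well_id=w.well_id,
                is_hit=bool(w.percent_activation < mean - sd_multiplier * sd),
                percent_activation=w.percent_activation,
                control_mean=mean,
                control_sd=sd,
                z_like=float(z_like),
            )
        )
    return calls


def summarize_nuclear_translocation(
    groups: dict[str, list[float]],
    min_n: int = 3,
) -> tuple[pd.DataFrame, list]:
    """Box-plot table (quartiles, min/max whiskers, n) per treatment group
    plus all pairwise unpaired two-tailed t-tests.

    Groups with fewer than ``min_n`` cells are excluded with a warning.
    """
    from .stats import t_test_unpaired

    kept = {}
    for name, vals in groups.items():
        vals = np.asarray(list(vals), dtype=float)
        if vals.size < min_n:
            logger.warning("group %r excluded: n=%d < %d", name, vals.size, min_n)
            continue
        kept[name] = vals
    if len(kept) < 2:
        raise ValueError("need >= 2 groups of sufficient size")
    rows = []
    for name, vals in kept.items():
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "group": name,
                "n": int(vals.size),
                "min": float(vals.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(vals.max()),
                "mean": float(vals.mean()),
            }
        )
    tests = [
        t_test_unpaired(kept[a], kept[b], labels=(a, b))
        for a, b in itertools.combinations(kept, 2)
    ]
    return pd.DataFrame(rows), tests
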