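"""Figure and table rendering for a completed analysis run."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "hcsquant"  # deterministic SVG ids
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import config_hash
from .io import write_table
from .stats import confidence_interval_mean


def _versions() -> dict:
    import matplotlib as mpl
    import scipy
    import skimage

    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-image": skimage.__version__,
        "matplotlib": mpl.__version__,
    }


def render_report(
    out_dir,
    ratio_groups: dict[str, list[float]] | None = None,
    well_table: pd.DataFrame | None = None,
    stats_tables: dict[str, pd.DataFrame] | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write figures, stats CSVs and a run-metadata log.

    * box plot of per-cell nuclear:ER ratios per treatment, whiskers at the
      minimum and maximum of the data;
    * bar chart of mean percent activation per treatment with 95%
      confidence-limit error bars;
    * any supplied stats tables as CSV;
    * ``run_metadata.json`` with config hash, seed, and library versions.

    Empty optional sections are skipped. Output is deterministic for
    identical inputs (figures carry no timestamps).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if ratio_groups:
        fig, ax = plt.subplots(figsize=(1.5 + len(ratio_groups), 4))
        names = list(ratio_groups)
        ax.boxplot([ratio_groups[n] for n in names], tick_labels=names, whis=(0, 100))
        ax.set_ylabel("nuclear : ER ratio (per cell)")
        ax.set_title("nuclear translocation")
        fig.savefig(out_dir / "ratio_boxplot.svg", metadata={"Date": None})
        plt.close(fig)

    if well_table is not None and len(well_table):
        grouped = well_table.groupby("treatment")["percent_activation"]
        names, means, err_lo, err_hi = [], [], [], []
        for name, vals in grouped:
            names.append(name)
            means.append(vals.mean())
            if len(vals) > 1:
                lo, hi = confidence_interval_mean(vals)
            else:
                lo = hi = vals.mean()
            err_lo.append(means[-1] - lo)
            err_hi.append(hi - means[-1])
        fig, ax = plt.subplots(figsize=(1.5 + len(names), 4))
        ax.bar(names, means, yerr=[err_lo, err_hi], capsize=4)
        ax.set_ylabel("percent activation (mean of wells, 95% CL)")
        fig.savefig(out_dir / "percent_activation.svg", metadata={"Date": None})
        plt.close(fig)
        write_table(well_table, out_dir / "wells.csv")

    for name, table in (stats_tables or {}).items():
        write_table(table, out_dir / f"{name}.csv")

    meta = {
        "config_hash": config_hash(config) if config else None,
        "seed": seed,
        "versions": _versions(),
    }
    with open(out_dir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return out_dir
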