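"""Reproductions that require the deposited survey data files.

The long-term study deposited its raw data as supplementary files: the
plot × species cover CSV, the flowering-count table and the stage
transition matrices.  Those files are not redistributed with this package;
place them under ``data/supplementary/`` (or pass explicit paths) and the
functions here recompute the published headline numbers from them.  Every
function raises :class:`FileNotFoundError` with the expected location when
a file is absent.

Expected files (converted to the package's CSV layouts where the deposit
is a PDF table):

* ``cover.csv`` — wide or long cover layout (see :mod:`floodmeadow.io`)
  with plot elevations, plots 1–76, survey years 1940/1982/1995/2016;
* ``flowering.csv`` — plot_id, year, morph counts for the 15 censuses;
* ``transition_1981_1982.csv`` and ``transition_1982_1983.csv`` — 5×5
  stage transition matrices, destination stages as rows (first column
  ``to_stage``), origin stages as columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from floodmeadow import community as comm
from floodmeadow import demography as dem
from floodmeadow import io

DEFAULT_DATA_DIR = Path("data/supplementary")

PROFILE1_PLOTS = tuple(range(1, 29))
MESIC_PLOTS = tuple(range(2, 17))
WET_PLOTS = tuple(range(18, 26))


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"deposited data file not found: {path} — place the supplementary "
            "data files under data/supplementary/ (see floodmeadow.reproduce)"
        )
    return path


def load_cover(data_dir: str | Path = DEFAULT_DATA_DIR):
    path = _require(Path(data_dir) / "cover.csv")
    return io.read_cover_csv(path)


def profile1_richness_diversity(data_dir: str | Path = DEFAULT_DATA_DIR) -> pd.DataFrame:
    """Species richness S and inverse Simpson D per survey for plots 1–28."""
    cover, _ = load_cover(data_dir)
    rows = []
    for year, cm in sorted(cover.items()):
        plots = [p for p in PROFILE1_PLOTS if p in cm.scores.index]
        prof = comm.abundance_profile(cm, plots, scale="midpoint")
        rows.append(
            {
                "survey_year": year,
                "S": comm.species_richness(cm, plots),
                "D": comm.inverse_simpson(prof),
            }
        )
    return pd.DataFrame(rows)


def clusters_1982(
    data_dir: str | Path = DEFAULT_DATA_DIR, k: int = 4
) -> pd.DataFrame:
    """Ward.D2 + k-cluster cut of the 1982 survey (all 76 plots).

    Returns one row per cluster with its size and mean plot elevation,
    ordered driest first.
    """
    cover, plots = load_cover(data_dir)
    cm = cover[1982]
    elev = {p.plot_id: p.elevation for p in plots}
    d = comm.dissimilarity_matrix(cm, scale="raw")
    assignment = comm.cut_clusters(comm.ward_cluster(d), k, elevations=elev)
    frame = pd.DataFrame(
        [{"plot_id": p, "cluster": lab, "elevation": elev[p]} for p, lab in assignment.labels.items()]
    )
    return (
        frame.groupby("cluster")
        .agg(n_plots=("plot_id", "count"), mean_elevation=("elevation", "mean"))
        .reset_index()
    )


def dominance_summary(data_dir: str | Path = DEFAULT_DATA_DIR) -> dict[str, float]:
    """The published dominance percentages and F. meleagris mesic cover means."""
    cover, _ = load_cover(data_dir)
    cm1940 = cover[1940]
    p1 = [p for p in PROFILE1_PLOTS if p in cm1940.scores.index]
    out = {
        "deschampsia_pct_1940": comm.relative_abundance(
            cm1940, "Deschampsia cespitosa", p1, scale="midpoint"
        ),
        "carex_acuta_pct_1940": comm.relative_abundance(
            cm1940, "Carex acuta", p1, scale="midpoint"
        ),
    }
    # A. pratensis over all profiles and surveys: pooled abundance share
    num = denom = 0.0
    for year in (1982, 1995, 2016):
        prof = comm.abundance_profile(cover[year], scale="midpoint")
        num += prof.abundance.get("Alopecurus pratensis", 0.0)
        denom += prof.abundance.sum()
    out["alopecurus_pct_all"] = 100.0 * num / denom
    for year, cm in sorted(cover.items()):
        plots = [p for p in MESIC_PLOTS if p in cm.scores.index]
        col = cm.scores.get("Fritillaria meleagris")
        out[f"fritillaria_mesic_mean_{year}"] = (
            float(col.loc[plots].mean()) if col is not None else 0.0
        )
    return out


def flowering_summary(data_dir: str | Path = DEFAULT_DATA_DIR) -> dict[str, float]:
    """Yearly totals over the six plots: min, max, mean; white-morph share."""
    path = _require(Path(data_dir) / "flowering.csv")
    censuses = io.read_flowering_table(path)
    frame = io.flowering_to_frame(censuses)
    yearly = frame.groupby("year").sum(numeric_only=True)
    classified = yearly[(yearly["purple"] + yearly["pink"] + yearly["white"]) > 0]
    white_pct = 100.0 * classified["white"] / (
        classified["purple"] + classified["pink"] + classified["white"]
    )
    return {
        "n_censuses": int(len(yearly)),
        "total_min": float(yearly["total"].min()),
        "total_max": float(yearly["total"].max()),
        "total_mean": float(yearly["total"].mean()),
        "white_pct_mean": float(white_pct.mean()),
    }


def growth_rates(data_dir: str | Path = DEFAULT_DATA_DIR) -> dict[str, float]:
    """λ of the deposited 1981→1982 and 1982→1983 transition matrices."""
    out = {}
    for label, fname in (
        ("lambda_1981_1982", "transition_1981_1982.csv"),
        ("lambda_1982_1983", "transition_1982_1983.csv"),
    ):
        path = _require(Path(data_dir) / fname)
        frame = pd.read_csv(path).set_index("to_stage")
        a = frame.to_numpy(dtype=float)
        if a.shape != (5, 5) or (a < 0).any():
            raise io.ValidationError(f"{path}: expected a non-negative 5x5 matrix")
        out[label] = dem.growth_rate(a)
    return out
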