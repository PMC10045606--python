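"""Domain types and tabular readers/writers shared across the pipeline.

All on-disk formats are plain comma-delimited CSV with decimal points
(UTF-8).  The cover format mirrors the deposited survey file: one row per
(plot, survey year) with one column per species in the wide layout, or one
row per (plot, survey year, species) in the long layout; both are accepted
and auto-detected.  Blank cover cells mean "absent" and are stored as 0.

Column names (the data dictionary):

``cover`` (wide)
    ``plot_id, survey_year[, profile][, elevation], <species 1>, ...``
``cover`` (long)
    ``plot_id, survey_year[, profile][, elevation], species, score``
``flowering``
    ``plot_id, year[, purple][, pink][, white][, unclassified][, total]``
``weather``
    ``year, period, temperature, precipitation`` with period one of
    ``june_prev, sept_prev, mar_apr``
``indicators``
    ``species, moisture, light, nitrogen, grazing_mowing,
    soil_disturbance, soil_reaction[, phosphorus]`` (blank = missing)
``histories``
    ``individual_id, year, stage`` with stage one of ``small, medium,
    large_vegetative, reproductive`` or blank (= not seen that year)
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_SCORES = frozenset(range(6))

WEATHER_PERIODS = ("june_prev", "sept_prev", "mar_apr")

OBSERVABLE_STAGES = ("small", "medium", "large_vegetative", "reproductive")
STAGES = OBSERVABLE_STAGES + ("dormant",)

INDICATOR_NAMES = (
    "moisture",
    "light",
    "nitrogen",
    "grazing_mowing",
    "soil_disturbance",
    "soil_reaction",
)

#: inclusive (low, high) bounds of each indicator scale
INDICATOR_BOUNDS: Mapping[str, tuple[float, float]] = {
    "moisture": (1, 12),
    "light": (1, 7),
    "nitrogen": (1, 9),
    "grazing_mowing": (1, 8),
    "soil_disturbance": (1, 9),
    "soil_reaction": (1, 8),
    "phosphorus": (1, 9),
}


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


@dataclass(frozen=True)
class SurveyPlot:
    """A permanent vegetation plot with its elevation above sea level."""

    plot_id: int
    elevation: float
    profile: int | None = None
    area_note: str = "2 m x 2 m"

    def __post_init__(self) -> None:
        # NaN marks "elevation unknown" (file without an elevation column)
        if np.isinf(self.elevation):
            raise ValidationError(f"plot {self.plot_id}: elevation not finite")


def validate_plots(
    plots: Sequence[SurveyPlot], elevation_band: tuple[float, float] = (0.0, 10.0)
) -> None:
    """Check plot-id uniqueness and that elevations sit in a plausible band."""
    ids = [p.plot_id for p in plots]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate plot ids: {dup}")
    lo, hi = elevation_band
    bad = [
        p.plot_id
        for p in plots
        if not np.isnan(p.elevation) and not (lo <= p.elevation <= hi)
    ]
    if bad:
        raise ValidationError(
            f"elevation outside plausible band [{lo}, {hi}] m for plots {bad}"
        )


@dataclass
class CoverMatrix:
    """Plot × species ordinal cover scores for one survey year.

    ``scores`` is a DataFrame indexed by plot_id with one column per
    species; every value is in {0,…,5} where 0 means absent.
    """

    survey_year: int
    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scores.columns.duplicated().any():
            dup = self.scores.columns[self.scores.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate species labels: {dup}")
        vals = self.scores.to_numpy()
        ok = np.isin(vals, list(VALID_SCORES))
        if not ok.all():
            rows, cols = np.nonzero(~ok)
            cells = [
                (self.scores.index[r], self.scores.columns[c], vals[r, c])
                for r, c in zip(rows[:10], cols[:10])
            ]
            raise ValidationError(
                f"cover scores outside 0..5 in survey {self.survey_year}: {cells}"
            )
        self.scores = self.scores.astype(int)

    @property
    def plot_ids(self) -> list[int]:
        return list(self.scores.index)

    @property
    def species_names(self) -> list[str]:
        return list(self.scores.columns)


@dataclass(frozen=True)
class FloweringCensus:
    """Per-plot, per-year flowering count, optionally split by colour morph."""

    plot_id: int
    year: int
    count_purple: int = 0
    count_pink: int = 0
    count_white: int = 0
    count_unclassified: int = 0
    total: int = field(default=-1)

    def __post_init__(self) -> None:
        counts = (
            self.count_purple,
            self.count_pink,
            self.count_white,
            self.count_unclassified,
        )
        if any(c < 0 for c in counts):
            raise ValidationError(
                f"negative morph count for plot {self.plot_id}, year {self.year}"
            )
        if self.total < 0:
            object.__setattr__(self, "total", sum(counts))
        elif self.total != sum(counts):
            raise ValidationError(
                f"total != sum of morph counts for plot {self.plot_id}, "
                f"year {self.year}: {self.total} vs {sum(counts)}"
            )


@dataclass(frozen=True)
class WeatherSeries:
    """One phenological period's weather in one year.

    ``temperature`` is the period mean (°C); ``precipitation`` the period
    total (mm).
    """

    year: int
    period: str
    temperature: float
    precipitation: float

    def __post_init__(self) -> None:
        if self.period not in WEATHER_PERIODS:
            raise ValidationError(f"unknown period {self.period!r}")
        if not np.isfinite(self.temperature):
            raise ValidationError(f"temperature not finite in {self.year}")
        if self.precipitation < 0:
            raise ValidationError(f"negative precipitation in {self.year}")


@dataclass(frozen=True)
class GroupAssignment:
    """Assignment of plots to named groups (e.g. Wet/Mesic or clusters)."""

    scheme: str
    labels: Mapping[int, str]

    def label(self, plot_id: int) -> str:
        return self.labels.get(plot_id, "unassigned")


# ---------------------------------------------------------------------------
# readers


def _strip_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [str(c).strip() for c in df.columns]
    return df


def read_cover_csv(
    path: str | Path, elevation_band: tuple[float, float] = (0.0, 10.0)
) -> tuple[dict[int, CoverMatrix], list[SurveyPlot]]:
    """Read a cover CSV (wide or long layout, auto-detected).

    Returns one :class:`CoverMatrix` per survey year found, and the plot
    list with elevations attached (elevation NaN if the file has none).
    """
    df = _strip_columns(pd.read_csv(path))
    required = {"plot_id", "survey_year"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"{path}: cover file must have columns {sorted(required)}"
        )
    is_long = {"species", "score"} <= set(df.columns)
    meta_cols = [c for c in ("plot_id", "survey_year", "profile", "elevation") if c in df.columns]

    # plots
    plot_meta = df[meta_cols].drop_duplicates("plot_id").set_index("plot_id")
    plots = [
        SurveyPlot(
            plot_id=int(pid),
            elevation=float(row["elevation"]) if "elevation" in plot_meta else float("nan"),
            profile=int(row["profile"]) if "profile" in plot_meta and pd.notna(row.get("profile")) else None,
        )
        for pid, row in plot_meta.iterrows()
    ]
    validate_plots(plots, elevation_band)

    matrices: dict[int, CoverMatrix] = {}
    if is_long:
        df["species"] = df["species"].astype(str).str.strip()
        for year, sub in df.groupby("survey_year"):
            wide = sub.pivot_table(
                index="plot_id", columns="species", values="score", aggfunc="first"
            )
            wide = wide.fillna(0)
            matrices[int(year)] = _as_cover_matrix(int(year), wide)
    else:
        species_cols = [c for c in df.columns if c not in meta_cols]
        if not species_cols:
            raise ValidationError(f"{path}: no species columns found")
        for year, sub in df.groupby("survey_year"):
            wide = sub.set_index("plot_id")[species_cols].fillna(0)
            matrices[int(year)] = _as_cover_matrix(int(year), wide)
    return matrices, plots


def _as_cover_matrix(year: int, wide: pd.DataFrame) -> CoverMatrix:
    if wide.index.duplicated().any():
        dup = sorted(set(wide.index[wide.index.duplicated()]))
        raise ValidationError(f"duplicate rows for plots {dup} in survey {year}")
    vals = wide.to_numpy(dtype=float)
    if not np.isclose(vals, np.round(vals)).all():
        raise ValidationError(f"non-integer cover score in survey {year}")
    wide = wide.round().astype(int)
    wide.columns = [str(c).strip() for c in wide.columns]
    return CoverMatrix(survey_year=year, scores=wide)


def read_flowering_table(path: str | Path) -> list[FloweringCensus]:
    """Read per-plot, per-year flowering counts.

    A file carrying only a ``total`` column yields censuses whose counts
    are all stored as unclassified (the late-census case).
    """
    df = _strip_columns(pd.read_csv(path))
    if not {"plot_id", "year"} <= set(df.columns):
        raise ValidationError(f"{path}: flowering file needs plot_id and year")
    out = []
    for i, row in df.iterrows():
        morphs = {
            m: int(row[m]) if m in df.columns and pd.notna(row[m]) else 0
            for m in ("purple", "pink", "white", "unclassified")
        }
        if any(v < 0 for v in morphs.values()):
            raise ValidationError(f"{path} row {i}: negative count")
        if "total" in df.columns and pd.notna(row["total"]):
            total = int(row["total"])
            known = morphs["purple"] + morphs["pink"] + morphs["white"]
            if total < known:
                raise ValidationError(f"{path} row {i}: total below morph sum")
            morphs["unclassified"] = total - known
        out.append(
            FloweringCensus(
                plot_id=int(row["plot_id"]),
                year=int(row["year"]),
                count_purple=morphs["purple"],
                count_pink=morphs["pink"],
                count_white=morphs["white"],
                count_unclassified=morphs["unclassified"],
            )
        )
    return out


def read_weather_csv(path: str | Path) -> list[WeatherSeries]:
    df = _strip_columns(pd.read_csv(path))
    recs = [
        WeatherSeries(
            year=int(r["year"]),
            period=str(r["period"]).strip(),
            temperature=float(r["temperature"]),
            precipitation=float(r["precipitation"]),
        )
        for _, r in df.iterrows()
    ]
    seen = set()
    for r in recs:
        key = (r.year, r.period)
        if key in seen:
            raise ValidationError(f"duplicate weather record for {key}")
        seen.add(key)
    return recs


def read_indicator_csv(path: str | Path) -> pd.DataFrame:
    """Read a species × indicator-value table; blanks become NaN.

    Values are range-checked against each indicator's declared scale.
    """
    df = _strip_columns(pd.read_csv(path))
    if "species" not in df.columns:
        raise ValidationError(f"{path}: indicator file needs a species column")
    df["species"] = df["species"].astype(str).str.strip()
    df = df.set_index("species")
    for col in df.columns:
        if col not in INDICATOR_BOUNDS:
            raise ValidationError(f"{path}: unknown indicator column {col!r}")
        lo, hi = INDICATOR_BOUNDS[col]
        vals = df[col].dropna()
        bad = vals[(vals < lo) | (vals > hi)]
        if len(bad):
            raise ValidationError(
                f"{path}: {col} values outside [{lo}, {hi}] for {list(bad.index[:5])}"
            )
    return df


def read_histories_csv(path: str | Path) -> "pd.DataFrame":
    """Read individual observation histories (long format).

    Returns a DataFrame with columns individual_id, year, stage where stage
    is one of the four observable stages or NaN for "not seen".
    """
    df = _strip_columns(pd.read_csv(path))
    need = {"individual_id", "year"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: histories file needs {sorted(need)}")
    if "stage" not in df.columns:
        df["stage"] = np.nan
    stages = df["stage"].dropna().astype(str).str.strip()
    bad = stages[~stages.isin(OBSERVABLE_STAGES)]
    if len(bad):
        raise ValidationError(f"{path}: unknown stages {sorted(set(bad))}")
    df["stage"] = df["stage"].where(df["stage"].notna(), np.nan)
    return df[["individual_id", "year", "stage"]]


# ---------------------------------------------------------------------------
# writers


def config_hash(config: Mapping | None) -> str:
    """Stable short hash of a (JSON-serialisable) configuration mapping."""
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> list[Path]:
    """Write result tables as CSV plus a JSON run manifest.

    Floats are written at full round-trip precision so that
    ``read(write(x)) == x``.  The manifest records the seed, a hash of the
    configuration and library versions.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        target = outdir / f"{name}.csv"
        table.to_csv(target, index=False, float_format="%.17g")
        written.append(target)
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "tables": sorted(tables),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    written.append(mpath)
    return written


def flowering_to_frame(censuses: Iterable[FloweringCensus]) -> pd.DataFrame:
    rows = [
        {
            "plot_id": c.plot_id,
            "year": c.year,
            "purple": c.count_purple,
            "pink": c.count_pink,
            "white": c.count_white,
            "unclassified": c.count_unclassified,
            "total": c.total,
        }
        for c in censuses
    ]
    return pd.DataFrame(rows).sort_values(["year", "plot_id"]).reset_index(drop=True)


def weather_to_frame(records: Iterable[WeatherSeries]) -> pd.DataFrame:
    rows = [
        {
            "year": w.year,
            "period": w.period,
            "temperature": w.temperature,
            "precipitation": w.precipitation,
        }
        for w in records
    ]
    return pd.DataFrame(rows).sort_values(["year", "period"]).reset_index(drop=True)


def cover_to_frame(
    matrices: Mapping[int, CoverMatrix], plots: Sequence[SurveyPlot] | None = None
) -> pd.DataFrame:
    """Wide-layout frame (one row per plot × survey year) for writing."""
    elev = {p.plot_id: p.elevation for p in plots} if plots else {}
    prof = {p.plot_id: p.profile for p in plots} if plots else {}
    frames = []
    for year in sorted(matrices):
        cm = matrices[year]
        block = cm.scores.reset_index().rename(columns={"index": "plot_id"})
        if "plot_id" not in block.columns:  # index name preserved
            block = block.rename(columns={block.columns[0]: "plot_id"})
        block.insert(1, "survey_year", year)
        if elev:
            block.insert(2, "elevation", [elev.get(p, np.nan) for p in block["plot_id"]])
        if prof and any(v is not None for v in prof.values()):
            block.insert(2, "profile", [prof.get(p) for p in block["plot_id"]])
        frames.append(block)
    return pd.concat(frames, ignore_index=True).fillna(0)
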