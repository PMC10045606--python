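"""Synthetic meadow surveys, weather, flowering counts and fate histories.

Every generator draws from an explicitly seeded NumPy Generator and is
bit-reproducible.  The defaults mirror the study conditions the analyses
assume: 76 plots along a 1.2–2.2 m elevation gradient surveyed in 1940,
1982, 1995 and 2016 (cover recorded on the 5-degree ordinal scale); six
10 m × 10 m flowering plots censused in 1938, 1981–1988 and 2016–2021
with Poisson counts driven by climate × elevation on the log scale; and
five-stage individual fate histories where the dormant stage is emitted
as "not seen".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from floodmeadow.community import percent_to_hsd
from floodmeadow.io import (
    OBSERVABLE_STAGES,
    STAGES,
    CoverMatrix,
    FloweringCensus,
    SurveyPlot,
    ValidationError,
    WeatherSeries,
)

SURVEY_YEARS = (1940, 1982, 1995, 2016)
CENSUS_YEARS = (1938,) + tuple(range(1981, 1989)) + tuple(range(2016, 2022))

#: plot elevations of the six flowering plots: 1–4 in the drier part
#: (~1.8 m a.s.l.), 5–6 in the wettest part of the species' range
FLOWERING_PLOT_ELEVATIONS = {1: 1.85, 2: 1.82, 3: 1.80, 4: 1.78, 5: 1.60, 6: 1.30}

#: (mean, s.d.) of period temperature (°C) and precipitation (mm) for a
#: hemiboreal lowland site: previous June, previous September, March–April
WEATHER_DEFAULTS = {
    "june_prev": {"temperature": (14.5, 1.3), "precipitation": (55.0, 28.0)},
    "sept_prev": {"temperature": (11.0, 1.2), "precipitation": (55.0, 25.0)},
    "mar_apr": {"temperature": (2.0, 1.8), "precipitation": (65.0, 25.0)},
}


# ---------------------------------------------------------------------------
# community surveys


@dataclass
class CommunityGenConfig:
    """Gaussian-niche community generator along the elevation gradient.

    Expected percent cover of species s in plot p is
    ``max_cover_s · exp(−(elev_p − optimum_s − drift_t)² / (2 width_s²))``,
    perturbed by log-normal multiplicative noise and discretised to the
    5-degree scale.  ``drift`` shifts every optimum per survey year,
    emulating the wetting/drying turnover between surveys.
    """

    n_plots: int = 76
    n_species: int = 40
    elevation_range: tuple[float, float] = (1.2, 2.2)
    survey_years: tuple[int, ...] = SURVEY_YEARS
    drift: dict[int, float] = field(default_factory=dict)
    niche_optima: Sequence[float] | None = None
    niche_widths: Sequence[float] | None = None
    max_cover: Sequence[float] | None = None
    noise_sd: float = 0.35
    absence_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.elevation_range
        if not hi > lo:
            raise ValidationError("degenerate elevation range")
        if self.n_plots < 1 or self.n_species < 1:
            raise ValidationError("need at least one plot and one species")
        if self.niche_widths is not None and np.any(np.asarray(self.niche_widths) <= 0):
            raise ValidationError("niche widths must be positive")


def _species_traits(cfg: CommunityGenConfig, rng: np.random.Generator):
    lo, hi = cfg.elevation_range
    span = hi - lo
    optima = (
        np.asarray(cfg.niche_optima, dtype=float)
        if cfg.niche_optima is not None
        else rng.uniform(lo - 0.1 * span, hi + 0.1 * span, cfg.n_species)
    )
    widths = (
        np.asarray(cfg.niche_widths, dtype=float)
        if cfg.niche_widths is not None
        else rng.uniform(0.12, 0.45, cfg.n_species)
    )
    max_cover = (
        np.asarray(cfg.max_cover, dtype=float)
        if cfg.max_cover is not None
        else rng.uniform(3.0, 60.0, cfg.n_species)
    )
    return optima, widths, max_cover


def gen_meadow_surveys(
    cfg: CommunityGenConfig,
) -> tuple[dict[int, CoverMatrix], list[SurveyPlot]]:
    """Generate one CoverMatrix per survey year plus the plot list."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.elevation_range
    elevations = np.linspace(lo, hi, cfg.n_plots)
    # plots are laid out along profiles, not sorted by wetness
    elevations = rng.permutation(elevations)
    n_profiles = min(4, max(1, cfg.n_plots // 19))
    plots = [
        SurveyPlot(
            plot_id=i + 1,
            elevation=float(elevations[i]),
            profile=1 + i * n_profiles // cfg.n_plots,
        )
        for i in range(cfg.n_plots)
    ]
    optima, widths, max_cover = _species_traits(cfg, rng)
    species = [f"species_{s + 1:03d}" for s in range(cfg.n_species)]

    matrices: dict[int, CoverMatrix] = {}
    for year in cfg.survey_years:
        shift = cfg.drift.get(year, 0.0)
        mu = max_cover[None, :] * np.exp(
            -((elevations[:, None] - optima[None, :] - shift) ** 2)
            / (2 * widths[None, :] ** 2)
        )
        if cfg.noise_sd > 0:
            mu = mu * rng.lognormal(0.0, cfg.noise_sd, size=mu.shape)
        scores = percent_to_hsd(np.minimum(mu, 100.0), cfg.absence_threshold)
        frame = pd.DataFrame(scores, index=[p.plot_id for p in plots], columns=species)
        frame.index.name = "plot_id"
        matrices[year] = CoverMatrix(survey_year=year, scores=frame)
    return matrices, plots


def gen_indicator_table(
    cfg: CommunityGenConfig, missing_rate: float = 0.1
) -> pd.DataFrame:
    """Indicator table matched to the generated community.

    The moisture indicator decreases with a species' elevation optimum
    (lower ground = wetter), so environmental-vector fits onto an
    ordination of the generated surveys carry real signal; the other five
    indicators are uninformative draws within their scale bounds, with a
    share of missing values.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    optima, _, _ = _species_traits(cfg, np.random.default_rng(cfg.seed))
    lo, hi = cfg.elevation_range
    rel = np.clip((optima - lo) / (hi - lo), 0, 1)
    moisture = np.clip(np.round(10.5 - 7 * rel + rng.normal(0, 0.7, len(optima))), 1, 12)
    table = pd.DataFrame(
        {
            "moisture": moisture,
            "light": rng.integers(3, 8, len(optima)),
            "nitrogen": rng.integers(2, 9, len(optima)),
            "grazing_mowing": rng.integers(2, 8, len(optima)),
            "soil_disturbance": rng.integers(1, 9, len(optima)),
            "soil_reaction": rng.integers(3, 8, len(optima)),
        },
        index=[f"species_{s + 1:03d}" for s in range(len(optima))],
        dtype=float,
    )
    table.index.name = "species"
    mask = rng.random(table.shape) < missing_rate
    mask[:, 0] = False  # keep moisture complete
    return table.mask(mask)


# ---------------------------------------------------------------------------
# flowering counts


@dataclass
class FloweringGenConfig:
    """Generative twin of the climate × elevation Poisson GLMM.

    ``beta`` is (β0, β1 climate, β2 elevation, β3 interaction) on the log
    scale in standardized-predictor units; θ_p ~ Normal(0, σ_θ²).
    """

    beta: tuple[float, float, float, float] = (4.0, 0.3, -0.2, -0.4)
    sigma_theta: float = 0.5
    elevations: dict[int, float] = field(
        default_factory=lambda: dict(FLOWERING_PLOT_ELEVATIONS)
    )
    years: tuple[int, ...] = CENSUS_YEARS
    period: str = "mar_apr"
    variable: str = "temperature"
    weather_params: dict = field(default_factory=lambda: WEATHER_DEFAULTS)
    white_fraction: float = 0.037
    pink_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_theta < 0:
            raise ValidationError("sigma_theta must be non-negative")


def gen_weather(cfg: FloweringGenConfig, rng: np.random.Generator) -> list[WeatherSeries]:
    """Independent Normal temperature and zero-truncated Normal precipitation."""
    out = []
    # weather needed for census years and the year preceding each census
    years = sorted({y for c in cfg.years for y in (c, c - 1)})
    for year in years:
        for period, params in cfg.weather_params.items():
            tmean, tsd = params["temperature"]
            pmean, psd = params["precipitation"]
            out.append(
                WeatherSeries(
                    year=year,
                    period=period,
                    temperature=float(rng.normal(tmean, tsd)),
                    precipitation=float(max(0.0, rng.normal(pmean, psd))),
                )
            )
    return out


def gen_flowering_counts(
    cfg: FloweringGenConfig,
) -> tuple[list[FloweringCensus], list[WeatherSeries], dict]:
    """Draw Poisson flower counts from the log-linear truth model.

    Returns censuses, the weather series, and a truth record holding the
    parameters, the realized plot intercepts and the standardisation used.
    """
    rng = np.random.default_rng(cfg.seed)
    weather = gen_weather(cfg, rng)
    clim_by_year = {
        w.year: getattr(w, cfg.variable) for w in weather if w.period == cfg.period
    }
    years = list(cfg.years)
    plot_ids = sorted(cfg.elevations)
    # standardize over observation rows (year × plot), exactly as the
    # fitting design does, so the generator is the model's exact inverse
    rows = [(y, p) for y in years for p in plot_ids]
    clim_rows = np.array([clim_by_year[y] for y, _ in rows])
    elev_rows = np.array([cfg.elevations[p] for _, p in rows])
    clim_z_rows = (clim_rows - clim_rows.mean()) / clim_rows.std(ddof=1)
    elev_z_rows = (elev_rows - elev_rows.mean()) / elev_rows.std(ddof=1)
    clim_z = {y: z for (y, _), z in zip(rows, clim_z_rows)}
    elev_z = {p: z for (_, p), z in zip(rows, elev_z_rows)}
    theta = rng.normal(0.0, cfg.sigma_theta, size=len(plot_ids))
    b0, b1, b2, b3 = cfg.beta

    censuses = []
    for year in years:
        for pi, plot in enumerate(plot_ids):
            eta = (
                b0
                + b1 * clim_z[year]
                + b2 * elev_z[plot]
                + b3 * clim_z[year] * elev_z[plot]
                + theta[pi]
            )
            total = int(rng.poisson(np.exp(eta)))
            white = int(rng.binomial(total, cfg.white_fraction))
            pink = int(rng.binomial(total - white, cfg.pink_fraction)) if total else 0
            censuses.append(
                FloweringCensus(
                    plot_id=plot,
                    year=year,
                    count_purple=total - white - pink,
                    count_pink=pink,
                    count_white=white,
                )
            )
    truth = {
        "beta": dict(zip(("intercept", "clim", "elev", "clim_elev"), cfg.beta)),
        "sigma_theta": cfg.sigma_theta,
        "theta": dict(zip(plot_ids, theta.tolist())),
        "period": cfg.period,
        "variable": cfg.variable,
        "clim_standardisation": {"mean": float(clim_rows.mean()), "sd": float(clim_rows.std(ddof=1))},
        "elev_standardisation": {"mean": float(elev_rows.mean()), "sd": float(elev_rows.std(ddof=1))},
        "seed": cfg.seed,
    }
    return censuses, weather, truth


# ---------------------------------------------------------------------------
# individual fate histories


def default_truth_matrix() -> pd.DataFrame:
    """Default stage-transition truth (columns = origin; deficit = death).

    Dormancy entries come mostly from the smallest class and most dormant
    plants re-emerge small, as observed in bulbous geophytes; dormant
    mortality is fixed at 0 because a census design with perfect
    above-ground detection cannot identify it (a plant that dies while
    dormant is indistinguishable from one that died the year after its
    last sighting).
    """
    cols = {
        "small": [0.45, 0.15, 0.02, 0.03, 0.20],
        "medium": [0.15, 0.40, 0.20, 0.10, 0.08],
        "large_vegetative": [0.05, 0.20, 0.40, 0.25, 0.03],
        "reproductive": [0.05, 0.15, 0.35, 0.30, 0.05],
        "dormant": [0.55, 0.20, 0.10, 0.05, 0.10],
    }
    return pd.DataFrame(cols, index=list(STAGES))


@dataclass
class DemographyGenConfig:
    """Individual-based simulation of the five-stage fate process."""

    truth_matrix: pd.DataFrame = field(default_factory=default_truth_matrix)
    initial_distribution: tuple[float, ...] = (0.35, 0.25, 0.15, 0.15, 0.10)
    n_individuals: int = 10_000
    n_years: int = 3
    start_year: int = 1981
    seed: int = 0

    def __post_init__(self) -> None:
        a = self.truth_matrix.to_numpy(dtype=float)
        if (a < 0).any() or (a > 1).any():
            raise ValidationError("transition probabilities outside [0, 1]")
        if (a.sum(axis=0) > 1 + 1e-9).any():
            raise ValidationError("truth-matrix column sums exceed 1")
        if not np.isclose(sum(self.initial_distribution), 1.0):
            raise ValidationError("initial distribution must sum to 1")


def gen_individual_fates(
    cfg: DemographyGenConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate individual stage walks and emit census-style observations.

    Returns ``(observed, truth_states, truth_matrix)``: ``observed`` is
    long-format (individual_id, year, stage) with dormant years absent —
    exactly what a field census records; ``truth_states`` keeps every true
    yearly state including ``dormant`` and ``dead``.  Individuals never
    observed above ground (dormant throughout) do not appear in
    ``observed``.
    """
    rng = np.random.default_rng(cfg.seed)
    a = cfg.truth_matrix.to_numpy(dtype=float)
    death = 1.0 - a.sum(axis=0)
    full = np.vstack([a, death])  # destination rows: 5 stages + dead
    years = [cfg.start_year + t for t in range(cfg.n_years)]
    state = rng.choice(len(STAGES), size=cfg.n_individuals, p=cfg.initial_distribution)

    truth_rows = []
    obs_rows = []
    alive = np.ones(cfg.n_individuals, dtype=bool)
    for t, year in enumerate(years):
        for i in range(cfg.n_individuals):
            if not alive[i]:
                continue
            stage = STAGES[state[i]]
            truth_rows.append((i + 1, year, stage))
            if stage != "dormant":
                obs_rows.append((i + 1, year, stage))
        if t < len(years) - 1:
            u = rng.random(cfg.n_individuals)
            for i in range(cfg.n_individuals):
                if not alive[i]:
                    continue
                probs = full[:, state[i]]
                dest = np.searchsorted(np.cumsum(probs), u[i], side="right")
                dest = min(dest, len(STAGES))
                if dest == len(STAGES):
                    alive[i] = False
                    truth_rows.append((i + 1, years[t + 1], "dead"))
                else:
                    state[i] = dest
    truth_states = pd.DataFrame(
        truth_rows, columns=["individual_id", "year", "stage"]
    )
    observed = pd.DataFrame(obs_rows, columns=["individual_id", "year", "stage"])
    return observed, truth_states, cfg.truth_matrix.copy()


def tally_true_transitions(truth_states: pd.DataFrame) -> dict[tuple[int, int], pd.DataFrame]:
    """Empirical transition counts from the true yearly states."""
    out: dict[tuple[int, int], pd.DataFrame] = {}
    by_ind = {
        ind: dict(zip(sub["year"], sub["stage"]))
        for ind, sub in truth_states.groupby("individual_id")
    }
    years = sorted(truth_states["year"].unique())
    for t in years[:-1]:
        frame = pd.DataFrame(
            np.zeros((len(STAGES) + 1, len(STAGES)), dtype=int),
            index=list(STAGES) + ["dead"],
            columns=list(STAGES),
        )
        for states in by_ind.values():
            a, b = states.get(t), states.get(t + 1)
            if a in STAGES and b is not None:
                frame.loc[b, a] += 1
        out[(t, t + 1)] = frame
    return out
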