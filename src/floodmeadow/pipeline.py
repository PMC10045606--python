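"""End-to-end orchestration: simulate → community → indicators → flowering → demography.

A run is described by a declarative config mapping (usually loaded from
YAML); each data stream comes either from an input CSV path or from the
synthetic generators, never both.  Outputs are CSV tables plus a JSON
manifest per stage; identical (config, seed) pairs give identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from floodmeadow import community as comm
from floodmeadow import demography as dem
from floodmeadow import flowering as flow
from floodmeadow import indicators as ind
from floodmeadow import io, ordination, simulate

log = logging.getLogger("floodmeadow")

STAGE_ORDER = ("simulate", "community", "indicators", "flowering", "demography")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "stages": list(STAGE_ORDER),
    "inputs": {},
    "community": {
        "survey_year": 1982,
        "clusters": 4,
        "nmds_dimensions": 2,
        "nmds_restarts": 20,
        "dissimilarity_scale": "raw",
    },
    "flowering": {"period": "mar_apr", "variable": "temperature", "n_quad": 15},
    "demography": {"window": None},
    "simulate": {"community": {}, "flowering": {}, "demography": {}},
}


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


@dataclass
class RunResult:
    """Status and in-memory tables of a pipeline run."""

    status: dict[str, str] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    scalars: dict[str, Any] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(v == "ok" for v in self.status.values())


def _validate_inputs(cfg: Mapping) -> None:
    for name, path in (cfg.get("inputs") or {}).items():
        if not Path(path).exists():
            raise FileNotFoundError(f"configured input {name!r} not found: {path}")


def run_pipeline(cfg: Mapping, outdir: str | Path) -> RunResult:
    """Execute requested stages in dependency order, writing per-stage outputs.

    A stage failure aborts downstream stages; earlier results are kept and
    the status report names the failed stage.
    """
    _validate_inputs(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    result = RunResult()
    data: dict[str, Any] = {}

    stages = [s for s in STAGE_ORDER if s in cfg.get("stages", STAGE_ORDER)]
    for stage in stages:
        try:
            log.info("stage %s starting", stage)
            _STAGE_FUNCS[stage](cfg, seed, data, result)
            result.status[stage] = "ok"
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            result.status[stage] = f"failed: {exc}"
            log.error("stage %s failed: %s", stage, exc)
            break
        stage_tables = {
            k.split("/", 1)[1]: v
            for k, v in result.tables.items()
            if k.startswith(stage + "/")
        }
        if stage_tables:
            io.write_results(stage_tables, outdir / stage, seed=seed, config=dict(cfg))
    (outdir / "status.json").write_text(
        json.dumps({"status": result.status, "scalars": _jsonable(result.scalars)}, indent=2)
    )
    return result


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=lambda o: float(o) if np.isscalar(o) else str(o)))


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg, seed, data, result) -> None:
    inputs = cfg.get("inputs") or {}
    if "cover" in inputs:
        data["cover"], data["plots"] = io.read_cover_csv(inputs["cover"])
    else:
        ccfg = simulate.CommunityGenConfig(seed=seed, **cfg["simulate"].get("community", {}))
        data["cover"], data["plots"] = simulate.gen_meadow_surveys(ccfg)
        data["indicator_table"] = simulate.gen_indicator_table(ccfg)
        result.tables["simulate/cover"] = io.cover_to_frame(data["cover"], data["plots"])
    if "indicators" in inputs:
        data["indicator_table"] = io.read_indicator_csv(inputs["indicators"])
    if "flowering" in inputs and "weather" in inputs:
        data["flowering"] = io.read_flowering_table(inputs["flowering"])
        data["weather"] = io.read_weather_csv(inputs["weather"])
        data["flowering_truth"] = None
    else:
        fcfg = simulate.FloweringGenConfig(seed=seed + 1, **cfg["simulate"].get("flowering", {}))
        data["flowering"], data["weather"], data["flowering_truth"] = (
            simulate.gen_flowering_counts(fcfg)
        )
        data["flowering_elevations"] = fcfg.elevations
        result.tables["simulate/flowering"] = io.flowering_to_frame(data["flowering"])
        result.tables["simulate/weather"] = io.weather_to_frame(data["weather"])
    if "histories" in inputs:
        data["histories"] = io.read_histories_csv(inputs["histories"])
        data["history_window"] = None
    else:
        dcfg = simulate.DemographyGenConfig(seed=seed + 2, **cfg["simulate"].get("demography", {}))
        observed, truth_states, truth_matrix = simulate.gen_individual_fates(dcfg)
        data["histories"] = observed
        data["demography_truth"] = truth_matrix
        data["history_window"] = (dcfg.start_year, dcfg.start_year + dcfg.n_years - 1)
        result.tables["simulate/histories"] = observed


def _stage_community(cfg, seed, data, result) -> None:
    opts = cfg["community"]
    cover = data["cover"]
    plots = data["plots"]
    elev = {p.plot_id: p.elevation for p in plots}

    rows = []
    for year, cm in sorted(cover.items()):
        prof = comm.abundance_profile(cm, scale="midpoint")
        rows.append(
            {
                "survey_year": year,
                "S": comm.species_richness(cm),
                "D": comm.inverse_simpson(prof),
            }
        )
    result.tables["community/diversity"] = pd.DataFrame(rows)

    year = opts.get("survey_year") or max(cover)
    if year not in cover:
        year = max(cover)
    cm = cover[year]
    d = comm.dissimilarity_matrix(cm, scale=opts.get("dissimilarity_scale", "raw"))
    result.tables["community/dissimilarity"] = pd.DataFrame(
        d.values, index=d.labels, columns=[str(c) for c in d.labels]
    ).reset_index(names="plot_id")

    tree = comm.ward_cluster(d)
    assignment = comm.cut_clusters(tree, int(opts.get("clusters", 4)), elevations=elev)
    result.tables["community/clusters"] = pd.DataFrame(
        [
            {"plot_id": p, "cluster": lab, "elevation": elev.get(p)}
            for p, lab in assignment.labels.items()
        ]
    )
    data["cluster_assignment"] = assignment

    ordn = ordination.nmds(
        d,
        k=int(opts.get("nmds_dimensions", 2)),
        n_restarts=int(opts.get("nmds_restarts", 20)),
        seed=seed + 10,
    )
    scores = ordn.scores.reset_index(names="plot_id")
    result.tables["community/nmds_scores"] = scores
    result.scalars["nmds_stress"] = ordn.stress
    result.scalars["nmds_converged"] = bool(ordn.converged)
    data["ordination"] = ordn


def _stage_indicators(cfg, seed, data, result) -> None:
    table = data.get("indicator_table")
    if table is None:
        raise io.ValidationError("no indicator table available")
    frames = [
        ind.weighted_indicator_table(cm, table) for _, cm in sorted(data["cover"].items())
    ]
    weighted = pd.concat(frames, ignore_index=True)
    result.tables["indicators/weighted"] = weighted
    if "cluster_assignment" in data:
        result.tables["indicators/trajectories"] = ind.indicator_trajectories(
            weighted, data["cluster_assignment"]
        )
    if "ordination" in data:
        year = int(weighted["survey_year"].min())
        wide = (
            weighted[weighted["survey_year"] == year]
            .pivot(index="plot_id", columns="indicator", values="value")
        )
        ordn = data["ordination"]
        usable = wide.loc[[p for p in ordn.scores.index if p in wide.index]].dropna(axis=1)
        if len(usable) == len(ordn.scores) and not usable.empty:
            result.tables["indicators/env_vectors"] = ordination.fit_environment_vectors(
                ordn, usable, n_perm=199, seed=seed + 20
            )


def _stage_flowering(cfg, seed, data, result) -> None:
    opts = cfg["flowering"]
    counts = data["flowering"]
    elevations = data.get("flowering_elevations")
    if elevations is None:
        elevations = {p.plot_id: p.elevation for p in data["plots"]}
    fit = flow.fit_poisson_glmm(
        counts,
        data["weather"],
        period=opts.get("period", "mar_apr"),
        variable=opts.get("variable", "temperature"),
        elevations=elevations,
        n_quad=int(opts.get("n_quad", 15)),
    )
    r2m, r2c = flow.r2_marginal_conditional(fit)
    coef = pd.DataFrame(
        {"effect": fit.beta.index, "estimate": fit.beta.values, "se": fit.se.values}
    )
    result.tables["flowering/coefficients"] = coef
    result.scalars.update(
        {
            "glmm_sigma_theta": fit.sigma_theta,
            "glmm_loglik": fit.loglik,
            "glmm_r2_marginal": r2m,
            "glmm_r2_conditional": r2c,
        }
    )
    result.tables["flowering/independence"] = flow.predictor_independence_check(
        data["weather"]
    )
    try:
        prev = flow.prev_year_model(counts, elevations, n_quad=int(opts.get("n_quad", 15)))
        result.tables["flowering/prev_year_coefficients"] = pd.DataFrame(
            {"effect": prev.beta.index, "estimate": prev.beta.values, "se": prev.se.values}
        )
    except io.ValidationError as exc:
        result.scalars["prev_year_model"] = f"skipped: {exc}"
    data["glmm_fit"] = fit


def _stage_demography(cfg, seed, data, result) -> None:
    opts = cfg["demography"]
    window = opts.get("window") or data.get("history_window")
    if window is None:
        hist = data["histories"].dropna(subset=["stage"])
        window = (int(hist["year"].min()), int(hist["year"].max()))
    window = (int(window[0]), int(window[1]))
    fates = dem.classify_fates(data["histories"], window)
    pairs = sorted(fates.counts)
    donor = next(
        (p for p in pairs if fates.counts[p]["dormant"].sum() > 0), None
    )
    rows = []
    for pair in pairs:
        try:
            pm = dem.build_projection_matrix(fates, pair, reuse_dormant_from=donor)
        except io.ValidationError as exc:
            result.scalars[f"matrix_{pair[0]}_{pair[1]}"] = f"skipped: {exc}"
            continue
        res = dem.analyse(pm)
        result.tables[f"demography/matrix_{pair[0]}_{pair[1]}"] = (
            pm.matrix.reset_index(names="to_stage")
        )
        result.tables[f"demography/sensitivity_{pair[0]}_{pair[1]}"] = (
            res.sensitivity.reset_index(names="to_stage")
        )
        rows.append(
            {
                "year_pair": f"{pair[0]}-{pair[1]}",
                "lambda": res.lam,
                "flags": "; ".join(pm.flags),
            }
        )
        result.scalars[f"lambda_{pair[0]}_{pair[1]}"] = res.lam
    result.tables["demography/growth_rates"] = pd.DataFrame(rows)
    result.tables["demography/dormancy_flows"] = dem.dormancy_flow_summary(fates)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "community": _stage_community,
    "indicators": _stage_indicators,
    "flowering": _stage_flowering,
    "demography": _stage_demography,
}
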