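"""Stage-structured matrix population model with a cryptic dormant stage.

Five stages: small, medium, large vegetative, reproductive and dormant.
Dormancy is operationally defined by non-detection: a plant recorded in
two census years but missed in between is placed in the dormant stage for
the gap years; a plant never relocated after its last record is assumed
dead from the first missing year; a newly discovered plant is assumed to
have been dormant in the preceding year.  Death is an absorbing implicit
state — projection-matrix columns sum to the survival probability (≤ 1)
and there is no fecundity row (recruitment by seed is excluded).

From a projection matrix A the module computes the asymptotic growth rate
λ (dominant eigenvalue), the stable stage distribution w, reproductive
values v, sensitivities s_ij = v_i w_j/(v·w) and elasticities
e_ij = (a_ij/λ)·s_ij.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from floodmeadow.io import OBSERVABLE_STAGES, STAGES, ValidationError

DEAD = "dead"
FATE_COLUMNS = STAGES + (DEAD,)


@dataclass
class FateTable:
    """Counts of individual transitions per year-pair.

    ``counts[(t, t+1)]`` is a DataFrame with origin stages as columns and
    destination stages (five stages plus ``dead``) as rows.
    """

    counts: dict[tuple[int, int], pd.DataFrame]
    dormant_years: dict = field(default_factory=dict)
    dead_from: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, frame in self.counts.items():
            if (frame.to_numpy() < 0).any():
                raise ValidationError(f"negative fate count in {pair}")


def _empty_counts() -> pd.DataFrame:
    return pd.DataFrame(
        np.zeros((len(FATE_COLUMNS), len(STAGES)), dtype=int),
        index=list(FATE_COLUMNS),
        columns=list(STAGES),
    )


def classify_fates(
    histories: pd.DataFrame, window: tuple[int, int]
) -> FateTable:
    """Infer each individual's yearly stage (including dormancy and death).

    ``histories`` is long-format with columns individual_id, year, stage
    (stage NaN/absent = not seen).  The window is inclusive.  Rules:

    * unobserved year(s) flanked by observations → dormant for every gap
      year;
    * observed, then never seen again → dead from the first missing year;
    * first appearance after the window start → dormant in the preceding
      year (earlier years are "pre-appearance" and contribute nothing);
    * an individual with zero observations in the window is rejected.
    """
    start, end = window
    if end - start < 1:
        raise ValidationError("window must span at least 2 years")
    counts: dict[tuple[int, int], pd.DataFrame] = {
        (t, t + 1): _empty_counts() for t in range(start, end)
    }
    dormant_years: dict = {}
    dead_from: dict = {}

    obs = histories.dropna(subset=["stage"])
    obs = obs[(obs["year"] >= start) & (obs["year"] <= end)]
    all_ids = histories["individual_id"].unique()
    seen_ids = set(obs["individual_id"].unique())
    unseen = [i for i in all_ids if i not in seen_ids]
    if unseen:
        raise ValidationError(
            f"individuals with zero observations in window: {unseen[:5]}"
        )

    for ind, sub in obs.groupby("individual_id"):
        stage_by_year = dict(zip(sub["year"].astype(int), sub["stage"]))
        first = min(stage_by_year)
        last = max(stage_by_year)
        states: dict[int, str] = {}
        for year in range(first, last + 1):
            if year in stage_by_year:
                states[year] = stage_by_year[year]
            else:
                states[year] = "dormant"
                dormant_years.setdefault(ind, []).append(year)
        if first > start:
            states[first - 1] = "dormant"
            dormant_years.setdefault(ind, []).append(first - 1)
        if last < end:
            states[last + 1] = DEAD
            dead_from[ind] = last + 1
        for t in range(start, end):
            if t in states and (t + 1) in states:
                counts[(t, t + 1)].loc[states[t + 1], states[t]] += 1
    return FateTable(counts=counts, dormant_years=dormant_years, dead_from=dead_from)


@dataclass
class ProjectionMatrix:
    """5×5 stage transition probabilities; column deficits are mortality."""

    matrix: pd.DataFrame
    year_pair: tuple[int, int] | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = self.matrix.to_numpy(dtype=float)
        if a.shape != (len(STAGES), len(STAGES)):
            raise ValidationError("projection matrix must be 5x5")
        if (a < -1e-12).any() or (a > 1 + 1e-12).any():
            raise ValidationError("transition probabilities outside [0, 1]")
        sums = a.sum(axis=0)
        if (sums > 1 + 1e-9).any():
            bad = [STAGES[i] for i in np.nonzero(sums > 1 + 1e-9)[0]]
            raise ValidationError(f"column sums exceed 1 for stages {bad}")

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)


def build_projection_matrix(
    fates: FateTable,
    year_pair: tuple[int, int],
    reuse_dormant_from: tuple[int, int] | None = None,
) -> ProjectionMatrix:
    """Column-wise transition probabilities a_ij = n(j→i)/n(j→anything).

    When the requested year-pair has no individuals leaving the dormant
    stage (its fate is unobservable at the window end), the dormant column
    can be reused from another year-pair via ``reuse_dormant_from``; the
    reuse is flagged on the result.
    """
    if year_pair not in fates.counts:
        raise ValidationError(f"no fate counts for year pair {year_pair}")
    frame = fates.counts[year_pair]
    flags: list[str] = []
    mat = pd.DataFrame(
        np.zeros((len(STAGES), len(STAGES))), index=list(STAGES), columns=list(STAGES)
    )
    for stage in STAGES:
        n_total = frame[stage].sum()
        if n_total == 0:
            if stage == "dormant" and reuse_dormant_from is not None:
                donor = fates.counts[reuse_dormant_from]
                n_donor = donor["dormant"].sum()
                if n_donor == 0:
                    raise ValidationError(
                        "donor year pair also lacks dormant-stage exits"
                    )
                mat["dormant"] = (
                    donor.loc[list(STAGES), "dormant"] / n_donor
                ).to_numpy()
                flags.append(
                    f"dormant column reused from year pair {reuse_dormant_from}"
                )
                continue
            raise ValidationError(
                f"origin stage {stage!r} has no individuals in {year_pair}"
            )
        mat[stage] = (frame.loc[list(STAGES), stage] / n_total).to_numpy()
    return ProjectionMatrix(matrix=mat, year_pair=year_pair, flags=flags)


# ---------------------------------------------------------------------------
# eigen analysis


def _as_array(a) -> np.ndarray:
    if isinstance(a, ProjectionMatrix):
        return a.values
    arr = np.asarray(a, dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("non-finite matrix entries")
    if (arr < 0).any():
        raise ValidationError("projection matrix must be non-negative")
    return arr


def growth_rate(a, cross_check: bool = True) -> float:
    """Asymptotic growth rate λ: the Perron root (spectral radius).

    Cross-checked against power iteration to 1e-10 for primitive matrices.
    """
    arr = _as_array(a)
    vals = np.linalg.eigvals(arr)
    lam = float(np.max(vals.real[np.isclose(vals.imag, 0, atol=1e-8)]))
    if abs(lam) < np.abs(vals).max() - 1e-8:
        # dominant eigenvalue must be the real Perron root for λ to be
        # interpretable; for non-negative matrices it always is
        raise ValidationError("no real dominant eigenvalue")
    if cross_check and lam > 1e-12:
        lam_pi = _power_iteration_lambda(arr)
        if lam_pi is not None and abs(lam_pi - lam) > 1e-8 * max(1.0, lam):
            raise ValidationError(
                f"power iteration disagrees with eigen solve: {lam_pi} vs {lam}"
            )
    return lam


def _power_iteration_lambda(arr: np.ndarray, max_iter: int = 100000) -> float | None:
    x = np.ones(arr.shape[0]) / arr.shape[0]
    lam = 0.0
    for _ in range(max_iter):
        y = arr @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return 0.0
        y = y / norm
        lam_new = float(y @ arr @ y / (y @ y))
        if abs(lam_new - lam) < 1e-12:
            return lam_new
        lam, x = lam_new, y
    return None  # subdominant oscillation (imprimitive matrix): skip check


def stable_structure(a) -> tuple[np.ndarray, np.ndarray]:
    """Stable stage distribution w (Σw = 1) and reproductive values v (v·w = 1)."""
    arr = _as_array(a)
    vals, vecs = np.linalg.eig(arr)
    order = np.argsort(-vals.real)
    vals_sorted = vals[np.argsort(-np.abs(vals))]
    if len(vals_sorted) > 1 and np.isclose(
        np.abs(vals_sorted[0]), np.abs(vals_sorted[1]), atol=1e-10
    ):
        raise ValidationError("dominant eigenvalue is not simple")
    lam_idx = order[0]
    if vals[lam_idx].real <= 0:
        raise ValidationError("dominant eigenvalue not positive")
    w = vecs[:, lam_idx].real
    w = np.abs(w) / np.abs(w).sum()
    lvals, lvecs = np.linalg.eig(arr.T)
    lidx = np.argmin(np.abs(lvals - vals[lam_idx]))
    v = np.abs(lvecs[:, lidx].real)
    v = v / (v @ w)
    return w, v


def sensitivity_matrix(a) -> np.ndarray:
    """Sensitivities s_ij = ∂λ/∂a_ij = v_i w_j / (v·w)."""
    w, v = stable_structure(a)
    return np.outer(v, w) / (v @ w)


def elasticity_matrix(a) -> np.ndarray:
    """Elasticities e_ij = (a_ij/λ)·s_ij; they sum to 1 when λ > 0."""
    arr = _as_array(a)
    lam = growth_rate(arr, cross_check=False)
    if lam <= 0:
        raise ValidationError("elasticities undefined for λ ≤ 0")
    return arr / lam * sensitivity_matrix(arr)


@dataclass
class DemographyResult:
    """λ with its eigenvectors and perturbation matrices for one matrix."""

    lam: float
    w: np.ndarray
    v: np.ndarray
    sensitivity: pd.DataFrame
    elasticity: pd.DataFrame
    year_pair: tuple[int, int] | None = None


def analyse(a: ProjectionMatrix) -> DemographyResult:
    lam = growth_rate(a)
    w, v = stable_structure(a)
    s = pd.DataFrame(sensitivity_matrix(a), index=list(STAGES), columns=list(STAGES))
    e = pd.DataFrame(elasticity_matrix(a), index=list(STAGES), columns=list(STAGES))
    return DemographyResult(
        lam=lam, w=w, v=v, sensitivity=s, elasticity=e, year_pair=a.year_pair
    )


def dormancy_flow_summary(fates: FateTable) -> pd.DataFrame:
    """Entries into and exits from dormancy, by stage and year-pair."""
    rows = []
    for pair, frame in sorted(fates.counts.items()):
        into = frame.loc["dormant", list(OBSERVABLE_STAGES)]
        n_into = int(into.sum())
        outof = frame.loc[list(OBSERVABLE_STAGES), "dormant"]
        n_out = int(outof.sum())
        for stage in OBSERVABLE_STAGES:
            rows.append(
                {
                    "year_pair": f"{pair[0]}-{pair[1]}",
                    "direction": "into_dormancy",
                    "stage": stage,
                    "count": int(into[stage]),
                    "percent": 100.0 * into[stage] / n_into if n_into else 0.0,
                }
            )
            rows.append(
                {
                    "year_pair": f"{pair[0]}-{pair[1]}",
                    "direction": "out_of_dormancy",
                    "stage": stage,
                    "count": int(outof[stage]),
                    "percent": 100.0 * outof[stage] / n_out if n_out else 0.0,
                }
            )
    return pd.DataFrame(rows)
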