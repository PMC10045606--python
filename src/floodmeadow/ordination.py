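"""Non-metric multidimensional scaling with Kruskal stress-1.

The ordination embeds entities in k dimensions so that configuration
distances are monotone with the input dissimilarities.  Each restart
alternates a pool-adjacent-violators (PAVA) isotonic fit of the
configuration distances on the dissimilarity ranks with a Guttman-transform
update of the configuration; stress-1 is

    stress = sqrt( Σ (d̂ − d*)² / Σ d̂² )

with d̂ the configuration distances and d* their monotone regression.
Ties in the input dissimilarities receive the primary treatment (tied
pairs are free to take any order).  The best configuration over restarts
is returned, centred and rotated to its principal axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist

from floodmeadow.community import DissimilarityMatrix
from floodmeadow.io import ValidationError


def pava(y, weights=None, increasing: bool = True) -> np.ndarray:
    """Least-squares monotone (isotonic) regression of a sequence.

    Returns the non-decreasing (or non-increasing) fit minimising the
    weighted sum of squared deviations from ``y``.
    """
    y = np.asarray(y, dtype=float)
    res = isotonic_regression(y, weights=weights, increasing=increasing)
    return np.asarray(res.x, dtype=float)


@dataclass
class OrdinationResult:
    """NMDS scores with the stress achieved and restart diagnostics."""

    scores: pd.DataFrame
    stress: float
    n_restarts: int
    converged: bool
    seed: int | None
    restart_stresses: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.stress <= 1.0 + 1e-12:
            raise ValidationError(f"stress {self.stress} outside [0, 1]")
        if self.restart_stresses and self.stress > min(self.restart_stresses) + 1e-12:
            raise ValidationError("reported stress exceeds best restart stress")


def _classical_mds(d_full: np.ndarray, k: int) -> np.ndarray:
    """Principal-coordinates start configuration (Torgerson scaling)."""
    n = d_full.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d_full**2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[idx], 0, None)
    return vecs[:, idx] * np.sqrt(vals)


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = (dist**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - disp) ** 2).sum() / denom))


def _disparities(dist: np.ndarray, diss: np.ndarray) -> np.ndarray:
    # primary tie treatment: within blocks of tied dissimilarity, order by
    # current distance so tied pairs impose no constraint on each other
    order = np.lexsort((dist, diss))
    fit = pava(dist[order])
    disp = np.empty_like(fit)
    disp[order] = fit
    return disp


def _smacof_restart(
    diss: np.ndarray, x0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool]:
    n = x0.shape[0]
    x = x0.copy()
    best_x, best_stress = x.copy(), np.inf
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        dist = pdist(x)
        disp = _disparities(dist, diss)
        stress = _stress1(dist, disp)
        if stress < best_stress:
            best_stress, best_x = stress, x.copy()
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # Guttman transform with the current disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, disp / dist, 0.0)
        from scipy.spatial.distance import squareform

        r_full = squareform(ratio, checks=False)
        b = -r_full
        np.fill_diagonal(b, r_full.sum(axis=1))
        x = b @ x / n
    return best_x, best_stress, converged


def nmds(
    d: DissimilarityMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Best-of-restarts NMDS of a dissimilarity matrix into k dimensions.

    Restart 0 starts from the principal-coordinates configuration; the
    remaining restarts start from seeded random configurations.
    Non-convergence of every restart is flagged, not fatal.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    rng = np.random.default_rng(seed)
    diss = d.condensed
    n = len(d.labels)
    if n <= k:
        raise ValidationError("need more entities than dimensions")

    best_x, best_stress, any_converged = None, np.inf, False
    restart_stresses = []
    scale = max(diss.max(), 1e-12)
    for r in range(max(1, n_restarts)):
        if r == 0:
            x0 = _classical_mds(d.values, k)
            if not np.isfinite(x0).all() or np.allclose(x0, 0):
                x0 = rng.normal(size=(n, k)) * scale
        else:
            x0 = rng.normal(size=(n, k)) * scale
        x, stress, conv = _smacof_restart(diss, x0, max_iter, tol)
        restart_stresses.append(stress)
        any_converged = any_converged or conv
        if stress < best_stress:
            best_stress, best_x = stress, x

    best_x = best_x - best_x.mean(axis=0)
    # rotate to principal axes for a reproducible orientation
    _, _, vt = np.linalg.svd(best_x, full_matrices=False)
    scores = best_x @ vt.T
    # fix sign convention: largest-magnitude loading positive per axis
    for col in range(scores.shape[1]):
        imax = np.argmax(np.abs(scores[:, col]))
        if scores[imax, col] < 0:
            scores[:, col] *= -1
    frame = pd.DataFrame(
        scores, index=d.labels, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        scores=frame,
        stress=best_stress,
        n_restarts=max(1, n_restarts),
        converged=any_converged,
        seed=seed,
        restart_stresses=restart_stresses,
    )


def fit_environment_vectors(
    ordination: OrdinationResult,
    variables: pd.DataFrame,
    n_perm: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Least-squares environmental vectors on the ordination scores.

    Each variable is regressed on the (centred) score columns; the arrow is
    the unit coefficient vector and r² the fraction of variance explained.
    With ``n_perm > 0`` a permutation p-value is appended (variable values
    permuted over entities, seeded).
    """
    missing = [i for i in ordination.scores.index if i not in variables.index]
    if missing:
        raise ValidationError(f"variables missing for entities: {missing[:5]}")
    s = ordination.scores.to_numpy()
    s = s - s.mean(axis=0)
    rng = np.random.default_rng(seed)
    rows = []
    for name in variables.columns:
        v = variables.loc[ordination.scores.index, name].to_numpy(dtype=float)
        rows.append(_fit_one_vector(s, v, name, n_perm, rng))
    return pd.DataFrame(rows)


def _r2(s: np.ndarray, v: np.ndarray) -> tuple[float, np.ndarray]:
    vc = v - v.mean()
    ss_tot = (vc**2).sum()
    if ss_tot == 0:
        return 0.0, np.zeros(s.shape[1])
    coef, *_ = np.linalg.lstsq(s, vc, rcond=None)
    ss_res = ((vc - s @ coef) ** 2).sum()
    return float(1 - ss_res / ss_tot), coef


def _fit_one_vector(s, v, name, n_perm, rng) -> dict:
    r2, coef = _r2(s, v)
    norm = np.linalg.norm(coef)
    direction = coef / norm if norm > 0 else np.zeros_like(coef)
    row = {"variable": name, "r2": r2}
    for i, c in enumerate(direction):
        row[f"axis{i + 1}"] = float(c)
    if n_perm > 0:
        hits = sum(_r2(s, rng.permutation(v))[0] >= r2 for _ in range(n_perm))
        row["p_perm"] = (hits + 1) / (n_perm + 1)
    return row
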