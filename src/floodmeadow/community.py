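"""Vegetation-structure analyses on ordinal cover data.

Covers the Hult-Sernander-Du Rietz (HSD) midpoint transform, species
richness, inverse Simpson diversity, relative and rank abundance,
Bray–Curtis dissimilarity, Ward.D2 hierarchical clustering with cluster
cutting, and the exact binomial colonisation/extinction test.  Ordination
(NMDS) lives in :mod:`floodmeadow.ordination`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from floodmeadow.io import CoverMatrix, GroupAssignment, ValidationError

#: percent-cover midpoints of the geometrically halving HSD classes
#: (0–6.25, 6.25–12.5, 12.5–25, 25–50, 50–100 %); score 0 = absent.
HSD_MIDPOINTS = np.array([0.0, 3.125, 9.375, 18.75, 37.5, 75.0])

#: upper class bounds used when discretising percent cover back to scores
HSD_UPPER_BOUNDS = np.array([6.25, 12.5, 25.0, 50.0])


def hsd_to_percent(score):
    """Map HSD score(s) in {0..5} to percent-cover class midpoints."""
    arr = np.asarray(score)
    if not np.isin(arr, np.arange(6)).all():
        raise ValidationError(f"HSD score outside 0..5: {arr}")
    out = HSD_MIDPOINTS[arr.astype(int)]
    return float(out) if np.isscalar(score) or arr.ndim == 0 else out


def percent_to_hsd(percent, absence_threshold: float = 0.5):
    """Discretise percent cover to the 5-degree scale.

    Cover below ``absence_threshold`` (%) is recorded as absent (0); the
    class bounds halve geometrically down from 100 %.
    """
    arr = np.atleast_1d(np.asarray(percent, dtype=float))
    scores = 1 + np.searchsorted(HSD_UPPER_BOUNDS, arr, side="left")
    scores = np.where(arr < absence_threshold, 0, scores)
    return scores if np.ndim(percent) else int(scores[0])


def _subset(cover: CoverMatrix, plots: Sequence[int] | None) -> pd.DataFrame:
    if plots is None:
        return cover.scores
    missing = [p for p in plots if p not in cover.scores.index]
    if missing:
        raise ValidationError(f"plots not in survey {cover.survey_year}: {missing}")
    return cover.scores.loc[list(plots)]


def species_richness(cover: CoverMatrix, plots: Sequence[int] | None = None) -> int:
    """Number of species present (score > 0) in at least one plot of the subset."""
    sub = _subset(cover, plots)
    if sub.empty:
        raise ValidationError("empty plot subset")
    return int((sub.sum(axis=0) > 0).sum())


@dataclass
class AbundanceProfile:
    """Per-species abundances for one entity (plot, group, pooled survey)."""

    label: str
    abundance: pd.Series

    def __post_init__(self) -> None:
        if (self.abundance < 0).any():
            raise ValidationError("negative abundance")

    @property
    def relative(self) -> pd.Series:
        total = self.abundance.sum()
        if total <= 0:
            raise ValidationError(f"profile {self.label!r} has zero total abundance")
        return self.abundance / total


def abundance_profile(
    cover: CoverMatrix,
    plots: Sequence[int] | None = None,
    scale: str = "midpoint",
    label: str | None = None,
) -> AbundanceProfile:
    """Pool cover over a plot subset into per-species abundances.

    ``scale="midpoint"`` sums percent-cover class midpoints (the default
    for dominance statements); ``scale="raw"`` sums the ordinal scores.
    """
    sub = _subset(cover, plots)
    if scale == "midpoint":
        vals = pd.Series(
            hsd_to_percent(sub.to_numpy()).sum(axis=0), index=sub.columns
        )
    elif scale == "raw":
        vals = sub.sum(axis=0).astype(float)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return AbundanceProfile(label=label or f"survey {cover.survey_year}", abundance=vals)


def inverse_simpson(profile: AbundanceProfile | pd.Series | np.ndarray) -> float:
    """Inverse Simpson diversity D = 1/Σp_i² (effective species number)."""
    if isinstance(profile, AbundanceProfile):
        p = profile.relative.to_numpy()
    else:
        arr = np.asarray(profile, dtype=float)
        if (arr < 0).any():
            raise ValidationError("negative abundance")
        total = arr.sum()
        if total <= 0:
            raise ValidationError("all-zero abundance profile")
        p = arr / total
    return float(1.0 / np.sum(p**2))


def relative_abundance(
    cover: CoverMatrix,
    species: str,
    plots: Sequence[int] | None = None,
    scale: str = "midpoint",
) -> float:
    """Percent of total (pooled) abundance contributed by one species."""
    prof = abundance_profile(cover, plots, scale=scale)
    if species not in prof.abundance.index:
        raise ValidationError(f"species {species!r} not in survey {cover.survey_year}")
    return float(prof.relative[species] * 100.0)


def rank_abundance(
    cover: CoverMatrix, plots: Sequence[int] | None = None
) -> pd.DataFrame:
    """Species ranked by mean raw cover score (descending, ties alphabetical)."""
    sub = _subset(cover, plots)
    if sub.empty:
        raise ValidationError("empty plot subset")
    means = sub.mean(axis=0)
    out = (
        means.rename("mean_cover")
        .reset_index()
        .rename(columns={"index": "species"})
        .sort_values(["mean_cover", "species"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity Σ|x−y| / Σ(x+y) of two abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("negative abundances")
    denom = (x + y).sum()
    if denom == 0:
        raise ValidationError("both profiles empty: Bray-Curtis undefined")
    return float(np.abs(x - y).sum() / denom)


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with entity labels."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.isnan(v).any():
            raise ValidationError("NaN in dissimilarity matrix")
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix not symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValidationError("nonzero diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValidationError("entries outside [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def dissimilarity_matrix(
    cover: CoverMatrix, plots: Sequence[int] | None = None, scale: str = "raw"
) -> DissimilarityMatrix:
    """Pairwise Bray–Curtis between plots of one survey.

    Raw ordinal scores are the default input scale; ``scale="midpoint"``
    switches to percent-cover midpoints.
    """
    sub = _subset(cover, plots)
    data = sub.to_numpy(dtype=float)
    if scale == "midpoint":
        data = hsd_to_percent(sub.to_numpy())
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    n = data.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(data[i], data[j])
    return DissimilarityMatrix(labels=list(sub.index), values=out)


@dataclass
class ClusterResult:
    """Agglomerative merge tree (scipy linkage encoding) over labelled entities."""

    labels: list
    linkage_matrix: np.ndarray

    def __post_init__(self) -> None:
        heights = self.linkage_matrix[:, 2]
        if not (np.diff(heights) >= -1e-10).all():
            raise ValidationError("merge heights not non-decreasing")

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def ward_cluster(d: DissimilarityMatrix) -> ClusterResult:
    """Agglomerative clustering with the Ward.D2 criterion.

    Operates directly on the supplied dissimilarities via the
    Lance–Williams update of the D2 variant (squared internally, heights
    reported on the dissimilarity scale).
    """
    if len(d.labels) < 2:
        raise ValidationError("need at least two entities to cluster")
    Z = linkage(d.condensed, method="ward")
    return ClusterResult(labels=list(d.labels), linkage_matrix=Z)


def cut_clusters(
    result: ClusterResult,
    k: int,
    elevations: Mapping[int, float] | None = None,
    scheme: str = "cluster",
) -> GroupAssignment:
    """Cut the merge tree into k groups.

    Cluster ids are relabelled by descending mean elevation (cluster 1 =
    driest) when elevations are supplied; otherwise by first appearance.
    """
    n = len(result.labels)
    if not 1 <= k <= n:
        raise ValidationError(f"k = {k} out of range 1..{n}")
    raw = fcluster(result.linkage_matrix, t=k, criterion="maxclust")
    ids = sorted(set(raw))
    if elevations is not None:
        mean_elev = {
            c: np.mean([elevations[lab] for lab, r in zip(result.labels, raw) if r == c])
            for c in ids
        }
        order = sorted(ids, key=lambda c: -mean_elev[c])
    else:
        seen: list[int] = []
        for r in raw:
            if r not in seen:
                seen.append(r)
        order = seen
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = {
        lab: f"Cluster{relabel[r]}" for lab, r in zip(result.labels, raw)
    }
    return GroupAssignment(scheme=scheme, labels=labels)


def cluster_sizes(assignment: GroupAssignment) -> dict[str, int]:
    out: dict[str, int] = {}
    for lab in assignment.labels.values():
        out[lab] = out.get(lab, 0) + 1
    return dict(sorted(out.items()))


def frequency_change_test(gains: int, losses: int) -> float:
    """Exact two-sided binomial test of gains vs losses (p = 0.5).

    The two-sided p-value doubles the smaller tail probability and is
    capped at 1.
    """
    if gains < 0 or losses < 0:
        raise ValidationError("negative counts")
    n = gains + losses
    if n == 0:
        raise ValidationError("no colonisations or extinctions: test undefined")
    k = min(gains, losses)
    tail = sum(math.comb(n, i) for i in range(k + 1)) / 2**n
    return min(1.0, 2.0 * tail)
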