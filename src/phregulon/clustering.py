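"""Expression-profile standardization and fuzzy c-means clustering.

Per-gene profiles are replicate-averaged condition means, centered and
scaled to unit (population) standard deviation, so that clustering sees
profile *shape* rather than absolute level or amplitude — the canonical
preprocessing for soft time-course clustering. The clustering itself is
fuzzy c-means: each gene holds a membership distribution over ``c``
clusters, with softness controlled by the fuzzifier ``m > 1``; alternating
updates of memberships and centroids monotonically decrease the objective

.. math:: J = \\sum_{i,j} u_{ij}^m \\, \\lVert x_j - v_i \\rVert^2 .

The fuzzifier default can be estimated from the data by the
dispersion-based heuristic used in the soft-clustering ecosystem, with a
fixed fallback of 1.25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class FuzzyClusterModel:
    n_clusters: int
    fuzzifier: float
    centroids: np.ndarray          # c x n_conditions
    memberships: pd.DataFrame      # genes x c
    objective: float
    seed: int
    n_iter: int
    condition_labels: list = field(default_factory=list)


def condition_means(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Average replicates within each (strain, pH, time point) cell.

    Columns are labelled ``strain:pH:time`` in design order of first
    appearance.
    """
    cells = design[["strain", "ph", "time_point"]].drop_duplicates()
    out = {}
    for _, cell in cells.iterrows():
        mask = (
            (design["strain"] == cell["strain"])
            & (design["ph"] == cell["ph"])
            & (design["time_point"] == cell["time_point"])
        )
        cols = design.loc[mask, "sample_id"].tolist()
        label = f"{cell['strain']}:{cell['ph']:g}:{cell['time_point']}"
        out[label] = matrix[cols].mean(axis=1)
    return pd.DataFrame(out, index=matrix.index)


def standardize_profiles(
    matrix: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Condition-mean profiles centered to mean 0 and scaled to sd 1.

    Uses the population standard deviation across condition cells. Genes
    with zero variance carry no shape information and are dropped; the
    second return value is the dropped count.
    """
    means = condition_means(matrix, design)
    if means.shape[1] < 2:
        raise ValueError("standardization needs >= 2 condition cells")
    values = means.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population sd
    keep = sd[:, 0] > 0
    n_dropped = int((~keep).sum())
    std = (values[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(std, index=means.index[keep], columns=means.columns), n_dropped


def estimate_fuzzifier(profiles: pd.DataFrame) -> float:
    """Dispersion-based fuzzifier estimate from data dimensions.

    ``m = 1 + (1418/N + 22.05) D^-2 + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)``
    with N genes and D conditions; falls back to 1.25 when the formula is
    outside its validity range (tiny inputs).
    """
    N, D = profiles.shape
    if N < 10 or D < 2:
        return 1.25
    m = (
        1.0
        + (1418.0 / N + 22.05) * D ** -2
        + (12.33 / N + 0.243) * D ** (-0.0406 * math.log(N) - 0.1134)
    )
    return float(m) if m > 1.0 else 1.25


def _kmeanspp_init(x: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style centroid seeding from the gene profiles."""
    n = x.shape[0]
    centroids = np.empty((c, x.shape[1]))
    idx = rng.integers(n)
    centroids[0] = x[idx]
    d2 = ((x - centroids[0]) ** 2).sum(axis=1)
    for i in range(1, c):
        total = d2.sum()
        if total <= 0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centroids[i] = x[idx]
        d2 = np.minimum(d2, ((x - centroids[i]) ** 2).sum(axis=1))
    return centroids


def _memberships_from_distances(d2: np.ndarray, m: float) -> np.ndarray:
    """u_ij = 1 / sum_k (d_ij/d_kj)^(2/(m-1)); exact-coincidence ties split
    membership equally among the coincident centroids."""
    power = 1.0 / (m - 1.0)
    zero = d2 <= 0
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** -power
        u = inv / inv.sum(axis=1, keepdims=True)
    if any_zero.any():
        rows = np.where(any_zero)[0]
        u[rows] = 0.0
        z = zero[rows]
        u[rows] = z / z.sum(axis=1, keepdims=True)
    return u


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int = 50,
    m: float | None = None,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 10,
    record_objective: bool = False,
) -> FuzzyClusterModel:
    """Fuzzy c-means with k-means++ seeding and multiple restarts.

    Alternates membership and centroid updates until the largest membership
    change falls below ``tol``; the best of ``n_restarts`` runs (lowest
    objective) is returned. Deterministic under ``seed``. With
    ``record_objective`` the model carries the per-iteration objective
    trajectory of the winning restart (``objective_trace``).
    """
    if c < 2:
        raise ValueError("need c >= 2 clusters")
    x = profiles.to_numpy(dtype=float)
    n = x.shape[0]
    if n < c:
        raise ValueError(f"need at least c={c} genes, got {n}")
    if m is None:
        m = estimate_fuzzifier(profiles)
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        centroids = _kmeanspp_init(x, c, rng)
        u_prev = None
        trace = []
        for it in range(1, max_iter + 1):
            d2 = cdist(x, centroids, "sqeuclidean")
            u = _memberships_from_distances(d2, m)
            um = u ** m
            denom = um.sum(axis=0)[:, None]
            # empty cluster guard: keep previous centroid
            nonzero = denom[:, 0] > 0
            new_centroids = centroids.copy()
            new_centroids[nonzero] = (um.T @ x)[nonzero] / denom[nonzero]
            centroids = new_centroids
            if record_objective:
                trace.append(float((um * d2).sum()))
            if u_prev is not None and np.abs(u - u_prev).max() < tol:
                break
            u_prev = u
        d2 = cdist(x, centroids, "sqeuclidean")
        u = _memberships_from_distances(d2, m)
        objective = float((u ** m * d2).sum())
        if best is None or objective < best[0]:
            best = (objective, centroids, u, it, trace)
    objective, centroids, u, n_iter, trace = best
    model = FuzzyClusterModel(
        n_clusters=c,
        fuzzifier=float(m),
        centroids=centroids,
        memberships=pd.DataFrame(
            u, index=profiles.index, columns=[f"cluster_{i + 1}" for i in range(c)]
        ),
        objective=objective,
        seed=seed,
        n_iter=n_iter,
        condition_labels=list(profiles.columns),
    )
    if record_objective:
        model.objective_trace = trace
    return model


def assign_clusters(model: FuzzyClusterModel) -> pd.DataFrame:
    """Hard labels: argmax membership, ties broken toward the lowest index.

    Returns a frame with 1-based ``cluster`` labels and ``max_membership``.
    """
    u = model.memberships.to_numpy()
    labels = u.argmax(axis=1) + 1  # argmax takes first maximum: lowest index
    return pd.DataFrame(
        {"cluster": labels, "max_membership": u.max(axis=1)},
        index=model.memberships.index,
    )
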