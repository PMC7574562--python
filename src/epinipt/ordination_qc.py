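"""Ordination-based sample QC.

Outlier screening follows the coverage-profile route: Hellinger-transformed
count matrices, Bray–Curtis dissimilarity, 2-D non-metric multidimensional
scaling (Kruskal stress-1, isotonic regression of embedded distances on
dissimilarity ranks), and a per-group two-standard-deviation rule on either
ordination axis. A one-way ANOVA helper summarises group differences in
per-sample totals or fractions.

Bray–Curtis is a dissimilarity; the standard dissimilarity form
sum|a-b| / sum(a+b) is used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof


@dataclass
class OrdinationResult:
    embedding: np.ndarray          # (n_samples, dims), centred at the origin
    stress: float                  # Kruskal stress-1 of the returned solution
    n_restarts: int
    converged: bool
    restart_stresses: np.ndarray   # final stress of every restart


def bray_curtis(matrix: np.ndarray, sample_ids: list[str] | None = None) -> np.ndarray:
    """Pairwise Bray–Curtis dissimilarity between sample rows.

    d(a, b) = sum|a_i - b_i| / sum(a_i + b_i); symmetric, zero diagonal,
    values in [0, 1] for non-negative input.
    """
    matrix = np.asarray(matrix, dtype=float)
    if np.any(matrix < 0):
        raise ValueError("Bray-Curtis requires non-negative entries")
    zero = np.where(matrix.sum(axis=1) == 0)[0]
    if zero.size >= 2:
        names = [sample_ids[i] if sample_ids else f"row {i}" for i in zero]
        raise ValueError(f"all-zero rows make Bray-Curtis undefined: {names}")
    d = squareform(pdist(matrix, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return d


def _classical_mds(d: np.ndarray, dims: int) -> np.ndarray:
    """Classical (Torgerson) metric MDS used as the first nMDS start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    comps = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
    return comps


def nmds(
    dissimilarity: np.ndarray,
    dims: int = 2,
    restarts: int = 20,
    max_iter: int = 300,
    seed: int = 0,
    eps: float = 1e-9,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1.

    One start from classical metric MDS of the dissimilarity plus
    ``restarts - 1`` seeded random starts; the lowest-stress solution is
    returned with its embedding centred at the origin.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("dissimilarities must be finite")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    inits: list[np.ndarray | None] = [_classical_mds(d, dims)]
    inits += [rng.standard_normal((d.shape[0], dims)) for _ in range(restarts - 1)]
    best = None
    stresses = []
    for init in inits:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb, stress, n_iter = smacof(
                d, metric=False, n_components=dims, init=init, n_init=1,
                max_iter=max_iter, eps=eps, normalized_stress=True,
                random_state=0, return_n_iter=True,
            )
        stresses.append(stress)
        if best is None or stress < best[1]:
            best = (emb, stress, n_iter)
    emb, stress, n_iter = best
    emb = emb - emb.mean(axis=0)
    return OrdinationResult(
        embedding=emb,
        stress=float(stress),
        n_restarts=restarts,
        converged=n_iter < max_iter,
        restart_stresses=np.asarray(stresses),
    )


def flag_outliers(
    embedding: np.ndarray,
    groups: list[str] | np.ndarray,
    k: float = 2.0,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group k-SD outlier rule on each ordination axis.

    A sample is flagged when its coordinate deviates from its own group's
    mean by more than ``k`` group standard deviations (ddof=1) on either
    axis. Groups with fewer than 3 members are skipped with a warning.
    Flagged samples are listed, never silently dropped.
    """
    embedding = np.asarray(embedding, dtype=float)
    groups = np.asarray(groups)
    n = embedding.shape[0]
    if groups.size != n:
        raise ValueError("groups length must match embedding rows")
    ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]
    flagged = np.zeros(n, dtype=bool)
    axis_hit = np.full(n, "", dtype=object)
    skipped = np.zeros(n, dtype=bool)
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < 3:
            warnings.warn(f"group {g!r} has fewer than 3 members; skipped")
            skipped[mask] = True
            continue
        mean = embedding[mask].mean(axis=0)
        sd = embedding[mask].std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dev = np.abs(embedding[mask] - mean) > k * sd
        dev &= sd > 0                      # identical coordinates: never flagged
        flagged[mask] = dev.any(axis=1)
        hits = np.where(
            dev[:, 0] & dev[:, 1], "both",
            np.where(dev[:, 0], "nMDS1", np.where(dev[:, 1], "nMDS2", "")),
        )
        axis_hit[mask] = hits
    return pd.DataFrame(
        {"sample_id": ids, "group": groups, "outlier": flagged,
         "axis": axis_hit, "group_skipped": skipped}
    )


def group_anova(
    values: np.ndarray, groups: list[str] | np.ndarray, log2_transform: bool = False
) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of per-sample values across groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if log2_transform:
        values = np.log2(values)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if values.size - uniq.size < 1:
        raise ValueError("ANOVA needs at least 2 residual degrees of freedom")
    samples = [values[groups == g] for g in uniq]
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*samples)
    if np.isnan(f):                         # all values identical everywhere
        f, p = 0.0, 1.0
    return float(f), float(p)
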