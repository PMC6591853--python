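"""Dermatotype calling: Jensen-Shannon distances, PAM clustering, model selection.

A *dermatotype* is a cluster of skin-microbiome samples with similar
composition, the skin analogue of gut enterotypes.  The calling procedure is
the enterotype convention:

1. pairwise sample distance = sqrt of the Jensen-Shannon divergence with
   logarithms base 2 (bounded in [0, 1] and a proper metric);
2. partitioning around medoids (PAM, deterministic BUILD + SWAP) for each
   candidate number of clusters k;
3. the Calinski-Harabasz (CH) index — evaluated on the classical-MDS (PCoA)
   embedding of the distance matrix, using every positive-eigenvalue axis —
   selects k (ties broken toward smaller k), verified by average silhouette
   width.

The CH index is defined for coordinate data; computing it in full PCoA space
is exact for Euclidean-embeddable distances and makes the generalisation to
distance-only data explicit and reproducible.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

__all__ = [
    "jsd_distance",
    "jsd_matrix",
    "pam",
    "ch_index",
    "silhouette",
    "pcoa",
    "select_dermatotypes",
    "PCoAResult",
    "DermatotypeResult",
    "DegenerateDistancesWarning",
]

_EPS = 1e-12


class DegenerateDistancesWarning(UserWarning):
    pass


def _as_prob(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if (v < 0).any():
        raise ValueError("negative abundance")
    s = v.sum()
    if s <= 0:
        raise ValueError("zero total abundance")
    return v / s


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def jsd_distance(
    p: Sequence[float] | pd.Series,
    q: Sequence[float] | pd.Series,
    sqrt: bool = True,
) -> float:
    """Jensen-Shannon distance between two abundance profiles.

    Profiles are rescaled to probabilities; logs are base 2, so the divergence
    lies in [0, 1] with 1 attained on disjoint supports.  By default the
    square root is returned (the metric form); ``sqrt=False`` gives the plain
    divergence.  Profiles must share the same taxon universe — mismatched
    pandas indexes raise rather than silently re-aligning.
    """
    if isinstance(p, pd.Series) and isinstance(q, pd.Series):
        if not p.index.equals(q.index):
            raise ValueError("profiles have mismatched taxon sets/order")
    pa, qa = _as_prob(np.asarray(p, dtype=float)), _as_prob(np.asarray(q, dtype=float))
    if pa.shape != qa.shape:
        raise ValueError("profiles have different lengths")
    m = 0.5 * (pa + qa)
    d = _entropy2(m) - 0.5 * (_entropy2(pa) + _entropy2(qa))
    d = min(max(d, 0.0), 1.0)
    return float(np.sqrt(d)) if sqrt else float(d)


def jsd_matrix(abundances: pd.DataFrame, sqrt: bool = True, block: int = 128) -> pd.DataFrame:
    """Pairwise Jensen-Shannon distance matrix of an abundance table.

    Vectorised: row entropies are computed once and mixture entropies in
    blocks, so the cost is O(n^2 k) with small constants.
    """
    P = abundances.to_numpy(dtype=float)
    sums = P.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("abundance table has an all-zero row")
    P = P / sums[:, None]
    n = P.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(P > 0, np.log2(np.where(P > 0, P, 1.0)), 0.0)
    h = -(P * logs).sum(axis=1)
    D = np.zeros((n, n))
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        M = 0.5 * (P[i0:i1, None, :] + P[None, :, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            logm = np.where(M > 0, np.log2(np.where(M > 0, M, 1.0)), 0.0)
        hm = -(M * logm).sum(axis=-1)
        D[i0:i1] = hm - 0.5 * (h[i0:i1, None] + h[None, :])
    np.clip(D, 0.0, 1.0, out=D)
    if sqrt:
        np.sqrt(D, out=D)
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)  # kill float asymmetry
    return pd.DataFrame(D, index=abundances.index, columns=abundances.index)


def _check_square(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    return d


def pam(
    d: pd.DataFrame | np.ndarray,
    k: int,
    seed: int | None = None,
    max_iter: int = 200,
    exact_limit: int = 2000,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Partitioning around medoids on a precomputed distance matrix.

    Exact when the medoid search space is tiny (C(n, k) <= ``exact_limit``
    subsets are enumerated outright — at that scale exactness is cheaper
    than cleverness); otherwise deterministic BUILD (greedy medoid addition
    minimising total cost) followed by SWAP (best single medoid/non-medoid
    exchange, repeated to a local optimum).  All ties break toward the
    lowest sample index, so the result depends only on ``d`` — ``seed`` is
    accepted for interface symmetry and ignored.

    Returns ``(labels, medoid_indices, objective)`` where the objective is
    the summed distance of every sample to its medoid.
    """
    del seed
    D = _check_square(np.asarray(d))
    n = D.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n_samples, got k={k}, n={n}")

    if math.comb(n, k) <= exact_limit:
        best_obj, best_set = np.inf, None
        for med in itertools.combinations(range(n), k):
            obj = D[:, med].min(axis=1).sum()
            if obj < best_obj - _EPS:
                best_obj, best_set = obj, med
        medoid_arr = np.asarray(best_set, dtype=int)
        labels = np.argmin(D[medoid_arr], axis=0)
        labels[medoid_arr] = np.arange(k)
        return labels, medoid_arr, float(best_obj)

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dmin = D[medoids[0]].copy()
    while len(medoids) < k:
        cand = np.minimum(dmin[None, :], D).sum(axis=1)
        cand[medoids] = np.inf
        j = int(np.argmin(cand))
        medoids.append(j)
        np.minimum(dmin, D[j], out=dmin)
    medoids = sorted(medoids)
    obj = float(dmin.sum())

    # SWAP: for each current medoid m, the objective after replacing m by h
    # (for all h at once) is sum_i min(d(i, remaining medoids), d(i, h)).
    for _ in range(max_iter):
        Dm = D[medoids]                      # k x n
        order = np.argsort(Dm, axis=0)
        nearest = Dm[order[0], np.arange(n)]
        second = Dm[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
        best = (obj, None, None)
        for mi, m in enumerate(medoids):
            rest = np.where(order[0] == mi, second, nearest)
            cand = np.minimum(rest[None, :], D).sum(axis=1)
            cand[medoids] = np.inf
            h = int(np.argmin(cand))
            if cand[h] < best[0] - _EPS:
                best = (float(cand[h]), mi, h)
        if best[1] is None:
            break
        obj, mi, h = best
        medoids[mi] = h
        medoids = sorted(medoids)
    medoid_arr = np.asarray(medoids, dtype=int)
    labels = np.argmin(D[medoid_arr], axis=0)
    labels[medoid_arr] = np.arange(k)  # medoids always label themselves
    obj = float(D[medoid_arr].min(axis=0).sum())
    return labels, medoid_arr, obj


def pcoa(d: pd.DataFrame | np.ndarray, n_axes: int | None = None) -> "PCoAResult":
    """Classical multidimensional scaling (principal coordinate analysis).

    Double-centres -0.5 d^2, eigendecomposes, keeps positive-eigenvalue axes
    ordered by decreasing eigenvalue, and reports the total magnitude of any
    negative eigenvalues dropped.  Explained fractions are relative to the sum
    of positive eigenvalues.
    """
    D = _check_square(np.asarray(d))
    n = D.shape[0]
    ids = list(d.index) if isinstance(d, pd.DataFrame) else list(range(n))
    B = -0.5 * D**2
    B -= B.mean(axis=0)[None, :]
    B -= B.mean(axis=1)[:, None]
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1]
    evals, evecs = evals[idx], evecs[:, idx]
    pos = evals > max(evals.max(), 0.0) * 1e-10 if evals.size else np.zeros(0, bool)
    neg_mag = float(-evals[evals < 0].sum())
    lam = evals[pos]
    coords = evecs[:, pos] * np.sqrt(lam)[None, :]
    if n_axes is not None:
        coords, lam_kept = coords[:, :n_axes], lam[:n_axes]
    else:
        lam_kept = lam
    total = lam.sum()
    explained = lam_kept / total if total > 0 else np.zeros_like(lam_kept)
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=ids,
                                 columns=[f"PCo{i+1}" for i in range(coords.shape[1])]),
        eigenvalues=lam_kept,
        explained_fraction=explained,
        negative_eigenvalue_magnitude=neg_mag,
    )


@dataclasses.dataclass
class PCoAResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    negative_eigenvalue_magnitude: float


def ch_index(
    d: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
    coords: np.ndarray | None = None,
) -> float:
    """Calinski-Harabasz index of a clustering of a distance matrix.

    Evaluated on the full positive PCoA embedding of ``d`` (pass ``coords``
    to reuse a precomputed embedding): CH = [B/(k-1)] / [W/(n-k)] with B and
    W the between-/within-cluster sums of squared Euclidean deviations from
    centroids.  A clustering with W = 0 (all within-cluster points identical)
    returns +inf, ranking above every finite value.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = len(uniq), len(labels)
    if k < 2:
        raise ValueError("CH index needs at least 2 clusters")
    if coords is None:
        coords = pcoa(d).coordinates.to_numpy()
    X = np.asarray(coords, dtype=float)
    overall = X.mean(axis=0)
    W = 0.0
    B = 0.0
    for c in uniq:
        Xi = X[labels == c]
        cen = Xi.mean(axis=0)
        W += float(((Xi - cen) ** 2).sum())
        B += len(Xi) * float(((cen - overall) ** 2).sum())
    if W <= _EPS * max(B, 1.0):
        return float("inf")
    if n == k:
        raise ValueError("k must be < n")
    return (B / (k - 1)) / (W / (n - k))


def silhouette(
    d: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
) -> tuple[np.ndarray, float]:
    """Per-sample silhouette widths and their mean, from a distance matrix.

    s_i = (b_i - a_i) / max(a_i, b_i); samples in singleton clusters get 0.
    """
    D = _check_square(np.asarray(d))
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    widths = silhouette_samples(D, labels, metric="precomputed")
    return widths, float(widths.mean())


@dataclasses.dataclass
class DermatotypeResult:
    """Outcome of dermatotype calling over a range of candidate k."""

    k_selected: int
    labels: pd.Series                      # sample_id -> dermatotype (1-based)
    medoid_ids: list
    ch_by_k: dict[int, float]
    mean_silhouette_by_k: dict[int, float]
    silhouette_widths: pd.Series           # per sample, at k_selected
    distance: pd.DataFrame
    ordination: PCoAResult


def _canonical_labels(labels: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Renumber clusters 1..k by decreasing size, ties by lowest medoid index."""
    sizes = {c: int((labels == c).sum()) for c in range(len(medoids))}
    order = sorted(sizes, key=lambda c: (-sizes[c], medoids[c]))
    remap = {c: i + 1 for i, c in enumerate(order)}
    return np.array([remap[c] for c in labels]), [int(medoids[c]) for c in order]


def select_dermatotypes(
    abundances: pd.DataFrame,
    k_range: Iterable[int] = range(2, 11),
    seed: int | None = None,
    sqrt_jsd: bool = True,
) -> DermatotypeResult:
    """Call dermatotypes: JSD matrix, PAM per k, CH-index selection.

    ``abundances`` is a samples x taxa relative-abundance table.  Candidate
    cluster numbers with k >= n_samples are skipped with a warning.  The k
    maximising the CH index wins; exact ties go to the smaller k.  Cluster
    ids are renumbered 1..k by decreasing size (then lowest medoid index).
    """
    d = jsd_matrix(abundances, sqrt=sqrt_jsd)
    if float(d.to_numpy().max()) <= _EPS:
        raise ValueError("all profiles are identical; dermatotypes are undefined")
    ordination = pcoa(d)
    coords = ordination.coordinates.to_numpy()
    n = len(d)
    ch_by_k: dict[int, float] = {}
    sil_by_k: dict[int, float] = {}
    fits: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in k_range:
        if k >= n:
            warnings.warn(f"skipping k={k}: only {n} samples", DegenerateDistancesWarning)
            continue
        labels, medoids, _ = pam(d, k, seed=seed)
        ch_by_k[k] = ch_index(d, labels, coords=coords)
        _, sil_by_k[k] = silhouette(d, labels)
        fits[k] = (labels, medoids)
    if not ch_by_k:
        raise ValueError("no feasible k in k_range")
    k_sel = max(sorted(ch_by_k), key=lambda k: (ch_by_k[k], -k))
    labels, medoids = fits[k_sel]
    canon, medoid_order = _canonical_labels(labels, medoids)
    widths, _ = silhouette(d, canon)
    ids = list(abundances.index)
    return DermatotypeResult(
        k_selected=k_sel,
        labels=pd.Series(canon, index=ids, name="dermatotype"),
        medoid_ids=[ids[m] for m in medoid_order],
        ch_by_k=ch_by_k,
        mean_silhouette_by_k=sil_by_k,
        silhouette_widths=pd.Series(widths, index=ids, name="silhouette"),
        distance=d,
        ordination=ordination,
    )
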