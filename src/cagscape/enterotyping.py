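"""Discrete clusters (enterotypes) versus a continuum (enterogradient).

Samples are clustered with a deterministic partitioning-around-medoids
(PAM: greedy BUILD followed by best-improvement SWAP, ties broken by lowest
index) for every k in a range, and the average silhouette index decides the
verdict: below 0.50 there is no cluster support, 0.50-0.75 moderate, above
0.75 strong.  The gradient alternative correlates each retained OTU with
the leading ordination axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
import skbio
from scipy import stats

from .core_io import AbundanceTable
from .association import bh_fdr
from .diversity import Ordination

SI_MODERATE = 0.50
SI_STRONG = 0.75


def pam(
    dm: skbio.DistanceMatrix, k: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids; returns (medoid indices, labels).

    Deterministic given the distance matrix: BUILD adds the medoid that
    most reduces total distance-to-nearest-medoid cost; SWAP applies the
    best cost-reducing (medoid, non-medoid) exchange until a local optimum.
    The ``seed`` argument is accepted for interface stability but unused.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k={k} out of range for n={n}")

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=0)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.minimum(d, nearest[:, None]).sum(axis=0)
        gains[medoids] = np.inf
        best = int(np.argmin(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, d[:, best])

    medoids = sorted(medoids)
    while True:
        med = np.array(medoids)
        dist_to_med = d[:, med]  # (n, k)
        order = np.argsort(dist_to_med, axis=1, kind="stable")
        nearest_idx = order[:, 0]
        nearest_d = dist_to_med[np.arange(n), nearest_idx]
        second_d = dist_to_med[np.arange(n), order[:, 1]]
        non_med = np.setdiff1d(np.arange(n), med)
        best_delta, best_swap = -1e-12, None
        for mi in range(len(med)):
            lose = nearest_idx == mi
            dh = d[:, non_med]  # (n, |H|)
            delta = np.where(
                lose[:, None],
                np.minimum(dh, second_d[:, None]) - nearest_d[:, None],
                np.minimum(dh - nearest_d[:, None], 0.0),
            ).sum(axis=0)
            j = int(np.argmin(delta))
            if delta[j] < best_delta:
                best_delta, best_swap = float(delta[j]), (mi, int(non_med[j]))
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids = sorted(medoids)

    med = np.array(medoids)
    labels = np.argmin(d[:, med], axis=1)
    return med, labels


def silhouette(dm: skbio.DistanceMatrix, labels) -> float:
    """Average silhouette s(i) = (b - a) / max(a, b); singletons score 0."""
    d = np.asarray(dm.data, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = d.shape[0]
    sizes = {c: int((labels == c).sum()) for c in uniq}
    mean_to_cluster = np.column_stack(
        [d[:, labels == c].sum(axis=1) / sizes[c] for c in uniq]
    )
    s = np.zeros(n)
    for i in range(n):
        ci = np.where(uniq == labels[i])[0][0]
        size = sizes[labels[i]]
        if size == 1:
            s[i] = 0.0
            continue
        a = mean_to_cluster[i, ci] * size / (size - 1)  # exclude self
        b = np.min(np.delete(mean_to_cluster[i], ci))
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


@dataclass
class ClusterEvaluation:
    """Silhouette-over-k scan result."""

    si_by_k: pd.Series  # k -> average SI
    assignments: dict[int, np.ndarray]
    medoids: dict[int, np.ndarray]
    best_k: int
    best_si: float
    verdict: str  # none | moderate | strong


def enterotype_scan(
    dm: skbio.DistanceMatrix, k_min: int = 2, k_max: int = 20, seed: int | None = None
) -> ClusterEvaluation:
    """Run PAM + silhouette for k in [k_min, k_max] and classify support."""
    n = dm.shape[0]
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be below n={n}")
    si_by_k, assignments, medoids = {}, {}, {}
    for k in range(k_min, k_max + 1):
        med, labels = pam(dm, k, seed=seed)
        si_by_k[k] = silhouette(dm, labels)
        assignments[k] = labels
        medoids[k] = med
    si = pd.Series(si_by_k, name="average_silhouette")
    best_k = int(si.idxmax())
    best_si = float(si.max())
    if best_si < SI_MODERATE:
        verdict = "none"
    elif best_si < SI_STRONG:
        verdict = "moderate"
    else:
        verdict = "strong"
    return ClusterEvaluation(si, assignments, medoids, best_k, best_si, verdict)


def _spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with t-approximation p; exact permutation p for n < 10."""
    n = len(x)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rho = stats.spearmanr(x, y).statistic
    if n < 10:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in permutations(ry):
            r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += r >= obs - 1e-12
            total += 1
        return float(rho), count / total
    p = stats.spearmanr(x, y).pvalue
    return float(rho), float(p)


@dataclass
class GradientReport:
    """Per-OTU correlations with the leading ordination axes."""

    table: pd.DataFrame  # otu, axis, rho, p, q, flag_rho
    counts_flagged: pd.Series  # per axis: number of |rho| > cut OTUs
    counts_significant: pd.Series  # per axis: number of q < 0.05 OTUs
    rho_cut: float


def enterogradient(
    t: AbundanceTable,
    ordination: Ordination,
    n_axes: int = 3,
    rho_cut: float = 0.3,
) -> GradientReport:
    """Correlate every OTU with the first ``n_axes`` PCoA axes.

    FDR is applied jointly across the whole OTU x axis family; constant
    OTUs are reported with missing rho rather than raised.
    """
    if n_axes > ordination.coordinates.shape[1]:
        raise ValueError(
            f"requested {n_axes} axes, ordination has "
            f"{ordination.coordinates.shape[1]}"
        )
    coords = ordination.coordinates.loc[t.sample_ids]
    rows = []
    for otu in t.otu_ids:
        x = t.data[otu].to_numpy(dtype=float)
        for axis in range(n_axes):
            rho, p = _spearman_with_p(x, coords.iloc[:, axis].to_numpy())
            rows.append((otu, f"PCo{axis + 1}", rho, p))
    table = pd.DataFrame(rows, columns=["otu", "axis", "rho", "p"])
    q = np.full(len(table), np.nan)
    valid = table["p"].notna().to_numpy()
    if valid.any():
        q[valid] = bh_fdr(table.loc[valid, "p"].to_numpy())
    table["q"] = q
    table["flag_rho"] = table["rho"].abs() > rho_cut
    table.loc[table["rho"].isna(), "flag_rho"] = False
    counts_flagged = table.groupby("axis")["flag_rho"].sum().astype(int)
    counts_significant = (
        table.assign(sig=(table["q"] < 0.05).fillna(False))
        .groupby("axis")["sig"]
        .sum()
        .astype(int)
    )
    return GradientReport(table, counts_flagged, counts_significant, rho_cut)
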