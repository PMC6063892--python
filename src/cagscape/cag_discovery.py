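"""Co-abundance group (CAG) discovery and robustness validation.

CAGs are consortia of positively co-abundant OTUs: Ward's linkage (ward.D2
convention by default) on the dissimilarity d = 1 - rho of the pairwise
Spearman matrix, cut into K groups, each named after its member OTU with
the highest median abundance.  1 - rho (rather than 1 - |rho|) keeps
co-excluding OTUs apart.  Robustness is checked two ways: a split-half
Mantel test (random halves of the cohort, correlation of the two OTU x OTU
matrices, permutation p and bootstrap CI) and a SparCC compositional
correlation network that does not inherit closure-induced correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_io import AbundanceTable, COUNTS, RELATIVE


def spearman_coabundance(t: AbundanceTable) -> pd.DataFrame:
    """Pairwise Spearman correlation between OTUs (average-rank ties).

    Constant OTU columns get missing correlations (with a warning); they
    must be excluded before clustering.
    """
    if t.mode != RELATIVE:
        raise ValueError("spearman_coabundance requires a relative-mode table")
    if t.n_samples < 3:
        raise ValueError("need at least 3 samples")
    x = t.values
    constant = np.all(x == x[0, :], axis=0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant OTU(s) have undefined correlations",
            stacklevel=2,
        )
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    rho = np.corrcoef(ranks, rowvar=False)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=t.otu_ids, columns=t.otu_ids)


@dataclass
class CagModel:
    """OTU -> CAG partition with names and per-sample abundance profile."""

    k: int
    membership: pd.Series  # otu_id -> CAG label (string)
    names: dict[str, str]  # CAG label -> naming OTU id
    linkage_tree: np.ndarray
    profile: pd.DataFrame  # sample x CAG


def ward_cags(
    rho: pd.DataFrame,
    t: AbundanceTable,
    k: int,
    convention: str = "ward.D2",
) -> CagModel:
    """Cut a Ward dendrogram over d = 1 - rho into K CAGs.

    ``convention="ward.D"`` reproduces the alternative hclust recurrence
    (exact for memberships via a square-root transform of the input
    dissimilarities).  OTUs are sorted by id first so the result is
    invariant to input column order.
    """
    otus = sorted(rho.index)
    if list(rho.index) != list(rho.columns):
        raise ValueError("rho matrix index/columns mismatch")
    if not 2 <= k <= len(otus):
        raise ValueError(f"K={k} out of range for {len(otus)} OTUs")
    r = rho.loc[otus, otus].to_numpy(dtype=float)
    if np.isnan(r).any():
        raise ValueError("missing correlations among clustered OTUs")
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    condensed = squareform(d, checks=False)
    if convention == "ward.D":
        condensed = np.sqrt(condensed)
    elif convention != "ward.D2":
        raise ValueError(f"unknown Ward convention {convention!r}")
    z = linkage(condensed, method="ward")
    flat = fcluster(z, t=k, criterion="maxclust")

    rel = t
    medians = pd.Series(np.median(rel.data[otus].to_numpy(), axis=0), index=otus)
    # order CAGs by the median abundance of their naming OTU, descending
    clusters: dict[int, list[str]] = {}
    for otu, c in zip(otus, flat):
        clusters.setdefault(int(c), []).append(otu)
    top = {
        c: max(members, key=lambda o: (medians[o], o))
        for c, members in clusters.items()
    }
    order = sorted(clusters, key=lambda c: (-medians[top[c]], top[c]))
    label_of = {c: f"{top[c]}-CAG" for c in order}
    membership = pd.Series(
        {otu: label_of[int(c)] for otu, c in zip(otus, flat)}, name="cag"
    ).loc[otus]
    names = {label_of[c]: top[c] for c in order}
    model = CagModel(
        k=k,
        membership=membership,
        names=names,
        linkage_tree=z,
        profile=pd.DataFrame(),
    )
    model.profile = cag_profile(t, model)
    return model


def cag_profile(t: AbundanceTable, model: CagModel) -> pd.DataFrame:
    """Per-sample summed relative abundance of each CAG's member OTUs."""
    missing = [o for o in model.membership.index if o not in t.data.columns]
    if missing:
        raise ValueError(f"OTUs in model absent from table: {missing[:5]}")
    cols = {}
    for label in model.names:
        members = model.membership.index[model.membership == label]
        cols[label] = t.data[list(members)].sum(axis=1)
    return pd.DataFrame(cols)


@dataclass
class MantelResult:
    r: float
    p_value: float
    ci_lower: float
    ci_upper: float
    n_permutations: int
    n_bootstrap: int


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices_from(m, k=-1)
    return m[i, j]


def _spearman_matrix(x: np.ndarray) -> np.ndarray:
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho[sd == 0, :] = np.nan
    rho[:, sd == 0] = np.nan
    return rho


def split_half_mantel(
    t: AbundanceTable,
    n_perm: int = 10_000,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> MantelResult:
    """Split samples in random halves and Mantel-correlate the two OTU x OTU
    Spearman matrices.

    r is the Pearson correlation of the lower triangles; p is one-sided by
    simultaneous row/column permutation of one matrix; the CI is a
    percentile bootstrap over OTUs (resampled jointly in both matrices,
    self-pairs from duplicated OTUs excluded).
    """
    if t.n_samples < 20:
        raise ValueError("need at least 20 samples to split")
    rng = np.random.default_rng(seed)
    n = t.n_samples
    perm = rng.permutation(n)
    half = (n + 1) // 2
    x = t.values
    m1 = _spearman_matrix(x[perm[:half]])
    m2 = _spearman_matrix(x[perm[half:]])
    ok = ~(np.isnan(m1).all(axis=0) | np.isnan(m2).all(axis=0))
    m1, m2 = m1[np.ix_(ok, ok)], m2[np.ix_(ok, ok)]
    p_otus = m1.shape[0]
    v1 = _lower_triangle(m1)
    r_obs = float(np.corrcoef(v1, _lower_triangle(m2))[0, 1])

    exceed = 0
    for _ in range(n_perm):
        pi = rng.permutation(p_otus)
        r_perm = np.corrcoef(v1, _lower_triangle(m2[np.ix_(pi, pi)]))[0, 1]
        exceed += r_perm >= r_obs
    p_value = (1 + exceed) / (n_perm + 1)

    tril_i, tril_j = np.tril_indices(p_otus, k=-1)
    boot_r = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(p_otus, size=p_otus)
        keep = idx[tril_i] != idx[tril_j]  # drop duplicated-OTU self pairs
        b1 = m1[idx[tril_i], idx[tril_j]][keep]
        b2 = m2[idx[tril_i], idx[tril_j]][keep]
        boot_r[b] = np.corrcoef(b1, b2)[0, 1]
    lo, hi = np.percentile(boot_r, [2.5, 97.5])
    return MantelResult(r_obs, float(p_value), float(lo), float(hi), n_perm, n_boot)


@dataclass
class SparccNetwork:
    """SparCC inference result (medians over resampled instances)."""

    rho: pd.DataFrame  # median correlation per pair
    basis_variance: pd.Series  # median omega per OTU
    log_ratio_variance: pd.DataFrame  # median t_ij per pair
    exclusions: list[list[tuple[str, str]]] = field(default_factory=list)
    n_instances: int = 0


def _sparcc_single(
    frac: np.ndarray, excl_threshold: float, max_excl_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """One SparCC pass on a fraction matrix (samples x OTUs)."""
    logf = np.log(frac)
    cov = np.cov(logf, rowvar=False)
    var = np.diag(cov)
    tij = var[:, None] + var[None, :] - 2 * cov  # var(log f_i/f_j)
    tij = np.maximum(tij, 0.0)
    p = tij.shape[0]
    included = np.ones((p, p), dtype=bool)
    np.fill_diagonal(included, False)
    excluded_pairs: list[tuple[int, int]] = []

    def solve() -> tuple[np.ndarray, np.ndarray]:
        partners = included.sum(axis=1).astype(float)
        m = included.astype(float)
        m[np.arange(p), np.arange(p)] = partners
        t_sum = (tij * included).sum(axis=1)
        omega, *_ = np.linalg.lstsq(m, t_sum, rcond=None)
        omega = np.maximum(omega, 1e-10)
        denom = 2 * np.sqrt(np.outer(omega, omega))
        rho = (omega[:, None] + omega[None, :] - tij) / denom
        np.fill_diagonal(rho, 1.0)
        return omega, np.clip(rho, -1.0, 1.0)

    omega, rho = solve()
    for _ in range(max_excl_iter):
        masked = np.where(included, np.abs(rho), 0.0)
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        if masked[i, j] <= excl_threshold:
            break
        included[i, j] = included[j, i] = False
        excluded_pairs.append((min(i, j), max(i, j)))
        omega, rho = solve()
    return omega, tij, rho, excluded_pairs


def sparcc(
    t: AbundanceTable,
    n_instances: int = 20,
    excl_threshold: float = 0.1,
    max_excl_iter: int = 10,
    seed: int | None = None,
) -> SparccNetwork:
    """SparCC correlations as the median over Dirichlet-resampled instances.

    Per instance, fractions are drawn from Dirichlet(counts + 1) per
    sample, basis variances are solved from the log-ratio variance system
    under the sparsity approximation, and the strongest pair is iteratively
    excluded while any |rho| exceeds the threshold.
    """
    if t.mode != COUNTS:
        raise ValueError("sparcc requires a counts-mode table")
    if t.n_otus < 4:
        raise ValueError("SparCC system is underdetermined below 4 OTUs")
    rng = np.random.default_rng(seed)
    counts = t.values
    n, p = counts.shape
    rhos = np.empty((n_instances, p, p))
    omegas = np.empty((n_instances, p))
    tijs = np.empty((n_instances, p, p))
    exclusions = []
    for it in range(n_instances):
        frac = np.empty((n, p))
        for j in range(n):
            frac[j] = rng.dirichlet(counts[j] + 1.0)
        omega, tij, rho, excl = _sparcc_single(frac, excl_threshold, max_excl_iter)
        omegas[it], tijs[it], rhos[it] = omega, tij, rho
        exclusions.append(
            [(t.otu_ids[i], t.otu_ids[j]) for i, j in excl]
        )
    ids = t.otu_ids
    return SparccNetwork(
        rho=pd.DataFrame(np.median(rhos, axis=0), index=ids, columns=ids),
        basis_variance=pd.Series(np.median(omegas, axis=0), index=ids),
        log_ratio_variance=pd.DataFrame(
            np.median(tijs, axis=0), index=ids, columns=ids
        ),
        exclusions=exclusions,
        n_instances=n_instances,
    )
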