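"""Host-variable statistics.

PERMANOVA partitions a beta-diversity distance matrix by a categorical
factor; dominated-group profiles are contrasted with one-way ANOVA on
log-transformed values (plus Tukey HSD) or chi-squared tests; whole-cohort
associations use Spearman correlations between CAG abundances and
health/diversity variables; Western/non-Western marker genera are tested
for mean abundance greater than zero.  All families are FDR-adjusted with
Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import AbundanceTable, RELATIVE, aggregate_by_taxon


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PermanovaResult:
    factor: str
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    n_samples: int


def _permanova_stats(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray):
    n = d2.shape[0]
    a = onehot.shape[1]
    ss_total = d2.sum() / (2 * n)
    within = (onehot * (d2 @ onehot)).sum(axis=0) / (2 * sizes)
    ss_within = within.sum()
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore"):
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return ss_between / ss_total, f


def permanova(
    dm: skbio.DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    factor: str = "factor",
) -> PermanovaResult:
    """Single-factor PERMANOVA with whole-sample label permutation."""
    labels = np.asarray(groups)
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    if len(labels) != n:
        raise ValueError("group labels do not match distance matrix")
    uniq, inv = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(inv).astype(float)
    if (sizes == 0).any():
        raise ValueError("group with 0 members")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    onehot = np.eye(len(uniq))[inv]
    r2, f_obs = _permanova_stats(d2, onehot, sizes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, f_perm = _permanova_stats(d2, onehot[perm], sizes)
        exceed += f_perm >= f_obs
    p = (1 + exceed) / (n_perm + 1)
    return PermanovaResult(factor, float(r2), float(f_obs), float(p), n_perm, n)


def _log_transform(x: np.ndarray) -> np.ndarray:
    """ln(x + shift) with shift = eps - min(x) for nonpositive values,
    eps = half the smallest positive observed value."""
    if (x > 0).all():
        return np.log(x)
    positive = x[x > 0]
    eps = positive.min() / 2.0 if positive.size else 1.0
    shift = eps - min(x.min(), 0.0)
    return np.log(x + shift)


def group_profiles(
    meta: pd.DataFrame,
    groups: pd.Series,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Contrast metadata variables across dominated groups.

    Continuous variables: one-way ANOVA on log-transformed values with
    Tukey HSD contrasts; categorical: Pearson chi-squared (uncorrected).
    Missing values are dropped per variable (pairwise-complete); FDR is
    applied across the whole variable family.
    """
    groups = groups.dropna()
    meta = meta.loc[groups.index]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups")
    if continuous is None:
        continuous = [
            c for c in meta.columns if pd.api.types.is_numeric_dtype(meta[c])
        ]
    if categorical is None:
        categorical = [c for c in meta.columns if c not in continuous]
    level_order = sorted(groups.unique())
    rows = []
    for var in continuous:
        x = meta[var]
        ok = x.notna()
        if x[ok].nunique() < 2:
            raise ValueError(f"variable {var!r} has a single distinct value")
        by_group = [x[ok & (groups == g)].to_numpy(dtype=float) for g in level_order]
        # one shared offset from the pooled variable, then split back
        logged = _log_transform(np.concatenate(by_group))
        logged_groups = np.split(logged, np.cumsum([len(g) for g in by_group])[:-1])
        stat, p = stats.f_oneway(*logged_groups)
        tukey = stats.tukey_hsd(*logged_groups)
        contrasts = {
            f"{level_order[i]} vs {level_order[j]}": float(tukey.pvalue[i, j])
            for i in range(len(level_order))
            for j in range(i + 1, len(level_order))
        }
        summary = " / ".join(
            f"{np.mean(g):.3g} ± {np.std(g, ddof=1):.3g}" for g in by_group
        )
        rows.append(
            {
                "variable": var,
                "test": "anova_log",
                "summary": summary,
                "statistic": float(stat),
                "p": float(p),
                "tukey": contrasts,
            }
        )
    for var in categorical:
        x = meta[var]
        ok = x.notna()
        if x[ok].nunique() < 2:
            raise ValueError(f"variable {var!r} has a single distinct value")
        contingency = pd.crosstab(x[ok], groups[ok])
        stat, p, _, _ = stats.chi2_contingency(contingency, correction=False)
        pct = contingency / contingency.sum(axis=0)
        summary = "; ".join(
            f"{lvl}: " + "/".join(f"{v * 100:.1f}%" for v in pct.loc[lvl])
            for lvl in contingency.index
        )
        rows.append(
            {
                "variable": var,
                "test": "chi_squared",
                "summary": summary,
                "statistic": float(stat),
                "p": float(p),
                "tukey": None,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def cohort_correlations(
    profile: pd.DataFrame, variables: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho between every CAG column and every variable column.

    Missing values are pairwise-dropped (the per-pair n is reported); FDR
    is applied jointly across all variable x CAG pairs.
    """
    common = profile.index.intersection(variables.index)
    if len(common) < 10:
        raise ValueError("need at least 10 overlapping samples")
    profile = profile.loc[common]
    variables = variables.loc[common]
    rows = []
    for var in variables.columns:
        v = variables[var]
        for cag in profile.columns:
            c = profile[cag]
            ok = v.notna() & c.notna()
            n = int(ok.sum())
            if n < 3 or v[ok].nunique() < 2 or c[ok].nunique() < 2:
                rho, p = np.nan, np.nan
            else:
                res = stats.spearmanr(v[ok], c[ok])
                rho, p = float(res.statistic), float(res.pvalue)
            rows.append({"variable": var, "cag": cag, "rho": rho, "p": p, "n": n})
    out = pd.DataFrame(rows)
    q = np.full(len(out), np.nan)
    valid = out["p"].notna().to_numpy()
    if valid.any():
        q[valid] = bh_fdr(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    return out


def marker_tests(
    t: AbundanceTable,
    tax: pd.DataFrame,
    markers: list[str],
    rank: str = "genus",
) -> pd.DataFrame:
    """One-sample, one-sided t-tests that each marker genus has mean > 0.

    Reports mean and SD in percent (the scale the aggregate abundances are
    conventionally quoted on).  An all-zero aggregate is reported as not
    significant (p = 1) rather than raised.
    """
    if t.mode != RELATIVE:
        raise ValueError("marker_tests requires a relative-mode table")
    rows = []
    for marker in markers:
        agg = aggregate_by_taxon(t, tax, rank, marker).to_numpy()
        mean, sd = float(agg.mean()), float(agg.std(ddof=1))
        if sd == 0:
            stat = np.nan
            p = 0.0 if mean > 0 else 1.0
        else:
            res = stats.ttest_1samp(agg, 0.0, alternative="greater")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "marker": marker,
                "mean_pct": mean * 100,
                "sd_pct": sd * 100,
                "t": stat,
                "p_one_sided": p,
            }
        )
    return pd.DataFrame(rows)
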