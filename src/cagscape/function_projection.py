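"""Community functional potential from per-OTU genome content.

The sample x OTU abundance matrix is projected through an OTU x function
weight table (the arithmetic core of 16S-based metagenome inference; the
reference table itself is an input), collapsed into metabolic modules,
reduced to ternary coordinates for three chosen modules, and contrasted
across sample groups with Kruskal-Wallis tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AbundanceTable, RELATIVE
from .association import bh_fdr


def read_function_table(path) -> pd.DataFrame:
    f = pd.read_csv(path, sep="\t", index_col=0)
    f.index = f.index.astype(str)
    if f.index.has_duplicates or f.columns.has_duplicates:
        raise ValueError("duplicate ids in function table")
    if (f.to_numpy() < 0).any():
        raise ValueError("negative weights in function table")
    return f


def read_module_map(path) -> dict[str, list[str]]:
    """Read a module<TAB>function two-column mapping."""
    mapping: dict[str, list[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["module", "function"])
    for module, group in df.groupby("module", sort=False):
        mapping[str(module)] = [str(f) for f in group["function"]]
    return mapping


def project(t: AbundanceTable, functions: pd.DataFrame) -> pd.DataFrame:
    """Sample x function profile: abundances (restricted to shared OTUs,
    renormalized) times per-OTU function weights; rows renormalized to 1."""
    if t.mode != RELATIVE:
        raise ValueError("project requires a relative-mode table")
    shared = [o for o in t.otu_ids if o in functions.index]
    if not shared:
        raise ValueError("no overlap between abundance table and function table")
    a = t.data[shared].to_numpy(dtype=float)
    sums = a.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        bad = t.data.index[(sums <= 0).ravel()][0]
        raise ValueError(f"sample {bad!r} has no abundance on shared OTUs")
    a = a / sums
    profile = a @ functions.loc[shared].to_numpy(dtype=float)
    row_sums = profile.sum(axis=1, keepdims=True)
    profile = np.divide(
        profile, row_sums, out=np.zeros_like(profile), where=row_sums > 0
    )
    return pd.DataFrame(profile, index=t.data.index, columns=functions.columns)


@dataclass
class ModuleProfile:
    values: pd.DataFrame  # sample x module
    mapping: dict[str, list[str]]
    overlapping: bool  # modules share functions: row sums may exceed 1
    missing_functions: list[str] = field(default_factory=list)


def collapse_modules(
    profile: pd.DataFrame,
    mapping: dict[str, list[str]],
    renormalize: bool = False,
) -> ModuleProfile:
    """Sum member-function abundances per module.

    Functions named in the mapping but absent from the profile are counted
    and warned about, not raised.
    """
    if not mapping or all(len(v) == 0 for v in mapping.values()):
        raise ValueError("empty module mapping")
    missing = sorted(
        {f for funcs in mapping.values() for f in funcs if f not in profile.columns}
    )
    if missing:
        warnings.warn(
            f"{len(missing)} mapped function(s) absent from profile", stacklevel=2
        )
    used: list[str] = []
    cols = {}
    for module, funcs in mapping.items():
        present = [f for f in funcs if f in profile.columns]
        used.extend(present)
        cols[module] = profile[present].sum(axis=1) if present else pd.Series(
            0.0, index=profile.index
        )
    values = pd.DataFrame(cols)
    overlapping = len(used) != len(set(used))
    if renormalize:
        sums = values.sum(axis=1)
        values = values.div(sums.where(sums > 0), axis=0)
    return ModuleProfile(values, mapping, overlapping, missing)


def ternary_coords(
    m: ModuleProfile, modules: tuple[str, str, str]
) -> tuple[pd.DataFrame, list[str]]:
    """Close three module abundances to sum exactly 1 per sample.

    Samples with all three modules at zero are dropped and reported in the
    second return value.
    """
    if len(set(modules)) != 3:
        raise ValueError("need three distinct modules")
    for mod in modules:
        if mod not in m.values.columns:
            raise ValueError(f"module {mod!r} not in profile")
    sub = m.values[list(modules)]
    sums = sub.sum(axis=1)
    missing = list(sub.index[sums <= 0])
    coords = sub[sums > 0].div(sums[sums > 0], axis=0)
    return coords, missing


def module_tests(
    m: ModuleProfile,
    groups: pd.Series,
    cag_profile: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Kruskal-Wallis per module across groups (tie-corrected), FDR across
    modules; optionally Spearman rho per module x CAG."""
    groups = groups.dropna()
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups")
    values = m.values.loc[groups.index]
    level_order = sorted(groups.unique())
    rows = []
    for module in values.columns:
        by_group = [
            values.loc[groups == g, module].to_numpy(dtype=float)
            for g in level_order
        ]
        pooled = np.concatenate(by_group)
        if np.all(pooled == pooled[0]):
            raise ValueError(f"module {module!r} is constant")
        stat, p = stats.kruskal(*by_group)
        rows.append({"module": module, "kw_statistic": float(stat), "p": float(p)})
    kw = pd.DataFrame(rows)
    kw["q"] = bh_fdr(kw["p"].to_numpy())

    spearman = None
    if cag_profile is not None:
        common = m.values.index.intersection(cag_profile.index)
        srows = []
        for module in m.values.columns:
            for cag in cag_profile.columns:
                res = stats.spearmanr(
                    m.values.loc[common, module], cag_profile.loc[common, cag]
                )
                srows.append(
                    {
                        "module": module,
                        "cag": cag,
                        "rho": float(res.statistic),
                        "p": float(res.pvalue),
                    }
                )
        spearman = pd.DataFrame(srows)
        spearman["q"] = bh_fdr(spearman["p"].to_numpy())
    return kw, spearman
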