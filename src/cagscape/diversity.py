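"""Alpha diversity, beta-diversity distances and principal coordinates.

Two beta-diversity metrics drive the enterotype/enterogradient analysis:
the square root of the Jensen-Shannon divergence (base-2 logs, so the
metric is bounded by 1) and UniFrac in its weighted-normalized and
unweighted variants.  UniFrac is computed from a per-branch table of
descendant abundances; branches ancestral to the last common ancestor of
the taxa present in either sample of a pair contribute to neither the
numerator nor the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform

from .core_io import AbundanceTable, RELATIVE, to_relative

_LN2 = np.log(2.0)


def alpha_diversity(t: AbundanceTable) -> pd.DataFrame:
    """Per-sample richness S, Shannon entropy H (nats) and Pielou evenness J.

    J = H / ln(S) is undefined (NaN) for single-OTU samples.
    """
    rel = to_relative(t) if t.mode != RELATIVE else t
    p = rel.values
    if (p.sum(axis=1) <= 0).any():
        raise ValueError("empty sample")
    richness = (p > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    shannon = -plogp.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pielou = np.where(richness > 1, shannon / np.log(richness), np.nan)
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon, "pielou": pielou},
        index=rel.data.index,
    )


def jsd_sqrt_matrix(t: AbundanceTable) -> skbio.DistanceMatrix:
    """Pairwise sqrt Jensen-Shannon divergence with base-2 logs (d in [0,1])."""
    if t.mode != RELATIVE:
        raise ValueError("jsd_sqrt_matrix requires a relative-mode table")
    p = t.values
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows must sum to 1")
    # scipy's jensenshannon returns sqrt(JSD) in nats; rescale to bits.
    condensed = pdist(p, metric="jensenshannon") / np.sqrt(_LN2)
    d = squareform(np.clip(condensed, 0.0, 1.0))
    return skbio.DistanceMatrix(d, ids=t.sample_ids)


@dataclass
class _BranchTable:
    lengths: np.ndarray  # (B,)
    leaf_sets: np.ndarray  # (B, n_leaves) boolean: leaf descends from branch
    leaf_ids: list[str]


def _branch_table(tree: skbio.TreeNode) -> _BranchTable:
    if len(tree.children) > 2:
        raise ValueError("unrooted tree: root has more than two children")
    leaves = [n.name for n in tree.tips()]
    leaf_pos = {name: i for i, name in enumerate(leaves)}
    lengths, rows = [], []
    descend: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=False):
        mask = np.zeros(len(leaves), dtype=bool)
        if node.is_tip():
            mask[leaf_pos[node.name]] = True
        else:
            for child in node.children:
                mask |= descend[id(child)]
        descend[id(node)] = mask
        length = 0.0 if node.length is None else float(node.length)
        if not np.isfinite(length) or length < 0:
            raise ValueError(f"invalid branch length on node {node.name!r}")
        lengths.append(length)
        rows.append(mask)
    return _BranchTable(np.asarray(lengths), np.asarray(rows), leaves)


def unifrac_matrix(
    t: AbundanceTable, tree: skbio.TreeNode, weighted: bool = True
) -> skbio.DistanceMatrix:
    """Pairwise UniFrac distances over the relative-abundance table.

    weighted (normalized): d = sum_b L_b |A_b - B_b| / sum_b L_b (A_b + B_b)
    unweighted: d = (branch length unique to one sample) / (branch length
    of the union of branches leading to taxa present in either sample),
    both sums restricted to branches below the pair's last common ancestor.
    """
    if t.mode != RELATIVE:
        raise ValueError("unifrac_matrix requires a relative-mode table")
    bt = _branch_table(tree)
    leaf_pos = {name: i for i, name in enumerate(bt.leaf_ids)}
    p_leaf = np.zeros((t.n_samples, len(bt.leaf_ids)))
    present_mask = t.values.sum(axis=0) > 0
    for col, otu in enumerate(t.otu_ids):
        if otu in leaf_pos:
            p_leaf[:, leaf_pos[otu]] = t.values[:, col]
        elif present_mask[col]:
            raise ValueError(f"abundant OTU {otu!r} missing from tree")

    ind = bt.leaf_sets.astype(float)  # (B, leaves)
    L = bt.lengths
    n = t.n_samples
    A = p_leaf @ ind.T  # (n, B): abundance descending from each branch
    totals = p_leaf.sum(axis=1, keepdims=True)
    d = np.zeros((n, n))

    if weighted:
        above = A >= totals - 1e-12  # branch is ancestral to all of the sample
        AL = A * L[None, :]
        # denominator before the above-LCA correction, via matmuls
        base = AL.sum(axis=1)
        corr = (AL * above) @ above.T
        den = base[:, None] + base[None, :] - corr - corr.T
        for i in range(n):
            num = np.abs(A[i][None, :] - A) @ L
            with np.errstate(invalid="ignore", divide="ignore"):
                row = np.where(den[i] > 0, num / np.maximum(den[i], 1e-300), 0.0)
            d[i] = row
    else:
        pres_leaf = p_leaf > 0
        count = pres_leaf.astype(float) @ ind.T  # present leaves under branch
        pres = count > 0
        above = count >= pres_leaf.sum(axis=1, keepdims=True) - 1e-9
        presL = pres * L[None, :]
        sL = presL.sum(axis=1)
        shared = presL @ pres.T
        union = sL[:, None] + sL[None, :] - shared
        num = sL[:, None] + sL[None, :] - shared - shared.T
        corr = ((above * L[None, :]) @ above.T)
        den = union - corr
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return skbio.DistanceMatrix(d, ids=t.sample_ids)


@dataclass
class Ordination:
    """PCoA result: coordinates on positive-eigenvalue axes only."""

    coordinates: pd.DataFrame  # samples x axes, columns PCo1..
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    n_negative_dropped: int = 0


def pcoa(dm: skbio.DistanceMatrix) -> Ordination:
    """Classical scaling (Gower centering of -d^2/2, eigendecomposition).

    Negative eigenvalues are dropped and excluded from the
    proportion-explained denominator.
    """
    d = dm.data
    n = d.shape[0]
    b = -0.5 * d**2
    b = b - b.mean(axis=0, keepdims=True) - b.mean(axis=1, keepdims=True) + b.mean()
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, np.abs(evals).max() * 1e-10) if n else 0.0
    positive = evals > tol
    n_dropped = int((evals < -tol).sum())
    evals_pos = evals[positive]
    coords = evecs[:, positive] * np.sqrt(evals_pos)[None, :]
    total = evals_pos.sum()
    props = evals_pos / total if total > 0 else np.zeros_like(evals_pos)
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=evals_pos,
        proportion_explained=props,
        n_negative_dropped=n_dropped,
    )
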