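"""Synthetic 16S cohorts with planted co-abundance structure.

The generator emulates a cross-sectional urban cohort: ~100 abundant OTUs
organized into K co-abundance blocks, a handful of rare OTUs that fall below
the median-abundance filter, per-sample block activities with a heavy right
tail (so a few percent of samples are dominated by a single block),
categorical covariates (city, sex, age range, BMI class) and continuous
health variables linearly coupled to the block activities.  Every run
records its ground truth so downstream stages can be scored on recovery.

Model
-----
Latent log-abundance of OTU i in sample j::

    log y_ij = mu_i + lambda_i * s_{j, b(i)} + eps_ij,   eps ~ N(0, sigma^2)

with positive within-block loadings ``lambda_i`` and block activities
``s_jk`` drawn i.i.d. Gamma (gradient mode) or from K well-separated Gamma
modes (clusters mode).  Compositions are the row-wise softmax of the latent
logs and counts are multinomial at fixed sequencing depth.

One block (the last, "pathogen-like") has a wider loading spread and a
depressed baseline so that samples it dominates show reduced alpha
diversity, giving diversity-association stages a truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import skbio

from .core_io import AbundanceTable, COUNTS

CITIES = ("Bogota", "Medellin", "Cali", "Barranquilla", "Bucaramanga")

def default_effects(k_blocks: int) -> dict[str, tuple[float, dict[int, float], float]]:
    """Default linear couplings of continuous metadata to block activities:
    variable -> (intercept, {1-based block index: slope}, residual SD).

    The last block (pathogen-like) raises blood pressure and BMI; the
    second-to-last (mucin-degrader-like) is protective; block 1
    (fiber-associated) raises dietary fiber.  ``body_fat_pct`` is a
    deliberate null variable.
    """
    patho = k_blocks
    prot = max(k_blocks - 1, 1)
    second = min(2, k_blocks)
    effects = {
        "bmi": (27.0, {patho: 1.5, second: 2.0, prot: -1.5}, 3.5),
        "waist_cm": (92.0, {patho: 4.0, prot: -4.0}, 9.0),
        "systolic_bp": (120.0, {patho: 6.0, prot: -3.0}, 10.0),
        "diastolic_bp": (80.0, {patho: 4.0, prot: -2.0}, 8.0),
        "adiponectin": (6.0, {prot: 1.2, patho: -0.8}, 2.0),
        "fiber_g": (18.0, {1: 1.5}, 4.0),
        "body_fat_pct": (37.0, {}, 6.0),
    }
    if prot == patho:  # degenerate single-block config
        effects = {
            var: (b0, {patho: sum(b.values())} if b else {}, sd)
            for var, (b0, b, sd) in effects.items()
        }
    return effects


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    n_samples: int = 441
    n_otus: int = 100
    n_rare_otus: int = 20
    k_blocks: int = 5
    depth: int = 30_000
    baseline_sigma: float = 1.0
    noise_sigma: float = 0.7
    loading_low: float = 0.8
    loading_high: float = 1.2
    activity_shape: float = 1.2
    activity_scale: float = 1.0
    mode: str = "gradient"  # or "clusters"
    cluster_separation: float = 3.0
    pathogen_loading_high: float = 2.2
    pathogen_mu_shift: float = -1.8
    rare_mu_shift: float = -6.0
    overdispersion: float | None = None  # Dirichlet-multinomial scale, None = multinomial
    city_coupling: float = 0.8
    effects: dict[str, tuple[float, dict[int, float], float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effects is None:
            self.effects = default_effects(self.k_blocks)

    def validate(self) -> None:
        if self.n_otus < self.k_blocks:
            raise ValueError("K exceeds number of abundant OTUs")
        if self.k_blocks < 1:
            raise ValueError("k_blocks must be positive")
        for name in (
            "n_samples", "n_otus", "depth", "noise_sigma", "activity_shape",
            "activity_scale", "cluster_separation", "baseline_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mode not in ("gradient", "clusters"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for var, (_, betas, _) in (self.effects or {}).items():
            for k in betas:
                if not 1 <= k <= self.k_blocks:
                    raise ValueError(f"effect {var!r} references unknown block {k}")


@dataclass
class SyntheticTruth:
    """Planted structure recorded alongside every simulated cohort."""

    block_of_otu: pd.Series  # otu_id -> 1-based block index
    activities: pd.DataFrame  # samples x K
    effects: dict[str, tuple[float, dict[int, float], float]]
    mode: str
    seed: int
    cluster_of_sample: pd.Series | None = None  # clusters mode only

    @property
    def k_blocks(self) -> int:
        return self.activities.shape[1]

    def abundant_blocks(self, otu_ids) -> pd.Series:
        return self.block_of_otu.loc[list(otu_ids)]


def _otu_name(i: int, width: int) -> str:
    return f"OTU_{i + 1:0{width}d}"


def _block_assignment(cfg: SimulationConfig) -> pd.Series:
    """Abundant OTUs in contiguous near-equal blocks; rare OTUs round-robin."""
    total = cfg.n_otus + cfg.n_rare_otus
    width = len(str(total))
    names = [_otu_name(i, width) for i in range(total)]
    blocks = np.empty(total, dtype=int)
    bounds = np.linspace(0, cfg.n_otus, cfg.k_blocks + 1).astype(int)
    for k in range(cfg.k_blocks):
        blocks[bounds[k]:bounds[k + 1]] = k + 1
    for j in range(cfg.n_rare_otus):
        blocks[cfg.n_otus + j] = (j % cfg.k_blocks) + 1
    return pd.Series(blocks, index=names, name="block")


def _random_topology(leaves: list, rng: np.random.Generator) -> skbio.TreeNode:
    """Rooted binary topology by uniform sequential edge attachment.

    ``leaves`` may contain leaf names or already-built subtrees.
    """
    nodes = [
        item if isinstance(item, skbio.TreeNode) else skbio.TreeNode(name=item)
        for item in leaves
    ]
    if len(nodes) == 1:
        return nodes[0]
    root = skbio.TreeNode()
    root.extend([nodes[0], nodes[1]])
    attachable = [nodes[0], nodes[1]]  # non-root nodes = edges
    for leaf in nodes[2:]:
        target = attachable[int(rng.integers(len(attachable)))]
        parent = target.parent
        parent.remove(target)
        joint = skbio.TreeNode()
        joint.extend([target, leaf])
        parent.append(joint)
        attachable.extend([joint, leaf])
    return root


def simulate_tree(
    n_otus: int,
    seed: int,
    block_of_otu: pd.Series | None = None,
) -> skbio.TreeNode:
    """Random rooted bifurcating tree with i.i.d. Exp(1) branch lengths.

    When ``block_of_otu`` is given, each block grows as its own subtree and
    the block subtrees are joined near the root, so planted co-abundance
    blocks are phylogenetically coherent.  Topology is drawn first (uniform
    sequential attachment); branch lengths are assigned afterwards so they
    are i.i.d. regardless of attachment order.
    """
    if n_otus < 2:
        raise ValueError("need at least 2 OTUs for a tree")
    rng = np.random.default_rng(seed)
    if block_of_otu is None:
        width = len(str(n_otus))
        block_of_otu = pd.Series(1, index=[_otu_name(i, width) for i in range(n_otus)])
    elif len(block_of_otu) != n_otus:
        raise ValueError("block_of_otu length does not match n_otus")
    subtrees = []
    for k in sorted(block_of_otu.unique()):
        members = list(block_of_otu.index[block_of_otu == k])
        subtrees.append(_random_topology(members, rng))
    tree = _random_topology(subtrees, rng)
    for node in tree.postorder(include_self=False):
        node.length = float(rng.exponential(1.0))
    tree.length = None
    return tree


def _simulate_activities(cfg: SimulationConfig, rng: np.random.Generator):
    n, K = cfg.n_samples, cfg.k_blocks
    if cfg.mode == "gradient":
        s = rng.gamma(cfg.activity_shape, cfg.activity_scale, size=(n, K))
        clusters = None
    else:
        clusters = rng.integers(K, size=n)
        s = rng.gamma(0.5, 0.2, size=(n, K))
        own = cfg.cluster_separation + rng.gamma(2.0, 0.5, size=n)
        s[np.arange(n), clusters] = own
    return s, clusters


def simulate_community(cfg: SimulationConfig) -> tuple[AbundanceTable, SyntheticTruth]:
    """Draw a counts table and its ground truth from the latent-factor model."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    block_of_otu = _block_assignment(cfg)
    otu_ids = list(block_of_otu.index)
    m = len(otu_ids)
    n, K = cfg.n_samples, cfg.k_blocks

    mu = rng.normal(0.0, cfg.baseline_sigma, size=m)
    lam = rng.uniform(cfg.loading_low, cfg.loading_high, size=m)
    pathogen = block_of_otu.to_numpy() == K
    lam[pathogen] = rng.uniform(
        cfg.loading_low, cfg.pathogen_loading_high, size=int(pathogen.sum())
    )
    mu[pathogen] += cfg.pathogen_mu_shift
    rare = np.zeros(m, dtype=bool)
    rare[cfg.n_otus:] = True
    mu[rare] += cfg.rare_mu_shift

    s, clusters = _simulate_activities(cfg, rng)
    eps = rng.normal(0.0, cfg.noise_sigma, size=(n, m))
    block_idx = block_of_otu.to_numpy() - 1
    log_y = mu[None, :] + lam[None, :] * s[:, block_idx] + eps
    log_y -= log_y.max(axis=1, keepdims=True)  # softmax stability
    y = np.exp(log_y)
    p = y / y.sum(axis=1, keepdims=True)

    counts = np.empty((n, m), dtype=np.int64)
    for j in range(n):
        pj = p[j]
        if cfg.overdispersion is not None:
            pj = rng.dirichlet(pj * cfg.overdispersion)
        counts[j] = rng.multinomial(cfg.depth, pj)

    sample_ids = [f"S{j + 1:03d}" for j in range(n)]
    table = AbundanceTable(
        pd.DataFrame(counts, index=sample_ids, columns=otu_ids), mode=COUNTS
    )
    truth = SyntheticTruth(
        block_of_otu=block_of_otu,
        activities=pd.DataFrame(
            s, index=sample_ids, columns=[f"block_{k + 1}" for k in range(K)]
        ),
        effects=cfg.effects,
        mode=cfg.mode,
        seed=cfg.seed,
        cluster_of_sample=(
            None
            if clusters is None
            else pd.Series(clusters + 1, index=sample_ids, name="cluster")
        ),
    )
    return table, truth


def simulate_metadata(truth: SyntheticTruth, cfg: SimulationConfig) -> pd.DataFrame:
    """Host metadata with continuous variables linearly coupled to activities.

    City is drawn with probabilities softmax-weighted by block activities
    (city c favours block c), so community structure differs by city; sex
    and age range are independent of the microbiota by design.
    """
    cfg.validate()
    rng = np.random.default_rng(_derive_seed(cfg.seed, "metadata"))
    s = truth.activities.to_numpy()
    n, K = s.shape
    meta = pd.DataFrame(index=truth.activities.index)

    for var, (beta0, betas, sd) in cfg.effects.items():
        signal = np.full(n, float(beta0))
        for k, b in betas.items():
            if not 1 <= k <= K:
                raise ValueError(f"effect {var!r} references unknown block {k}")
            signal = signal + b * s[:, k - 1]
        meta[var] = signal + rng.normal(0.0, sd, size=n)

    logits = cfg.city_coupling * s[:, np.arange(min(K, len(CITIES))) % K]
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    cum = probs.cumsum(axis=1)
    u = rng.random(n)
    city_idx = (u[:, None] > cum).sum(axis=1)
    meta["city"] = np.array(CITIES[: probs.shape[1]])[city_idx]
    meta["sex"] = np.where(rng.random(n) < 0.5, "female", "male")
    meta["age_range"] = np.where(rng.random(n) < 0.5, "18-40", "41-62")
    if "bmi" in meta:
        meta["bmi_class"] = pd.cut(
            meta["bmi"], [-np.inf, 25.0, 30.0, np.inf],
            labels=["lean", "overweight", "obese"],
        ).astype(str)
    return meta


def simulate_function_table(
    truth: SyntheticTruth,
    cfg: SimulationConfig,
    n_background: int = 10,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-OTU genome content with one marker function exclusive to each block.

    Returns the OTU x function weight table (rows sum to 1) and a
    module -> function mapping: one single-function module per block marker
    plus a "central_metabolism" module over the shared background functions.
    """
    rng = np.random.default_rng(_derive_seed(cfg.seed, "functions"))
    otu_ids = list(truth.block_of_otu.index)
    K = truth.k_blocks
    bg = [f"F_bg_{i + 1:02d}" for i in range(n_background)]
    markers = [f"F_marker_block_{k + 1}" for k in range(K)]
    weights = pd.DataFrame(0.0, index=otu_ids, columns=bg + markers)
    weights.loc[:, bg] = rng.dirichlet(np.full(n_background, 5.0), size=len(otu_ids))
    blocks = truth.block_of_otu.to_numpy()
    marker_share = 0.3
    for k in range(K):
        mask = blocks == k + 1
        weights.loc[mask, bg] *= 1.0 - marker_share
        weights.loc[mask, markers[k]] = marker_share
    mapping = {f"marker_module_{k + 1}": [markers[k]] for k in range(K)}
    mapping["central_metabolism"] = list(bg)
    return weights, mapping


def _derive_seed(master_seed: int, label: str) -> int:
    """Stable sub-stream seed below 2**31 from (master seed, label)."""
    import hashlib

    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SyntheticBundle:
    table: AbundanceTable  # counts
    tree: skbio.TreeNode
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame
    function_table: pd.DataFrame
    module_map: dict[str, list[str]]
    truth: SyntheticTruth


def simulate_all(cfg: SimulationConfig) -> SyntheticBundle:
    """Full cohort: counts, tree, metadata, taxonomy, genome content, truth."""
    table, truth = simulate_community(cfg)
    tree = simulate_tree(
        len(truth.block_of_otu),
        _derive_seed(cfg.seed, "tree"),
        block_of_otu=truth.block_of_otu,
    )
    metadata = simulate_metadata(truth, cfg)
    functions, module_map = simulate_function_table(truth, cfg)
    taxonomy = _synthetic_taxonomy(truth)
    return SyntheticBundle(table, tree, metadata, taxonomy, functions, module_map, truth)


def _synthetic_taxonomy(truth: SyntheticTruth) -> pd.DataFrame:
    """Placeholder ranked labels: genus encodes the planted block."""
    otu_ids = list(truth.block_of_otu.index)
    blocks = truth.block_of_otu.to_numpy()
    return pd.DataFrame(
        {
            "kingdom": "Bacteria",
            "phylum": [f"Phylum_{b}" for b in blocks],
            "class": "unclassified",
            "order": "unclassified",
            "family": [f"Family_{b}" for b in blocks],
            "genus": [f"Genus_block_{b}" for b in blocks],
            "species": "unclassified",
        },
        index=otu_ids,
    )


def config_to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)
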