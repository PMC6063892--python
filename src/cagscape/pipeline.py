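"""End-to-end orchestration: simulate/load -> filter -> diversity ->
enterotype scan -> gradient -> CAGs -> dominance -> associations ->
functional projection, with a manifest recording parameters, derived seeds
and per-output checksums.

Every stochastic stage consumes an independent seed derived by stable
hashing of (master seed, stage name), so changing one stage's stream
leaves upstream outputs byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import association, cag_discovery, core_io, diversity, dominance
from . import enterotyping, function_projection, synthetic_data


def derive_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Parameters of the full workflow (defaults follow the protocol)."""

    # inputs; None for any of them triggers simulation
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    function_table_path: str | None = None
    module_map_path: str | None = None
    simulate: bool = False
    sim: synthetic_data.SimulationConfig = field(
        default_factory=synthetic_data.SimulationConfig
    )
    # analysis parameters
    median_threshold: float = 1e-4
    n_axes: int = 3
    rho_cut: float = 0.3
    k_min: int = 2
    k_max: int = 20
    si_moderate: float = 0.50
    si_strong: float = 0.75
    k_cags: int = 5
    ward_convention: str = "ward.D2"
    mantel_permutations: int = 10_000
    mantel_bootstrap: int = 10_000
    sparcc_instances: int = 20
    sparcc_threshold: float = 0.1
    dominance_percentile: float = 95.0
    n_trees: int = 1000
    n_permutations: int = 999
    use_unifrac: bool = True
    permanova_factors: tuple[str, ...] = ("city", "bmi_class", "sex", "age_range")
    marker_genera: tuple[str, ...] = ()
    ternary_modules: tuple[str, str, str] | None = None
    seed: int = 0


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: PipelineConfig, outdir) -> Path:
    """Execute the full workflow, writing all outputs plus manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {},
        "parameters": {
            k: v
            for k, v in asdict(cfg).items()
            if not isinstance(v, dict)
        },
        "outputs": {},
    }
    truth = None

    # ---- inputs -------------------------------------------------------
    stage = "inputs"
    try:
        if cfg.simulate or cfg.table_path is None:
            sim_cfg = cfg.sim
            sim_cfg.seed = derive_seed(cfg.seed, "simulate")
            manifest["stage_seeds"]["simulate"] = sim_cfg.seed
            bundle = synthetic_data.simulate_all(sim_cfg)
            table, tree, meta = bundle.table, bundle.tree, bundle.metadata
            tax, truth = bundle.taxonomy, bundle.truth
            functions, module_map = bundle.function_table, bundle.module_map
            core_io.write_abundance_table(table, outdir / "table.tsv")
            core_io.write_tree(tree, outdir / "tree.nwk")
            meta.to_csv(outdir / "metadata.tsv", sep="\t")
            core_io.write_taxonomy(tax, outdir / "taxonomy.tsv")
            _write_truth(truth, outdir / "truth.json")
        else:
            table = core_io.read_abundance_table(cfg.table_path)
            tree = core_io.read_tree(cfg.tree_path) if cfg.tree_path else None
            meta = (
                core_io.read_metadata(cfg.metadata_path)
                if cfg.metadata_path
                else None
            )
            tax = (
                core_io.read_taxonomy(cfg.taxonomy_path)
                if cfg.taxonomy_path
                else None
            )
            functions = (
                function_projection.read_function_table(cfg.function_table_path)
                if cfg.function_table_path
                else None
            )
            module_map = (
                function_projection.read_module_map(cfg.module_map_path)
                if cfg.module_map_path
                else None
            )
    except Exception as exc:  # noqa: BLE001 - stage context is the contract
        raise StageError(stage, exc) from exc

    # ---- core_io: relative abundances + median filter -----------------
    stage = "core_io"
    try:
        rel = core_io.to_relative(table)
        filtered = core_io.filter_by_median_abundance(rel, cfg.median_threshold)
        core_io.write_abundance_table(filtered, outdir / "filtered.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- diversity ----------------------------------------------------
    stage = "diversity"
    try:
        alpha = diversity.alpha_diversity(rel)
        alpha.to_csv(outdir / "alpha.tsv", sep="\t")
        jsd = diversity.jsd_sqrt_matrix(rel)
        pd.DataFrame(jsd.data, index=jsd.ids, columns=jsd.ids).to_csv(
            outdir / "distance_sqrt_jsd.tsv", sep="\t"
        )
        if cfg.use_unifrac:
            if tree is None:
                raise ValueError("UniFrac requested but no tree provided")
            wuf = diversity.unifrac_matrix(rel, tree, weighted=True)
            uuf = diversity.unifrac_matrix(rel, tree, weighted=False)
            pd.DataFrame(wuf.data, index=wuf.ids, columns=wuf.ids).to_csv(
                outdir / "distance_weighted_unifrac.tsv", sep="\t"
            )
            pd.DataFrame(uuf.data, index=uuf.ids, columns=uuf.ids).to_csv(
                outdir / "distance_unweighted_unifrac.tsv", sep="\t"
            )
            main_dm = wuf
        else:
            wuf = uuf = None
            main_dm = jsd
        ordination = diversity.pcoa(main_dm)
        ordination.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
        pd.DataFrame(
            {
                "eigenvalue": ordination.eigenvalues,
                "proportion_explained": ordination.proportion_explained,
            }
        ).to_csv(outdir / "pcoa_eigenvalues.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- enterotyping -------------------------------------------------
    stage = "enterotyping"
    try:
        scan = enterotyping.enterotype_scan(jsd, cfg.k_min, cfg.k_max)
        scan.si_by_k.rename_axis("k").to_csv(outdir / "si_curve.tsv", sep="\t")
        pd.DataFrame(
            {"sample": list(jsd.ids), "cluster": scan.assignments[scan.best_k]}
        ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        gradient = enterotyping.enterogradient(
            filtered, ordination, n_axes=cfg.n_axes, rho_cut=cfg.rho_cut
        )
        gradient.table.to_csv(outdir / "gradient_report.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- CAG discovery ------------------------------------------------
    stage = "cag_discovery"
    try:
        rho = cag_discovery.spearman_coabundance(filtered)
        model = cag_discovery.ward_cags(
            rho, filtered, cfg.k_cags, convention=cfg.ward_convention
        )
        pd.DataFrame(
            {
                "otu_id": model.membership.index,
                "cag": model.membership.to_numpy(),
            }
        ).to_csv(outdir / "cag_assignments.tsv", sep="\t", index=False)
        model.profile.to_csv(outdir / "cag_profile.tsv", sep="\t")
        mantel_seed = derive_seed(cfg.seed, "mantel")
        manifest["stage_seeds"]["mantel"] = mantel_seed
        mantel = cag_discovery.split_half_mantel(
            filtered, cfg.mantel_permutations, cfg.mantel_bootstrap, mantel_seed
        )
        (outdir / "mantel.json").write_text(
            json.dumps(asdict(mantel), indent=2) + "\n"
        )
        sparcc_seed = derive_seed(cfg.seed, "sparcc")
        manifest["stage_seeds"]["sparcc"] = sparcc_seed
        counts_filtered = core_io.AbundanceTable(
            table.data[filtered.otu_ids], mode=core_io.COUNTS
        )
        net = cag_discovery.sparcc(
            counts_filtered,
            n_instances=cfg.sparcc_instances,
            excl_threshold=cfg.sparcc_threshold,
            seed=sparcc_seed,
        )
        _write_edges(net.rho, outdir / "sparcc_edges.tsv")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- dominance ----------------------------------------------------
    stage = "dominance"
    try:
        selection = dominance.select_dominated(
            model.profile, percentile=cfg.dominance_percentile
        )
        selection.thresholds.rename_axis("cag").to_csv(
            outdir / "thresholds.tsv", sep="\t"
        )
        selection.dominated_by.rename_axis("sample").to_csv(
            outdir / "selection.tsv", sep="\t"
        )
        rf_seed = derive_seed(cfg.seed, "reclassify")
        manifest["stage_seeds"]["reclassify"] = rf_seed
        report = dominance.reclassify(
            filtered, selection, n_trees=cfg.n_trees, seed=rf_seed
        )
        (outdir / "reclassification.json").write_text(
            json.dumps(
                {
                    "n_trees": report.n_trees,
                    "oob_accuracy": report.oob_accuracy,
                    "resubstitution_accuracy": report.resubstitution_accuracy,
                    "confusion": report.confusion.to_dict(),
                    "seed": report.seed,
                },
                indent=2,
            )
            + "\n"
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- association --------------------------------------------------
    stage = "association"
    try:
        if meta is not None:
            perm_rows = []
            labels = selection.dominated_by.dropna()
            sub_ids = list(labels.index)
            dm_for_groups = main_dm.filter(sub_ids)
            factors = [("cag", labels)] + [
                (f, meta.loc[sub_ids, f])
                for f in cfg.permanova_factors
                if f in meta.columns
            ]
            for name, lab in factors:
                pseed = derive_seed(cfg.seed, f"permanova:{name}")
                manifest["stage_seeds"][f"permanova:{name}"] = pseed
                res = association.permanova(
                    dm_for_groups,
                    lab.to_numpy(),
                    n_perm=cfg.n_permutations,
                    seed=pseed,
                    factor=name,
                )
                perm_rows.append(asdict(res))
            pd.DataFrame(perm_rows).to_csv(
                outdir / "permanova.tsv", sep="\t", index=False
            )
            profiles = association.group_profiles(meta, selection.dominated_by)
            profiles.drop(columns="tukey").to_csv(
                outdir / "group_profiles.tsv", sep="\t", index=False
            )
            numeric = meta.select_dtypes("number").join(
                alpha, how="inner"
            )
            correlations = association.cohort_correlations(model.profile, numeric)
            correlations.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
        if tax is not None and cfg.marker_genera:
            markers = association.marker_tests(rel, tax, list(cfg.marker_genera))
            markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- function projection ------------------------------------------
    stage = "function_projection"
    try:
        if functions is not None:
            func_profile = function_projection.project(rel, functions)
            if module_map:
                modules = function_projection.collapse_modules(
                    func_profile, module_map
                )
                modules.values.to_csv(outdir / "module_profile.tsv", sep="\t")
                kw, spear = function_projection.module_tests(
                    modules, selection.dominated_by, cag_profile=model.profile
                )
                kw.to_csv(outdir / "module_tests.tsv", sep="\t", index=False)
                if spear is not None:
                    spear.to_csv(
                        outdir / "module_cag_correlations.tsv", sep="\t", index=False
                    )
                ternary = cfg.ternary_modules
                if ternary is None and len(modules.values.columns) >= 3:
                    ternary = tuple(modules.values.columns[:3])
                if ternary is not None:
                    coords, _ = function_projection.ternary_coords(modules, ternary)
                    coords.to_csv(outdir / "ternary.tsv", sep="\t")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    for path in sorted(outdir.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _checksum(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir


def _write_truth(truth: synthetic_data.SyntheticTruth, path: Path) -> None:
    payload = {
        "block_of_otu": truth.block_of_otu.to_dict(),
        "activities": truth.activities.to_dict(orient="index"),
        "effects": {
            var: {"intercept": b0, "betas": betas, "sd": sd}
            for var, (b0, betas, sd) in truth.effects.items()
        },
        "mode": truth.mode,
        "seed": truth.seed,
    }
    if truth.cluster_of_sample is not None:
        payload["cluster_of_sample"] = truth.cluster_of_sample.to_dict()
    path.write_text(json.dumps(payload, indent=2) + "\n")


def _write_edges(rho: pd.DataFrame, path: Path) -> None:
    ids = list(rho.index)
    i, j = np.tril_indices(len(ids), k=-1)
    pd.DataFrame(
        {
            "otu_i": [ids[a] for a in i],
            "otu_j": [ids[b] for b in j],
            "median_rho": rho.to_numpy()[i, j],
        }
    ).to_csv(path, sep="\t", index=False)
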