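"""End-to-end driver: simulate -> demography/stats -> OTU -> diversity -> network.

``run_pipeline`` executes the stages in study order on synthetic inputs
(or files supplied in the config), writes every intermediate as
CSV/TSV/JSON under an output directory and finishes with a manifest
recording parameters, seeds, checksums and package version, so any output
is re-derivable from the manifest alone.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .conet import (
    build_network,
    graph_metrics,
    keystone,
    node_metrics,
    spearman_matrix,
    stage_composition_tests,
)
from .demography import (
    life_history_summary,
    max_density,
    population_growth_rate,
)
from .diversity import alpha_table, anosim, bray_curtis, nmds
from .group_stats import anova_oneway, posthoc_letters
from .io import (
    read_cohort_csv,
    read_density_csv,
    read_otu_tsv,
    write_cohort_csv,
    write_density_csv,
    write_json,
    write_otu_tsv,
    write_tree,
)
from .otu_pipeline import (
    abundance_filter,
    aggregate_taxonomy,
    rarefy,
    remove_chloroplast,
    remove_singletons,
    shared_fraction,
    top_k_taxa,
    venn_partition,
)
from .synthetic_data import (
    DEFAULT_FECUNDITY,
    default_cohort_config,
    default_otu_config,
    simulate_cohort,
    simulate_density,
    simulate_otu_table,
    simulate_tree,
)

logger = logging.getLogger("rotipop.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]

# per-group fecundity scaling for the simulated media contrast: sterile
# medium (SE) < sterile + bacterioplankton (SEB) < natural water (NW)
GROUP_FECUNDITY_SCALE = {"SE": 0.75, "SEB": 1.0, "NW": 1.25}
GROUP_DENSITY_PARAMS = {
    "SE": {"r_true": 0.55, "K": 115.0},
    "SEB": {"r_true": 0.60, "K": 150.0},
    "NW": {"r_true": 0.70, "K": 250.0},
}


@dataclass
class PipelineConfig:
    """Stage toggles, per-stage parameters and input/output paths."""

    out_dir: Path = Path("rotipop_out")
    seed: int = 1
    run_demography: bool = True
    run_otu: bool = True
    cohort_csv: Path | None = None  # external inputs override simulation
    density_csv: Path | None = None
    otu_tsv: Path | None = None
    otu_metadata_tsv: Path | None = None
    interval: float = 8.0
    growth_window: tuple = (2.0, 6.0)
    rarefy_depth: int | None = None  # None = auto-min
    abundance_threshold: float = 0.01
    network_rank: str = "order"
    network_top: int = 50
    rho_min: float = 0.5
    p_max: float = 0.05
    use_abs: bool = True
    keystone_top_k: int = 20
    anosim_permutations: int = 999
    nmds_starts: int = 8


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Any stage failure is logged with the stage name and re-raised, so a
    shell caller exits nonzero; downstream stages are skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "interval": config.interval,
            "growth_window": list(config.growth_window),
            "rarefy_depth": config.rarefy_depth,
            "abundance_threshold": config.abundance_threshold,
            "network_rank": config.network_rank,
            "network_top": config.network_top,
            "rho_min": config.rho_min,
            "p_max": config.p_max,
            "use_abs": config.use_abs,
            "keystone_top_k": config.keystone_top_k,
        },
        "stages": {},
        "outputs": {},
    }

    def _register(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "demography"
    try:
        if config.run_demography:
            results = _demography_stage(config, out, _register)
            manifest["stages"][stage] = results
        stage = "otu"
        if config.run_otu:
            results = _otu_stage(config, out, _register)
            manifest["stages"][stage] = results
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise
    manifest_path = out / "manifest.json"
    write_json(manifest, manifest_path)
    return manifest


def _demography_stage(config: PipelineConfig, out: Path, register) -> dict:
    results: dict = {"groups": {}}
    per_group_lh: dict[str, list] = {}
    for gi, (group, scale) in enumerate(sorted(GROUP_FECUNDITY_SCALE.items())):
        if config.cohort_csv is not None:
            cohort = read_cohort_csv(config.cohort_csv, interval=config.interval)
        else:
            cfg = default_cohort_config(
                seed=config.seed * 1000 + gi,
                fecundity_schedule=DEFAULT_FECUNDITY * scale,
            )
            cohort = simulate_cohort(cfg)
            write_cohort_csv(cohort, out / f"cohort_{group}.csv")
            register(f"cohort_{group}", out / f"cohort_{group}.csv")
        summary = life_history_summary(cohort)
        logger.info("group %s pooled life history: %s", group, summary.to_dict())
        per_rep = [
            life_history_summary(cohort.for_replicate(rep)).to_dict()
            for rep in cohort.replicates
        ]
        per_group_lh[group] = per_rep

        if config.density_csv is not None:
            density = read_density_csv(config.density_csv)
        else:
            pars = GROUP_DENSITY_PARAMS[group]
            density = simulate_density(
                pars["r_true"], pars["K"], 2.0, 9, noise_cv=0.1,
                seed=config.seed * 1000 + 100 + gi,
            )
            write_density_csv(density, out / f"density_{group}.csv")
            register(f"density_{group}", out / f"density_{group}.csv")
        growth = population_growth_rate(density, window=config.growth_window)
        dmax = max_density(density)
        results["groups"][group] = {
            "pooled": summary.to_dict(),
            "per_replicate": per_rep,
            "r_per_day": {"mean": growth.mean, "se": growth.se},
            "Dmax": {"mean": dmax.mean, "se": dmax.se},
        }
        if config.cohort_csv is not None and config.density_csv is not None:
            break  # external input: a single cohort/density, no group contrast

    if config.cohort_csv is None:
        # media-effect ANOVA + letters on per-replicate R0, as in a culture study
        labels = sorted(per_group_lh)
        r0_groups = [[rep["R0"] for rep in per_group_lh[lab]] for lab in labels]
        aov = anova_oneway(r0_groups)
        letters = posthoc_letters(r0_groups, method="snk", labels=labels)
        logger.info("post-hoc method snk, alpha=0.05 (letter display %s)", letters)
        results["R0_anova"] = aov.to_dict()
        results["R0_letters"] = letters
        write_json(results["R0_anova"], out / "R0_anova.json")
        register("R0_anova", out / "R0_anova.json")
    write_json(results, out / "demography_summary.json")
    register("demography_summary", out / "demography_summary.json")
    return results


def _otu_stage(config: PipelineConfig, out: Path, register) -> dict:
    if config.otu_tsv is not None and config.otu_metadata_tsv is not None:
        table = read_otu_tsv(config.otu_tsv, config.otu_metadata_tsv)
        truth = None
    else:
        table, truth = simulate_otu_table(default_otu_config(seed=config.seed))
        write_otu_tsv(table, out / "otu_raw.tsv", out / "otu_metadata.tsv")
        register("otu_raw", out / "otu_raw.tsv")
        register("otu_metadata", out / "otu_metadata.tsv")
    results: dict = {"n_otus_raw": len(table.otu_ids)}

    # cleaning order fixed: chloroplast -> singletons -> rarefaction
    table, removed_chloro = remove_chloroplast(table)
    logger.info("chloroplast filter removed %d OTUs", len(removed_chloro))
    table, removed_single = remove_singletons(table)
    logger.info("singleton filter removed %d OTUs", len(removed_single))
    table = rarefy(table, depth=config.rarefy_depth, seed=config.seed)
    logger.info("rarefied to depth %d", int(table.sample_totals.iloc[0]))
    results["n_chloroplast_removed"] = len(removed_chloro)
    results["n_singletons_removed"] = len(removed_single)
    results["n_otus_clean"] = len(table.otu_ids)
    results["rarefaction_depth"] = int(table.sample_totals.iloc[0])
    write_otu_tsv(table, out / "otu_clean.tsv")
    register("otu_clean", out / "otu_clean.tsv")

    filtered = abundance_filter(table, threshold=config.abundance_threshold,
                                mode="any-sample")
    logger.info("abundance filter mode=any-sample strict=True kept %d OTUs",
                len(filtered.otu_ids))
    results["n_otus_above_1pct"] = len(filtered.otu_ids)

    regions = venn_partition(table, by="group")
    venn = {"+".join(sorted(k)): v for k, v in regions.items()}
    total = sum(regions.values())
    shared = regions.get(frozenset(table.metadata["group"].unique()), 0)
    results["venn"] = venn
    results["shared_otus"] = shared
    results["shared_percent"] = shared_fraction(shared, total) if total else 0.0

    tree = simulate_tree(table.otu_ids, seed=config.seed)
    write_tree(tree, out / "otu_tree.nwk")
    register("otu_tree", out / "otu_tree.nwk")
    alpha = alpha_table(table, tree=tree)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    register("alpha_diversity", out / "alpha_diversity.tsv")
    results["alpha_group_means"] = (
        alpha.join(table.metadata["group"]).groupby("group").mean().to_dict()
    )

    dist = bray_curtis(table.counts)
    dist.to_csv(out / "bray_curtis.tsv", sep="\t")
    register("bray_curtis", out / "bray_curtis.tsv")
    ord_res = nmds(dist, n_starts=config.nmds_starts, seed=config.seed)
    coords = ord_res.coordinates.copy()
    coords.to_csv(out / "nmds_coordinates.tsv", sep="\t")
    register("nmds_coordinates", out / "nmds_coordinates.tsv")
    results["nmds_stress"] = ord_res.stress
    groups = table.metadata.loc[dist.index, "group"]
    ano = anosim(dist, groups, n_perm=config.anosim_permutations, seed=config.seed)
    results["anosim"] = ano
    write_json(ano, out / "anosim.json")
    register("anosim", out / "anosim.json")

    agg = aggregate_taxonomy(table, config.network_rank)
    top = top_k_taxa(agg, k=config.network_top)
    abundances = agg[top].T  # taxa x samples
    rho, p = spearman_matrix(abundances)
    logger.info("network thresholds: |rho|>%s (use_abs=%s), p<%s",
                config.rho_min, config.use_abs, config.p_max)
    net = build_network(rho, p, rho_min=config.rho_min, p_max=config.p_max,
                        use_abs=config.use_abs)
    nm = node_metrics(net)
    nm.to_csv(out / "network_node_metrics.tsv", sep="\t")
    register("network_node_metrics", out / "network_node_metrics.tsv")
    gm = graph_metrics(net)
    write_json(gm, out / "network_graph_metrics.json")
    register("network_graph_metrics", out / "network_graph_metrics.json")
    ks = keystone(net, top_k=min(config.keystone_top_k, max(1, len(nm))))
    write_json(
        {
            "degree_min": ks.degree_min,
            "closeness_min": ks.closeness_min,
            "betweenness_max": ks.betweenness_max,
            "selected": list(ks.selected),
        },
        out / "keystone.json",
    )
    register("keystone", out / "keystone.json")
    results["network"] = gm
    results["keystone_taxa"] = list(ks.selected)

    comp = stage_composition_tests(table, by="stage", rank="genus", top_n=15)
    comp.to_csv(out / "stage_composition_tests.tsv", sep="\t")
    register("stage_composition_tests", out / "stage_composition_tests.tsv")
    results["n_stage_significant_genera"] = int(comp["significant"].sum())

    if truth is not None:
        write_json(truth, out / "otu_ground_truth.json")
        register("otu_ground_truth", out / "otu_ground_truth.json")
    write_json(results, out / "otu_summary.json")
    register("otu_summary", out / "otu_summary.json")
    return results
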