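"""One-command orchestration from subject tables to comparison reports.

Stage order: (optional) simulation -> covariate correction and z-scoring ->
network construction across the density grid -> global metrics per network
-> density screening and selection -> group comparisons (global metrics at
the selected density, range-averaged regional centralities, metabolites) ->
partial Spearman correlations -> plain-text/JSON report. Every stage output
is persisted as TSV/JSON and checksummed into a run manifest; a single
pipeline seed fans out to per-stage child seeds so identically configured
runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import graph_metrics as gm
from .cohort import COVARIATE_COLUMNS, CohortBundle
from .density_selection import DensitySelection, evaluate_criteria, select_density_range
from .group_stats import (
    ComparisonResult,
    CorrelationResult,
    ancova_group_age,
    compare_groups_table,
    bh_fdr_adjust,
    correlations_to_frame,
    partial_spearman,
    results_to_frame,
)
from .idscn_builder import BinaryNetwork, DensityGrid, build_all_networks
from .morphometry_prep import (
    ZScoreMatrix,
    average_hemispheres,
    load_thickness_table,
    prepare_zscores,
)
from .synthetic_cohort import SimConfig, simulate_behavior, simulate_cohort, simulate_metabolites

logger = logging.getLogger("idscn")

GLOBAL_METRIC_FAMILY = ("clustering", "efficiency", "modularity_q", "small_worldness")
CENTRALITY_FAMILIES = ("betweenness", "eigenvector", "closeness")

#: Default exploratory correlation set (metabolite/centrality/behavior pairs).
DEFAULT_CORRELATION_PAIRS: tuple[tuple[str, str], ...] = (
    ("tNAA", "PANAS_negative"),
    ("tNAA", "eigenvector_caudalanteriorcingulate"),
    ("tNAA", "eigenvector_precuneus"),
    ("eigenvector_middletemporal", "BIS_attention"),
    ("eigenvector_lateraloccipital", "PANAS_negative"),
    ("eigenvector_precuneus", "BIS_motor"),
)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Full run configuration (exactly one input mode: simulate or paths)."""

    simulate: SimConfig | None = None
    thickness_path: str | None = None
    covariate_path: str | None = None
    metabolite_path: str | None = None
    behavior_path: str | None = None
    average_hemispheres: bool = False
    grid: str = "0.05:0.30:0.01"
    kernel: str = "gaussian"
    kernel_scale: float = 1.0
    fit_group: str | None = "HC"
    screening_nulls: int = 10
    comparison_nulls: int = 100
    rewires_per_edge: int = 10
    modularity_restarts: int = 20
    majority: float = 0.5
    correlation_pairs: tuple[tuple[str, str], ...] = DEFAULT_CORRELATION_PAIRS
    seed: int = 0
    out_dir: str = "idscn_out"

    def __post_init__(self) -> None:
        has_paths = self.thickness_path is not None or self.covariate_path is not None
        if (self.simulate is None) == (not has_paths):
            raise ValueError(
                "exactly one of a simulate block or input table paths is required"
            )
        if has_paths and (self.thickness_path is None or self.covariate_path is None):
            raise ValueError("both thickness_path and covariate_path are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if raw.get("simulate") is not None:
            raw["simulate"] = SimConfig(**raw["simulate"])
        if "correlation_pairs" in raw and raw["correlation_pairs"] is not None:
            raw["correlation_pairs"] = tuple(tuple(p) for p in raw["correlation_pairs"])
        return cls(**raw)

    def config_hash(self) -> str:
        def default(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: CohortBundle
    zscores: ZScoreMatrix
    metrics: pd.DataFrame
    criteria: pd.DataFrame
    selection: DensitySelection
    global_comparison: list[ComparisonResult]
    regional_comparisons: dict[str, list[ComparisonResult]]
    metabolite_comparison: list[ComparisonResult] | None
    ancova_tnaa: tuple[float, float, dict] | None
    correlations: list[CorrelationResult]
    centralities: pd.DataFrame | None = None
    paths: dict[str, Path] = field(default_factory=dict)


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("simulate", "metrics", "comparison_sigma", "spare")
    return {name: int(s % (2**31)) for name, s in zip(names, state)}


def _network_seed(stage_seed: int, subject_index: int, density_index: int) -> int:
    ss = np.random.SeedSequence((stage_seed, subject_index, density_index))
    return int(ss.generate_state(1)[0] % (2**31))


def _sigma_with_convention(net: BinaryNetwork, null_config: gm.NullModelConfig) -> float:
    """Small-worldness with a screening convention for degenerate nulls.

    A sparse network's rewired ensemble can be entirely triangle-free
    (zero null clustering). The ratio is then taken as +inf when the
    observed network has clustering (it passes the sigma > 1 screen) and 0
    when it has none (it fails); both conventions only matter at densities
    the screening discards anyway.
    """
    try:
        return gm.small_worldness(net, null_config)
    except ValueError as exc:
        if "zero clustering" not in str(exc):
            raise
        _, c_obs = gm.clustering_coefficients(net)
        return float("inf") if c_obs > 0 else 0.0


def compute_global_metrics(
    networks: dict[str, list[BinaryNetwork]],
    grid: DensityGrid,
    stage_seed: int,
    n_nulls: int = 10,
    rewires_per_edge: int = 10,
    modularity_restarts: int = 20,
) -> pd.DataFrame:
    """Global metric record for every subject x density network."""
    rows = []
    for s_idx, (subject_id, nets) in enumerate(networks.items()):
        for d_idx, net in enumerate(nets):
            seed = _network_seed(stage_seed, s_idx, d_idx)
            _, clustering = gm.clustering_coefficients(net)
            q, _ = gm.modularity_partition(
                net, n_restarts=modularity_restarts, seed=seed
            )
            sigma = _sigma_with_convention(
                net,
                gm.NullModelConfig(
                    n_nulls=n_nulls, rewires_per_edge=rewires_per_edge, seed=seed
                ),
            )
            rows.append(
                {
                    "subject_id": subject_id,
                    "density": float(grid.values[d_idx]),
                    "clustering": clustering,
                    "efficiency": gm.global_efficiency(net),
                    "modularity_q": q,
                    "path_length": gm.characteristic_path_length(net),
                    "small_worldness": sigma,
                    "largest_component_fraction": gm.largest_component_fraction(net),
                }
            )
    return pd.DataFrame(rows)


def compute_range_centralities(
    networks: dict[str, list[BinaryNetwork]],
    grid: DensityGrid,
    retained: np.ndarray,
) -> pd.DataFrame:
    """Per-subject centralities averaged over the retained density range.

    Returns a long frame with columns subject_id, measure, region index
    columns R0..R(n-1) are avoided: one row per subject x measure with one
    column per region position.
    """
    retained_idx = [
        i for i, k in enumerate(grid.values) if np.any(np.isclose(k, retained))
    ]
    if not retained_idx:
        raise ValueError("retained range does not intersect the density grid")
    rows = []
    for subject_id, nets in networks.items():
        acc = {m: None for m in CENTRALITY_FAMILIES}
        for i in retained_idx:
            net = nets[i]
            values = {
                "betweenness": gm.betweenness_centrality(net),
                "eigenvector": gm.eigenvector_centrality(net),
                "closeness": gm.closeness_centrality(net),
            }
            for measure, vec in values.items():
                acc[measure] = vec if acc[measure] is None else acc[measure] + vec
        for measure, total in acc.items():
            rows.append(
                {"subject_id": subject_id, "measure": measure}
                | {f"node_{i}": v for i, v in enumerate(total / len(retained_idx))}
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full chain and persist every stage output under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    paths: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame, index: bool = True) -> None:
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)
        paths[name] = path

    # --- stage 1: inputs -------------------------------------------------
    metabolites = behavior = None
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=seeds["simulate"])
        logger.info("simulate: %d subjects/group, seed %d", sim.n_per_group, sim.seed)
        cohort = simulate_cohort(sim)
        metabolites = simulate_metabolites(sim, cohort)
        behavior = simulate_behavior(sim, cohort)
    else:
        cohort = load_thickness_table(config.thickness_path, config.covariate_path)
        if config.average_hemispheres:
            thickness = average_hemispheres(cohort.thickness)
            subjects = cohort.subjects.drop(columns="global_mean_thickness")
            cohort = CohortBundle(subjects, thickness)
        if config.metabolite_path:
            metabolites = pd.read_csv(config.metabolite_path, sep="\t", index_col="subject_id")
        if config.behavior_path:
            behavior = pd.read_csv(config.behavior_path, sep="\t", index_col="subject_id")
    logger.info("cohort: %d subjects, %d regions", cohort.n_subjects, cohort.n_regions)
    save("subjects", cohort.subjects)
    save("thickness", cohort.thickness)
    if metabolites is not None:
        save("metabolites", metabolites)
    if behavior is not None:
        save("behavior", behavior)

    # --- stage 2: covariate correction and z-scoring ---------------------
    zscores = prepare_zscores(cohort, fit_group=config.fit_group)
    save("zscores", zscores.z)

    # --- stage 3: networks across the density grid -----------------------
    grid = DensityGrid.from_string(config.grid)
    networks = build_all_networks(
        zscores, grid, kernel=config.kernel, scale=config.kernel_scale
    )
    edge_rows = []
    for subject_id, nets in networks.items():
        for net in nets:
            iu, ju = np.nonzero(np.triu(net.adjacency, 1))
            edge_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_id,
                        "density": net.density,
                        "i": iu,
                        "j": ju,
                    }
                )
            )
    save("edges", pd.concat(edge_rows, ignore_index=True), index=False)
    logger.info("networks: %d subjects x %d densities", len(networks), len(grid))

    # --- stage 4: global metrics -----------------------------------------
    metrics = compute_global_metrics(
        networks,
        grid,
        stage_seed=seeds["metrics"],
        n_nulls=config.screening_nulls,
        rewires_per_edge=config.rewires_per_edge,
        modularity_restarts=config.modularity_restarts,
    )
    save("global_metrics", metrics, index=False)

    # --- stage 5: density screening and selection ------------------------
    criteria = evaluate_criteria(metrics)
    save("criteria", criteria)
    selection = select_density_range(criteria, majority=config.majority)
    logger.info(
        "density selection: retained %.2f-%.2f, selected %.2f (pass fraction %.2f)",
        selection.k_low, selection.k_high, selection.k_selected,
        selection.pass_fraction_at_selected,
    )

    # --- stage 6: group comparisons --------------------------------------
    groups = cohort.groups
    sel_idx = int(np.argmin(np.abs(grid.values - selection.k_selected)))
    subject_ids = list(networks)
    sigma_rng_seed = seeds["comparison_sigma"]
    sigma_final = {
        sid: _sigma_with_convention(
            networks[sid][sel_idx],
            gm.NullModelConfig(
                n_nulls=config.comparison_nulls,
                rewires_per_edge=config.rewires_per_edge,
                seed=_network_seed(sigma_rng_seed, s_idx, sel_idx),
            ),
        )
        for s_idx, sid in enumerate(subject_ids)
    }
    at_selected = (
        metrics[np.isclose(metrics["density"], grid.values[sel_idx])]
        .set_index("subject_id")
        .loc[subject_ids]
    )
    global_values = at_selected[list(GLOBAL_METRIC_FAMILY)].copy()
    global_values["small_worldness"] = [sigma_final[s] for s in global_values.index]
    global_comparison = compare_groups_table(
        global_values, groups.loc[global_values.index], family="global"
    )
    save("global_comparison", results_to_frame(global_comparison), index=False)

    centralities = compute_range_centralities(networks, grid, selection.retained)
    regions = cohort.regions
    node_cols = [f"node_{i}" for i in range(len(regions))]
    regional_comparisons: dict[str, list[ComparisonResult]] = {}
    regional_frames = []
    for measure in CENTRALITY_FAMILIES:
        block = (
            centralities[centralities["measure"] == measure]
            .set_index("subject_id")[node_cols]
            .loc[subject_ids]
        )
        block.columns = regions
        regional_comparisons[measure] = compare_groups_table(
            block, groups.loc[block.index], family=measure
        )
        regional_frames.append(results_to_frame(regional_comparisons[measure]))
    save("centralities", centralities, index=False)
    save("regional_comparison", pd.concat(regional_frames, ignore_index=True), index=False)

    metabolite_comparison = None
    ancova_tnaa = None
    if metabolites is not None:
        metabolite_comparison = compare_groups_table(
            metabolites, groups.loc[metabolites.index],
            family="metabolites", remove_outliers=True,
        )
        save("metabolite_comparison", results_to_frame(metabolite_comparison), index=False)
        if "tNAA" in metabolites.columns:
            ancova_tnaa = ancova_group_age(
                metabolites["tNAA"].to_numpy(),
                groups.loc[metabolites.index].to_numpy(),
                cohort.subjects.loc[metabolites.index, "age"].to_numpy(),
            )

    # --- stage 7: partial Spearman correlations --------------------------
    correlations: list[CorrelationResult] = []
    pool = pd.DataFrame(index=cohort.subjects.index)
    if metabolites is not None:
        pool = pool.join(metabolites)
    if behavior is not None:
        pool = pool.join(behavior)
    eigen_block = (
        centralities[centralities["measure"] == "eigenvector"]
        .set_index("subject_id")[node_cols]
    )
    eigen_block.columns = [f"eigenvector_{r}" for r in regions]
    pool = pool.join(eigen_block)
    covs = cohort.subjects[list(COVARIATE_COLUMNS)]
    for var_x, var_y in config.correlation_pairs:
        if var_x not in pool.columns or var_y not in pool.columns:
            logger.warning("correlation pair (%s, %s) not available; skipped", var_x, var_y)
            continue
        block = pool[[var_x, var_y]].join(covs).dropna()
        correlations.append(
            partial_spearman(
                block[var_x].to_numpy(),
                block[var_y].to_numpy(),
                block[list(COVARIATE_COLUMNS)].to_numpy(),
                names=(var_x, var_y),
                covariate_names=COVARIATE_COLUMNS,
            )
        )
    if correlations:
        adjusted = bh_fdr_adjust(np.array([c.p for c in correlations]))
        for corr, p_adj in zip(correlations, adjusted):
            corr.p_adj = float(p_adj)
        save("correlations", correlations_to_frame(correlations), index=False)

    result = PipelineResult(
        config=config, cohort=cohort, zscores=zscores, metrics=metrics,
        criteria=criteria, selection=selection,
        global_comparison=global_comparison,
        regional_comparisons=regional_comparisons,
        metabolite_comparison=metabolite_comparison,
        ancova_tnaa=ancova_tnaa,
        correlations=correlations,
        centralities=centralities,
        paths=paths,
    )

    # --- stage 8: report and manifest ------------------------------------
    report = write_report(result)
    report_path = out / "report.txt"
    report_path.write_text(report)
    paths["report"] = report_path
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(_summary_dict(result), indent=2, sort_keys=True))
    paths["summary"] = summary_path

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stage_checksums": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(paths.items())
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return result


def _summary_dict(result: PipelineResult) -> dict:
    sel = result.selection
    significant = [
        vars(r)
        for family in (
            [result.global_comparison]
            + list(result.regional_comparisons.values())
            + ([result.metabolite_comparison] if result.metabolite_comparison else [])
        )
        for r in family
        if r.p_adj < 0.05
    ]
    out = {
        "k_selected": sel.k_selected,
        "k_low": sel.k_low,
        "k_high": sel.k_high,
        "pass_fraction_at_selected": sel.pass_fraction_at_selected,
        "n_significant_after_fdr": len(significant),
        "significant": significant,
    }
    if result.ancova_tnaa is not None:
        f, p, adj = result.ancova_tnaa
        out["ancova_tnaa"] = {"F": f, "p": p, "adjusted_means": adj}
    return out


def write_report(result: PipelineResult) -> str:
    """Human-readable run summary (selected density, significant rows)."""
    sel = result.selection
    lines = [
        "Individualized structural covariance network analysis",
        "=" * 53,
        f"Subjects: {result.cohort.n_subjects} ("
        + ", ".join(
            f"{group} {int(count)}"
            for group, count in result.cohort.groups.value_counts().sort_index().items()
        )
        + f"), regions: {result.cohort.n_regions}",
        f"Retained density range: K = {sel.k_low:.2f}-{sel.k_high:.2f}",
        f"Selected density: K = {sel.k_selected:.2f} "
        f"(all-criteria pass fraction {sel.pass_fraction_at_selected:.2f})",
        "",
    ]
    families = {"global metrics": result.global_comparison}
    for measure, comp in result.regional_comparisons.items():
        families[f"{measure} centrality"] = comp
    if result.metabolite_comparison:
        families["metabolites"] = result.metabolite_comparison
    any_significant = False
    for name, comparisons in families.items():
        sig = [r for r in comparisons if r.p_adj < 0.05]
        lines.append(f"{name}: {len(sig)}/{len(comparisons)} significant after FDR")
        for r in sig:
            any_significant = True
            lines.append(
                f"  {r.variable}: {r.group_a} median {r.median_a:.3g} "
                f"(IQR {r.iqr_a:.3g}) vs {r.group_b} {r.median_b:.3g} "
                f"(IQR {r.iqr_b:.3g}); W = {r.w:.1f}, p = {r.p:.2g}, "
                f"p-adj = {r.p_adj:.2g}, Cliff's delta = {r.delta:.2f} "
                f"[{r.ci_low:.2f}, {r.ci_high:.2f}]"
            )
    if not any_significant:
        lines.append("no significant differences after FDR correction")
    if result.ancova_tnaa is not None:
        f, p, _ = result.ancova_tnaa
        lines.append("")
        lines.append(f"ANCOVA on tNAA (age covariate): F = {f:.2f}, p = {p:.2g}")
    if result.correlations:
        lines.append("")
        lines.append("partial Spearman correlations (age/sex/education/global thickness):")
        for c in result.correlations:
            lines.append(
                f"  {c.var_x} ~ {c.var_y}: rho = {c.rho:.2f}, "
                f"p = {c.p:.2g}, p-adj = {c.p_adj:.2g} (n = {c.n})"
            )
    return "\n".join(lines) + "\n"
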