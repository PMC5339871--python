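"""End-to-end radiogenomic pipeline orchestration.

Runs the full workflow from a single config: load (or synthesise) the
cohort, preprocess, collapse redundant imaging traits to one representative,
build the co-expression network and detect modules, correlate module
eigengenes with the retained traits, screen individual genes per trait,
split the cohort into radiogenomic subgroups, test the planted gene sets by
pre-ranked GSEA on the trait-associated module's kME ranking, and contrast
subgroup survival.  Every stage seed is derived deterministically from the
global seed, all tables are written with 12 significant digits, and the run
log records seeds plus a config snapshot — two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gsea as gsea_mod
from . import network, preprocess, screening, survival, synthetic

__all__ = ["PipelineConfig", "PipelineError", "ReportBundle", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """All pipeline knobs with defaults; round-trips through YAML unchanged."""

    schema_version: int = 1
    # inputs: either file paths, or synthetic-cohort parameters (paths win)
    expression_path: str | None = None
    traits_path: str | None = None
    survival_path: str | None = None
    gene_sets_path: str | None = None
    # synthetic cohort (used when expression_path is unset)
    n_genes: int = 500
    n_samples: int = 40
    module_sizes: list[int] = field(default_factory=lambda: [50, 50, 50, 50, 50])
    intra_cor: float = 0.64
    neg_fraction: float = 0.4
    link_cor: float = 0.8
    log_hr_per_sd: float = float(-np.log(4.0))
    censor_rate: float = 0.1
    n_decoy: int = 5
    decoy_size: int = 40
    # preprocessing
    quantile_normalize: bool = True
    top_k_genes: int | None = None
    redundancy_threshold: float = 0.9
    representative_traits: list[str] = field(default_factory=lambda: ["MD"])
    # network
    power: int | None = None  # explicit soft power; None = use power_selection
    power_selection: str = "recommended"  # "recommended" (by sample size) or "scale-free"
    powers: list[int] = field(default_factory=lambda: list(range(1, 21)))
    r2_target: float = 0.8
    signed: bool = False
    cut_height: float = 0.995
    min_module_size: int = 10
    merge_height: float = 0.25
    export_threshold: float = 0.1
    # screening / clustering
    rho_threshold: float = 0.6
    q_threshold: float = 1.0
    k_clusters: int = 2
    # GSEA
    n_perm: int = 1000
    exponent: float = 1.0
    min_set_size: int = 5
    max_set_size: int = 500
    # run
    seed: int = 0
    outdir: str = "radnet_out"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable stage name and error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class ReportBundle:
    """Everything a pipeline run produced, in memory plus on disk."""

    config: PipelineConfig
    outdir: Path
    partition: pd.Series
    eigengenes: pd.DataFrame
    module_trait: pd.DataFrame
    retained_traits: list[str]
    trait_groups: list[list[str]]
    screening: dict[str, pd.DataFrame]
    selected_genes: dict[str, list[str]]
    clusters: dict[str, pd.Series]
    cluster_summaries: dict[str, pd.DataFrame]
    gsea: dict[str, pd.DataFrame]
    survival_report: dict
    files: dict[str, str]
    log: dict


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int((int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31))


def validate_inputs(
    expression: pd.DataFrame,
    traits: pd.DataFrame,
    survival_data: pd.DataFrame | None = None,
) -> dict:
    """Sample-alignment report across the input tables.

    Hard failure when no sample is shared; otherwise reports shared ids, the
    ids dropped from each table, and per-table missing-value counts.
    """
    expr_ids = list(expression.columns)
    trait_ids = set(traits.index)
    shared = [s for s in expr_ids if s in trait_ids]
    if survival_data is not None:
        surv_ids = set(survival_data.index)
        shared = [s for s in shared if s in surv_ids]
    if not shared:
        raise PipelineError("validate", "alignment-empty", "no samples shared across input tables")
    report = {
        "n_shared": len(shared),
        "shared": shared,
        "dropped_expression": sorted(set(expr_ids) - set(shared)),
        "dropped_traits": sorted(trait_ids - set(shared)),
        "missing_expression": int(expression.isna().sum().sum()),
        "missing_traits": int(traits.isna().sum().sum()),
    }
    if survival_data is not None:
        report["dropped_survival"] = sorted(set(survival_data.index) - set(shared))
        report["missing_survival"] = int(survival_data.isna().sum().sum())
    return report


def _write(df: pd.DataFrame, path: Path, sep: str = "\t", index: bool = True) -> None:
    df.to_csv(path, sep=sep, float_format="%.12g", index=index)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full workflow described in the module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    log: dict = {"schema_version": config.schema_version, "seed": config.seed, "stage_seeds": {}, "stages": []}

    def record(name: str) -> int:
        s = stage_seed(config.seed, name)
        log["stage_seeds"][name] = s
        log["stages"].append(name)
        return s

    # ---- load ------------------------------------------------------------
    truth = None
    gene_sets = None
    if config.expression_path is not None:
        record("load")
        for role, path in (
            ("expression", config.expression_path),
            ("traits", config.traits_path),
        ):
            if path is None or not Path(path).exists():
                raise PipelineError("preprocess", "missing-input", f"{role} table not found: {path}")
        expression = preprocess.read_expression(config.expression_path)
        traits = preprocess.read_traits(config.traits_path)
        surv = None
        if config.survival_path is not None:
            if not Path(config.survival_path).exists():
                raise PipelineError("preprocess", "missing-input", f"survival table not found: {config.survival_path}")
            surv = preprocess.read_survival(config.survival_path)
        if config.gene_sets_path is not None:
            gene_sets = gsea_mod.read_gmt(config.gene_sets_path)
        validate_inputs(expression, traits, surv)
        if surv is not None:
            expression, traits, surv = preprocess.align_samples(expression, traits, surv)
        else:
            expression, traits = preprocess.align_samples(expression, traits)
    else:
        s = record("simulate")
        cohort = synthetic.generate_cohort(
            n_genes=config.n_genes,
            n_samples=config.n_samples,
            module_sizes=tuple(config.module_sizes),
            intra_cor=config.intra_cor,
            neg_fraction=config.neg_fraction,
            link_cor=config.link_cor,
            log_hr_per_sd=config.log_hr_per_sd,
            censor_rate=config.censor_rate,
            n_decoy=config.n_decoy,
            decoy_size=config.decoy_size,
            seed=s,
        )
        expression, traits, surv = cohort.expression, cohort.traits, cohort.survival
        gene_sets, truth = cohort.gene_sets, cohort.truth

    # ---- preprocess -------------------------------------------------------
    record("preprocess")
    try:
        if config.quantile_normalize:
            expression = preprocess.quantile_normalize(expression)
        if config.top_k_genes is not None:
            expression = preprocess.filter_top_variance(expression, config.top_k_genes)
        variances = expression.to_numpy().var(axis=1)
        if np.any(variances == 0):
            keep = expression.index[variances > 0]
            warnings.warn(f"dropping {int((variances == 0).sum())} zero-variance genes", stacklevel=2)
            expression = expression.loc[keep]
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("preprocess", "stage-failure", str(exc)) from exc

    # ---- trait redundancy -------------------------------------------------
    record("trait_redundancy")
    try:
        profiles = preprocess.gene_trait_profiles(expression, traits, method="spearman")
        trait_groups, retained = preprocess.trait_redundancy(
            profiles,
            threshold=config.redundancy_threshold,
            preferred=tuple(config.representative_traits),
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("trait_redundancy", "stage-failure", str(exc)) from exc

    # ---- network ----------------------------------------------------------
    record("network")
    try:
        if config.power is not None:
            beta, reached = int(config.power), True
        elif config.power_selection == "recommended":
            beta, reached = network.recommended_power(expression.shape[1], signed=config.signed), True
        elif config.power_selection == "scale-free":
            st = network.soft_threshold_select(
                expression, powers=config.powers, r2_target=config.r2_target, signed=config.signed
            )
            beta, reached = st.power, st.reached_target
        else:
            raise PipelineError("network", "bad-config", f"unknown power_selection {config.power_selection!r}")
        adj = network.adjacency(expression, beta, signed=config.signed)
        tom_matrix = network.tom(adj)
        dissim = 1.0 - tom_matrix
        partition = network.detect_modules(
            dissim,
            min_module_size=config.min_module_size,
            merge_height=config.merge_height,
            cut_height=config.cut_height,
            expression=expression,
        )
        if partition.max() == 0:
            raise PipelineError("network", "no-modules", "no module survived the size threshold")
        eigengenes = network.module_eigengene(expression, partition)
        kme_matrix = network.kme(expression, eigengenes)
        module_trait = network.module_trait_correlation(eigengenes, traits[retained])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("network", "stage-failure", str(exc)) from exc
    log["soft_power"] = beta
    log["soft_power_reached_target"] = reached
    log["n_modules"] = int(partition.max())

    # ---- per-trait screening, clustering, GSEA, survival -------------------
    screening_tables: dict[str, pd.DataFrame] = {}
    selected: dict[str, list[str]] = {}
    clusters: dict[str, pd.Series] = {}
    summaries: dict[str, pd.DataFrame] = {}
    gsea_tables: dict[str, pd.DataFrame] = {}
    survival_report: dict = {"traits": {}}
    top_module: dict[str, int] = {}
    for trait_name in retained:
        record(f"screening:{trait_name}")
        try:
            table = screening.gene_trait_spearman(expression, traits[trait_name])
            genes = screening.select_correlated_genes(
                table, rho_threshold=config.rho_threshold, q_threshold=config.q_threshold
            )
            table = table.assign(selected=table.index.isin(genes))
            screening_tables[trait_name] = table
            selected[trait_name] = genes
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("screening", "stage-failure", f"{trait_name}: {exc}") from exc

        sub = module_trait[module_trait["trait"] == trait_name]
        best = int(sub.loc[sub["r"].abs().idxmax(), "module"])
        top_module[trait_name] = best

        if gene_sets is not None and len(gene_sets) > 0:
            s = stage_seed(config.seed, f"gsea:{trait_name}")
            log["stage_seeds"][f"gsea:{trait_name}"] = s
            try:
                ranking = gsea_mod.rank_genes(kme_matrix[best])
                gsea_tables[trait_name] = gsea_mod.gsea_preranked(
                    ranking,
                    gene_sets,
                    n_perm=config.n_perm,
                    exponent=config.exponent,
                    seed=s,
                    min_size=config.min_set_size,
                    max_size=config.max_set_size,
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("gsea", "stage-failure", f"{trait_name}: {exc}") from exc

        if len(genes) < 2:
            warnings.warn(
                f"trait {trait_name}: fewer than 2 genes pass |rho| >= {config.rho_threshold}; "
                "skipping clustering and survival contrast",
                stacklevel=2,
            )
            continue
        record(f"clustering:{trait_name}")
        try:
            labels, summary = screening.cluster_samples(
                expression.loc[genes], traits[trait_name], k=config.k_clusters
            )
            clusters[trait_name] = labels
            summaries[trait_name] = summary
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("clustering", "stage-failure", f"{trait_name}: {exc}") from exc

        if surv is not None and config.k_clusters == 2:
            record(f"survival:{trait_name}")
            try:
                data = surv.copy()
                data["group"] = labels.loc[data.index]
                chi2, p_logrank = survival.logrank_test(data)
                indicator = (data["group"] == "II").astype(float)
                fit = survival.cox_fit(data, indicator)
                groups = survival.summarize_groups(data)
                lo, hi = fit.confidence_interval()
                survival_report["traits"][trait_name] = {
                    "logrank_chi2": chi2,
                    "logrank_p": p_logrank,
                    "cox_log_hr": fit.log_hr,
                    "cox_hr": fit.hr,
                    "cox_hr_ci95": [lo, hi],
                    "cox_wald_p": fit.p,
                    "cox_converged": fit.converged,
                    "groups": json.loads(groups.to_json(orient="index")),
                }
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("survival", "stage-failure", f"{trait_name}: {exc}") from exc

    log["trait_groups"] = trait_groups
    log["retained_traits"] = retained
    log["trait_top_module"] = top_module

    # ---- exports ----------------------------------------------------------
    record("export")
    edges, nodes = network.export_network(tom_matrix, partition, config.export_threshold)
    assignment = pd.DataFrame(
        {
            "module_label": partition,
            "kME_own_module": [
                kme_matrix.loc[g, partition[g]] if partition[g] > 0 else np.nan
                for g in partition.index
            ],
        }
    ).rename_axis("gene_id")
    _write(assignment, outdir / "module_assignment.tsv")
    files["module_assignment"] = "module_assignment.tsv"
    _write(module_trait, outdir / "module_trait_correlation.tsv", index=False)
    files["module_trait_correlation"] = "module_trait_correlation.tsv"
    _write(eigengenes.rename_axis("module"), outdir / "eigengenes.tsv")
    files["eigengenes"] = "eigengenes.tsv"
    _write(edges, outdir / "network_edges.tsv", index=False)
    files["network_edges"] = "network_edges.tsv"
    _write(nodes, outdir / "network_nodes.tsv", index=False)
    files["network_nodes"] = "network_nodes.tsv"
    for trait_name, table in screening_tables.items():
        name = f"gene_trait_{trait_name}.tsv"
        _write(table.rename_axis("gene_id"), outdir / name)
        files[f"gene_trait_{trait_name}"] = name
    for trait_name, labels in clusters.items():
        name = f"clusters_{trait_name}.csv"
        out = pd.DataFrame({"cluster": labels, "trait_value": traits.loc[labels.index, trait_name]})
        _write(out.rename_axis("sample_id"), outdir / name, sep=",")
        files[f"clusters_{trait_name}"] = name
    for trait_name, table in gsea_tables.items():
        name = f"gsea_{trait_name}.tsv"
        _write(table, outdir / name)
        files[f"gsea_{trait_name}"] = name
    with open(outdir / "survival_report.json", "w") as fh:
        json.dump(survival_report, fh, indent=2, sort_keys=True)
    files["survival_report"] = "survival_report.json"
    log["config"] = dataclasses.asdict(config)
    log["files"] = files
    if truth is not None:
        log["planted"] = {
            "trait_module_links": {k: list(v) for k, v in truth.trait_module_links.items()},
            "enriched_sets": truth.enriched_sets,
            "survival_link": list(truth.survival_link) if truth.survival_link else None,
        }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    files["run_log"] = "run_log.json"

    return ReportBundle(
        config=config,
        outdir=outdir,
        partition=partition,
        eigengenes=eigengenes,
        module_trait=module_trait,
        retained_traits=retained,
        trait_groups=trait_groups,
        screening=screening_tables,
        selected_genes=selected,
        clusters=clusters,
        cluster_summaries=summaries,
        gsea=gsea_tables,
        survival_report=survival_report,
        files=files,
        log=log,
    )
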