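"""End-to-end orchestration: ingest/simulate → QC → DE filter → branches.

The analysis graph mirrors the study's data flow: probe-level data are
summarized to probe sets, arrays are QC-checked and excluded, a moderated
four-group linear model with all pairwise contrasts feeds the joint
p/fold-change inclusion filter, and the filtered gene set feeds two
independent branches — (A) hierarchical clustering with per-cluster pathway
over-representation and trait correlation, and (B) the expression-pattern
taxonomy, which depends only on the contrast table.

Every stage is a pure function of its inputs plus parameters; a run with the
same configuration and seed writes byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import pandas as pd
import yaml

from . import clustering, diffexpr, enrichment, io, patterns, preprocess, simulate, traits
from .errors import ValidationError
from .params import AnalysisParams

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Inputs, parameters and stage toggles for one pipeline run.

    Either the real-data paths (``expression``, ``probe_map``,
    ``sample_sheet``) or a :class:`~ifliver.simulate.SimConfig` must be
    given.  ``gmt`` and ``trait_table`` are optional; the corresponding
    stages are skipped without them (synthetic runs generate their own
    traits).
    """

    out_dir: str
    expression: str | None = None
    probe_map: str | None = None
    sample_sheet: str | None = None
    gmt: str | None = None
    trait_table: str | None = None
    already_log: bool = True
    summarize_method: str = "median"
    qc_min_corr: float = 0.8
    qc_pc_mad_multiplier: float = 5.0
    params: AnalysisParams = dataclasses.field(default_factory=AnalysisParams)
    sim: simulate.SimConfig | None = None
    seed: int | None = None
    run_qc: bool = True
    run_clustering: bool = True
    run_enrichment: bool = True
    run_traits: bool = True
    run_patterns: bool = True

    def __post_init__(self) -> None:
        synthetic = self.sim is not None
        real = all(
            p is not None for p in (self.expression, self.probe_map, self.sample_sheet)
        )
        if not synthetic and not real:
            raise ValidationError(
                "config needs either a SimConfig or all three real-data paths "
                "(expression, probe_map, sample_sheet)"
            )
        if synthetic and self.seed is None:
            raise ValidationError("synthetic runs require an explicit seed")


def load_config(path: str) -> PipelineConfig:
    """Read a pipeline configuration from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "params" in raw and raw["params"] is not None:
        raw["params"] = AnalysisParams(**raw["params"])
    if "sim" in raw and raw["sim"] is not None:
        raw["sim"] = simulate.SimConfig(**raw["sim"])
    return PipelineConfig(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Writes one TSV per result table plus ``run_report.json`` under
    ``config.out_dir`` and returns the run report (per-stage row counts,
    parameters, warnings, and headline counts).
    """
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {"stages": {}, "headline": {}, "warnings": []}
    params = config.params
    bundle: dict[str, pd.DataFrame] = {}

    def stage(name: str, **info) -> None:
        report["stages"][name] = info
        log.info("stage %s: %s", name, info)

    # ---- ingest or simulate -------------------------------------------------
    if config.sim is not None:
        sim_cfg = dataclasses.replace(config.sim, seed=int(config.seed))
        probe_matrix, probe_map, sheet, truth = simulate.simulate_dataset(sim_cfg)
        bundle["planted_truth"] = truth.reset_index()
        stage(
            "simulate",
            n_probes=len(probe_matrix),
            n_probesets=sim_cfg.n_probesets,
            n_arrays=probe_matrix.shape[1],
            seed=int(config.seed),
        )
    else:
        probe_matrix = io.read_expression_table(
            config.expression, log_scale=config.already_log
        )
        probe_map = io.read_probe_map(config.probe_map)
        sheet = io.read_sample_sheet(config.sample_sheet)
        truth = None
        stage(
            "ingest",
            n_probes=len(probe_matrix),
            n_arrays=probe_matrix.shape[1],
        )

    probe_matrix = preprocess.log_transform(probe_matrix, already_log=True)

    # ---- QC and exclusion ---------------------------------------------------
    if config.run_qc:
        qc = preprocess.array_qc_stats(probe_matrix)
        qc = preprocess.flag_failed_arrays(
            qc,
            min_median_correlation=config.qc_min_corr,
            pc_mad_multiplier=config.qc_pc_mad_multiplier,
        )
        probe_matrix = preprocess.exclude_arrays(probe_matrix, qc, sheet)
        sheet = sheet.loc[probe_matrix.columns]
        bundle["qc_report"] = qc.reset_index()
        stage(
            "qc",
            flagged=int(qc["flagged"].sum()),
            surviving_arrays=probe_matrix.shape[1],
            per_treatment=sheet["treatment"].value_counts().to_dict(),
        )

    # ---- summarization ------------------------------------------------------
    expr = preprocess.summarize_probesets(
        probe_matrix, probe_map, method=config.summarize_method
    )
    stage("summarize", n_probesets=len(expr), method=config.summarize_method)

    # ---- differential expression -------------------------------------------
    fit = diffexpr.fit_linear_model(expr, sheet)
    if params.moderation == "ebayes":
        prior = diffexpr.estimate_variance_prior(fit)
    else:
        prior = diffexpr.VariancePrior(d0=0.0, s0sq=0.0)
    contrast_table = diffexpr.pairwise_contrasts(fit, prior, params)
    deg = diffexpr.filter_de(contrast_table, params)
    counts = diffexpr.updown_counts(contrast_table, params)
    bundle["contrasts"] = contrast_table
    bundle["updown_counts"] = counts
    bundle["deg_set"] = pd.DataFrame({"gene": sorted(deg)})
    stage(
        "diffexpr",
        d0=float(prior.d0),
        s0sq=float(prior.s0sq),
        n_filtered=len(deg),
    )
    report["headline"]["filtered_genes"] = len(deg)

    # ---- branch A: clustering, enrichment, traits ---------------------------
    assignment = None
    cmeans = None
    if config.run_clustering and len(deg) >= params.k_clusters:
        std = clustering.standardize_rows(expr.loc[sorted(deg)])
        gene_dend = clustering.cluster_genes(std)
        sample_dend = clustering.cluster_samples(std)
        assignment = clustering.cut_k(gene_dend, params.k_clusters)
        cmeans = clustering.cluster_means(std, assignment)
        bundle["cluster_assignment"] = assignment.rename("cluster").reset_index()
        bundle["cluster_means"] = cmeans.reset_index()
        bundle["heatmap_matrix"] = clustering.leaf_ordered_matrix(
            std, gene_dend, sample_dend
        ).reset_index()
        sample_cut = clustering.cut_k(sample_dend, 2)
        bundle["sample_clusters"] = sample_cut.rename("cluster").reset_index()
        sizes = assignment.value_counts().sort_index()
        stage("clustering", cluster_sizes=sizes.to_dict())
        report["headline"]["cluster_sizes"] = {
            str(k): int(v) for k, v in sizes.items()
        }

    if (
        config.run_enrichment
        and config.gmt is not None
        and assignment is not None
    ):
        pathways = io.read_gmt(config.gmt)
        universe = enrichment.annotated_universe(pathways, set(expr.index))
        if universe:
            enr_frames = []
            su_frames = []
            for c in sorted(assignment.unique()):
                genes = set(assignment.index[assignment == c])
                table = enrichment.ora(genes, pathways, universe)
                table.insert(0, "cluster", c)
                enr_frames.append(table)
                su = enrichment.shared_unique(table.drop(columns="cluster"))
                su.insert(0, "cluster", c)
                su_frames.append(su)
            bundle["enrichment"] = pd.concat(enr_frames, ignore_index=True)
            bundle["shared_unique"] = pd.concat(su_frames, ignore_index=True)
            stage(
                "enrichment",
                n_pathways=len(pathways),
                universe=len(universe),
                significant=int((bundle["enrichment"]["p_adj"] < 0.05).sum()),
            )

    if config.run_traits and cmeans is not None:
        trait_table = None
        if config.trait_table is not None:
            trait_table = io.read_trait_table(config.trait_table)
        elif config.sim is not None:
            # synthetic runs: plant a strong correlation between the first
            # cluster's mean expression and relative liver mass
            specs = [simulate.TraitSimSpec("relative_liver_mass", 0.8)]
            archetype = pd.Series(
                cmeans.iloc[0].to_numpy(),
                index=sheet.loc[cmeans.columns, "individual_id"],
            )
            trait_table = simulate.simulate_traits(
                archetype, specs, seed=int(config.seed) + 1
            )
        if trait_table is not None:
            corr = traits.correlate_units(cmeans, trait_table, sheet, params)
            bundle["trait_correlations"] = corr
            stage(
                "traits",
                n_tests=len(corr),
                significant=int(corr["significant"].sum()),
                threshold=corr.attrs["threshold"],
            )
            report["headline"]["significant_correlations"] = int(
                corr["significant"].sum()
            )

    # ---- branch B: pattern taxonomy ----------------------------------------
    if config.run_patterns:
        filtered_table = contrast_table[contrast_table["gene"].isin(deg)]
        if len(filtered_table):
            calls = patterns.classify_gene_patterns(filtered_table, params)
            summary = patterns.summarize_patterns(calls)
            bundle["pattern_calls"] = calls.reset_index()
            bundle["pattern_summary"] = summary.reset_index()
            stage(
                "patterns",
                **{
                    str(k): int(v)
                    for k, v in summary["count"].items()
                    if k in patterns.FLAG_COLUMNS
                },
            )
            report["headline"]["pattern_counts"] = {
                str(k): int(v) for k, v in summary["count"].items()
            }

    written = io.write_results(bundle, config.out_dir)
    report["artifacts"] = [os.path.basename(p) for p in written]
    with open(os.path.join(config.out_dir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
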