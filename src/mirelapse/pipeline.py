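"""End-to-end orchestration from a single configuration.

A :class:`PipelineConfig` either points at input files (expression
matrices, pairing table, prediction resources, gene sets, survival and Ct
tables) or asks for a synthetic run, in which case every input is
generated with the synthetic module, written to the output directory, and
then consumed exactly as user-supplied files would be.  The run report
records the package version, seed, thresholds and per-stage counts, and
the fully serialized configuration for provenance.  Any stage error aborts
with a stage-labelled message; partial outputs are retained.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, io
from .enrichment import enrich, enrichment_frame
from .integration import (
    edge_recall_precision,
    filter_by_target_support,
    find_anticorrelated_pairs,
    pairs_frame,
    summarize_pairs,
)
from .profiling import (
    classify_vs_reference,
    merge_status,
    normalize_counts,
    paired_de_test,
    status_frame,
)
from .qpcr import relative_expression_frame, relative_expression_from_table
from .survival import cox_fit, km_estimate, optimal_cutpoint
from .synthetic import (
    component_seed,
    generate_gene_sets,
    generate_mrna_expression,
    generate_paired_mirna_counts,
    generate_reference_expression,
    generate_survival_cohort,
    generate_target_resources,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and provenance for one pipeline run."""

    out_dir: str = "mirelapse_run"
    seed: int = 0
    simulate: bool = False

    # input paths (ignored when simulate=True)
    mirna_counts: str | None = None
    sample_meta: str | None = None
    pairing: str | None = None
    mrna_expression: str | None = None
    mrna_sample_meta: str | None = None
    reference_expression: str | None = None
    resources: str | None = None
    gene_sets: str | None = None
    survival_table: str | None = None
    ct_table: str | None = None
    ct_calibrator: str | None = None

    # thresholds (defaults mirror the analysis conventions)
    rho_max: float = -0.7
    p_max: float = 0.05
    de_alpha: float = 0.05
    de_method: str = "paired_t"
    min_support: int = 1
    min_group_frac: float = 0.1
    up_log2fc: float = 1.0
    down_log2fc: float = 1.0
    pseudocount: float = 0.5
    survival_biomarker: str = "biomarker"
    cox_terms: list[str] = field(default_factory=list)

    # synthetic-run sizes (the study design scale)
    sim: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not -1 <= self.rho_max <= 1:
            raise ValueError("rho_max must lie in [-1, 1]")
        for name in ("p_max", "de_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.min_support < 0:
            raise ValueError("min_support must be >= 0")
        if not 0 <= self.min_group_frac < 0.5:
            raise ValueError("min_group_frac must lie in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


def _simulate_inputs(config: PipelineConfig, out: Path) -> dict:
    sim = dict(config.sim)
    seed = config.seed
    mirna, truth, pairing = generate_paired_mirna_counts(
        n_mirnas=sim.get("n_mirnas", 300),
        n_pairs=sim.get("n_pairs", 7),
        de_fraction=sim.get("de_fraction", 0.026 * 500 / 300),
        effect_log2fc=sim.get("effect_log2fc", 2.0),
        dispersion=sim.get("dispersion", 0.1),
        depth=sim.get("depth", 1e6),
        seed=component_seed(seed, "mirna_counts"),
    )
    mrna = generate_mrna_expression(
        mirna,
        truth,
        noise_sd=sim.get("noise_sd", 0.2),
        n_genes=sim.get("n_genes", 1500),
        targets_per_mirna=sim.get("targets_per_mirna", 30),
        strength=sim.get("strength", -1.5),
        seed=component_seed(seed, "mrna"),
    )
    mirna_log2 = normalize_counts(mirna, config.pseudocount)
    offsets = {m: 3.0 for m in truth.mirna_universe[:24]}
    offsets.update({m: -3.0 for m in truth.mirna_universe[24 : 24 + 50]})
    reference = generate_reference_expression(
        mirna_log2, offsets, seed=component_seed(seed, "reference")
    )
    resources = generate_target_resources(
        truth,
        n_resources=sim.get("n_resources", 5),
        sensitivity=sim.get("sensitivity", 0.8),
        fp_rate=sim.get("fp_rate", 0.0005),
        seed=component_seed(seed, "resources"),
    )
    gene_sets = generate_gene_sets(
        truth, n_sets=sim.get("n_sets", 50), seed=component_seed(seed, "gene_sets")
    )
    surv, surv_truth = generate_survival_cohort(
        n=sim.get("n_survival", 233),
        hazard_ratio=sim.get("hazard_ratio", 4.0),
        censor_rate=sim.get("censor_rate", 0.3),
        covariates={"name": "IPI", "levels": ["0-2", "3-5"], "probs": [0.6, 0.4],
                    "hazard_ratios": [1.0, 2.0]},
        seed=component_seed(seed, "survival"),
    )
    truth.true_cutpoint = surv_truth.true_cutpoint
    truth.true_hazard_ratio = surv_truth.true_hazard_ratio

    inputs = out / "inputs"
    io.ensure_dir(inputs)
    io.write_expression_tsv(mirna, inputs / "mirna_counts.tsv", inputs / "mirna_samples.tsv")
    io.write_expression_tsv(mrna, inputs / "mrna_log2.tsv", inputs / "mrna_samples.tsv")
    io.write_expression_tsv(reference, inputs / "reference_log2.tsv",
                            inputs / "reference_samples.tsv")
    io.write_pairing_tsv(pairing, inputs / "pairing.tsv")
    io.write_resource_tsv(resources, inputs / "resources.tsv")
    io.write_gmt(gene_sets, inputs / "gene_sets.gmt")
    io.write_survival_tsv(surv, inputs / "survival.tsv")
    io.write_truth(truth, inputs / "truth.txt")
    return {
        "mirna": mirna,
        "pairing": pairing,
        "mrna": mrna,
        "reference": reference,
        "resources": resources,
        "gene_sets": gene_sets,
        "survival": surv,
        "truth": truth,
        "ct": None,
    }


def _load_inputs(config: PipelineConfig) -> dict:
    if config.mirna_counts is None:
        raise ValueError("mirna_counts path is required when simulate is false")
    mirna = io.read_expression_tsv(config.mirna_counts, config.sample_meta, scale="counts")
    pairing = io.read_pairing_tsv(config.pairing) if config.pairing else None
    mrna = (
        io.read_expression_tsv(
            config.mrna_expression,
            config.mrna_sample_meta or config.sample_meta,
            scale="log2",
        )
        if config.mrna_expression
        else None
    )
    reference = (
        io.read_expression_tsv(config.reference_expression, None, scale="log2")
        if config.reference_expression
        else None
    )
    resources = io.read_resource_tsv(config.resources) if config.resources else []
    gene_sets = io.read_gmt(config.gene_sets) if config.gene_sets else None
    surv = io.read_survival_tsv(config.survival_table) if config.survival_table else None
    ct = io.read_ct_tsv(config.ct_table) if config.ct_table else None
    return {
        "mirna": mirna,
        "pairing": pairing,
        "mrna": mrna,
        "reference": reference,
        "resources": resources,
        "gene_sets": gene_sets,
        "survival": surv,
        "truth": None,
        "ct": ct,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; return the run report dict."""
    config.validate()
    out = io.ensure_dir(config.out_dir)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    stage = "inputs"
    try:
        data = _simulate_inputs(config, out) if config.simulate else _load_inputs(config)
        report["stages"]["inputs"] = {
            "n_mirnas": len(data["mirna"].feature_ids),
            "n_samples": len(data["mirna"].sample_ids),
        }

        stage = "expression"
        log2 = normalize_counts(data["mirna"], config.pseudocount)
        de = paired_de_test(log2, data["pairing"], config.de_method, config.de_alpha)
        de_calls = [s for s in de if s.mirna_class in ("DE_up", "DE_down")]
        statuses = de
        n_high = n_low = 0
        if data["reference"] is not None:
            ref_status = classify_vs_reference(
                log2, data["reference"], config.up_log2fc, config.down_log2fc,
                config.de_alpha,
            )
            statuses = merge_status(de, ref_status)
            n_high = sum(s.mirna_class == "high" for s in statuses)
            n_low = sum(s.mirna_class == "low" for s in statuses)
        status_frame(statuses).to_csv(out / "mirna_status.tsv", sep="\t", index=False)
        report["stages"]["expression"] = {
            "n_de": len(de_calls),
            "n_de_up": sum(s.mirna_class == "DE_up" for s in de_calls),
            "n_de_down": sum(s.mirna_class == "DE_down" for s in de_calls),
            "n_high": n_high,
            "n_low": n_low,
        }

        if data["mrna"] is not None:
            stage = "integration"
            subset = [s.mirna for s in de_calls] or None
            pairs = find_anticorrelated_pairs(
                log2, data["mrna"], mirna_subset=subset,
                rho_max=config.rho_max, p_max=config.p_max,
            )
            supported = (
                filter_by_target_support(pairs, data["resources"], config.min_support)
                if data["resources"]
                else pairs
            )
            n_pairs, n_genes, _ = summarize_pairs(supported)
            pairs_frame(supported).to_csv(out / "anticorr_pairs.tsv", sep="\t", index=False)
            io.write_edge_list(supported, out / "network_edges.tsv")
            report["stages"]["integration"] = {
                "n_candidate_pairs": len(pairs),
                "n_supported_pairs": n_pairs,
                "n_unique_genes": n_genes,
            }
            if data["truth"] is not None:
                recall, precision = edge_recall_precision(supported, data["truth"])
                report["stages"]["integration"]["recall_vs_truth"] = recall
                report["stages"]["integration"]["precision_vs_truth"] = precision

            if data["gene_sets"] is not None and n_genes:
                stage = "enrichment"
                query = {p.gene for p in supported}
                rows = enrich(query, data["gene_sets"])
                enrichment_frame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
                report["stages"]["enrichment"] = {
                    "n_sets_tested": len(rows),
                    "top_set": rows[0].set_id if rows else None,
                    "top_adjusted_p": rows[0].adjusted_p if rows else None,
                }

        if data["survival"] is not None:
            stage = "survival"
            surv = data["survival"]
            cut = optimal_cutpoint(
                surv[config.survival_biomarker].to_numpy(), surv,
                config.min_group_frac, biomarker=config.survival_biomarker,
            )
            cut.profile.to_csv(out / "cutpoint_profile.tsv", sep="\t", index=False)
            import pandas as pd

            surv = surv.assign(
                expression_group=pd.Categorical(
                    (surv[config.survival_biomarker] > cut.cutpoint)
                    .map({True: "high", False: "low"}),
                    categories=["low", "high"],
                )
            )
            for grp in ("low", "high"):
                sub = surv[surv["expression_group"] == grp]
                km = km_estimate(sub["time_months"], sub["event"])
                km.as_frame().to_csv(out / f"km_{grp}.tsv", sep="\t", index=False)
            terms = ["expression_group"] + list(config.cox_terms)
            terms = [t for t in terms if t in surv.columns]
            if config.simulate:
                terms = ["expression_group", "IPI"]
            fit = cox_fit(surv, terms)
            fit.as_frame().to_csv(out / "cox_fit.tsv", sep="\t", index=False)
            report["stages"]["survival"] = {
                "cutpoint": cut.cutpoint,
                "logrank_p": cut.p_value,
                "n_low": cut.n_low,
                "n_high": cut.n_high,
                "cox_terms": fit.terms,
                "cox_rr": [float(x) for x in fit.rr],
                "cox_converged": fit.converged,
            }

        if data["ct"] is not None:
            stage = "qpcr"
            if not config.ct_calibrator:
                raise ValueError("ct_calibrator is required with a Ct table")
            rel = relative_expression_from_table(data["ct"], config.ct_calibrator)
            relative_expression_frame(rel).to_csv(
                out / "relative_expression.tsv", sep="\t", index=False
            )
            report["stages"]["qpcr"] = {"n_quantities": len(rel)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "run_report.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
    return report
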