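"""Discovery and validation orchestration.

Discovery: CPE per subject -> per-gene ranking -> GSEA screen -> select the
top FDR-passing pathway (max NES, leading-edge then name as tie-breaks) ->
pathway PCA oriented against CPE -> three Firth-penalized Cox models
(CPE only, PC1 only, both), all adjusted for age, size, grade, and the
AST x nodal construct.

Validation: moment-match a second cohort's expression to the discovery
cohort, project the frozen PCA loadings, and fit a standard Cox model on
the standardized PC1.

Every stage records its parameters and seed in the run report, which is
reproducible byte-for-byte for a fixed config and inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cpegx import io as _io
from cpegx.association import log_cpm
from cpegx.gsea import GeneSetCollection, gsea
from cpegx.imaging import standardize
from cpegx.pathway import PathwayPcaModel, fit_pathway_pca, translate_cohort, project
from cpegx.survival import cox_fit, fit_paper_models, build_design

__all__ = ["PipelineConfig", "RunReport", "run_discovery", "run_validation"]


@dataclass
class PipelineConfig:
    expression_path: str = ""
    clinical_path: str = ""
    gene_sets_path: str = ""
    output_dir: str = "cpegx_out"
    expression_kind: str = "counts"     # counts (discovery) or continuous
    cpe_column: str = "cpe"
    n_perm: int = 1000
    scheme: str = "response"
    weight_exponent: float = 1.0
    min_set_size: int = 5
    max_set_size: int = 500
    fdr_threshold: float = 0.25
    moderation: str = "none"
    seed: int = 0
    penalize: str = "firth"
    validation_penalize: str = "none"
    min_gene_overlap: int = 2

    def __post_init__(self):
        if not (0.0 <= self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    stage: str
    config: dict
    cpe_summary: dict = field(default_factory=dict)
    gsea_table: pd.DataFrame | None = None
    selected_pathway: str | None = None
    pca_summary: dict = field(default_factory=dict)
    model_tables: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_payload(self) -> dict:
        payload = {
            "stage": self.stage,
            "config": self.config,
            "cpe_summary": self.cpe_summary,
            "selected_pathway": self.selected_pathway,
            "pca_summary": self.pca_summary,
            "warnings": list(self.warnings),
        }
        if self.gsea_table is not None:
            payload["gsea_table"] = self.gsea_table.to_dict(orient="records")
        payload["model_tables"] = {
            name: df.reset_index().to_dict(orient="records")
            for name, df in self.model_tables.items()
        }
        return payload

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"report_{self.stage}.json").write_text(
            json.dumps(self.to_payload(), indent=2, default=float) + "\n")
        if self.gsea_table is not None:
            self.gsea_table.to_csv(out / "gsea_results.tsv", sep="\t", index=False)
        for name, df in self.model_tables.items():
            df.to_csv(out / f"model_{name}.tsv", sep="\t")


def select_pathway(gsea_table: pd.DataFrame, fdr_threshold: float) -> str | None:
    """Strongest FDR-passing enrichment: max |NES|, leading edge then name
    as tie-breaks.  Magnitude, not signed NES, so that a pathway whose
    members anti-correlate with CPE (enriched at the bottom of the ranking)
    is selected just like a positively enriched one."""
    passing = gsea_table[gsea_table["fdr_q"] < fdr_threshold].copy()
    if passing.empty:
        return None
    passing["abs_nes"] = passing["nes"].abs()
    ordered = passing.sort_values(
        ["abs_nes", "leading_edge", "set_name"],
        ascending=[False, False, True], kind="stable")
    return str(ordered.iloc[0]["set_name"])


def _summary_frame(fit) -> pd.DataFrame:
    return fit.summary()


def run_discovery(config: PipelineConfig, write: bool = True) -> RunReport:
    """Full discovery arm on one cohort; see module docstring for stages."""
    expr_raw = _io.read_expression_tsv(config.expression_path,
                                       kind=config.expression_kind)
    clinical = _io.read_clinical_csv(config.clinical_path)
    collection = GeneSetCollection.read_gmt(config.gene_sets_path)
    if config.cpe_column not in clinical.columns:
        raise ValueError(f"clinical table has no column {config.cpe_column!r}")
    cpe = clinical[config.cpe_column].to_numpy(dtype=float)
    cpe_z, cpe_std = standardize(cpe)

    expr = log_cpm(expr_raw) if config.expression_kind == "counts" else expr_raw

    table = gsea(
        expr, cpe_z, collection,
        n_perm=config.n_perm, scheme=config.scheme,
        weight_exponent=config.weight_exponent, seed=config.seed,
        min_size=config.min_set_size, max_size=config.max_set_size,
        moderation=config.moderation)

    report = RunReport(
        stage="discovery",
        config=asdict(config),
        cpe_summary={
            "n": int(cpe.size),
            "median": float(np.median(cpe)),
            "min": float(cpe.min()), "max": float(cpe.max()),
            "mean": cpe_std.mean, "sd": cpe_std.sd,
        },
        gsea_table=table,
    )

    selected = select_pathway(table, config.fdr_threshold)
    report.selected_pathway = selected
    if selected is None:
        report.warnings.append(
            f"no gene set passed FDR < {config.fdr_threshold}; "
            "survival stages skipped")
        if write:
            report.write(config.output_dir)
        return report

    model, scores = fit_pathway_pca(expr, collection[selected], orient_against=cpe_z)
    pc1_z = scores.pc1 / model.score_sd
    from cpegx.association import pearson_with_ci
    corr = pearson_with_ci(pc1_z, cpe_z)
    report.pca_summary = {
        "pathway": selected,
        "n_genes_used": len(model.gene_ids),
        "variance_explained": model.variance_explained,
        "cor_pc1_cpe": corr.r,
        "cor_ci": [corr.ci_low, corr.ci_high],
        "cor_p": corr.p,
    }

    for which in ("cpe_only", "pc1_only", "both"):
        fit = fit_paper_models(clinical, cpe=cpe_z, pc1=pc1_z, which=which,
                               penalize=config.penalize)
        report.model_tables[which] = _summary_frame(fit)
        report.warnings.extend(fit.warnings_)

    if write:
        report.write(config.output_dir)
        model.to_json(Path(config.output_dir) / "pathway_pca_model.json")
    return report


def run_validation(
    config: PipelineConfig,
    model: PathwayPcaModel,
    write: bool = True,
) -> RunReport:
    """Validation arm: translate -> project -> standardized PC1 -> Cox."""
    expr = _io.read_expression_tsv(config.expression_path,
                                   kind=config.expression_kind)
    if config.expression_kind == "counts":
        expr = log_cpm(expr)
    clinical = _io.read_clinical_csv(config.clinical_path)
    overlap = len(set(model.gene_ids) & set(expr.gene_ids))
    if overlap < config.min_gene_overlap:
        raise ValueError(
            f"only {overlap} of {len(model.gene_ids)} model genes present "
            f"in the validation cohort (floor {config.min_gene_overlap})")

    translated = translate_cohort(expr, model)
    scores = project(translated, model)
    pc1_z, _ = standardize(scores.pc1)

    fit = fit_paper_models(clinical, pc1=pc1_z, which="pc1_only",
                           penalize=config.validation_penalize)
    report = RunReport(
        stage="validation",
        config=asdict(config),
        pca_summary={
            "n_model_genes": len(model.gene_ids),
            "n_genes_shared": overlap,
            "variance_explained_training": model.variance_explained,
        },
        model_tables={"pc1_only": _summary_frame(fit)},
        warnings=list(fit.warnings_),
    )
    if write:
        report.write(config.output_dir)
    return report
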