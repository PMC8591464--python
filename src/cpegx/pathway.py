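"""Pathway PCA: condense a gene set's expression into PC1 and carry the
model onto an independent cohort measured on a different platform.

The training cohort's expression for the set's genes is z-scaled per gene,
PCA is run on the scaled matrix, and PC1 is used as a one-number pathway
activity score.  To score a second cohort, each shared gene is first
linearly rescaled to the reference cohort's per-gene mean and variance
(moment matching across platforms, e.g. RNA-seq vs microarray), then the
reference centering/scaling and loadings are applied unchanged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cpegx.association import ExpressionMatrix

__all__ = [
    "PathwayPcaModel", "PathwayScores",
    "fit_pathway_pca", "translate_cohort", "project",
]


@dataclass(frozen=True)
class PathwayPcaModel:
    """Frozen PCA of a gene set: per-gene reference moments plus loadings.

    ``loadings`` is the unit-norm PC1 coefficient vector over ``gene_ids``;
    ``components`` optionally retains the full rotation (rows = components).
    ``sign_anchor`` records how the PC1 sign ambiguity was resolved.
    """

    gene_ids: tuple
    ref_means: np.ndarray
    ref_sds: np.ndarray
    loadings: np.ndarray
    variance_explained: float
    sign_anchor: str = "largest-loading-positive"
    components: np.ndarray | None = None
    explained_ratios: np.ndarray | None = None
    dropped_genes: tuple = ()
    score_sd: float = 1.0

    def to_json(self, path=None) -> str:
        payload = {
            "gene_ids": list(self.gene_ids),
            "ref_means": self.ref_means.tolist(),
            "ref_sds": self.ref_sds.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_explained": self.variance_explained,
            "sign_anchor": self.sign_anchor,
            "dropped_genes": list(self.dropped_genes),
            "score_sd": self.score_sd,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PathwayPcaModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            gene_ids=tuple(d["gene_ids"]),
            ref_means=np.asarray(d["ref_means"], dtype=float),
            ref_sds=np.asarray(d["ref_sds"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            variance_explained=float(d["variance_explained"]),
            sign_anchor=d.get("sign_anchor", "largest-loading-positive"),
            dropped_genes=tuple(d.get("dropped_genes", ())),
            score_sd=float(d.get("score_sd", 1.0)),
        )


@dataclass(frozen=True)
class PathwayScores:
    sample_ids: tuple
    pc1: np.ndarray

    def standardized(self, sd: float) -> "PathwayScores":
        return PathwayScores(self.sample_ids, self.pc1 / sd)


def fit_pathway_pca(
    expr: ExpressionMatrix,
    gene_set,
    orient_against=None,
) -> tuple[PathwayPcaModel, PathwayScores]:
    """PCA on the z-scaled expression of a gene set's members.

    Per-gene scaling uses the training sample mean and SD (ddof=1); constant
    genes are dropped with a warning and recorded on the model.  The PC1
    sign is oriented so that the scores correlate *negatively* with
    ``orient_against`` when given (the convention for a pathway expected to
    anti-correlate with CPE); otherwise the largest-magnitude loading is
    made positive.
    """
    sub = expr.subset_genes(gene_set)
    if sub.n_genes == 0:
        raise ValueError("none of the gene set's members are present in the matrix")
    n = sub.n_samples
    if n <= 2:
        raise ValueError("need more than 2 samples for a pathway PCA")

    means = sub.values.mean(axis=1)
    sds = sub.values.std(axis=1, ddof=1)
    usable = sds > 0
    dropped = tuple(g for g, u in zip(sub.gene_ids, usable) if not u)
    if dropped:
        warnings.warn(f"dropping constant genes from pathway PCA: {dropped}",
                      stacklevel=2)
    if usable.sum() < 2:
        raise ValueError("fewer than 2 non-constant member genes")
    gene_ids = tuple(g for g, u in zip(sub.gene_ids, usable) if u)
    means, sds = means[usable], sds[usable]
    z = (sub.values[usable] - means[:, None]) / sds[:, None]  # genes x samples

    # PCA via SVD of the samples x genes matrix (already column-centered
    # up to numerical noise since each gene is z-scaled on these samples)
    u, s, vt = np.linalg.svd(z.T, full_matrices=False)
    eigvals = s**2 / (n - 1)
    ratios = eigvals / eigvals.sum()
    loadings = vt[0]
    scores = z.T @ loadings

    if orient_against is not None:
        cov = np.cov(scores, np.asarray(orient_against, dtype=float))[0, 1]
        if cov > 0:
            loadings = -loadings
            scores = -scores
        anchor = "negative-correlation-with-covariate"
    else:
        if loadings[np.argmax(np.abs(loadings))] < 0:
            loadings = -loadings
            scores = -scores
        anchor = "largest-loading-positive"

    model = PathwayPcaModel(
        gene_ids=gene_ids,
        ref_means=means,
        ref_sds=sds,
        loadings=loadings,
        variance_explained=float(ratios[0]),
        sign_anchor=anchor,
        components=vt,
        explained_ratios=ratios,
        dropped_genes=dropped,
        score_sd=float(np.std(scores, ddof=1)),
    )
    return model, PathwayScores(sub.sample_ids, scores)


def translate_cohort(
    target_expr: ExpressionMatrix,
    model: PathwayPcaModel,
) -> ExpressionMatrix:
    """Moment-match each shared gene of the target cohort to the reference.

    For gene g: ``y' = (y - mean_t(g)) / sd_t(g) * ref_sd(g) + ref_mean(g)``,
    so the translated per-gene mean and SD equal the reference values exactly.
    Genes absent from the target are dropped (projection later renormalizes
    the loadings); target genes with zero SD are pinned at the reference mean
    and flagged.
    """
    sub = target_expr.subset_genes(model.gene_ids)
    if sub.n_genes < 2:
        raise ValueError("target cohort shares fewer than 2 model genes")
    missing = set(model.gene_ids) - set(sub.gene_ids)
    if missing:
        warnings.warn(f"model genes missing from target cohort: {sorted(missing)}",
                      stacklevel=2)
    idx = {g: i for i, g in enumerate(model.gene_ids)}
    out = np.empty_like(sub.values)
    for row, g in enumerate(sub.gene_ids):
        y = sub.values[row]
        mu_t, sd_t = y.mean(), y.std(ddof=1)
        j = idx[g]
        if sd_t == 0:
            warnings.warn(f"gene {g} constant in target; set to reference mean",
                          stacklevel=2)
            out[row] = model.ref_means[j]
        else:
            out[row] = (y - mu_t) / sd_t * model.ref_sds[j] + model.ref_means[j]
    return ExpressionMatrix(sub.gene_ids, sub.sample_ids, out, kind="continuous")


def project(
    target_expr_translated: ExpressionMatrix,
    model: PathwayPcaModel,
    standardize_scores: bool = False,
) -> PathwayScores:
    """Score a (translated) cohort with the reference PCA.

    Centers by the reference means, scales by the reference SDs, and takes
    the dot product with the PC1 loadings.  When some model genes are
    absent the remaining loadings are renormalized to unit norm.  With
    ``standardize_scores`` the training-score SD sets the unit.
    """
    present = [g for g in model.gene_ids if g in set(target_expr_translated.gene_ids)]
    if len(present) < 2:
        raise ValueError("fewer than 2 model genes available for projection")
    sub = target_expr_translated.subset_genes(present)
    idx = {g: i for i, g in enumerate(model.gene_ids)}
    rows = [idx[g] for g in sub.gene_ids]
    means = model.ref_means[rows]
    sds = model.ref_sds[rows]
    load = model.loadings[rows]
    norm = np.linalg.norm(load)
    if len(present) < len(model.gene_ids):
        load = load / norm
    z = (sub.values - means[:, None]) / sds[:, None]
    scores = z.T @ load
    if standardize_scores:
        scores = scores / model.score_sd
    return PathwayScores(sub.sample_ids, scores)
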