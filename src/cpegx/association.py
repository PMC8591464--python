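"""Per-gene association with CPE: log-CPM transform, t-statistic ranking,
and Pearson correlation with a Fisher-z confidence interval.

Each gene is regressed on the (standardized) CPE vector by simple linear
regression; genes are ranked by the t statistic of the slope, descending.
An optional empirical-Bayes step shrinks the per-gene residual variances
toward their trimmed mean before forming t, which stabilizes the ranking
at small n in the spirit of moderated-t pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix", "RankedGeneList", "CorrelationResult",
    "log_cpm", "gene_cpe_ranking", "pearson_with_ci",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples expression matrix.

    ``kind`` is ``"counts"`` (nonnegative integers, e.g. RNA-seq) or
    ``"continuous"`` (log-CPM, microarray intensities, ...).
    """

    gene_ids: tuple
    sample_ids: tuple
    values: np.ndarray
    kind: str = "continuous"

    def __post_init__(self):
        genes = tuple(str(g) for g in self.gene_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        vals = np.asarray(self.values, dtype=float)
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene ids")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        if vals.shape != (len(genes), len(samples)):
            raise ValueError(
                f"values shape {vals.shape} != ({len(genes)}, {len(samples)})"
            )
        if self.kind not in ("counts", "continuous"):
            raise ValueError(f"kind must be 'counts' or 'continuous', got {self.kind!r}")
        if self.kind == "counts":
            if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
                raise ValueError("counts matrix must contain nonnegative integers")
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "values", vals)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str = "continuous") -> "ExpressionMatrix":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(), kind=kind)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        keep = [g for g in gene_ids if g in index]
        rows = [index[g] for g in keep]
        return ExpressionMatrix(tuple(keep), self.sample_ids,
                                self.values[rows], kind=self.kind)


@dataclass(frozen=True)
class RankedGeneList:
    """Genes ordered by association t statistic, descending.

    ``table`` has columns gene_id, slope, se, t, rank (1-based) and is
    sorted by t descending with lexicographic gene-id tie-break, so output
    files are deterministic.
    """

    table: pd.DataFrame

    @property
    def gene_ids(self) -> tuple:
        return tuple(self.table["gene_id"])

    @property
    def statistics(self) -> np.ndarray:
        return self.table["t"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int
    p: float


def log_cpm(counts: ExpressionMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """Counts-per-million on a log2 scale with a pseudocount.

    Per sample j with library size L_j, gene g maps to
    ``log2((c_gj + prior) / (L_j + 2 * prior) * 1e6)``; the doubled prior in
    the denominator keeps the transform finite and roughly unbiased, the
    convention used by edgeR-style ``cpm(log=TRUE)``.
    """
    if counts.kind != "counts":
        raise ValueError("log_cpm expects a counts matrix")
    lib = counts.values.sum(axis=0)
    if np.any(lib == 0):
        bad = [counts.sample_ids[i] for i in np.where(lib == 0)[0]]
        raise ValueError(f"samples with zero total count: {bad}")
    out = np.log2((counts.values + prior_count) / (lib + 2.0 * prior_count) * 1e6)
    return ExpressionMatrix(counts.gene_ids, counts.sample_ids, out, kind="continuous")


def _ols_against(expr_values: np.ndarray, x: np.ndarray):
    """Vectorized per-row simple linear regression of expression on x.

    Returns (slope, se, t, df) with zero-variance rows given t = 0 and
    perfect fits capped at the largest finite float.
    """
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = expr_values - expr_values.mean(axis=1, keepdims=True)
    slope = (yc @ xc) / sxx
    syy = np.einsum("ij,ij->i", yc, yc)
    df = n - 2
    rss = np.maximum(syy - slope**2 * sxx, 0.0)
    resvar = rss / df
    return slope, resvar, sxx, syy, df


def gene_cpe_ranking(
    expr: ExpressionMatrix,
    cpe: np.ndarray,
    moderation: str = "none",
    prior_df: float = 4.0,
) -> RankedGeneList:
    """Rank every gene by the t statistic of its regression on CPE.

    moderation="empirical_bayes" shrinks residual variances toward the
    trimmed (10%) mean of all per-gene residual variances with ``prior_df``
    pseudo-observations before forming t.
    """
    if moderation not in ("none", "empirical_bayes"):
        raise ValueError(f"unknown moderation {moderation!r}")
    x = np.asarray(cpe, dtype=float)
    if x.size != expr.n_samples:
        raise ValueError("CPE vector length does not match sample count")
    if x.size < 4:
        raise ValueError("need n >= 4 samples for a t-based ranking")
    if not np.all(np.isfinite(x)):
        raise ValueError("CPE vector contains non-finite values")
    if np.unique(x).size < 2:
        raise ValueError("CPE vector has zero variance")

    slope, resvar, sxx, syy, df = _ols_against(expr.values, x)
    if moderation == "empirical_bayes":
        positive = resvar[resvar > 0]
        s0 = float(stats.trim_mean(positive, 0.10)) if positive.size else 0.0
        resvar = (prior_df * s0 + df * resvar) / (prior_df + df)

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(resvar / sxx)
        t = slope / se
    flagged = syy <= 1e-300  # constant genes: association undefined, t := 0
    t[flagged] = 0.0
    se[flagged] = 0.0
    cap = np.finfo(float).max
    t = np.clip(np.nan_to_num(t, nan=0.0, posinf=cap, neginf=-cap), -cap, cap)

    table = pd.DataFrame({
        "gene_id": list(expr.gene_ids),
        "slope": slope,
        "se": se,
        "t": t,
        "zero_variance": flagged,
    })
    table = table.sort_values(
        ["t", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return RankedGeneList(table)


def pearson_with_ci(x, y, conf: float = 0.95) -> CorrelationResult:
    """Pearson r with a Fisher-z confidence interval.

    CI = tanh(atanh(r) +/- z_(1-a/2) / sqrt(n - 3)); two-sided p from the
    exact t transform r * sqrt(n-2) / sqrt(1-r^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if 1.0 - abs(r) < 1e-12:
        r = 1.0 if r > 0 else -1.0
        return CorrelationResult(r=r, ci_low=r, ci_high=r, n=n, p=0.0)
    zcrit = stats.norm.ppf(0.5 + conf / 2.0)
    half = zcrit / np.sqrt(n - 3)
    lo, hi = np.tanh(np.arctanh(r) - half), np.tanh(np.arctanh(r) + half)
    tstat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(tstat), df=n - 2)
    return CorrelationResult(r=r, ci_low=float(lo), ci_high=float(hi), n=n, p=float(p))
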