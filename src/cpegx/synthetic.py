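"""Synthetic cohorts with the statistical structure the analysis assumes,
with full ground truth recorded for parameter-recovery tests.

Three generators, composable or standalone:

* ``gen_dce_study`` — a registered 5-timepoint DCE series (pre-contrast plus
  post-contrast volumes 90 s apart) over an ellipsoidal breast with an inner
  fibroglandular compartment, whose per-voxel enhancement amplitudes are
  drawn so the top-decile delayed-enhancement statistic recovers a requested
  CPE value.
* ``gen_expression_matrix`` — negative-binomial RNA-seq-like counts with
  log-normal library sizes and gene-wise dispersions; a planted gene set's
  log-mean shifts with (standardized) CPE at a known slope.
* ``gen_survival_data`` — Weibull proportional-hazards event times under
  known coefficients with independent exponential censoring, the censoring
  rate calibrated numerically to a target fraction.

``gen_cohort`` ties them together (imaging or "fast" mode, which draws CPE
values directly from a Beta-shaped distribution spanning roughly 0.1-1.0,
the range observed for this statistic in breast cohorts) and can write every
file in the pipeline's interchange formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from cpegx.association import ExpressionMatrix
from cpegx.gsea import GeneSetCollection
from cpegx.imaging import DceStudy, TissueMasks, enhancement_ratio_map, compute_cpe, standardize
from cpegx import io as _io

__all__ = [
    "SyntheticConfig", "SyntheticTruth", "CohortBundle",
    "gen_dce_study", "gen_expression_matrix", "gen_survival_data", "gen_cohort",
]

# uptake curve anchors: fraction of peak enhancement reached at the first
# post-contrast series and at the last one.  Only these two values matter
# for the CPE statistic; the curve between them is a free choice.
_F_EARLY = 0.45
_F_LATE = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort."""

    n_subjects: int = 200
    volume_shape: tuple = (32, 32, 32)
    n_timepoints: int = 5
    timepoint_spacing: float = 90.0
    n_genes: int = 2000
    planted_set_size: int = 40
    gene_effect: float = -0.5
    dispersion: float = 0.15
    survival_betas: dict = field(default_factory=lambda: {"pathway": 0.5, "cpe": -0.5})
    censoring_rate: float = 0.85
    seed: int = 0
    n_gene_sets: int = 50
    background_set_size: int = 40
    latent_correlation: float = 0.8
    weibull_shape: float = 1.2
    weibull_scale: float = 250.0
    planted_seed: int | None = None  # share planted gene ids across cohorts

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_genes < 1 or self.planted_set_size < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_timepoints < 3:
            raise ValueError("need >= 3 timepoints (pre + early + late)")
        if self.planted_set_size > self.n_genes:
            raise ValueError("planted_set_size exceeds n_genes")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in [0, 1)")
        if not (0.0 < self.latent_correlation <= 1.0):
            raise ValueError("latent_correlation must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Every planted parameter, for recovery tests."""

    true_cpe_per_subject: np.ndarray
    planted_gene_ids: tuple
    gene_effect_used: float
    survival_betas_used: dict
    latent_pc_scores: np.ndarray

    def to_json(self, path=None) -> str:
        payload = {
            "true_cpe_per_subject": np.asarray(self.true_cpe_per_subject).tolist(),
            "planted_gene_ids": list(self.planted_gene_ids),
            "gene_effect_used": self.gene_effect_used,
            "survival_betas_used": dict(self.survival_betas_used),
            "latent_pc_scores": np.asarray(self.latent_pc_scores).tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _ellipsoid(shape, semiaxes_frac):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    centers = [(s - 1) / 2.0 for s in shape]
    semi = [f * s / 2.0 for f, s in zip(semiaxes_frac, shape)]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centers, semi))
    return d2 <= 1.0


def gen_dce_study(
    config: SyntheticConfig,
    target_cpe: float,
    subject_seed: int,
) -> tuple[DceStudy, TissueMasks]:
    """Synthesize one registered DCE study whose CPE recovers ``target_cpe``.

    Fibroglandular voxels follow ``S(t) = S0 * (1 + A_v * f(t))`` with a
    monotone uptake curve f anchored at ``f(early) = 0.45``,
    ``f(late) = 1.0``; the per-voxel amplitudes ``A_v`` are inverted from
    delayed-enhancement ratios drawn uniform on (0, target/0.95), so the
    expected top-decile mean equals the target.  Non-fibroglandular breast
    tissue enhances negligibly and background not at all.
    """
    if target_cpe <= -1.0:
        raise ValueError("target_cpe must exceed -1 (enhancement ratio undefined)")
    shape = tuple(int(s) for s in config.volume_shape)
    breast = _ellipsoid(shape, (0.9, 0.9, 0.9))
    fgt = _ellipsoid(shape, (0.55, 0.55, 0.55))
    if fgt.sum() == 0:
        raise ValueError(f"volume {shape} too small to contain a fibroglandular mask")
    masks = TissueMasks(breast_mask=breast, fibroglandular_mask=fgt)

    rng = np.random.default_rng(subject_seed)
    times = tuple(config.timepoint_spacing * i for i in range(config.n_timepoints))
    t_early, t_late = times[1], times[-1]
    f_vals = np.interp(times, [0.0, t_early, t_late], [0.0, _F_EARLY, _F_LATE])
    delta_f = _F_LATE - _F_EARLY

    n_fgt = int(fgt.sum())
    if target_cpe == 0:
        ratios = np.zeros(n_fgt)
    elif target_cpe > 0:
        # uniform(0, c): the expected mean of the top decile is 0.95 c
        ratios = rng.uniform(0.0, target_cpe / 0.95, size=n_fgt)
    else:
        ratios = rng.uniform(target_cpe / 0.05, 0.0, size=n_fgt)
    denom = delta_f - ratios * _F_EARLY
    if np.any(denom <= 0):
        raise ValueError("target_cpe too large for the configured uptake curve")
    amps = ratios / denom
    if np.any(1.0 + amps * _F_EARLY <= 0):
        raise ValueError("target_cpe yields non-positive early-phase intensities")

    s0 = np.full(shape, 20.0)                       # background
    s0[breast] = 400.0 + rng.normal(0, 10.0, size=int(breast.sum()))  # fat
    s0[fgt] = 200.0 + rng.normal(0, 10.0, size=n_fgt)
    s0 = np.clip(s0, 1.0, None)
    amp_vol = np.zeros(shape)
    amp_vol[breast] = rng.uniform(0.0, 0.01, size=int(breast.sum()))
    amp_vol[fgt] = amps

    volumes = tuple(s0 * (1.0 + amp_vol * fv) for fv in f_vals)
    study = DceStudy(volumes=volumes, acquisition_times=times)
    return study, masks


def gen_expression_matrix(
    config: SyntheticConfig,
    cpe_z: np.ndarray,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Negative-binomial counts with a planted CPE-responsive gene set.

    Planted genes have natural-log mean ``baseline + gene_effect * cpe_z``;
    background genes are independent of CPE.  Library sizes vary
    log-normally; gene-wise dispersions are log-normal around
    ``config.dispersion``.
    """
    cpe_z = np.asarray(cpe_z, dtype=float)
    if not np.all(np.isfinite(cpe_z)):
        raise ValueError("cpe_z contains non-finite values")
    n = cpe_z.size
    if n != config.n_subjects:
        raise ValueError(f"cpe_z length {n} != n_subjects {config.n_subjects}")
    if n < 2:
        raise ValueError("need >= 2 subjects (no variance definable for 1)")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    g = config.n_genes
    gene_ids = tuple(f"G{i:05d}" for i in range(g))
    sample_ids = tuple(f"S{j:04d}" for j in range(n))
    if config.planted_seed is not None:
        planted_rng = np.random.default_rng(config.planted_seed)
        planted_idx = planted_rng.choice(g, size=config.planted_set_size, replace=False)
    else:
        planted_idx = rng.choice(g, size=config.planted_set_size, replace=False)
    planted_mask = np.zeros(g, dtype=bool)
    planted_mask[planted_idx] = True

    base_log = rng.normal(np.log(50.0), 1.0, size=g)           # per-gene baseline
    log_mu = np.tile(base_log[:, None], (1, n))
    log_mu[planted_mask] += config.gene_effect * cpe_z[None, :]
    lib_factor = np.exp(rng.normal(0.0, 0.3, size=n))          # library-size offsets
    mu = np.exp(log_mu) * lib_factor[None, :]

    phi = np.exp(rng.normal(np.log(config.dispersion), 0.5, size=g))
    size = 1.0 / phi
    p = size[:, None] / (size[:, None] + mu)
    counts = rng.negative_binomial(size[:, None], p).astype(float)

    expr = ExpressionMatrix(gene_ids, sample_ids, counts, kind="counts")
    truth = SyntheticTruth(
        true_cpe_per_subject=cpe_z.copy(),
        planted_gene_ids=tuple(gene_ids[i] for i in sorted(planted_idx)),
        gene_effect_used=config.gene_effect,
        survival_betas_used={},
        latent_pc_scores=config.gene_effect * cpe_z,
    )
    return expr, truth


def gen_survival_data(
    covariates: pd.DataFrame,
    betas: dict,
    baseline: tuple = (1.2, 250.0),
    censoring_rate: float = 0.85,
    seed: int = 0,
) -> pd.DataFrame:
    """Weibull proportional-hazards event times with exponential censoring.

    ``T = scale * (E / exp(x'beta))^(1/shape)`` with ``E ~ Exp(1)``; the
    censoring rate lambda is solved numerically so the expected realized
    censoring fraction ``E[1 - exp(-lambda T)]`` matches the target.
    Returns a DataFrame with columns time (> 0) and event (0/1).
    """
    shape, scale = float(baseline[0]), float(baseline[1])
    if shape <= 0 or scale <= 0:
        raise ValueError("Weibull shape and scale must be positive")
    if not (0.0 <= censoring_rate < 1.0):
        raise ValueError("censoring_rate must be in [0, 1)")
    missing = [c for c in betas if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate columns named in betas are absent: {missing}")
    rng = np.random.default_rng(seed)
    n = len(covariates)
    lp = np.zeros(n)
    for name, b in betas.items():
        lp += float(b) * covariates[name].to_numpy(dtype=float)
    e = rng.exponential(size=n)
    t_event = scale * (e / np.exp(lp)) ** (1.0 / shape)

    if censoring_rate == 0.0:
        return pd.DataFrame({"time": t_event, "event": np.ones(n, dtype=int)})

    def realized(lam):
        return float(np.mean(1.0 - np.exp(-lam * t_event))) - censoring_rate

    lo, hi = 1e-12, 1.0 / max(t_event.min(), 1e-12)
    while realized(hi) < 0:
        hi *= 10.0
        if hi > 1e12:
            raise ValueError("cannot calibrate censoring to the requested rate")
    lam = brentq(realized, lo, hi)
    c = rng.exponential(1.0 / lam, size=n)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    return pd.DataFrame({"time": np.maximum(time, 1e-9), "event": event})


@dataclass(frozen=True)
class CohortBundle:
    """Everything one synthetic cohort contains, plus its ground truth."""

    cpe: np.ndarray                 # raw CPE per subject
    cpe_z: np.ndarray               # standardized CPE
    expression: ExpressionMatrix    # counts
    clinical: pd.DataFrame          # sample_id, covariates, time, event, cpe
    collection: GeneSetCollection
    planted_set_name: str
    truth: SyntheticTruth

    def write(self, out_dir) -> dict:
        """Write the interchange files; returns {name: path}."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": out / "expression.tsv",
            "clinical": out / "clinical.csv",
            "gene_sets": out / "gene_sets.gmt",
            "truth": out / "truth.json",
        }
        _io.write_expression_tsv(self.expression, paths["expression"])
        _io.write_clinical_csv(self.clinical, paths["clinical"])
        self.collection.write_gmt(paths["gene_sets"])
        self.truth.to_json(paths["truth"])
        return paths


def _draw_cpe_fast(rng, n):
    """Beta-shaped CPE values spanning roughly 0.1-1.0 (median near 0.44)."""
    return 0.1 + 0.9 * rng.beta(2.0, 3.0, size=n)


def _draw_clinical(rng, n):
    age = np.clip(rng.normal(59.0, 9.0, size=n), 30.0, 90.0)
    size_mm = np.clip(rng.lognormal(np.log(19.0), 0.35, size=n), 4.0, 90.0)
    grade = rng.choice([1, 2, 3], size=n, p=[0.36, 0.50, 0.14])
    load = rng.choice(["0", "1-3", "4+"], size=n, p=[0.63, 0.29, 0.08])
    node_pos = load != "0"
    p_ast = np.where(node_pos, 0.80, 0.25)
    ast = np.where(rng.uniform(size=n) < p_ast, "yes", "no")
    return pd.DataFrame({
        "age": age, "size_mm": size_mm, "grade": grade,
        "axillary_load": load, "ast": ast,
    })


def gen_cohort(
    config: SyntheticConfig,
    mode: str = "fast",
    out_dir=None,
) -> CohortBundle:
    """Generate a full cohort: CPE, expression, clinical covariates, survival.

    ``mode="imaging"`` synthesizes DCE volumes per subject and computes each
    CPE through the imaging module; ``mode="fast"`` draws CPE values
    directly from the same target distribution (identical downstream
    structure, no volumes).  Survival is driven by the latent pathway
    activity (which the planted genes express) and by CPE itself, through
    ``config.survival_betas``.
    """
    if mode not in ("fast", "imaging"):
        raise ValueError(f"mode must be 'fast' or 'imaging', got {mode!r}")
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    targets = _draw_cpe_fast(rng, n)
    if mode == "imaging":
        cpe = np.empty(n)
        for i in range(n):
            study, masks = gen_dce_study(config, targets[i],
                                         subject_seed=config.seed * 100003 + i)
            ratio = enhancement_ratio_map(
                study, study.acquisition_times[1], study.acquisition_times[-1])
            cpe[i] = compute_cpe(ratio, masks).value
    else:
        cpe = targets
    cpe_z, _ = standardize(cpe)

    # latent pathway activity: correlated with CPE at sign(gene_effect),
    # with independent noise so CPE and pathway are not collinear
    r = config.latent_correlation
    sign = np.sign(config.gene_effect) if config.gene_effect != 0 else 0.0
    noise = rng.normal(size=n)
    latent = sign * r * cpe_z + np.sqrt(max(0.0, 1.0 - r**2)) * noise
    if config.gene_effect == 0:
        latent = noise

    # planted genes respond to the latent activity at |gene_effect|, so the
    # induced expression-on-CPE slope is gene_effect * latent_correlation
    expr_cfg_seed = rng.integers(2**31)
    expr, expr_truth = gen_expression_matrix(
        _replace_effect(config, abs(config.gene_effect)), latent,
        seed=int(expr_cfg_seed))

    clinical = _draw_clinical(rng, n)
    covs = clinical.copy()
    covs["cpe"] = cpe_z
    covs["pathway"] = latent
    surv = gen_survival_data(
        covs, config.survival_betas,
        baseline=(config.weibull_shape, config.weibull_scale),
        censoring_rate=config.censoring_rate,
        seed=int(rng.integers(2**31)))
    clinical.insert(0, "sample_id", list(expr.sample_ids))
    clinical["time"] = surv["time"].to_numpy()
    clinical["event"] = surv["event"].to_numpy()
    clinical["cpe"] = cpe

    planted = expr_truth.planted_gene_ids
    sets = {"PLANTED_PATHWAY": list(planted)}
    background_pool = [g for g in expr.gene_ids if g not in set(planted)]
    for s in range(config.n_gene_sets - 1):
        members = rng.choice(len(background_pool),
                             size=min(config.background_set_size, len(background_pool)),
                             replace=False)
        sets[f"BACKGROUND_{s:03d}"] = [background_pool[i] for i in sorted(members)]
    collection = GeneSetCollection(sets)

    truth = SyntheticTruth(
        true_cpe_per_subject=targets,
        planted_gene_ids=planted,
        gene_effect_used=config.gene_effect,
        survival_betas_used=dict(config.survival_betas),
        latent_pc_scores=latent,
    )
    bundle = CohortBundle(
        cpe=cpe, cpe_z=cpe_z, expression=expr, clinical=clinical,
        collection=collection, planted_set_name="PLANTED_PATHWAY", truth=truth)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _replace_effect(config: SyntheticConfig, effect: float) -> SyntheticConfig:
    from dataclasses import replace
    return replace(config, gene_effect=effect)
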