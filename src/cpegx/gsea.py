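"""Gene set enrichment analysis against a CPE-ranked gene list.

Implements the classic weighted Kolmogorov–Smirnov-style running sum: walking
down the ranked list, members of a set increment the sum by their weight
``|t|^p / sum_members |t|^p`` and non-members decrement it by ``1/(N-k)``.
The enrichment score (ES) is the walk value of maximal absolute excursion;
its position ("Max ES at", 1-based from the top) and the leading-edge
fraction (the share of members lying on the extremum side of the walk)
describe where in the ranking and how coherently the set responds.

Significance comes from a permutation null — either re-ranking the genes
under permuted CPE (response scheme, the default, matching the
regression-based ranking) or permuting gene labels on the fixed ranking
(gene scheme, fast) — from which NES, permutation p-values, and
sign-stratified GSEA-convention FDR q-values are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cpegx.association import ExpressionMatrix, RankedGeneList, _ols_against

__all__ = [
    "GeneSetCollection", "EnrichmentResult", "EsResult",
    "enrichment_score", "leading_edge_fraction",
    "permutation_null", "normalize_and_fdr", "gsea",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT-file semantics)."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for name, members in self.sets.items():
            members = [str(m) for m in members]
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")
            clean[str(name)] = tuple(members)
        object.__setattr__(self, "sets", clean)

    def __len__(self):
        return len(self.sets)

    def __getitem__(self, name):
        return self.sets[name]

    def filtered(self, universe, min_size: int = 5, max_size: int = 500):
        """Restrict each set to the universe and drop sets outside size bounds."""
        uni = set(universe)
        kept, desc = {}, {}
        for name, members in self.sets.items():
            inter = [m for m in members if m in uni]
            if min_size <= len(inter) <= max_size:
                kept[name] = inter
                desc[name] = self.descriptions.get(name, "")
        return GeneSetCollection(kept, desc)

    @classmethod
    def read_gmt(cls, path) -> "GeneSetCollection":
        sets, desc = {}, {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need name, description, >=1 member): {line!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            desc[name] = fields[1]
            sets[name] = [m for m in fields[2:] if m]
        return cls(sets, desc)

    def write_gmt(self, path) -> None:
        lines = [
            "\t".join([name, self.descriptions.get(name, "")] + list(members))
            for name, members in self.sets.items()
        ]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class EsResult:
    """Enrichment walk summary for one set against one ranking."""

    es: float
    max_es_at: int          # 1-based rank position of the walk extremum
    walk: np.ndarray        # full running sum, walk[i] = value after rank i+1
    member_positions: np.ndarray  # sorted 1-based ranks of the members
    n_members: int


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    size: int
    es: float
    nes: float
    max_es_at: int
    leading_edge: float
    p_perm: float
    fdr_q: float
    nes_defined: bool = True


def _member_walk_extremum(positions: np.ndarray, weights: np.ndarray, n_genes: int):
    """ES and extremum position from member positions alone.

    The walk rises only at member positions and falls linearly between them,
    so its global extrema lie at a member position (just after the increment)
    or one position earlier (just before it).  O(k) instead of O(N).
    """
    k = positions.size
    if k == n_genes:
        raise ValueError("gene set equals the whole universe")
    total = weights.sum()
    if total <= 0:
        raise ValueError("all member weights are zero; cannot normalize increments")
    w = weights / total
    miss = 1.0 / (n_genes - k)
    deficit = (positions - np.arange(1, k + 1)) * miss
    peaks = np.cumsum(w) - deficit          # value at position r_i
    valleys = peaks - w                     # value at position r_i - 1
    cand_vals = np.concatenate([peaks, valleys])
    cand_pos = np.concatenate([positions, positions - 1])
    ok = cand_pos >= 1                      # drop the walk origin
    cand_vals, cand_pos = cand_vals[ok], cand_pos[ok]
    order = np.lexsort((cand_pos, -np.abs(cand_vals)))
    best = order[0]
    return float(cand_vals[best]), int(cand_pos[best])


def _set_weights(abs_stats_sorted: np.ndarray, positions: np.ndarray, p: float):
    if p == 0:
        return np.ones(positions.size)
    return np.abs(abs_stats_sorted[positions - 1]) ** p


def enrichment_score(
    ranked: RankedGeneList,
    gene_set,
    weight_exponent: float = 1.0,
    min_size: int = 5,
) -> EsResult:
    """Running-sum enrichment of a gene set along the ranked list.

    Returns the full walk together with ES and its 1-based position.
    ``min_size`` guards against uninterpretably small intersections and can
    be lowered explicitly for toy cases.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    genes = ranked.gene_ids
    n = len(genes)
    members = set(str(g) for g in gene_set)
    member_mask = np.fromiter((g in members for g in genes), dtype=bool, count=n)
    k = int(member_mask.sum())
    if k == 0:
        raise ValueError("gene set has no members in the ranked universe")
    if k < min_size:
        raise ValueError(f"gene set intersection size {k} < min_size {min_size}")
    if k == n:
        raise ValueError("gene set equals the whole universe")

    stats = ranked.statistics
    weights = np.zeros(n)
    if weight_exponent == 0:
        weights[member_mask] = 1.0
    else:
        weights[member_mask] = np.abs(stats[member_mask]) ** weight_exponent
    total = weights.sum()
    if total <= 0:
        raise ValueError("all member weights are zero; cannot normalize increments")

    steps = np.where(member_mask, weights / total, -1.0 / (n - k))
    walk = np.cumsum(steps)
    pos0 = int(np.argmax(np.abs(walk)))
    es = float(walk[pos0])
    positions = np.flatnonzero(member_mask) + 1
    return EsResult(es=es, max_es_at=pos0 + 1, walk=walk,
                    member_positions=positions, n_members=k)


def leading_edge_fraction(es_result: EsResult) -> float:
    """Fraction of members on the extremum side of the walk.

    Positive ES: members ranked at or above the extremum; negative ES:
    members at or below it.  These are the genes that drive the score.
    """
    pos = es_result.member_positions
    if es_result.es >= 0:
        contributing = int((pos <= es_result.max_es_at).sum())
    else:
        contributing = int((pos >= es_result.max_es_at).sum())
    return contributing / es_result.n_members


def _es_batch(order_stats: np.ndarray, position_lists, weight_exponent: float):
    """ES for every set (given member positions in a ranking) via the fast path."""
    out = np.empty(len(position_lists))
    for i, positions in enumerate(position_lists):
        w = _set_weights(order_stats, positions, weight_exponent)
        out[i], _ = _member_walk_extremum(positions, w, order_stats.size)
    return out


def _positions_in_ranking(gene_order, member_sets):
    index = {g: i + 1 for i, g in enumerate(gene_order)}
    return [
        np.sort(np.fromiter((index[m] for m in members if m in index), dtype=np.int64))
        for members in member_sets
    ]


def permutation_null(
    expr: ExpressionMatrix,
    cpe: np.ndarray,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    scheme: str = "response",
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> np.ndarray:
    """Null ES matrix (n_sets x n_perm), rows in ``collection.sets`` order.

    response scheme: the CPE vector is permuted and the full per-gene ranking
    recomputed for every permutation.  gene scheme: member labels are
    permuted on the fixed observed ranking (fast, ignores inter-gene
    correlation).
    """
    if scheme not in ("response", "gene"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if n_perm < 50:
        import warnings
        warnings.warn(f"n_perm={n_perm} gives coarse p/FDR resolution", stacklevel=2)
    rng = np.random.default_rng(seed)
    cpe = np.asarray(cpe, dtype=float)
    names = list(collection.sets)
    member_sets = [collection.sets[n] for n in names]
    null = np.empty((len(names), n_perm))

    if scheme == "response":
        for j in range(n_perm):
            perm = rng.permutation(cpe)
            t = _rank_statistics(expr.values, perm)
            order = np.argsort(-t, kind="stable")
            order_stats = np.abs(t[order])
            gene_order = [expr.gene_ids[i] for i in order]
            pos = _positions_in_ranking(gene_order, member_sets)
            null[:, j] = _es_batch(order_stats, pos, weight_exponent)
    else:
        t = _rank_statistics(expr.values, cpe)
        order = np.argsort(-t, kind="stable")
        order_stats = np.abs(t[order])
        n = order_stats.size
        gene_order = [expr.gene_ids[i] for i in order]
        pos0 = [p - 1 for p in _positions_in_ranking(gene_order, member_sets)]
        for j in range(n_perm):
            # one label permutation shared by all sets, as in standard
            # gene-permutation GSEA; a set's members land on a uniformly
            # random k-subset of ranking positions
            perm = rng.permutation(n)
            for i in range(len(member_sets)):
                positions = np.sort(perm[pos0[i]]) + 1
                w = _set_weights(order_stats, positions, weight_exponent)
                null[i, j], _ = _member_walk_extremum(positions, w, n)
    return null


def _rank_statistics(expr_values: np.ndarray, x: np.ndarray) -> np.ndarray:
    slope, resvar, sxx, syy, df = _ols_against(expr_values, x)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(resvar / sxx)
    cap = np.finfo(float).max
    return np.clip(np.nan_to_num(t, nan=0.0, posinf=cap, neginf=-cap), -cap, cap)


def normalize_and_fdr(observed, null: np.ndarray, n_perm: int | None = None):
    """NES, permutation p, and sign-stratified FDR q for each set.

    ``observed`` is a list of dicts with keys set_name, size, es, max_es_at,
    leading_edge (one per row of ``null``).  NES divides each ES by the mean
    same-sign null ES of its own set; null ES values are normalized the same
    way, pooled, and the GSEA-convention q-value is the ratio of null to
    observed tail fractions on the matching sign, clipped to [0, 1].
    """
    null = np.asarray(null, dtype=float)
    if null.ndim != 2 or null.shape[0] != len(observed):
        raise ValueError("null matrix must be (n_sets, n_perm)")
    n_sets = len(observed)

    nes = np.full(n_sets, np.nan)
    p_perm = np.full(n_sets, np.nan)
    defined = np.ones(n_sets, dtype=bool)
    null_nes_pool = []
    for i, rec in enumerate(observed):
        es = rec["es"]
        row = null[i]
        pos_null, neg_null = row[row > 0], row[row < 0]
        pos_mean = pos_null.mean() if pos_null.size else np.nan
        neg_mean = np.abs(neg_null).mean() if neg_null.size else np.nan
        if np.isfinite(pos_mean):
            null_nes_pool.append(pos_null / pos_mean)
        if np.isfinite(neg_mean):
            null_nes_pool.append(neg_null / neg_mean)
        if es >= 0:
            if pos_null.size == 0:
                defined[i] = False
                continue
            nes[i] = es / pos_mean
            p_perm[i] = float((pos_null >= es).sum()) / pos_null.size
        else:
            if neg_null.size == 0:
                defined[i] = False
                continue
            nes[i] = es / neg_mean
            p_perm[i] = float((neg_null <= es).sum()) / neg_null.size
    null_nes = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])

    obs_nes = nes[defined & np.isfinite(nes)]
    results = []
    for i, rec in enumerate(observed):
        if not defined[i]:
            results.append(EnrichmentResult(
                set_name=rec["set_name"], size=rec["size"], es=rec["es"],
                nes=np.nan, max_es_at=rec["max_es_at"],
                leading_edge=rec["leading_edge"], p_perm=np.nan,
                fdr_q=np.nan, nes_defined=False))
            continue
        v = nes[i]
        if v >= 0:
            null_side = null_nes[null_nes >= 0]
            num = (null_side >= v).mean() if null_side.size else 0.0
            obs_side = obs_nes[obs_nes >= 0]
            den = (obs_side >= v).mean() if obs_side.size else 1.0
        else:
            null_side = null_nes[null_nes < 0]
            num = (null_side <= v).mean() if null_side.size else 0.0
            obs_side = obs_nes[obs_nes < 0]
            den = (obs_side <= v).mean() if obs_side.size else 1.0
        q = float(np.clip(num / den, 0.0, 1.0)) if den > 0 else 0.0
        results.append(EnrichmentResult(
            set_name=rec["set_name"], size=rec["size"], es=rec["es"],
            nes=float(v), max_es_at=rec["max_es_at"],
            leading_edge=rec["leading_edge"], p_perm=float(p_perm[i]),
            fdr_q=q))
    return results


def gsea(
    expr: ExpressionMatrix,
    cpe: np.ndarray,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    scheme: str = "response",
    weight_exponent: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
    moderation: str = "none",
) -> pd.DataFrame:
    """End-to-end screen: rank genes on CPE, score every set, permute, FDR.

    Returns a DataFrame (one row per retained set) sorted by NES descending
    with columns set_name, size, es, nes, max_es_at, leading_edge, p_perm,
    fdr_q.
    """
    from cpegx.association import gene_cpe_ranking

    filtered = collection.filtered(expr.gene_ids, min_size=min_size, max_size=max_size)
    if len(filtered) == 0:
        raise ValueError("no gene set survives the universe/size filters")
    ranked = gene_cpe_ranking(expr, cpe, moderation=moderation)
    observed = []
    for name, members in filtered.sets.items():
        res = enrichment_score(ranked, members, weight_exponent=weight_exponent,
                               min_size=min(min_size, len(members)))
        observed.append({
            "set_name": name, "size": len(members), "es": res.es,
            "max_es_at": res.max_es_at,
            "leading_edge": leading_edge_fraction(res),
        })
    null = permutation_null(expr, cpe, filtered, n_perm=n_perm, scheme=scheme,
                            seed=seed, weight_exponent=weight_exponent)
    results = normalize_and_fdr(observed, null)
    df = pd.DataFrame([r.__dict__ for r in results])
    return df.sort_values("nes", ascending=False, kind="stable").reset_index(drop=True)
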