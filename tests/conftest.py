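"""Shared fixtures and independent test oracles.

The oracle functions here are deliberately naive (explicit loops,
sort-everything) so they stay independent of the library's vectorized
implementations they are used to check.
"""

import math
import warnings

import numpy as np
import pytest

from cpegx.synthetic import SyntheticConfig, gen_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small fast-mode cohort reused by read-only tests."""
    cfg = SyntheticConfig(n_subjects=120, n_genes=500, planted_set_size=25,
                          n_gene_sets=12, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return gen_cohort(cfg, mode="fast")


def walk_oracle(stats_in_rank_order, member_mask, p):
    """Explicit step-by-step enrichment walk.

    Returns (walk list, es, max_es_at 1-based, leading_edge fraction).
    """
    n = len(stats_in_rank_order)
    k = int(np.sum(member_mask))
    total = sum(abs(stats_in_rank_order[i]) ** p for i in range(n) if member_mask[i]) \
        if p > 0 else float(k)
    walk = []
    cur = 0.0
    for i in range(n):
        if member_mask[i]:
            inc = (abs(stats_in_rank_order[i]) ** p / total) if p > 0 else 1.0 / k
            cur += inc
        else:
            cur -= 1.0 / (n - k)
        walk.append(cur)
    best = 0
    for i in range(1, n):
        if abs(walk[i]) > abs(walk[best]):
            best = i
    es = walk[best]
    pos = best + 1
    if es >= 0:
        contributing = sum(1 for i in range(n) if member_mask[i] and i + 1 <= pos)
    else:
        contributing = sum(1 for i in range(n) if member_mask[i] and i + 1 >= pos)
    return walk, es, pos, contributing / k


def cpe_oracle(ratio_map, fgt_mask, top_fraction=0.10):
    """Sort-everything CPE oracle: collect valid in-mask ratios, sort
    descending, average the top ceil(fraction * m)."""
    vals = []
    it = np.nditer(ratio_map, flags=["multi_index"])
    for v in it:
        if fgt_mask[it.multi_index] and np.isfinite(v):
            vals.append(float(v))
    vals.sort(reverse=True)
    n_used = max(1, math.ceil(top_fraction * len(vals)))
    return float(np.mean(vals[:n_used]))


def breslow_loglik_oracle(X, time, event, beta):
    """Loop-based Breslow log partial likelihood for the brute-force
    maximizer oracle."""
    n = len(time)
    ll = 0.0
    eta = X @ beta
    for t in sorted(set(time[event == 1])):
        at_t = (time == t) & (event == 1)
        risk = time >= t
        d = int(at_t.sum())
        ll += eta[at_t].sum() - d * np.log(np.exp(eta[risk]).sum())
    return ll
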