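"""Shared fixtures: tiny hand-checkable matrices plus one full synthetic
panel (and its pipeline run) reused across the evaluation, synthetic and
acceptance tests so the expensive generation happens once per session."""

import numpy as np
import pandas as pd
import pytest

from slcscout import OmicsMatrix, SynthConfig, mrn_normalize, run_scoring_pipeline
from slcscout.synthetic import synth_drug_panel, synth_panel


@pytest.fixture
def tiny_counts():
    return OmicsMatrix(
        pd.DataFrame(
            {"s1": [2.0, 2.0], "s2": [8.0, 8.0]}, index=["g1", "g2"]
        ),
        "counts",
    )


@pytest.fixture
def tiny_metab():
    return OmicsMatrix(
        pd.DataFrame(
            {"s1": [1.0], "s2": [2.0], "s3": [3.0]}, index=["m1"]
        ),
        "metabolite_level",
        {"s1": "lung", "s2": "lung", "s3": "lung"},
    )


@pytest.fixture(scope="session")
def default_panel():
    return synth_panel(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(default_panel):
    return run_scoring_pipeline(default_panel)


@pytest.fixture(scope="session")
def drug_setup():
    cfg = SynthConfig(seed=2)
    panel = synth_panel(cfg)
    pseudo, _ = mrn_normalize(panel.counts)
    drug_panel, truth = synth_drug_panel(cfg, pseudo)
    return cfg, pseudo, drug_panel, truth


def spearman_oracle(x, y):
    """Brute-force Spearman rho: average ranks + Pearson on ranks."""
    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def bh_oracle(pvals):
    """Step-up BH adjustment, straight from the definition."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adj[idx] = running_min
    return adj


def wilcoxon_exact_oracle(a, b):
    """Two-sided rank-sum p by enumerating every group assignment."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    n = len(pooled)
    ranks = np.argsort(np.argsort(pooled, kind="mergesort")) + 1.0
    # assumes no ties (oracle restricted to tie-free inputs)
    obs = ranks[: len(a)].sum()
    sums = [sum(ranks[list(c)]) for c in combinations(range(n), len(a))]
    sums = np.array(sums)
    mean = sums.mean()
    extreme = np.sum(np.abs(sums - mean) >= abs(obs - mean) - 1e-12)
    return extreme / len(sums)


def bfs_oracle(adjacency_lists, source):
    """Hand breadth-first search distance map."""
    from collections import deque

    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adjacency_lists.get(u, ()):  # noqa: B909
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def mann_whitney_auc_oracle(pos, neg):
    """ROC AUC as the normalized count of winning (pos, neg) comparisons."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def hypergeom_oracle(k, N, K, n):
    """P(X >= k) for a hypergeometric draw, by direct enumeration."""
    from math import comb

    total = comb(N, n)
    return sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    ) / total
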