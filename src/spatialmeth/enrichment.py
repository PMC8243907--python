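"""Preranked gene-set enrichment over methylation-derived gene rankings.

Genes are ranked by signed mean delta beta for one cluster comparison
(most hypermethylated at the top, most hypomethylated — putatively
activated — at the bottom).  The enrichment score is the classic
weighted Kolmogorov-Smirnov running-sum statistic: set members push the
sum up in proportion to |score|^p, non-members pull it down uniformly,
and the ES is the signed maximum deviation.  Significance comes from a
gene-label permutation null: with only a handful of samples per
cluster, sample permutation is degenerate, so labels are shuffled over
the fixed score vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def rank_genes(gene_scores: pd.DataFrame) -> pd.DataFrame:
    """Order genes by signed score, descending; ties broken by symbol.

    Expects columns ``gene`` and ``score`` (signed mean delta beta).
    The most hypermethylated genes rank first; hypomethylated genes
    land at the bottom of the list.
    """
    if gene_scores.empty:
        raise ValueError("gene score table is empty")
    out = gene_scores[["gene", "score"]].copy()
    if out["gene"].duplicated().any():
        raise ValueError("duplicate gene symbols in ranking input")
    out = out.sort_values("gene", kind="mergesort").sort_values(
        "score", ascending=False, kind="mergesort"
    )
    return out.reset_index(drop=True)


def enrichment_score(
    ranked: pd.DataFrame, gene_set: set[str], weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS running sum for one gene set on a ranked list.

    Hits increment the running sum by ``|score|^weight`` normalized over
    hits; misses decrement by ``1 / (N - Nh)``.  Returns the signed
    maximum deviation (the ES), the full running sum, and the leading
    edge: for positive ES the set members at or before the maximum, for
    negative ES the members at or after the minimum.  A set covering the
    whole list has no misses; its ES is defined as 0.
    """
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    hit = np.isin(genes, list(gene_set))
    n, nh = len(genes), int(hit.sum())
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if nh == n:
        return 0.0, np.zeros(n), list(genes)
    running = _running_sum(scores, hit, weight)
    extremum = int(np.argmax(np.abs(running)))
    es = float(running[extremum])
    if es >= 0:
        leading = genes[: extremum + 1][hit[: extremum + 1]]
    else:
        leading = genes[extremum:][hit[extremum:]]
    return es, running, list(leading)


def _running_sum(scores: np.ndarray, hit: np.ndarray, weight: float) -> np.ndarray:
    n = len(scores)
    nh = int(hit.sum())
    w = np.abs(scores[hit]) ** weight
    denom = w.sum()
    steps = np.full(n, -1.0 / (n - nh))
    steps[hit] = w / denom if denom > 0 else 1.0 / nh
    return np.cumsum(steps)


def _es_only(scores: np.ndarray, hit: np.ndarray, weight: float) -> float:
    running = _running_sum(scores, hit, weight)
    return float(running[np.argmax(np.abs(running))])


@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p_value: float
    q_value: float
    leading_edge: list[str] = field(default_factory=list)


def permutation_significance(
    ranked: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 2,
) -> pd.DataFrame:
    """Gene-label permutation p-values for each gene set, BH-corrected.

    The null redraws the hit positions uniformly (equivalent to
    permuting gene labels over the fixed score vector).  ``p = (1 +
    #{|ES_null| >= |ES|}) / (n_perm + 1)``, so p is bounded below by
    ``1/(n_perm+1)``; NES is ES divided by the mean absolute null ES.
    Sets intersecting the list in fewer than ``min_size`` genes are
    dropped.  Seeded and reproducible.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    n = len(genes)
    rng = np.random.default_rng(seed)

    observed = {}
    for name in sorted(gene_sets):
        members = gene_sets[name]
        hit = np.isin(genes, list(members))
        nh = int(hit.sum())
        if nh < min_size or nh == n:
            continue
        es, _, leading = enrichment_score(ranked, members, weight)
        observed[name] = (nh, es, leading)

    # one permutation null per distinct intersection size
    null_by_size: dict[int, np.ndarray] = {}
    for nh in sorted({v[0] for v in observed.values()}):
        nulls = np.empty(n_perm)
        for i in range(n_perm):
            hit = np.zeros(n, dtype=bool)
            hit[rng.choice(n, size=nh, replace=False)] = True
            nulls[i] = _es_only(scores, hit, weight)
        null_by_size[nh] = nulls

    rows = []
    for name, (nh, es, leading) in observed.items():
        nulls = null_by_size[nh]
        p = (1 + int(np.sum(np.abs(nulls) >= abs(es)))) / (n_perm + 1)
        mean_abs = float(np.mean(np.abs(nulls)))
        nes = es / mean_abs if mean_abs > 0 else 0.0
        rows.append(
            {
                "name": name,
                "size": nh,
                "es": es,
                "nes": nes,
                "p_value": p,
                "leading_edge": ",".join(leading),
            }
        )
    out = pd.DataFrame(rows, columns=["name", "size", "es", "nes", "p_value", "leading_edge"])
    if len(out):
        out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out
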