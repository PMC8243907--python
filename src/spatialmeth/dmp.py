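"""Pairwise differential methylation between clusters.

Per-probe tests run on M values (variance stabilization); effect sizes
(delta beta) are reported on the beta scale for interpretability.  When
both clusters have at least two samples the test is Welch's t; when one
cluster is a single sample — the primary-resection case — that sample
is scored as a z statistic against the other cluster's probe-wise mean
and standard deviation, with the SD floored to keep the statistic
bounded.  Significance is controlled by Benjamini-Hochberg FDR across
all tested probes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GENE_LINKED_CLASSES, ProbeAnnotation
from .cluster import ClusterAssignment
from .matrices import BetaMatrix, beta_to_m

DEFAULT_FDR_Q = 0.01
DEFAULT_SD_FLOOR = 0.1  # M units


def pairwise_dmp(
    beta: BetaMatrix,
    assignment: ClusterAssignment,
    pair: tuple[int, int],
    space: str = "m",
    fdr_q: float = DEFAULT_FDR_Q,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> pd.DataFrame:
    """Test every probe for differential methylation between two clusters.

    Returns one row per probe: ``probe_id``, ``comparison`` (e.g.
    ``C1_vs_C2``), ``delta_beta`` (mean beta of the first cluster minus
    the second), ``statistic`` (sign matches delta on the test scale),
    ``p_value``, ``q_value`` (BH across all probes), ``significant``
    (q < ``fdr_q``) and ``direction`` (``hyper`` when the first cluster
    is more methylated, else ``hypo``).
    """
    first, second = pair
    for label in pair:
        if label not in assignment.cluster_ids():
            raise ValueError(f"cluster {label} not in assignment (has {assignment.cluster_ids()})")
    sa = assignment.samples_in(first)
    sb = assignment.samples_in(second)
    if not sa or not sb:
        raise ValueError(f"empty cluster in pair {pair}")
    if len(sa) == 1 and len(sb) == 1:
        raise ValueError("cannot test two single-sample clusters against each other")

    test_values = beta_to_m(beta).values if space == "m" else beta.values
    A = test_values[sa].to_numpy()
    B = test_values[sb].to_numpy()
    delta_beta = beta.values[sa].mean(axis=1) - beta.values[sb].mean(axis=1)

    if len(sa) >= 2 and len(sb) >= 2:
        import warnings

        with warnings.catch_warnings():
            # constant probes (e.g. a shared epigenetic state) yield NaN
            # statistics that are mapped to p = 1 below
            warnings.filterwarnings("ignore", message="Precision loss occurred")
            stat, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
        method = "welch_t"
    else:
        # one singleton cluster: z of the lone sample against the other
        # cluster's probe-wise mean/SD (SD floored)
        if len(sa) == 1:
            lone, group, sign = A[:, 0], B, 1.0
        else:
            lone, group, sign = B[:, 0], A, -1.0
        mu = group.mean(axis=1)
        sd = np.maximum(group.std(axis=1, ddof=1), sd_floor)
        stat = sign * (lone - mu) / sd
        p = 2.0 * stats.norm.sf(np.abs(stat))
        method = "z_vs_cluster"

    p = np.where(np.isnan(p), 1.0, p)
    stat = np.where(np.isnan(stat), 0.0, stat)
    _, q, _, _ = multipletests(p, method="fdr_bh")

    return pd.DataFrame(
        {
            "probe_id": beta.probe_ids,
            "comparison": f"C{first}_vs_C{second}",
            "delta_beta": delta_beta.to_numpy(),
            "statistic": stat,
            "p_value": p,
            "q_value": q,
            "significant": q < fdr_q,
            "direction": np.where(delta_beta.to_numpy() > 0, "hyper", "hypo"),
            "method": method,
        }
    )


def gene_scores(
    records: pd.DataFrame,
    annotation: ProbeAnnotation,
    classes=GENE_LINKED_CLASSES,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Per-gene mean delta beta over gene-linked probes of one comparison.

    Only probes whose region class links them to a gene contribute (the
    class set is configurable; gene summaries use all four gene-linked
    classes, enrichment rankings restrict to gene body and promoter).
    With ``significant_only`` (default) genes with no significant probe
    are excluded rather than scored zero.
    """
    ann = annotation.table[annotation.table["region_class"].isin(classes)]
    ann = ann[ann["gene"] != ""][["probe_id", "gene"]]
    used = records[records["significant"]] if significant_only else records
    merged = used.merge(ann, on="probe_id", how="inner")
    comparison = records["comparison"].iloc[0] if len(records) else ""
    if merged.empty:
        return pd.DataFrame(columns=["gene", "comparison", "mean_delta_beta", "n_probes"])
    grouped = (
        merged.groupby("gene")
        .agg(mean_delta_beta=("delta_beta", "mean"), n_probes=("delta_beta", "size"))
        .reset_index()
    )
    grouped["comparison"] = comparison
    return grouped[["gene", "comparison", "mean_delta_beta", "n_probes"]]


def summarize_genes(
    records: pd.DataFrame,
    annotation: ProbeAnnotation,
    top_n: int = 50,
    classes=GENE_LINKED_CLASSES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-N hyper- and hypomethylated gene lists for one comparison.

    A gene's score is the mean delta beta over its significant
    gene-linked probes (see :func:`gene_scores`).  Genes are ranked by
    absolute score within each direction (hyper: score > 0; hypo:
    score < 0), ties broken by gene symbol, and truncated to
    ``min(top_n, available)``.
    """
    grouped = gene_scores(records, annotation, classes=classes, significant_only=True)
    if grouped.empty:
        empty = pd.DataFrame(columns=["gene", "comparison", "mean_delta_beta", "n_probes", "rank"])
        return empty.copy(), empty.copy()

    def top(direction_sign: int) -> pd.DataFrame:
        side = grouped[np.sign(grouped["mean_delta_beta"]) == direction_sign].copy()
        side["abs_score"] = side["mean_delta_beta"].abs()
        side = side.sort_values(["abs_score", "gene"], ascending=[False, True], kind="mergesort")
        side = side.head(min(top_n, len(side))).drop(columns="abs_score").reset_index(drop=True)
        side["rank"] = np.arange(1, len(side) + 1)
        return side[["gene", "comparison", "mean_delta_beta", "n_probes", "rank"]]

    return top(+1), top(-1)


def venn_overlap(gene_lists: dict[str, set[str]]) -> dict[str, int]:
    """Exact cardinalities of the membership regions of three gene lists.

    Keys name the exact combination a gene belongs to (e.g.
    ``C1_vs_C2&C1_vs_C3`` for genes in those two lists and no other);
    the seven counts sum to the size of the union.
    """
    if len(gene_lists) != 3:
        raise ValueError(f"expected exactly 3 gene lists, got {len(gene_lists)}")
    labels = list(gene_lists)
    sets = {k: set(v) for k, v in gene_lists.items()}
    union = set().union(*sets.values())
    counts: dict[str, int] = {}
    from itertools import combinations

    for r in (1, 2, 3):
        for combo in combinations(labels, r):
            inside = set(union)
            for label in combo:
                inside &= sets[label]
            for label in labels:
                if label not in combo:
                    inside -= sets[label]
            counts["&".join(combo)] = len(inside)
    return counts
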