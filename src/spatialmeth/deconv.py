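"""MGMT promoter calls and reference-based microenvironment deconvolution.

MGMT promoter methylation — the predictive biomarker for temozolomide
response — is called per sample by thresholding the mean beta over a
configurable promoter probe list.  Cell-type composition is estimated
from a reference signature matrix by constrained least squares
(non-negative fractions summing to one), a deterministic stand-in with
the same contract as support-vector-regression deconvolution tools.
Between-cluster differences per cell type use rank-based tests.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterAssignment
from .matrices import BetaMatrix

logger = logging.getLogger(__name__)

MGMT_THRESHOLD = 0.35
_SUM_WEIGHT = 1.0e3  # weight of the sum-to-one row in the augmented NNLS system


def call_mgmt(
    beta: BetaMatrix,
    mgmt_promoter_probe_ids,
    threshold: float = MGMT_THRESHOLD,
) -> pd.DataFrame:
    """Threshold the mean promoter beta per sample.

    A sample is ``methylated`` iff its mean beta over the listed probes
    is >= ``threshold``.  Listed probes absent from the matrix are
    logged and skipped; if none remain it is an error.
    """
    wanted = list(mgmt_promoter_probe_ids)
    present = [p for p in wanted if p in beta.values.index]
    absent = sorted(set(wanted) - set(present))
    if absent:
        logger.info("MGMT probes absent from matrix: %s", absent)
    if not present:
        raise ValueError("none of the listed MGMT promoter probes are present in the matrix")
    means = beta.values.loc[present].mean(axis=0)
    return pd.DataFrame(
        {
            "sample_id": means.index,
            "mean_promoter_beta": means.to_numpy(),
            "status": np.where(means.to_numpy() >= threshold, "methylated", "unmethylated"),
            "threshold": threshold,
            "n_probes": len(present),
        }
    ).reset_index(drop=True)


def estimate_fractions(beta: BetaMatrix, signature: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cell-type fractions by constrained least squares.

    For each sample solve ``min ||S f - b||^2`` subject to ``f >= 0``
    and ``sum(f) = 1`` over the signature probes (``S``: probes x cell
    types; ``b``: the sample's betas at those probes).  The sum
    constraint is imposed as a heavily weighted extra row of the NNLS
    system, then the solution is renormalized exactly.  Returns a
    samples x cell-types frame plus a ``residual`` column (Euclidean
    norm of ``S f - b``).
    """
    if signature.shape[1] < 2:
        raise ValueError("signature matrix must have >= 2 cell types")
    probes = [p for p in signature.index if p in beta.values.index]
    if not probes:
        raise ValueError("no signature probes present in the beta matrix")
    if len(probes) < len(signature.index):
        logger.info(
            "%d/%d signature probes absent from matrix", len(signature.index) - len(probes),
            len(signature.index),
        )
    S = signature.loc[probes].to_numpy(dtype=float)
    if np.linalg.matrix_rank(S) < signature.shape[1]:
        warnings.warn("signature matrix is rank-deficient; fractions may be non-unique", stacklevel=2)

    A = np.vstack([S, np.full((1, S.shape[1]), _SUM_WEIGHT)])
    rows = {}
    for sample in beta.sample_ids:
        b = beta.values.loc[probes, sample].to_numpy(dtype=float)
        y = np.concatenate([b, [_SUM_WEIGHT]])
        f, _ = nnls(A, y)
        total = f.sum()
        f = f / total if total > 0 else np.full_like(f, 1.0 / len(f))
        residual = float(np.linalg.norm(S @ f - b))
        rows[sample] = np.concatenate([f, [residual]])
    out = pd.DataFrame(rows, index=[*signature.columns, "residual"]).T
    out.index.name = "sample_id"
    return out


def compare_fractions(
    fractions: pd.DataFrame,
    assignment: ClusterAssignment,
    correct: bool = False,
) -> pd.DataFrame:
    """Rank-based between-cluster test per cell type.

    Two clusters: exact Mann-Whitney U (asymptotic when ties prevent the
    exact null); more: Kruskal-Wallis.  Constant columns get p = 1 by
    convention (no evidence of difference).  No multiplicity correction
    by default; ``correct=True`` adds BH q values.
    """
    cell_types = [c for c in fractions.columns if c != "residual"]
    groups_idx = {
        label: [s for s in assignment.samples_in(label) if s in fractions.index]
        for label in assignment.cluster_ids()
    }
    if any(len(v) == 0 for v in groups_idx.values()):
        raise ValueError("every cluster must contain at least one sample with fractions")
    if len(groups_idx) < 2:
        raise ValueError("need >= 2 clusters to compare")

    rows = []
    for ct in cell_types:
        samples = [fractions.loc[idx, ct].to_numpy(dtype=float) for idx in groups_idx.values()]
        flat = np.concatenate(samples)
        if np.allclose(flat, flat[0]):
            stat_name, statistic, p = "constant", np.nan, 1.0
        elif len(samples) == 2:
            x, y = samples
            ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic" if ties else "exact"
            )
            stat_name, statistic, p = "mannwhitney_u", float(res.statistic), float(res.pvalue)
        else:
            res = stats.kruskal(*samples)
            stat_name, statistic, p = "kruskal_h", float(res.statistic), float(res.pvalue)
        rows.append({"cell_type": ct, "test": stat_name, "statistic": statistic, "p_value": p})
    out = pd.DataFrame(rows)
    if correct:
        out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out
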