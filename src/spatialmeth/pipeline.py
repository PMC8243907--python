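"""End-to-end orchestration: simulate or load, then run every stage.

The run order mirrors the analysis workflow: probe selection ->
hierarchical clustering -> phylogeny -> spread path -> pairwise
differential methylation -> gene lists and Venn overlaps -> copy-number
profile -> MGMT calls -> deconvolution -> gene-set enrichment.  All
randomness is seeded through the config; the JSON run report echoes
every parameter (plus a config hash) so a run can be reproduced
exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import ProbeAnnotation, read_probe_annotation, write_probe_annotation
from .cluster import hierarchical_cluster, sample_distance_matrix, select_top_variable_probes
from .cnv import copy_number_profile
from .deconv import call_mgmt, compare_fractions, estimate_fractions
from .dmp import gene_scores, pairwise_dmp, summarize_genes, venn_overlap
from .enrichment import permutation_significance, rank_genes
from .io import read_gmt, write_seg
from .matrices import (
    BetaMatrix,
    IntensityLog2Matrix,
    SampleMeta,
    read_beta_matrix,
    read_log2_matrix,
    read_sample_meta,
    write_beta_matrix,
    write_log2_matrix,
    write_sample_meta,
)
from .phylo import build_phylogeny, infer_spread_path
from .simulate import default_cohort_config, simulate_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "select",
    "cluster",
    "phylogeny",
    "path",
    "dmp",
    "genes",
    "venn",
    "cnv",
    "mgmt",
    "deconv",
    "gsea",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Every stage parameter of one run.  Seeds are mandatory (default 0)."""

    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    # inputs: either simulate a cohort or point at files on disk
    simulate: bool = True
    n_probes: int = 50_000
    beta_path: str | None = None
    annotation_path: str | None = None
    meta_path: str | None = None
    log2_path: str | None = None
    signature_path: str | None = None
    gmt_path: str | None = None

    # probe selection / clustering
    top_k_probes: int = 10_000
    k_clusters: int | None = None  # None = automatic silhouette selection
    metric: str = "euclidean"
    linkage: str = "ward"
    space: str = "m"

    # differential methylation
    fdr_q: float = 0.01
    sd_floor: float = 0.1
    top_n_genes: int = 50

    # copy number
    bin_size_probes: int = 50
    seg_alpha: float = 0.01
    min_segment_bins: int = 3
    seg_n_perm: int = 1000
    amp_threshold: float = 0.3
    gain_threshold: float = 0.1
    loss_threshold: float = -0.1

    # markers / deconvolution
    mgmt_threshold: float = 0.35
    mgmt_probes: tuple[str, ...] | None = None

    # enrichment
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    n_random_gene_sets: int = 20
    random_gene_set_size: int = 25

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if kwargs.get("mgmt_probes") is not None:
            kwargs["mgmt_probes"] = tuple(kwargs["mgmt_probes"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    _atomic_write_text(path, df.to_csv(sep="\t", **kwargs))


def run_all(config: PipelineConfig) -> dict:
    """Run every enabled stage in order; return (and write) the run report.

    A stage failure raises :class:`PipelineError` naming the stage.
    Outputs are written atomically under ``config.outdir``; the report
    itself contains no timestamps, so identical config and seed give a
    byte-identical report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    beta: BetaMatrix | None = None
    log2: IntensityLog2Matrix | None = None
    annotation: ProbeAnnotation | None = None
    meta: SampleMeta | None = None
    signature: pd.DataFrame | None = None
    gene_sets: dict[str, set[str]] | None = None
    selected: list[str] | None = None
    assignment = None
    phylogeny = None
    dmp_records: dict[str, pd.DataFrame] = {}
    gene_lists: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}

    def stage(name):
        def decorator(fn):
            nonlocal report
            if name not in enabled:
                return
            try:
                detail = fn() or {}
                report["stages"][name] = {"status": "ok", **detail}
            except Exception as exc:  # halt with stage context
                report["stages"][name] = {"status": "failed", "error": str(exc)}
                _atomic_write_text(outdir / "run_report.json", json.dumps(report, indent=2, sort_keys=True))
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return decorator

    # ---- inputs ---------------------------------------------------------
    @stage("simulate")
    def _simulate():
        nonlocal beta, log2, annotation, meta, signature
        if not config.simulate:
            return {"note": "simulation disabled in config; inputs must come from files"}
        sim_config = default_cohort_config(seed=config.seed, n_probes=config.n_probes)
        b, l2, ann, sm, truth = simulate_cohort(sim_config)
        beta, log2, annotation, meta, signature = b, l2, ann, sm, truth.signature
        write_beta_matrix(b, outdir / "beta.tsv")
        write_log2_matrix(l2, outdir / "log2.tsv")
        write_probe_annotation(ann, outdir / "annotation.tsv")
        write_sample_meta(sm, outdir / "samples.tsv")
        truth.signature.to_csv(outdir / "signature.tsv", sep="\t", index_label="probe_id")
        truth_json = {
            "clone_of": truth.clone_tree.clone_of,
            "mgmt_state": truth.mgmt_state,
            "n_drift_probes": len(truth.drift_probes),
            "cnv_truth": truth.cnv_truth.to_dict(orient="records"),
            "cell_fractions": truth.cell_fractions.round(6).to_dict(orient="index"),
        }
        _atomic_write_text(outdir / "truth.json", json.dumps(truth_json, indent=2, sort_keys=True))
        return {"n_probes": b.shape[0], "n_samples": b.shape[1]}

    if beta is None and not (config.simulate and "simulate" in enabled):
        # load whatever file inputs are configured
        if config.beta_path:
            beta = read_beta_matrix(config.beta_path)
        if config.log2_path:
            log2 = read_log2_matrix(config.log2_path)
        if config.annotation_path:
            annotation = read_probe_annotation(config.annotation_path)
        if config.meta_path:
            meta = read_sample_meta(config.meta_path)
        if config.signature_path:
            signature = pd.read_csv(config.signature_path, sep="\t", index_col=0)
    if config.gmt_path:
        gene_sets = read_gmt(config.gmt_path)

    def require(obj, what: str):
        if obj is None:
            raise ValueError(f"missing input for this stage: {what}")
        return obj

    # ---- clustering and phylogeny --------------------------------------
    @stage("select")
    def _select():
        nonlocal selected
        b = require(beta, "beta matrix")
        selected = select_top_variable_probes(b, k=config.top_k_probes)
        _atomic_write_text(outdir / "selected_probes.txt", "\n".join(selected) + "\n")
        return {"n_selected": len(selected)}

    @stage("cluster")
    def _cluster():
        nonlocal assignment
        b = require(beta, "beta matrix").select_probes(require(selected, "selected probes"))
        Z, assignment = hierarchical_cluster(
            b,
            k_clusters=config.k_clusters,
            metric=config.metric,
            linkage_method=config.linkage,
            space=config.space,
        )
        _atomic_write_tsv(assignment.to_frame(), outdir / "cluster_assignment.tsv", index=False)
        _atomic_write_text(
            outdir / "dendrogram.json",
            json.dumps({"linkage": Z.tolist(), "samples": b.sample_ids, "method": assignment.method}),
        )
        return {"k": assignment.k, "labels": assignment.labels, "method": assignment.method}

    @stage("phylogeny")
    def _phylogeny():
        nonlocal phylogeny
        b = require(beta, "beta matrix").select_probes(require(selected, "selected probes"))
        dist = sample_distance_matrix(b, metric=config.metric, space=config.space)
        root = None
        if meta is not None:
            root = meta.primary_sample
        root = root or b.sample_ids[0]
        phylogeny = build_phylogeny(dist, root_sample=root)
        newick = phylogeny.to_newick(outdir / "phylogeny.nwk")
        return {"root": root, "newick": newick.strip()}

    @stage("path")
    def _path():
        p = require(phylogeny, "phylogeny")
        m = require(meta, "sample metadata")
        path = infer_spread_path(p, m)
        _atomic_write_tsv(path.to_frame(), outdir / "spread_path.tsv", index=False)
        return {"visit_order": path.visit_order()}

    # ---- differential methylation ---------------------------------------
    @stage("dmp")
    def _dmp():
        b = require(beta, "beta matrix")
        a = require(assignment, "cluster assignment")
        counts = {}
        for i, j in combinations(a.cluster_ids(), 2):
            rec = pairwise_dmp(
                b, a, (i, j), space=config.space, fdr_q=config.fdr_q, sd_floor=config.sd_floor
            )
            label = rec["comparison"].iloc[0]
            dmp_records[label] = rec
            _atomic_write_tsv(rec, outdir / f"dmp_{label}.tsv", index=False)
            counts[label] = int(rec["significant"].sum())
        return {"significant_probes": counts}

    @stage("genes")
    def _genes():
        ann = require(annotation, "probe annotation")
        names = {}
        for label, rec in dmp_records.items():
            hyper, hypo = summarize_genes(rec, ann, top_n=config.top_n_genes)
            gene_lists[label] = (hyper, hypo)
            _atomic_write_tsv(hyper, outdir / f"genes_hyper_{label}.tsv", index=False)
            _atomic_write_tsv(hypo, outdir / f"genes_hypo_{label}.tsv", index=False)
            names[label] = {"hyper": len(hyper), "hypo": len(hypo)}
        return {"n_genes": names}

    @stage("venn")
    def _venn():
        if len(gene_lists) != 3:
            return {"note": f"venn needs exactly 3 comparisons, have {len(gene_lists)}"}
        out = {}
        for direction, idx in (("hyper", 0), ("hypo", 1)):
            lists = {label: set(pair[idx]["gene"]) for label, pair in gene_lists.items()}
            out[direction] = venn_overlap(lists)
        _atomic_write_text(outdir / "venn_counts.json", json.dumps(out, indent=2, sort_keys=True))
        return {"counts": out}

    # ---- copy number -----------------------------------------------------
    @stage("cnv")
    def _cnv():
        l2 = require(log2, "log2 intensity matrix")
        ann = require(annotation, "probe annotation")
        binned, called = copy_number_profile(
            l2,
            ann,
            bin_size_probes=config.bin_size_probes,
            alpha=config.seg_alpha,
            min_segment_bins=config.min_segment_bins,
            n_perm=config.seg_n_perm,
            seed=config.seed,
            amp_threshold=config.amp_threshold,
            gain_threshold=config.gain_threshold,
            loss_threshold=config.loss_threshold,
        )
        _atomic_write_tsv(binned, outdir / "cnv_profile.tsv", index=False)
        seg = called.rename(columns={})[
            ["sample_id", "chrom", "start", "end", "n_probes", "mean_log2", "call"]
        ]
        write_seg(seg, outdir / "cnv_segments.seg")
        return {
            "n_segments": int(len(called)),
            "calls": called["call"].value_counts().to_dict(),
        }

    # ---- markers / deconvolution -----------------------------------------
    @stage("mgmt")
    def _mgmt():
        b = require(beta, "beta matrix")
        probes = config.mgmt_probes
        if probes is None:
            ann = require(annotation, "probe annotation (or explicit MGMT probe list)")
            probes = ann.probes_for_gene("MGMT", classes={"promoter"})
        calls = call_mgmt(b, probes, threshold=config.mgmt_threshold)
        _atomic_write_tsv(calls, outdir / "mgmt_calls.tsv", index=False)
        return {"status_by_sample": dict(zip(calls["sample_id"], calls["status"]))}

    @stage("deconv")
    def _deconv():
        b = require(beta, "beta matrix")
        sig = require(signature, "cell-type signature matrix")
        fractions = estimate_fractions(b, sig)
        _atomic_write_tsv(fractions, outdir / "cell_fractions.tsv")
        detail = {"cell_types": [c for c in fractions.columns if c != "residual"]}
        if assignment is not None:
            table = compare_fractions(fractions, assignment)
            _atomic_write_tsv(table, outdir / "fraction_tests.tsv", index=False)
            detail["tests"] = table.set_index("cell_type")["p_value"].round(6).to_dict()
        return detail

    # ---- enrichment ------------------------------------------------------
    @stage("gsea")
    def _gsea():
        nonlocal gene_sets
        ann = require(annotation, "probe annotation")
        if not dmp_records:
            raise ValueError("missing input for this stage: differential methylation records")
        label, rec = _pick_gsea_comparison(dmp_records, require(assignment, "cluster assignment"))
        scores = gene_scores(rec, ann, classes={"gene_body", "promoter"}, significant_only=True)
        if len(scores) < 10:
            return {"note": f"too few scored genes ({len(scores)}) for enrichment", "comparison": label}
        ranking = rank_genes(scores.rename(columns={"mean_delta_beta": "score"}))
        _atomic_write_tsv(ranking, outdir / f"ranking_{label}.tsv", index=False)
        if gene_sets is None:
            gene_sets = _random_gene_sets(
                ranking["gene"].tolist(),
                n_sets=config.n_random_gene_sets,
                size=config.random_gene_set_size,
                seed=config.seed,
            )
            note = "no GMT provided; using seeded random gene sets over the ranked universe"
        else:
            note = f"gene sets from {config.gmt_path}"
        results = permutation_significance(
            ranking,
            gene_sets,
            n_perm=config.gsea_n_perm,
            seed=config.seed,
            weight=config.gsea_weight,
        )
        _atomic_write_tsv(results, outdir / f"gsea_{label}.tsv", index=False)
        return {
            "comparison": label,
            "n_sets_tested": int(len(results)),
            "note": note,
            "min_q": float(results["q_value"].min()) if len(results) else None,
        }

    _atomic_write_text(outdir / "run_report.json", json.dumps(report, indent=2, sort_keys=True))
    return report


def _pick_gsea_comparison(records: dict[str, pd.DataFrame], assignment) -> tuple[str, pd.DataFrame]:
    """Prefer the comparison between the two largest clusters (the recurrent
    clusters in the nine-sample design), falling back to the first."""
    sizes = {c: len(assignment.samples_in(c)) for c in assignment.cluster_ids()}
    best_label, best_key = None, None
    for label, rec in records.items():
        i, j = label.replace("C", "").split("_vs_")
        key = min(sizes.get(int(i), 0), sizes.get(int(j), 0))
        if best_key is None or key > best_key:
            best_label, best_key = label, key
    return best_label, records[best_label]


def _random_gene_sets(universe: list[str], n_sets: int, size: int, seed: int) -> dict[str, set[str]]:
    rng = np.random.default_rng([seed, 1001])
    size = min(size, max(2, len(universe) // 2))
    return {
        f"RANDOM_SET_{i + 1:03d}": set(rng.choice(universe, size=size, replace=False))
        for i in range(n_sets)
    }
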