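"""Clonal-evolution simulator for multi-region methylation cohorts.

Emulates a single tumor sampled at several anatomical sites, where the
samples belong to a small number of clones related by a rooted tree.
Baseline probe methylation is bimodal (mostly-unmethylated and
mostly-methylated CpGs); along each tree edge a fixed sparse subset of
"drift" probes accumulates Gaussian shifts in M space, inherited by
descendant clones, so clusters separate on a sparse epigenetic
signature.  Each sample additionally carries technical noise, stromal
admixture from reference cell-type profiles, clone-specific copy-number
segments on a parallel intensity matrix, and a clone-wise MGMT promoter
methylation state.  The returned truth bundle records every planted
quantity so downstream stages can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ProbeAnnotation
from .matrices import BetaMatrix, IntensityLog2Matrix, SampleMeta, m_to_beta

def _logit2(b: np.ndarray) -> np.ndarray:
    return np.log2(b / (1.0 - b))


# ---------------------------------------------------------------------------
# Planted clone tree


@dataclass(frozen=True)
class CloneTree:
    """Rooted tree over clones with per-edge drift lengths and a sample map.

    ``parents`` maps each non-root clone to its parent; ``edge_lengths``
    gives the drift length of the edge above each non-root clone;
    ``clone_of`` assigns every sample to exactly one clone (a clone may
    own several samples).
    """

    root: str
    parents: dict[str, str]
    edge_lengths: dict[str, float]
    clone_of: dict[str, str]

    def __post_init__(self) -> None:
        clones = self.clones()
        for child, parent in self.parents.items():
            if parent not in clones:
                raise ValueError(f"edge parent {parent!r} is not a known clone")
        if self.root in self.parents:
            raise ValueError("root clone must not have a parent")
        if set(self.edge_lengths) != set(self.parents):
            raise ValueError("edge_lengths keys must match parents keys")
        if any(length < 0 for length in self.edge_lengths.values()):
            raise ValueError("edge lengths must be >= 0")
        for clone in clones - {self.root}:
            seen = {clone}
            node = clone
            while node != self.root:
                node = self.parents[node]
                if node in seen:
                    raise ValueError("clone tree contains a cycle")
                seen.add(node)
        unknown = set(self.clone_of.values()) - clones
        if unknown:
            raise ValueError(f"samples assigned to unknown clones: {sorted(unknown)}")

    def clones(self) -> set[str]:
        return {self.root} | set(self.parents)

    def samples(self) -> list[str]:
        return list(self.clone_of)

    def path_to_root(self, clone: str) -> list[str]:
        """Edges (as child-clone labels) from ``clone`` up to the root."""
        path = []
        node = clone
        while node != self.root:
            path.append(node)
            node = self.parents[node]
        return path

    def path_length(self, a: str, b: str) -> float:
        """Tree distance between two clones in drift-length units."""
        up_a = {a: 0.0}
        node, acc = a, 0.0
        while node != self.root:
            acc += self.edge_lengths[node]
            node = self.parents[node]
            up_a[node] = acc
        node, acc = b, 0.0
        while node not in up_a:
            acc += self.edge_lengths[node]
            node = self.parents[node]
        return acc + up_a[node]

    def partition(self) -> dict[str, int]:
        """Sample -> integer clone label (contiguous from 1, by clone order)."""
        order = {c: i + 1 for i, c in enumerate(dict.fromkeys(self.clone_of.values()))}
        return {s: order[c] for s, c in self.clone_of.items()}


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class CNVSegmentSpec:
    """Planted copy-number segment for one clone (1-based closed interval)."""

    chrom: str
    start: int
    end: int
    log2_shift: float


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulated cohort.  ``seed`` is mandatory."""

    seed: int
    clone_tree: CloneTree
    n_probes: int = 50_000
    n_chromosomes: int = 4
    probe_spacing_bp: int = 10_000
    fraction_drift_probes: float = 0.05
    sigma_drift: float = 2.0      # M units per unit edge length
    sigma_noise: float = 0.3      # per-sample technical noise, M units
    beta_mixture: tuple[tuple[float, float, float], ...] = (
        (0.55, 1.5, 8.0),
        (0.45, 8.0, 1.5),
    )
    purity: dict[str, float] | float = 0.7
    stromal_types: tuple[str, ...] = ("endothelial", "fibroblast", "immune")
    stromal_weights: dict[str, tuple[float, ...]] = field(default_factory=dict)
    stromal_concentration: float = 200.0
    n_signature_probes: int = 500
    cnv_segments: dict[str, tuple[CNVSegmentSpec, ...]] = field(default_factory=dict)
    cnv_probe_noise_sd: float = 0.1
    mgmt_n_probes: int = 10
    mgmt_state: dict[str, str] = field(default_factory=dict)
    sites: dict[str, tuple[str, float, float, float, str]] = field(default_factory=dict)
    # sample -> (site label, x, y, z in mm, collection in {primary, autopsy})

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_drift_probes <= 1.0:
            raise ValueError("fraction_drift_probes must be in [0, 1]")
        if self.sigma_drift < 0 or self.sigma_noise < 0:
            raise ValueError("sigmas must be >= 0")
        for p in self.purity_map().values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("purity must be in [0, 1]")
        for clone, segs in self.cnv_segments.items():
            ordered = sorted(segs, key=lambda s: (s.chrom, s.start))
            for a, b in zip(ordered, ordered[1:]):
                if a.chrom == b.chrom and b.start <= a.end:
                    raise ValueError(f"overlapping CNV segments in clone {clone!r}")
        unknown = set(self.mgmt_state) - self.clone_tree.clones()
        if unknown:
            raise ValueError(f"MGMT states for unknown clones: {sorted(unknown)}")
        unknown = set(self.sites) - set(self.clone_tree.clone_of)
        if unknown:
            raise ValueError(f"site entries for unknown samples: {sorted(unknown)}")

    def purity_map(self) -> dict[str, float]:
        samples = self.clone_tree.samples()
        if isinstance(self.purity, dict):
            return {s: self.purity[s] for s in samples}
        return {s: float(self.purity) for s in samples}


@dataclass
class TruthBundle:
    """Everything the simulator planted, for scoring downstream stages."""

    clone_tree: CloneTree
    drift_probes: list[str]
    drift_shifts: pd.DataFrame       # drift probes x clones, cumulative M shift
    baseline_beta: pd.Series         # noiseless root-clone beta per probe
    cnv_truth: pd.DataFrame          # clone, chrom, start, end, log2_shift
    mgmt_state: dict[str, str]       # per sample
    cell_fractions: pd.DataFrame     # samples x (tumor + stromal types)
    signature: pd.DataFrame          # signature probes x cell types (reference input)
    mgmt_probes: list[str]


# ---------------------------------------------------------------------------
# Default cohort: 9 spatially distinct samples, 3 clones


def default_cohort_config(seed: int = 0, n_probes: int = 50_000) -> SimulationConfig:
    """Nine-sample, three-clone cohort of one multiregion-sampled tumor.

    Sample 1 is the primary resection (right temporal lobe); samples 2-9
    are autopsy samples.  Clone C1 owns sample 1, C2 owns samples 2-4
    and the midbrain sample 9, C3 owns the contralateral samples 5-8.
    MGMT promoter methylation is retained in C1 and C2 and lost in C3.
    Each clone carries its own copy-number segments; C3 is enriched for
    fibroblast admixture.
    """
    tree = CloneTree(
        root="C1",
        parents={"C2": "C1", "C3": "C1"},
        edge_lengths={"C2": 1.0, "C3": 1.0},
        clone_of={
            "s1": "C1",
            "s2": "C2", "s3": "C2", "s4": "C2", "s9": "C2",
            "s5": "C3", "s6": "C3", "s7": "C3", "s8": "C3",
        },
    )
    sites = {
        "s1": ("right temporal lobe (resection)", 45.0, -10.0, -15.0, "primary"),
        "s2": ("right temporal resection cavity wall", 48.0, -12.0, -12.0, "autopsy"),
        "s3": ("right parietal lobe", 40.0, -45.0, 35.0, "autopsy"),
        "s4": ("right occipital lobe", 25.0, -75.0, 5.0, "autopsy"),
        "s5": ("right frontal lobe / corpus callosum", 15.0, 25.0, 20.0, "autopsy"),
        "s6": ("left frontal lobe / corpus callosum", -15.0, 25.0, 20.0, "autopsy"),
        "s7": ("left superior frontal lobe", -20.0, 35.0, 45.0, "autopsy"),
        "s8": ("left lateral frontal lobe", -40.0, 30.0, 15.0, "autopsy"),
        "s9": ("midbrain", 3.0, -25.0, -20.0, "autopsy"),
    }
    # planted copy-number segments, expressed as probe-block intervals
    per_chrom = n_probes // 4
    spacing = 10_000

    def interval(chrom_idx: int, first_frac: float, last_frac: float) -> tuple[str, int, int]:
        first = int(per_chrom * first_frac)
        last = int(per_chrom * last_frac) - 1
        return (str(chrom_idx + 1), (first + 1) * spacing, (last + 1) * spacing)

    def seg(chrom_idx, lo, hi, shift):
        chrom, start, end = interval(chrom_idx, lo, hi)
        return CNVSegmentSpec(chrom, start, end, shift)

    cnv = {
        "C1": (seg(0, 0.10, 0.25, 0.35), seg(2, 0.50, 0.70, -0.35)),
        "C2": (seg(1, 0.20, 0.40, 0.40), seg(3, 0.55, 0.75, -0.40)),
        "C3": (seg(0, 0.60, 0.80, 0.50), seg(2, 0.10, 0.30, -0.30)),
    }
    return SimulationConfig(
        seed=seed,
        clone_tree=tree,
        n_probes=n_probes,
        cnv_segments=cnv,
        mgmt_state={"C1": "methylated", "C2": "methylated", "C3": "unmethylated"},
        stromal_weights={
            "C1": (1.0, 1.0, 1.0),
            "C2": (1.0, 1.0, 1.6),
            "C3": (1.0, 2.5, 1.0),
        },
        sites=sites,
    )


# ---------------------------------------------------------------------------
# Annotation layout

_BLOCK = 25  # probes per gene block
# within each block: fixed region-class layout; the two upstream probes
# are repositioned inside the 1.5-kb window ahead of the TSS
_BLOCK_CLASSES = (
    ["upstream"] * 2 + ["promoter"] * 2 + ["utr"] * 2 + ["gene_body"] * 14 + ["intergenic"] * 5
)


def _build_annotation(config: SimulationConfig) -> tuple[ProbeAnnotation, list[str]]:
    """Deterministic gene/region layout over an evenly spaced probe grid.

    Probes are laid out on ``n_chromosomes`` chromosomes at fixed
    spacing; every 25-probe block belongs to one synthetic gene with a
    fixed region-class pattern (2 upstream, 2 promoter, 2 UTR, 14 gene
    body, 5 intergenic).  One mid-genome block is relabelled as the MGMT
    gene; its promoter probes drive the MGMT methylation calls.
    """
    n = config.n_probes
    per_chrom = n // config.n_chromosomes
    idx = np.arange(n)
    chrom_idx = np.minimum(idx // per_chrom, config.n_chromosomes - 1)
    pos_in_chrom = idx - chrom_idx * per_chrom
    chrom = (chrom_idx + 1).astype(str)
    pos = (pos_in_chrom + 1) * config.probe_spacing_bp

    probe_ids = np.array([f"cg{i:08d}" for i in range(n)])
    block = idx // _BLOCK
    within = idx % _BLOCK
    classes = np.array(_BLOCK_CLASSES)[within]
    genes = np.where(classes == "intergenic", "", np.char.add("GENE", np.char.zfill(block.astype(str), 5)))

    # TSS of each gene = position of its first promoter probe (within == 2);
    # the upstream probes sit 1500 and 750 bp ahead of it on the + strand
    tss_pos = pos[np.minimum(block * _BLOCK + 2, n - 1)].astype(float)
    pos = pos.copy()
    pos[within == 0] = tss_pos[within == 0] - 1500
    pos[within == 1] = tss_pos[within == 1] - 750
    pos = np.maximum(pos, 1)
    has_gene = genes != ""
    dist = np.where(has_gene, tss_pos - pos, np.nan)

    # relabel one block (clear of planted CNV segments) as MGMT
    mgmt_block = (n // _BLOCK) // 2
    mgmt_members = np.where(block == mgmt_block)[0][: config.mgmt_n_probes]
    genes = genes.copy()
    genes[block == mgmt_block] = ""
    classes = classes.copy()
    classes[block == mgmt_block] = "intergenic"
    genes[mgmt_members] = "MGMT"
    classes[mgmt_members] = "promoter"

    table = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chrom,
            "pos": pos,
            "gene": genes,
            "tss": tss_pos,
            "strand": "+",
            "region_class": classes,
            "dist_to_tss": dist,
        }
    )
    return ProbeAnnotation(table), list(probe_ids[mgmt_members])


# ---------------------------------------------------------------------------
# The simulator


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[BetaMatrix, IntensityLog2Matrix, ProbeAnnotation, SampleMeta, TruthBundle]:
    """Generate one cohort; identical config and seed give identical output.

    Baseline betas come from the configured bimodal Beta mixture.  Drift
    probes (a fixed random subset shared by all edges) receive an
    M-space shift of variance ``sigma_drift**2 * edge_length`` per edge,
    inherited along the tree; per-sample technical noise is Gaussian in
    M space.  The tumor signal is mixed with stromal cell-type profiles
    at (1 - purity) in beta space.  Copy-number segments shift only the
    intensity matrix.  MGMT promoter probes are overridden per the
    clone's methylation state.
    """
    rng = np.random.default_rng(config.seed)
    tree = config.clone_tree
    samples = tree.samples()
    n = config.n_probes

    annotation, mgmt_probes = _build_annotation(config)
    probe_ids = np.array(annotation.probe_ids)

    # baseline tumor betas from the bimodal mixture
    weights = np.array([w for w, _, _ in config.beta_mixture])
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    baseline = np.empty(n)
    for ci, (_, a, b) in enumerate(config.beta_mixture):
        mask = comp == ci
        baseline[mask] = rng.beta(a, b, size=int(mask.sum()))
    baseline = np.clip(baseline, 1e-6, 1 - 1e-6)

    # signature probes: trailing block, excluded from drift so stromal
    # deconvolution sees a clone-invariant tumor profile
    n_sig = min(config.n_signature_probes, n)
    sig_idx = np.arange(n - n_sig, n)
    mgmt_idx = np.array([np.flatnonzero(probe_ids == p)[0] for p in mgmt_probes])
    eligible = np.setdiff1d(np.arange(n), np.concatenate([sig_idx, mgmt_idx]))
    n_drift = int(round(config.fraction_drift_probes * n))
    drift_idx = np.sort(rng.choice(eligible, size=min(n_drift, len(eligible)), replace=False))

    # per-clone cumulative M shift along the tree (preorder inheritance)
    shifts = {tree.root: np.zeros(n)}
    pending = [c for c in tree.parents if tree.parents[c] == tree.root]
    while pending:
        clone = pending.pop(0)
        parent_shift = shifts[tree.parents[clone]]
        delta = np.zeros(n)
        length = tree.edge_lengths[clone]
        if length > 0 and config.sigma_drift > 0 and len(drift_idx):
            delta[drift_idx] = rng.normal(0.0, config.sigma_drift * np.sqrt(length), size=len(drift_idx))
        shifts[clone] = parent_shift + delta
        pending.extend(c for c in tree.parents if tree.parents[c] == clone)

    base_m = _logit2(baseline)

    # MGMT promoter betas are a heritable epigenetic state: one draw per
    # distinct state, shared by every clone (and sample) carrying it
    state_of = {c: config.mgmt_state.get(c, "methylated") for c in sorted(tree.clones())}
    mgmt_beta_by_state = {}
    for state in sorted(set(state_of.values())):
        a, b = (8, 2) if state == "methylated" else (2, 8)
        mgmt_beta_by_state[state] = rng.beta(a, b, size=len(mgmt_idx))

    # stromal profiles over all probes; MGMT promoter kept unmethylated in
    # normal brain tissue
    n_types = len(config.stromal_types)
    stromal = np.empty((n, n_types))
    for t in range(n_types):
        side = rng.random(n) < 0.5
        stromal[:, t] = np.where(side, rng.beta(2, 10, size=n), rng.beta(10, 2, size=n))
    stromal[mgmt_idx, :] = rng.beta(2, 8, size=(len(mgmt_idx), n_types))

    purity = config.purity_map()
    default_weights = tuple(1.0 for _ in config.stromal_types)
    frac_rows = {}
    beta_cols = {}
    log2_cols = {}
    mgmt_state_sample = {}

    ann_chrom = annotation.table["chrom"].to_numpy()
    ann_pos = annotation.table["pos"].to_numpy()

    for s in samples:
        clone = tree.clone_of[s]
        m = base_m + shifts[clone]
        if config.sigma_noise > 0:
            m = m + rng.normal(0.0, config.sigma_noise, size=n)
        tumor_beta = m_to_beta(m)

        mgmt_state_sample[s] = state_of[clone]
        tumor_beta[mgmt_idx] = mgmt_beta_by_state[state_of[clone]]

        p = purity[s]
        w = np.array(config.stromal_weights.get(clone, default_weights), dtype=float)
        if n_types and p < 1.0:
            stromal_frac = rng.dirichlet(w / w.sum() * config.stromal_concentration) * (1.0 - p)
        else:
            stromal_frac = np.zeros(n_types)
        observed = tumor_beta * p + stromal @ stromal_frac
        beta_cols[s] = np.clip(observed, 0.0, 1.0)
        frac_rows[s] = np.concatenate([[p], stromal_frac])

        log2 = rng.normal(0.0, config.cnv_probe_noise_sd, size=n) if config.cnv_probe_noise_sd > 0 else np.zeros(n)
        for segspec in config.cnv_segments.get(clone, ()):
            in_seg = (ann_chrom == segspec.chrom) & (ann_pos >= segspec.start) & (ann_pos <= segspec.end)
            log2[in_seg] += segspec.log2_shift
        log2_cols[s] = log2

    beta = BetaMatrix(pd.DataFrame(beta_cols, index=probe_ids))
    log2m = IntensityLog2Matrix(pd.DataFrame(log2_cols, index=probe_ids))

    meta_rows = []
    for s in samples:
        site, x, y, z, collection = config.sites.get(s, (f"site {s}", 0.0, 0.0, 0.0, "autopsy"))
        meta_rows.append({"sample_id": s, "site": site, "x": x, "y": y, "z": z, "collection": collection})
    meta = SampleMeta(pd.DataFrame(meta_rows).set_index("sample_id"))

    cnv_truth = pd.DataFrame(
        [
            {"clone": clone, "chrom": sp.chrom, "start": sp.start, "end": sp.end, "log2_shift": sp.log2_shift}
            for clone, specs in config.cnv_segments.items()
            for sp in specs
        ],
        columns=["clone", "chrom", "start", "end", "log2_shift"],
    )
    fractions = pd.DataFrame(frac_rows, index=["tumor", *config.stromal_types]).T
    signature = pd.DataFrame(
        np.column_stack([baseline[sig_idx], stromal[sig_idx]]),
        index=probe_ids[sig_idx],
        columns=["tumor", *config.stromal_types],
    )
    clone_list = sorted(tree.clones())
    drift_shifts = pd.DataFrame(
        {c: shifts[c][drift_idx] for c in clone_list}, index=probe_ids[drift_idx]
    )
    truth = TruthBundle(
        clone_tree=tree,
        drift_probes=list(probe_ids[drift_idx]),
        drift_shifts=drift_shifts,
        baseline_beta=pd.Series(baseline, index=probe_ids),
        cnv_truth=cnv_truth,
        mgmt_state=mgmt_state_sample,
        cell_fractions=fractions,
        signature=signature,
        mgmt_probes=mgmt_probes,
    )
    return beta, log2m, annotation, meta, truth
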