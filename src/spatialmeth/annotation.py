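"""Probe-to-gene annotation and regulatory region classification.

Each array probe is tied to at most one gene and classified into one of
five region classes: ``promoter``, ``utr``, ``gene_body``, ``upstream``
(within 1.5 kb upstream of the transcription start site, on the gene's
strand), or ``intergenic``.  Coordinates are 1-based and fully closed,
matching array-manifest convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

UPSTREAM_WINDOW_BP = 1500

REGION_CLASSES = ("promoter", "utr", "gene_body", "upstream", "intergenic")
#: region classes that count as gene-linked for gene-level summaries
GENE_LINKED_CLASSES = frozenset({"promoter", "utr", "gene_body", "upstream"})

_COLUMNS = ["probe_id", "chrom", "pos", "gene", "tss", "strand", "region_class", "dist_to_tss"]


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene annotation: strand, TSS and sub-intervals (1-based, closed)."""

    gene: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int
    promoter: tuple[int, int] | None = None
    utrs: tuple[tuple[int, int], ...] = ()
    body: tuple[int, int] | None = None


def _contains(interval: tuple[int, int] | None, pos: int) -> bool:
    return interval is not None and interval[0] <= pos <= interval[1]


def upstream_distance(pos: int, tss: int, strand: str) -> int:
    """Signed strand-aware distance; positive = upstream of the TSS."""
    return tss - pos if strand == "+" else pos - tss


def annotate_region_class(
    pos: int,
    chrom: str,
    gene: GeneModel,
    upstream_window: int = UPSTREAM_WINDOW_BP,
) -> str:
    """Classify a probe position against one gene model.

    Sub-intervals take precedence (promoter, then UTR, then gene body);
    otherwise the probe is ``upstream`` iff it lies strictly upstream of
    the TSS by at most ``upstream_window`` bp on the gene's strand.  A
    probe on a different chromosome is ``intergenic``, never an error.
    The mapping is total: every (probe, gene) pair gets exactly one class.
    """
    if chrom != gene.chrom:
        return "intergenic"
    if _contains(gene.promoter, pos):
        return "promoter"
    if any(_contains(u, pos) for u in gene.utrs):
        return "utr"
    if _contains(gene.body, pos):
        return "gene_body"
    d = upstream_distance(pos, gene.tss, gene.strand)
    if 0 < d <= upstream_window:
        return "upstream"
    return "intergenic"


@dataclass
class ProbeAnnotation:
    """BED-like table of probe locations, gene links and region classes.

    One row per probe: ``probe_id``, ``chrom``, ``pos`` (1-based bp),
    ``gene`` (empty string when intergenic), ``tss`` (NaN when absent),
    ``strand``, ``region_class``, ``dist_to_tss`` (signed bp, positive =
    upstream).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.table["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids in annotation")
        if (self.table["pos"] < 1).any():
            raise ValueError("probe positions must be >= 1 (1-based coordinates)")
        bad = set(self.table["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise ValueError(f"unknown region classes: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def probe_ids(self) -> list[str]:
        return self.table["probe_id"].tolist()

    def gene_linked(self) -> pd.DataFrame:
        """Rows whose region class links the probe to a gene (non-intergenic)."""
        t = self.table
        return t[t["region_class"].isin(GENE_LINKED_CLASSES) & (t["gene"] != "")]

    def probes_for_gene(self, gene: str, classes=GENE_LINKED_CLASSES) -> list[str]:
        t = self.table
        sel = (t["gene"] == gene) & t["region_class"].isin(classes)
        return t.loc[sel, "probe_id"].tolist()

    def sorted_by_position(self) -> pd.DataFrame:
        return self.table.sort_values(["chrom", "pos"], kind="mergesort")


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    df["gene"] = df["gene"].fillna("")
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)
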