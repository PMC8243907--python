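"""Readers and writers for the small text formats the pipeline touches.

Newick trees go through scikit-bio; GMT gene sets and SEG segment tables
are simple tab-delimited conventions handled here directly.  Round-trips
are lossless at the printed precision.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from skbio import TreeNode

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "n_probes", "mean_log2", "call"]


# -- Newick -----------------------------------------------------------------

def read_newick(source) -> TreeNode:
    """Parse a Newick tree from a path or string."""
    text = source if isinstance(source, str) and source.strip().endswith(";") else Path(source).read_text()
    if text.count("(") != text.count(")"):
        raise ValueError("malformed Newick: unbalanced parentheses")
    return TreeNode.read(_io.StringIO(text))


def write_newick(tree: TreeNode, path=None) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# -- GMT gene sets ----------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}")
        name = fields[0]
        if name in sets:
            raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
        sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(genes)])
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# -- SEG segment tables -----------------------------------------------------

def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file missing columns: {missing}")
    bad = df["end"] < df["start"]
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(
            f"SEG segment with end < start: {row['sample_id']} "
            f"{row['chrom']}:{row['start']}-{row['end']}"
        )
    return df[SEG_COLUMNS]


def write_seg(segments: pd.DataFrame, path) -> None:
    segments.to_csv(path, sep="\t", index=False, columns=SEG_COLUMNS, float_format="%.6g")
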