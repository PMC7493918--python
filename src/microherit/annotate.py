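"""Positional candidate genes: intersect top 1-Mb windows with an annotation.

Gene records use BED's 0-based half-open coordinates internally; the window
grid is also half-open and bp-anchored, so overlap is plain interval
arithmetic: a gene overlaps window [start, end) iff
gene.start < end and gene.end > start.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["read_annotation", "genes_in_window", "window_gene_report"]


def _norm_chrom(label: str) -> str:
    label = str(label).strip()
    return label[3:] if label.lower().startswith("chr") else label


def read_annotation(path, fmt: str = "bed") -> pd.DataFrame:
    """Read a BED4 (or GFF3 gene-feature) annotation into a record table.

    Returns a DataFrame with columns ``chrom`` (str, "chr" prefix stripped),
    ``start``, ``end`` (0-based half-open) and ``gene``.  Malformed lines are
    skipped with a logged message carrying the line number; an annotation
    with no usable records is an error.
    """
    records = []
    fmt = fmt.lower()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    chrom, start, end, gene = (
                        fields[0], int(fields[1]), int(fields[2]), fields[3]
                    )
                elif fmt == "gff3":
                    if fields[2] != "gene":
                        continue
                    chrom = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])  # to 0-based
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                    )
                    gene = attrs.get("Name", attrs.get("ID", ""))
                else:
                    raise ValueError(f"unknown annotation format {fmt!r}")
            except (IndexError, ValueError) as exc:
                if isinstance(exc, ValueError) and "unknown annotation" in str(exc):
                    raise
                logger.warning("%s line %d: malformed record skipped (%s)",
                               path, lineno, exc)
                continue
            if start >= end:
                logger.warning("%s line %d: start >= end, record rejected",
                               path, lineno)
                continue
            records.append((_norm_chrom(chrom), start, end, gene))
    if not records:
        raise ValueError(f"annotation {path} contains no usable records")
    return (
        pd.DataFrame(records, columns=["chrom", "start", "end", "gene"])
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )


def genes_in_window(window: tuple, annotation: pd.DataFrame) -> list[str]:
    """Genes overlapping the half-open window (chrom, start_bp, end_bp) by >= 1 bp,
    sorted by gene start position."""
    chrom, start, end = window
    chrom = _norm_chrom(chrom)
    hits = annotation[
        (annotation["chrom"] == chrom)
        & (annotation["start"] < end)
        & (annotation["end"] > start)
    ]
    return list(hits.sort_values("start", kind="stable")["gene"])


def window_gene_report(window_table: pd.DataFrame, annotation: pd.DataFrame,
                       taxon: str | None = None) -> pd.DataFrame:
    """One row per (window, gene); windows with no genes keep an empty field.

    ``window_table`` must carry ``chrom``, ``start_bp``, ``end_bp`` columns
    (as produced by :func:`microherit.windows.window_variance` with a map).
    """
    rows = []
    for _, w in window_table.iterrows():
        genes = genes_in_window(
            (w["chrom"], int(w["start_bp"]), int(w["end_bp"])), annotation
        )
        base = {
            "taxon": taxon if taxon is not None else w.get("taxon", ""),
            "window_label": w.get("window_label", ""),
            "chrom": w["chrom"],
            "start_bp": int(w["start_bp"]),
            "end_bp": int(w["end_bp"]),
        }
        if genes:
            rows.extend({**base, "gene": g} for g in genes)
        else:
            rows.append({**base, "gene": ""})
    return pd.DataFrame(rows)
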