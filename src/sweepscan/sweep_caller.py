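"""Composite sweep calling from a window-statistics table.

A window is called as part of a selective sweep when it sits in the genome-wide
top 5% of both XP-CLR and F_ST distributions and its Tajima's D is strictly
negative in cultivars and strictly positive in wild accessions.  Called windows
are merged into maximal blocks (overlapping or book-ended) and blocks are
assigned the genes they overlap by at least one base pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import GeneSet

MIN_PERCENTILE_VALUES = 20


def percentile_threshold(values, q: float = 0.95) -> float:
    """Empirical quantile (linear interpolation); selection is inclusive (>=).

    Undefined (NaN) values are excluded before ranking; at least 20 finite
    values are required.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < MIN_PERCENTILE_VALUES:
        raise ValueError(
            f"need >= {MIN_PERCENTILE_VALUES} finite values for a percentile "
            f"threshold, have {len(v)}"
        )
    return float(np.quantile(v, q, method="linear"))


@dataclass
class CallDiagnostics:
    """Intermediate sets of the narrowing procedure, for reporting."""

    xpclr_threshold: float
    fst_threshold: float
    n_windows_defined: int
    n_xpclr_top: int
    n_fst_top: int
    n_overlap: int  # XP-CLR top AND F_ST top, before the Tajima's D signs
    n_final: int


def call_sweeps(
    window_table: pd.DataFrame,
    q_xpclr: float = 0.95,
    q_fst: float = 0.95,
) -> tuple[pd.DataFrame, CallDiagnostics]:
    """Select windows by the top-percentile intersection plus D-sign rule.

    Requires columns ``xpclr``, ``fst``, ``tajd_cult`` and ``tajd_wild``.
    Returns the selected windows and the intermediate-set diagnostics (the
    pre-D overlap mirrors the published two-statistic narrowing stage).
    """
    for col in ("xpclr", "fst", "tajd_cult", "tajd_wild"):
        if col not in window_table.columns:
            raise ValueError(f"window table is missing required column {col!r}")
    t = window_table
    defined = np.isfinite(t["xpclr"]) & np.isfinite(t["fst"])
    thr_x = percentile_threshold(t.loc[defined, "xpclr"], q_xpclr)
    thr_f = percentile_threshold(t.loc[defined, "fst"], q_fst)
    top_x = defined & (t["xpclr"] >= thr_x)
    top_f = defined & (t["fst"] >= thr_f)
    overlap = top_x & top_f
    final = (overlap
             & np.isfinite(t["tajd_cult"]) & (t["tajd_cult"] < 0)
             & np.isfinite(t["tajd_wild"]) & (t["tajd_wild"] > 0))
    diag = CallDiagnostics(
        xpclr_threshold=thr_x,
        fst_threshold=thr_f,
        n_windows_defined=int(defined.sum()),
        n_xpclr_top=int(top_x.sum()),
        n_fst_top=int(top_f.sum()),
        n_overlap=int(overlap.sum()),
        n_final=int(final.sum()),
    )
    return t[final].copy(), diag


@dataclass
class SweepBlock:
    """A maximal merged run of called windows with aggregated evidence."""

    chrom: str
    start: int
    end: int
    n_windows: int
    max_xpclr: float
    max_fst: float
    mean_tajd_wild: float
    mean_tajd_cult: float
    gene_ids: list[str] = field(default_factory=list)


def merge_blocks(selected: pd.DataFrame) -> list[SweepBlock]:
    """Merge overlapping or book-ended selected windows into maximal blocks."""
    blocks: list[SweepBlock] = []
    if selected.empty:
        return blocks
    sel = selected.sort_values(["chrom", "start"])
    cur: dict | None = None
    for row in sel.itertuples(index=False):
        if (cur is not None and row.chrom == cur["chrom"]
                and row.start <= cur["end"]):
            cur["end"] = max(cur["end"], int(row.end))
            cur["rows"].append(row)
        else:
            if cur is not None:
                blocks.append(_finish_block(cur))
            cur = dict(chrom=row.chrom, start=int(row.start), end=int(row.end),
                       rows=[row])
    blocks.append(_finish_block(cur))
    return blocks


def _finish_block(cur: dict) -> SweepBlock:
    rows = cur["rows"]
    return SweepBlock(
        chrom=cur["chrom"],
        start=cur["start"],
        end=cur["end"],
        n_windows=len(rows),
        max_xpclr=float(np.max([r.xpclr for r in rows])),
        max_fst=float(np.max([r.fst for r in rows])),
        mean_tajd_wild=float(np.mean([r.tajd_wild for r in rows])),
        mean_tajd_cult=float(np.mean([r.tajd_cult for r in rows])),
    )


def annotate_blocks(
    blocks: list[SweepBlock], genes: GeneSet
) -> tuple[list[SweepBlock], pd.DataFrame, dict]:
    """Assign genes overlapping each block by >= 1 bp (half-open intervals).

    Returns the blocks (gene lists filled in place), a flat selected-gene
    table, and a summary with selected/total counts and the percentage of
    annotated genes under selection (rounded to 2 decimals).
    """
    gdf = genes.genes
    flat_rows = []
    for blk in blocks:
        hit = gdf[(gdf["chrom"] == blk.chrom)
                  & (gdf["start"] < blk.end) & (gdf["end"] > blk.start)]
        blk.gene_ids = list(hit["gene_id"])
        for g in hit.itertuples(index=False):
            flat_rows.append(dict(gene_id=g.gene_id, chrom=g.chrom,
                                  start=g.start, end=g.end,
                                  block_start=blk.start, block_end=blk.end))
    flat = pd.DataFrame(flat_rows, columns=["gene_id", "chrom", "start", "end",
                                            "block_start", "block_end"])
    n_selected = flat["gene_id"].nunique()
    summary = gene_selection_summary(n_selected, len(gdf))
    return blocks, flat, summary


def gene_selection_summary(n_selected: int, n_total: int) -> dict:
    """Selected-gene counts and percentage, rounded to two decimals."""
    pct = round(100.0 * n_selected / n_total, 2) if n_total else 0.0
    return {
        "n_genes_selected": int(n_selected),
        "n_genes_total": int(n_total),
        "percent_genes_selected": pct,
    }


def blocks_to_frame(blocks: list[SweepBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(chrom=b.chrom, start=b.start, end=b.end, n_windows=b.n_windows,
                 max_xpclr=b.max_xpclr, max_fst=b.max_fst,
                 mean_tajd_wild=b.mean_tajd_wild, mean_tajd_cult=b.mean_tajd_cult,
                 genes=",".join(b.gene_ids))
            for b in blocks
        ],
        columns=["chrom", "start", "end", "n_windows", "max_xpclr", "max_fst",
                 "mean_tajd_wild", "mean_tajd_cult", "genes"],
    )
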