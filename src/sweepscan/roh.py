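"""Runs of homozygosity on single-copy-gene SNPs, with terminal-run detection.

Long homozygous tracts anchored at chromosome ends are the expected footprint
of mitotic recombination under long clonal propagation ('one-step' crop
domestication); a sexual founder bottleneck instead leaves interstitial
autozygous tracts.  The scan therefore restricts to SNPs inside single-copy
genes (where paralog collapse cannot fake homozygosity), calls per-sample runs
and flags those containing the first or last retained SNP of a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd

from .variant_io import GeneSet, GenotypeMatrix


@dataclass
class RohParams:
    """Run-calling knobs; defaults are deliberately conservative.

    max_het: heterozygous calls tolerated inside a run.
    min_snps: minimum SNPs (including tolerated heterozygotes) per run.
    min_length_bp: minimum physical span per run.
    terminal_fraction: a terminal run is 'extensive' when it covers at least
        this fraction of the chromosome's retained-SNP extent.
    chrom_fraction: a sample is flagged when at least this fraction of its
        reportable chromosomes carries an extensive terminal run (the clonal
        signature is genome-wide, not single-chromosome).
    """

    max_het: int = 0
    min_snps: int = 25
    min_length_bp: int = 10_000
    terminal_fraction: float = 0.25
    chrom_fraction: float = 0.5


def select_single_copy_snps(gm: GenotypeMatrix, genes: GeneSet) -> np.ndarray:
    """Boolean mask of SNPs lying inside single-copy gene intervals."""
    mask = np.zeros(gm.n_sites, dtype=bool)
    sc = genes.single_copy()
    if sc.empty:
        warn("no single-copy genes in the annotation; ROH mask is empty",
             stacklevel=2)
        return mask
    for chrom, sub in sc.groupby("chrom", sort=False):
        idx = gm.chrom_sites(chrom)
        if len(idx) == 0:
            continue
        pos = gm.pos[idx]
        starts = np.sort(sub["start"].to_numpy())
        ends = sub.sort_values("start")["end"].to_numpy()
        # genes are non-overlapping: position is inside a gene iff the nearest
        # gene start at or before it has an end beyond it
        j = np.searchsorted(starts, pos, side="right") - 1
        inside = (j >= 0) & (pos < ends[np.maximum(j, 0)])
        mask[idx[inside]] = True
    return mask


@dataclass
class RohRun:
    sample: str
    chrom: str
    start: int  # position of the first SNP in the run (0-based)
    end: int    # position after the last SNP (half-open)
    n_snps: int
    n_het: int
    terminal: bool = False


def call_roh(
    genotypes: np.ndarray,
    positions: np.ndarray,
    params: RohParams | None = None,
    sample: str = "",
    chrom: str = "",
) -> list[RohRun]:
    """Runs of homozygosity in one sample on one chromosome.

    ``genotypes``: dosage codes per masked SNP (0 hom-ref, 1 het, 2 hom-alt,
    -1 missing) sorted by position.  Missing calls are transparent: they
    neither break nor count toward a run.  Runs start and end on homozygous
    calls, tolerate up to ``max_het`` heterozygous interruptions, and are then
    filtered by ``min_snps`` (tolerated heterozygotes included in the count)
    and ``min_length_bp``.
    """
    if params is None:
        params = RohParams()
    called = genotypes >= 0
    gt = genotypes[called]
    pos = positions[called]
    het = gt == 1
    runs: list[RohRun] = []
    i = 0
    n = len(gt)
    # greedy left-to-right: runs start and end on homozygous calls, extend
    # while the heterozygote budget holds, and never overlap
    while i < n:
        if het[i]:
            i += 1
            continue
        j = i
        n_het = 0
        last_hom = i
        while j < n:
            if het[j]:
                if n_het == params.max_het:
                    break
                n_het += 1
            else:
                last_hom = j
            j += 1
        kept_het = int(het[i:last_hom + 1].sum())
        runs.append(RohRun(
            sample=sample, chrom=chrom,
            start=int(pos[i]), end=int(pos[last_hom]) + 1,
            n_snps=last_hom - i + 1, n_het=kept_het,
        ))
        i = last_hom + 1
    return [
        r for r in runs
        if r.n_snps >= params.min_snps and (r.end - r.start) >= params.min_length_bp
    ]


def roh_scan(
    gm: GenotypeMatrix,
    genes: GeneSet,
    params: RohParams | None = None,
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call ROH for every sample on single-copy-gene SNPs.

    Returns (runs table, per-sample/chromosome extent table).  Chromosomes
    whose retained-SNP count falls below ``min_snps`` are excluded and noted
    in the extent table with ``reported = False``.
    """
    if params is None:
        params = RohParams()
    mask = select_single_copy_snps(gm, genes)
    sub = gm.take(mask)
    if samples is None:
        samples = gm.samples
    sample_idx = {s: gm.samples.index(s) for s in samples}

    run_rows, extent_rows = [], []
    for chrom in pd.unique(sub.chrom):
        idx = sub.chrom_sites(chrom)
        pos = sub.pos[idx]
        reported = len(idx) >= params.min_snps
        for s in samples:
            h = sub.haps[idx][:, sample_idx[s], :]
            full = (h >= 0).all(axis=1)
            gt = np.where(full, (h == 1).sum(axis=1), -1)
            extent_rows.append(dict(
                sample=s, chrom=chrom, n_snps=len(idx),
                first_snp=int(pos[0]) if len(pos) else -1,
                last_snp=int(pos[-1]) if len(pos) else -1,
                reported=reported,
            ))
            if not reported:
                continue
            for r in call_roh(gt, pos, params, sample=s, chrom=chrom):
                run_rows.append(r)

    runs = pd.DataFrame(
        [dict(sample=r.sample, chrom=r.chrom, start=r.start, end=r.end,
              n_snps=r.n_snps, n_het=r.n_het) for r in run_rows],
        columns=["sample", "chrom", "start", "end", "n_snps", "n_het"],
    )
    extents = pd.DataFrame(
        extent_rows,
        columns=["sample", "chrom", "n_snps", "first_snp", "last_snp", "reported"],
    )
    return runs, extents


def terminal_homozygosity(
    runs: pd.DataFrame,
    extents: pd.DataFrame,
    params: RohParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag terminal runs and summarize the genome-wide clonal signature.

    A run is terminal when it contains the first or last retained SNP of its
    chromosome.  Per (sample, chromosome), the longest terminal run's span as
    a fraction of the retained-SNP extent is compared with
    ``terminal_fraction``; a sample's ``genome_flag`` is set when at least
    ``chrom_fraction`` of its reportable chromosomes exceed it.
    """
    if params is None:
        params = RohParams()
    ext = extents[extents["reported"]]
    per_rows = []
    for row in ext.itertuples(index=False):
        span = row.last_snp - row.first_snp + 1
        sub = runs[(runs["sample"] == row.sample) & (runs["chrom"] == row.chrom)]
        term = sub[(sub["start"] <= row.first_snp) | (sub["end"] > row.last_snp)]
        frac = float((term["end"] - term["start"]).max() / span) if len(term) else 0.0
        per_rows.append(dict(
            sample=row.sample, chrom=row.chrom,
            n_terminal_runs=len(term),
            terminal_fraction=frac,
            extensive=frac >= params.terminal_fraction,
        ))
    per = pd.DataFrame(per_rows, columns=["sample", "chrom", "n_terminal_runs",
                                          "terminal_fraction", "extensive"])
    summ_rows = []
    for s, sub in per.groupby("sample", sort=False):
        n_chrom = len(sub)
        n_ext = int(sub["extensive"].sum())
        summ_rows.append(dict(
            sample=s, n_chrom=n_chrom, n_extensive=n_ext,
            genome_flag=n_chrom > 0 and n_ext >= np.ceil(
                params.chrom_fraction * n_chrom),
        ))
    summary = pd.DataFrame(summ_rows, columns=["sample", "n_chrom",
                                               "n_extensive", "genome_flag"])
    return per, summary
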