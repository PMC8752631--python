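"""Reading/writing variant and annotation formats, and site filtering.

The central container is :class:`GenotypeMatrix`: diploid allele calls for a
set of samples at SNP sites, together with per-site QUAL, per-call depth and a
sample-to-population map.  Coordinates are 1-based in VCF/GFF3 on disk and
0-based half-open everywhere in memory (the BED convention).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # allele code for a missing call


@dataclass
class FilterRules:
    """Site/genotype filters for a resequencing SNP set.

    Defaults follow the common vcftools-style recipe for domestication
    panels: biallelic SNPs, site QUAL >= 30, depth within 4-60x, at most 10%
    missing calls and pooled minor-allele frequency >= 5%.
    """

    min_depth: int = 4
    max_depth: int = 60
    min_site_qual: float = 30.0
    min_maf: float = 0.05
    max_missing: float = 0.10
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must not exceed max_depth")
        if not 0 <= self.max_missing <= 1:
            raise ValueError("max_missing must be in [0, 1]")


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid allele calls with site and call metadata.

    Attributes
    ----------
    samples : list of sample IDs (column order of ``haps``/``dp``).
    chrom, pos : per-site chromosome and 0-based position (strictly
        increasing within each chromosome).
    ref, alt : per-site alleles; multiallelic records keep a comma-joined
        alt and are flagged ``biallelic == False``.
    qual : per-site QUAL.
    haps : int8 array (n_sites, n_samples, 2); 0 ref, 1..k alt, -1 missing.
    dp : int32 array (n_sites, n_samples); -1 where unknown.
    pops : mapping population name -> list of sample indices.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    haps: np.ndarray
    dp: np.ndarray
    biallelic: np.ndarray
    pops: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def pop_sample_indices(self, population: str) -> np.ndarray:
        try:
            return np.asarray(self.pops[population], dtype=int)
        except KeyError:
            raise KeyError(
                f"unknown population {population!r}; have {sorted(self.pops)}"
            ) from None

    def pop_haps(self, population: str) -> np.ndarray:
        """Haplotype calls for one population, shape (n_sites, 2*n_pop)."""
        idx = self.pop_sample_indices(population)
        h = self.haps[:, idx, :]
        return h.reshape(self.n_sites, 2 * len(idx))

    def take(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Subset sites by boolean mask or index array."""
        return replace(
            self,
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            qual=self.qual[mask],
            haps=self.haps[mask],
            dp=self.dp[mask],
            biallelic=self.biallelic[mask],
        )

    def chrom_sites(self, chrom: str) -> np.ndarray:
        return np.nonzero(self.chrom == chrom)[0]

    def allele_counts(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt count, non-missing allele count) for a population."""
        h = self.pop_haps(population)
        n = (h >= 0).sum(axis=1)
        k = (h == 1).sum(axis=1)
        return k, n


def read_population_map(path: str) -> dict[str, str]:
    """Two-column TSV ``sample_id<TAB>population`` -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["population"]))


def read_vcf(path: str, population_map: dict[str, str] | str) -> GenotypeMatrix:
    """Load SNP records from a VCF into a :class:`GenotypeMatrix`.

    Indel records are skipped; multiallelic SNPs are retained but flagged
    non-biallelic so the filter stage can account for them.  Missing calls
    ("./.") become allele code -1.
    """
    from cyvcf2 import VCF

    if isinstance(population_map, str):
        population_map = read_population_map(population_map)

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    missing_from_vcf = sorted(set(population_map) - set(samples))
    if missing_from_vcf:
        raise ValueError(
            "samples in population map absent from VCF: "
            + ", ".join(missing_from_vcf)
        )

    chroms, poss, refs, alts, quals, biall = [], [], [], [], [], []
    hap_rows, dp_rows = [], []
    n_samples = len(samples)
    for i, v in enumerate(vcf):
        if not v.is_snp:
            continue
        gts = np.array(v.genotype.array(), dtype=np.int16)
        if gts.shape != (n_samples, 3):
            raise ValueError(
                f"malformed genotype record at {path} line for "
                f"{v.CHROM}:{v.POS} (record #{i + 1})"
            )
        alleles = gts[:, :2].astype(np.int8)
        alleles[alleles < 0] = MISSING
        dp = v.format("DP")
        if dp is None:
            dp_row = np.full(n_samples, -1, dtype=np.int32)
        else:
            dp_row = np.asarray(dp, dtype=np.int32).reshape(n_samples)
            dp_row[dp_row < 0] = -1
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)  # 1-based on disk -> 0-based internally
        refs.append(v.REF)
        alts.append(",".join(v.ALT))
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        biall.append(len(v.ALT) == 1)
        hap_rows.append(alleles)
        dp_rows.append(dp_row)
    vcf.close()

    n_sites = len(poss)
    haps = (np.stack(hap_rows) if n_sites else
            np.empty((0, n_samples, 2), dtype=np.int8))
    dps = (np.stack(dp_rows) if n_sites else
           np.empty((0, n_samples), dtype=np.int32))
    pops: dict[str, list[int]] = {}
    for j, s in enumerate(samples):
        if s in population_map:
            pops.setdefault(population_map[s], []).append(j)

    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        qual=np.array(quals, dtype=float),
        haps=haps,
        dp=dps,
        biallelic=np.array(biall, dtype=bool),
        pops=pops,
    )


def apply_site_filters(
    gm: GenotypeMatrix, rules: FilterRules | None = None
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply SNP quality filters; return the filtered matrix and removal counts.

    Genotype calls whose depth falls outside ``[min_depth, max_depth]`` are set
    to missing *before* the missingness and MAF tests.  A site survives if it
    is biallelic, QUAL >= min_site_qual, site-mean depth within bounds,
    missing-call fraction <= max_missing, and pooled MAF >= min_maf.  Removal
    counts attribute each dropped site to its first failing rule, in the order
    biallelic -> qual -> depth -> missing -> maf.
    """
    if rules is None:
        rules = FilterRules()
    counts = {"biallelic": 0, "qual": 0, "depth": 0, "missing": 0, "maf": 0}
    if gm.n_sites == 0:
        warnings.warn("apply_site_filters: empty genotype matrix", stacklevel=2)
        return gm, counts

    haps = gm.haps.copy()
    known_dp = gm.dp >= 0
    bad_dp = known_dp & ((gm.dp < rules.min_depth) | (gm.dp > rules.max_depth))
    haps[bad_dp, :] = MISSING

    ok_biallelic = gm.biallelic if rules.biallelic_only else np.ones(gm.n_sites, bool)
    ok_qual = np.nan_to_num(gm.qual, nan=-np.inf) >= rules.min_site_qual

    with np.errstate(invalid="ignore"):
        dp_f = np.where(known_dp, gm.dp, np.nan).astype(float)
        mean_dp = np.nanmean(dp_f, axis=1)
    # sites with no depth information pass the depth rule
    ok_depth = np.where(
        np.isnan(mean_dp),
        True,
        (mean_dp >= rules.min_depth) & (mean_dp <= rules.max_depth),
    )

    flat = haps.reshape(gm.n_sites, -1)
    n_missing = (flat == MISSING).sum(axis=1)
    ok_missing = n_missing / flat.shape[1] <= rules.max_missing

    n_called = flat.shape[1] - n_missing
    n_alt = ((flat == 1) & ok_biallelic[:, None]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, n_alt / np.maximum(n_called, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    ok_maf = maf >= rules.min_maf

    keep = ok_biallelic & ok_qual & ok_depth & ok_missing & ok_maf
    fail = ~keep
    first = np.full(gm.n_sites, "", dtype=object)
    for name, ok in [("biallelic", ok_biallelic), ("qual", ok_qual),
                     ("depth", ok_depth), ("missing", ok_missing), ("maf", ok_maf)]:
        hit = fail & (first == "") & ~ok
        first[hit] = name
        counts[name] = int(hit.sum())

    out = replace(
        gm,
        chrom=gm.chrom[keep],
        pos=gm.pos[keep],
        ref=gm.ref[keep],
        alt=gm.alt[keep],
        qual=gm.qual[keep],
        haps=haps[keep],
        dp=gm.dp[keep],
        biallelic=gm.biallelic[keep],
    )
    logger.info("site filters kept %d/%d sites (%s)", out.n_sites, gm.n_sites, counts)
    return out, counts


# ---------------------------------------------------------------------------
# annotation and interval formats
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    """Gene annotation table; coordinates 0-based half-open internally."""

    genes: pd.DataFrame  # columns: gene_id, chrom, start, end, strand, single_copy

    def __len__(self) -> int:
        return len(self.genes)

    def single_copy(self) -> pd.DataFrame:
        return self.genes[self.genes["single_copy"]]


def _truthy(val: str) -> bool:
    return str(val).strip().lower() in {"true", "1", "yes"}


def read_gff(path: str) -> GeneSet:
    """Parse gene features from GFF3 (1-based inclusive -> 0-based half-open)."""
    import gffutils
    from gffutils.exceptions import EmptyInputError

    cols = ["gene_id", "chrom", "start", "end", "strand", "single_copy"]
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="error",
        )
    except EmptyInputError:
        return GeneSet(pd.DataFrame(columns=cols))
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        sc = feat.attributes.get("single_copy", ["false"])[0]
        rows.append(
            dict(gene_id=gene_id, chrom=feat.seqid, start=feat.start - 1,
                 end=feat.end, strand=feat.strand, single_copy=_truthy(sc))
        )
    df = pd.DataFrame(rows, columns=cols)
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()
        raise ValueError(f"duplicated gene IDs in {path}: {list(dupes)[:5]}")
    return GeneSet(df)


def write_bed(intervals: pd.DataFrame, path: str, extra_cols: list[str] | None = None
              ) -> None:
    """Write intervals (columns chrom/start/end, 0-based half-open) as BED."""
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    return df


def write_window_table(table: pd.DataFrame, path: str) -> None:
    """Window statistics as TSV with a stable column order."""
    lead = [c for c in ("chrom", "start", "end", "n_snps") if c in table.columns]
    rest = [c for c in table.columns if c not in lead]
    table[lead + rest].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_window_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
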