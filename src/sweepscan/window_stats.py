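"""Sliding-window population-genetic statistics.

Per-window nucleotide diversity (pi), Watterson's theta, Tajima's D and the
Weir & Cockerham (1984) two-population F_ST, plus the folded site frequency
spectrum, LD decay (genotype-dosage r^2 versus physical distance) and the
molecular-clock dating formula T = Ks / (2 r).

All per-bp statistics divide by the true window span, so truncated windows at
chromosome ends are reported on the correct scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix

DEFAULT_WINDOW_SIZE = 50_000
DEFAULT_WINDOW_STEP = 20_000
DEFAULT_MIN_SNPS = 10

# minimum haplotypes for a defined Tajima's D; sites with fewer non-missing
# alleles are excluded from the statistic
MIN_TAJIMA_N = 4


def make_windows(
    chrom_lengths: dict[str, int],
    size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_WINDOW_STEP,
) -> pd.DataFrame:
    """Sliding windows (0-based half-open) covering each chromosome.

    Starts advance by ``step`` while start < chromosome length; the final
    window is truncated at the chromosome end.
    """
    if not (size >= step > 0):
        raise ValueError("require size >= step > 0")
    rows = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + size, length)))
            start += step
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _window_site_index(gm: GenotypeMatrix, window) -> np.ndarray:
    chrom, start, end = window[0], int(window[1]), int(window[2])
    idx = gm.chrom_sites(chrom)
    pos = gm.pos[idx]
    lo = np.searchsorted(pos, start, side="left")
    hi = np.searchsorted(pos, end, side="left")
    return idx[lo:hi]


def _site_pairwise_diversity(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Mean pairwise difference per site: 2 k (n-k) / (n (n-1))."""
    out = np.zeros(len(k), dtype=float)
    ok = n >= 2
    kk, nn = k[ok].astype(float), n[ok].astype(float)
    out[ok] = 2.0 * kk * (nn - kk) / (nn * (nn - 1.0))
    return out


def nucleotide_diversity(gm: GenotypeMatrix, window, population: str) -> float:
    """Windowed pi per bp: sum over sites of 2 p q n/(n-1), over the span."""
    idx = _window_site_index(gm, window)
    span = int(window[2]) - int(window[1])
    if len(idx) == 0:
        return 0.0
    k, n = gm.allele_counts(population)
    k, n = k[idx], n[idx]
    if np.all(n < 2):
        return float("nan")
    return float(_site_pairwise_diversity(k, n).sum() / span)


def harmonic_number(n: int) -> float:
    """a1(n) = sum_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n)))


def wattersons_theta(gm: GenotypeMatrix, window, population: str) -> float:
    """Watterson's theta per bp: S / a1(n) / span, n the modal allele count."""
    idx = _window_site_index(gm, window)
    span = int(window[2]) - int(window[1])
    if len(idx) == 0:
        return 0.0
    k, n = gm.allele_counts(population)
    k, n = k[idx], n[idx]
    seg = (k > 0) & (k < n) & (n >= 2)
    if np.all(n < 2):
        return float("nan")
    s = int(seg.sum())
    if s == 0:
        return 0.0
    vals, cnts = np.unique(n[seg], return_counts=True)
    n_modal = int(vals[np.argmax(cnts)])
    return s / harmonic_number(n_modal) / span


def tajima_constants(n: int) -> dict[str, float]:
    """The standard n-dependent constants of Tajima's D."""
    if n < 2:
        raise ValueError("Tajima constants need n >= 2")
    a1 = harmonic_number(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(gm: GenotypeMatrix, window, population: str) -> float:
    """Tajima's D over a window; NaN when undefined (S = 0 or n too small).

    Sites with fewer than 4 non-missing alleles are excluded; the constants
    use the minimum non-missing allele count across the remaining segregating
    sites (a conservative choice under missing data).
    """
    idx = _window_site_index(gm, window)
    if len(idx) == 0:
        return float("nan")
    k, n = gm.allele_counts(population)
    k, n = k[idx], n[idx]
    use = (n >= MIN_TAJIMA_N) & (k > 0) & (k < n)
    s = int(use.sum())
    if s == 0:
        return float("nan")
    n_win = int(n[use].min())
    pi_sum = _site_pairwise_diversity(k[use], n[use]).sum()
    cc = tajima_constants(n_win)
    var = cc["e1"] * s + cc["e2"] * s * (s - 1)
    if var <= 0:
        return float("nan")
    return float((pi_sum - s / cc["a1"]) / np.sqrt(var))


def _pop_genotype_stats(gm: GenotypeMatrix, population: str
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n individuals with full genotypes, alt freq, het freq)."""
    idx = gm.pop_sample_indices(population)
    h = gm.haps[:, idx, :]
    full = (h >= 0).all(axis=2)
    n_ind = full.sum(axis=1).astype(float)
    dosage = np.where(full, (h == 1).sum(axis=2), 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dosage.sum(axis=1) / (2.0 * n_ind)
        het = np.where(full, (h[..., 0] != h[..., 1]), False).sum(axis=1) / n_ind
    return n_ind, p, het


def _wc_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site variance components for two samples."""
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    return a, b, c


def weir_cockerham_fst(gm: GenotypeMatrix, window, pop_a: str, pop_b: str) -> float:
    """Windowed WC84 F_ST = sum(a) / sum(a+b+c) (ratio-of-sums estimator).

    Negative estimates are reported as computed; NaN when the denominator is
    not positive (no usable variation in the window).
    """
    idx = _window_site_index(gm, window)
    if len(idx) == 0:
        return float("nan")
    n1, p1, h1 = (arr[idx] for arr in _pop_genotype_stats(gm, pop_a))
    n2, p2, h2 = (arr[idx] for arr in _pop_genotype_stats(gm, pop_b))
    ok = (n1 >= 1) & (n2 >= 1)
    if not ok.any():
        return float("nan")
    a, b, c = _wc_components(n1[ok], p1[ok], h1[ok], n2[ok], p2[ok], h2[ok])
    good = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a + b + c)[good].sum()
    if denom <= 0:
        return float("nan")
    return float(a[good].sum() / denom)


def folded_sfs(gm: GenotypeMatrix, population: str, n: int | None = None
               ) -> np.ndarray:
    """Folded SFS: counts indexed by minor-allele count 1..n//2.

    Sites are used at a fixed non-missing allele count ``n`` (default: twice
    the population sample size); sites with missing calls are dropped rather
    than projected.  Monomorphic sites contribute nothing, so the vector sums
    to the number of polymorphic sites used.
    """
    idx = gm.pop_sample_indices(population)
    if n is None:
        n = 2 * len(idx)
    if n < 2:
        raise ValueError("folded SFS needs n >= 2")
    k, nn = gm.allele_counts(population)
    use = nn == n
    k = k[use]
    minor = np.minimum(k, n - k)
    out = np.zeros(n // 2, dtype=np.int64)
    poly = minor[(minor >= 1)]
    np.add.at(out, poly - 1, 1)
    return out


def expected_neutral_folded_sfs(n: int) -> np.ndarray:
    """Neutral expectation, proportional to 1/i + 1/(n-i) (halved at i = n/2)."""
    i = np.arange(1, n // 2 + 1, dtype=float)
    w = 1.0 / i + 1.0 / (n - i)
    w[i == n - i] /= 2.0
    return w / w.sum()


def ld_decay(
    gm: GenotypeMatrix,
    population: str,
    max_dist: int = 200_000,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Mean genotype-dosage r^2 per physical-distance bin (phase-free).

    Missing dosages are mean-imputed per site; monomorphic sites are skipped.
    Returns a table with bin midpoints, mean r^2 and pair counts.
    """
    idx = gm.pop_sample_indices(population)
    if gm.n_sites < 2:
        raise ValueError("LD decay needs at least 2 SNPs")
    h = gm.haps[:, idx, :]
    full = (h >= 0).all(axis=2)
    dosage = np.where(full, (h == 1).sum(axis=2), np.nan).astype(float)
    mean = np.nanmean(dosage, axis=1)
    dosage = np.where(np.isnan(dosage), mean[:, None], dosage)
    sd = dosage.std(axis=1)
    edges = np.linspace(0, max_dist, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in pd.unique(gm.chrom):
        cidx = gm.chrom_sites(chrom)
        cidx = cidx[sd[cidx] > 0]
        pos = gm.pos[cidx]
        z = dosage[cidx] - dosage[cidx].mean(axis=1, keepdims=True)
        z /= z.std(axis=1, keepdims=True)
        m = z.shape[1]
        for a in range(len(cidx) - 1):
            hi = np.searchsorted(pos, pos[a] + max_dist, side="right")
            if hi <= a + 1:
                continue
            r = z[a + 1:hi] @ z[a] / m
            d = pos[a + 1:hi] - pos[a]
            b = np.minimum((d / max_dist * n_bins).astype(int), n_bins - 1)
            np.add.at(sums, b, r**2)
            np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "dist_mid": (edges[:-1] + edges[1:]) / 2.0,
        "mean_r2": mean_r2,
        "n_pairs": counts,
    })


def divergence_date(ks: float, r: float) -> float:
    """Molecular-clock age in years, T = Ks / (2 r)."""
    if r <= 0:
        raise ValueError("substitution rate r must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * r)


@dataclass
class WindowStatsConfig:
    size: int = DEFAULT_WINDOW_SIZE
    step: int = DEFAULT_WINDOW_STEP
    min_snps: int = DEFAULT_MIN_SNPS


def build_window_table(
    gm: GenotypeMatrix,
    windows: pd.DataFrame,
    pop_wild: str,
    pop_cult: str,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> pd.DataFrame:
    """Per-window diversity/differentiation table for two populations.

    Windows with fewer than ``min_snps`` SNPs carry NaN statistics and a
    ``defined`` flag of False; they are kept in the table (for coverage
    accounting) but excluded from downstream percentile ranking.
    """
    kw, nw = gm.allele_counts(pop_wild)
    kc, nc = gm.allele_counts(pop_cult)
    g1 = _pop_genotype_stats(gm, pop_wild)
    g2 = _pop_genotype_stats(gm, pop_cult)

    recs = []
    for chrom, start, end in windows[["chrom", "start", "end"]].itertuples(index=False):
        idx = _window_site_index(gm, (chrom, start, end))
        n_snps = len(idx)
        span = end - start
        rec = dict(chrom=chrom, start=start, end=end, n_snps=n_snps)
        if n_snps >= min_snps:
            rec["pi_wild"] = _site_pairwise_diversity(kw[idx], nw[idx]).sum() / span
            rec["pi_cult"] = _site_pairwise_diversity(kc[idx], nc[idx]).sum() / span
            rec["theta_wild"] = _theta_from_counts(kw[idx], nw[idx], span)
            rec["theta_cult"] = _theta_from_counts(kc[idx], nc[idx], span)
            rec["tajd_wild"] = _tajd_from_counts(kw[idx], nw[idx])
            rec["tajd_cult"] = _tajd_from_counts(kc[idx], nc[idx])
            rec["fst"] = _fst_from_stats(g1, g2, idx)
            rec["defined"] = True
        else:
            for col in ("pi_wild", "pi_cult", "theta_wild", "theta_cult",
                        "tajd_wild", "tajd_cult", "fst"):
                rec[col] = np.nan
            rec["defined"] = False
        recs.append(rec)
    return pd.DataFrame(recs)


def _theta_from_counts(k, n, span):
    seg = (k > 0) & (k < n) & (n >= 2)
    s = int(seg.sum())
    if s == 0:
        return 0.0
    vals, cnts = np.unique(n[seg], return_counts=True)
    return s / harmonic_number(int(vals[np.argmax(cnts)])) / span


def _tajd_from_counts(k, n):
    use = (n >= MIN_TAJIMA_N) & (k > 0) & (k < n)
    s = int(use.sum())
    if s == 0:
        return np.nan
    cc = tajima_constants(int(n[use].min()))
    var = cc["e1"] * s + cc["e2"] * s * (s - 1)
    if var <= 0:
        return np.nan
    pi_sum = _site_pairwise_diversity(k[use], n[use]).sum()
    return (pi_sum - s / cc["a1"]) / np.sqrt(var)


def _fst_from_stats(g1, g2, idx):
    n1, p1, h1 = (arr[idx] for arr in g1)
    n2, p2, h2 = (arr[idx] for arr in g2)
    ok = (n1 >= 1) & (n2 >= 1)
    if not ok.any():
        return np.nan
    a, b, c = _wc_components(n1[ok], p1[ok], h1[ok], n2[ok], p2[ok], h2[ok])
    good = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a + b + c)[good].sum()
    if denom <= 0:
        return np.nan
    return float(a[good].sum() / denom)
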