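"""Cross-population composite-likelihood-ratio (XP-CLR style) sweep scan.

The model: each SNP has reference-population (wild) frequency p1.  Under
neutral drift the object-population (cultivar) pre-sampling frequency q is p1
perturbed with variance omega * p1 (1 - p1), where omega is a genome-wide
drift coefficient estimated by method of moments.  Under a sweep at a focal
point, a lineage sampled at recombination distance r from the selected site
escapes the sweep with probability c = 1 - epsilon**(r/s); with probability
p1 the sweeping haplotype carried the alternate allele.  The pre-drift object
frequency is therefore a two-point mixture, (1-c) + c*p1 with weight p1 and
c*p1 with weight 1-p1, each then drifted.  Drift is modeled as a censored
normal on (0,1): density truncated-normal in shape, with the clipped tails
placed as point masses on 0 and 1.  The observed alternate-allele count k2 of
m2 sampled alleles is binomial given q, integrated over the drift density by
fixed-grid quadrature in the standardized variable.

The window score is CLR = 2 * max_s sum_sites [loglik_sweep(s) - loglik_neutral],
floored at zero, with the focal point at the window midpoint and equal SNP
weights.  Scores are comparable in rank, not in absolute value, to other
implementations of the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from functools import lru_cache

from scipy.special import gammaln, ndtr, roots_legendre, xlog1py, xlogy

from .variant_io import GenotypeMatrix
from .window_stats import DEFAULT_MIN_SNPS

LOG_FLOOR = 1e-300
# below this drift SD a mixture component is numerically a point mass
SIGMA_POINT_MASS = 1e-6
# integration half-width in standardized units
T_MAX = 8.0


@dataclass
class XpclrModel:
    """Parameters of the drift + hitchhiking-escape model."""

    omega: float = 0.05
    s_grid: tuple[float, ...] = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5)
    epsilon: float = 5e-5
    rrate: float = 1e-8  # Morgans per bp
    n_grid: int = 128
    c_min: float = 1e-6
    omega_min: float = 1e-4

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must be in (0, 1)")
        if any(s <= 0 for s in self.s_grid):
            raise ValueError("selection grid values must be positive")
        if self.n_grid < 100:
            raise ValueError("integration grid needs >= 100 points")


@dataclass
class XpclrScore:
    chrom: str
    start: int
    end: int
    clr: float
    s_hat: float
    n_snps: int


def escape_probability(distance_bp, s: float, model: XpclrModel):
    """Probability a lineage recombines off the sweep: 1 - epsilon**(r/s).

    r = rrate * distance in Morgans.  Clamped to [c_min, 1]: at the selected
    site itself escape is never exactly impossible, and far sites behave
    neutrally.
    """
    if s <= 0:
        raise ValueError("s must be positive")
    r = model.rrate * np.asarray(distance_bp, dtype=float)
    c = 1.0 - np.exp(-(r / s) * np.log(1.0 / model.epsilon))
    return np.clip(c, model.c_min, 1.0)


def estimate_omega_from_freqs(
    p1: np.ndarray, p2: np.ndarray, m1: np.ndarray, m2: np.ndarray,
    omega_min: float = 1e-4, min_snps: int = 100,
) -> float:
    """Method-of-moments genome-wide drift coefficient.

    omega = mean[(p1-p2)^2 / (p1 (1-p1))] - mean[1/m1 + 1/m2], floored at
    ``omega_min``; only SNPs with reference frequency in (0.05, 0.95) are
    used.  The subtracted term removes expected binomial sampling variance.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    m1 = np.asarray(m1, float)
    m2 = np.asarray(m2, float)
    use = (p1 > 0.05) & (p1 < 0.95) & (m1 > 0) & (m2 > 0)
    if use.sum() < min_snps:
        raise ValueError(
            f"need >= {min_snps} usable SNPs to estimate omega, have {int(use.sum())}"
        )
    ratio = (p1[use] - p2[use]) ** 2 / (p1[use] * (1 - p1[use]))
    noise = 1.0 / m1[use] + 1.0 / m2[use]
    return float(max(ratio.mean() - noise.mean(), omega_min))


def estimate_omega(
    gm: GenotypeMatrix, pop_ref: str, pop_obj: str,
    omega_min: float = 1e-4, min_snps: int = 100,
) -> float:
    """Genome-wide omega from a genotype matrix (see estimate_omega_from_freqs)."""
    k1, m1 = gm.allele_counts(pop_ref)
    k2, m2 = gm.allele_counts(pop_obj)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(m1 > 0, k1 / np.maximum(m1, 1), np.nan)
        p2 = np.where(m2 > 0, k2 / np.maximum(m2, 1), np.nan)
    ok = (m1 > 0) & (m2 > 0)
    return estimate_omega_from_freqs(
        p1[ok], p2[ok], m1[ok], m2[ok], omega_min=omega_min, min_snps=min_snps
    )


@lru_cache(maxsize=8)
def _gl_nodes(n_grid: int) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = roots_legendre(n_grid)
    return nodes, weights


def _binom_log_const(k2: np.ndarray, m2: np.ndarray) -> np.ndarray:
    return gammaln(m2 + 1) - gammaln(k2 + 1) - gammaln(m2 - k2 + 1)


def _component_likelihood(
    m: np.ndarray, k2: np.ndarray, m2: np.ndarray, log_const: np.ndarray,
    omega: float, n_grid: int,
) -> np.ndarray:
    """Likelihood of (k2 | m2) for one drifted mixture component, vectorized.

    ``m`` is the pre-drift mean; drift variance is omega * m (1-m).  The
    integral over the censored-normal drift density is taken by fixed-order
    Gauss-Legendre quadrature in the standardized variable t = (q - m)/sigma,
    so narrow densities are resolved as well as wide ones; the censored tails
    are point masses at 0 and 1 scored by the binomial atoms.
    """
    m = np.asarray(m, float)
    sigma = np.sqrt(omega * m * (1.0 - m))
    point = sigma < SIGMA_POINT_MASS

    sig = np.where(point, 1.0, sigma)  # placeholder to keep the math finite
    t_lo = np.maximum(-T_MAX, (0.0 - m) / sig)
    t_hi = np.minimum(T_MAX, (1.0 - m) / sig)
    width = t_hi - t_lo
    nodes, wts = _gl_nodes(n_grid)
    mid = (t_lo + t_hi) / 2.0
    t = mid[..., None] + (width[..., None] / 2.0) * nodes  # (..., n_grid)
    q = np.clip(m[..., None] + sig[..., None] * t, 1e-12, 1.0 - 1e-12)
    log_pmf = (log_const[..., None] + xlogy(k2[..., None], q)
               + xlog1py((m2 - k2)[..., None], -q))
    phi = np.exp(-0.5 * t * t) / np.sqrt(2.0 * np.pi)
    integral = np.sum(np.exp(log_pmf) * phi * wts, axis=-1) * width / 2.0

    atom0 = ndtr(-m / sig)
    atom1 = 1.0 - ndtr((1.0 - m) / sig)
    lik = integral + atom0 * (k2 == 0) + atom1 * (k2 == m2)

    # degenerate-variance components collapse to a binomial at the mean
    qm = np.clip(m, 1e-12, 1.0 - 1e-12)
    lik_point = np.exp(log_const + xlogy(k2, qm) + xlog1py(m2 - k2, -qm))
    lik_point = np.where(m <= 1e-12, (k2 == 0).astype(float), lik_point)
    lik_point = np.where(m >= 1 - 1e-12, (k2 == m2).astype(float), lik_point)
    return np.where(point, lik_point, lik)


def site_log_likelihood(p1, k2, m2, model: XpclrModel, c) -> np.ndarray:
    """Log-likelihood of object counts under the sweep mixture (c = 1: neutral).

    Broadcasts over arrays of sites; returns per-site log-likelihoods.
    """
    p1, c = np.broadcast_arrays(np.asarray(p1, float), np.asarray(c, float))
    k2 = np.asarray(k2, float)
    m2 = np.asarray(m2, float)
    if np.any((p1 < 0) | (p1 > 1)):
        raise ValueError("p1 must lie in [0, 1]")
    if np.any((c <= 0) | (c > 1)):
        raise ValueError("c must lie in (0, 1]")
    log_const = _binom_log_const(k2, m2)
    m_hi = (1.0 - c) + c * p1
    m_lo = c * p1
    lik = (p1 * _component_likelihood(m_hi, k2, m2, log_const,
                                      model.omega, model.n_grid)
           + (1.0 - p1) * _component_likelihood(m_lo, k2, m2, log_const,
                                                model.omega, model.n_grid))
    return np.log(np.maximum(lik, LOG_FLOOR))


def _window_freq_data(gm: GenotypeMatrix, idx: np.ndarray,
                      pop_ref: str, pop_obj: str):
    k1, m1 = gm.allele_counts(pop_ref)
    k2, m2 = gm.allele_counts(pop_obj)
    k1, m1, k2, m2 = k1[idx], m1[idx], k2[idx], m2[idx]
    ok = (m1 > 0) & (m2 > 0)
    # pseudocount of 0.5 per allele class keeps p1 off the boundary
    p1 = (k1[ok] + 0.5) / (m1[ok] + 1.0)
    return p1, k2[ok], m2[ok], gm.pos[idx][ok]


def xpclr_window(
    gm: GenotypeMatrix, window, pop_ref: str, pop_obj: str,
    model: XpclrModel, min_snps: int = DEFAULT_MIN_SNPS,
) -> XpclrScore:
    """Composite likelihood ratio for one window, focal point at the midpoint."""
    chrom, start, end = window[0], int(window[1]), int(window[2])
    cidx = gm.chrom_sites(chrom)
    pos = gm.pos[cidx]
    lo = np.searchsorted(pos, start, side="left")
    hi = np.searchsorted(pos, end, side="left")
    idx = cidx[lo:hi]
    p1, k2, m2, spos = _window_freq_data(gm, idx, pop_ref, pop_obj)
    if len(p1) < min_snps:
        return XpclrScore(chrom, start, end, np.nan, np.nan, len(p1))
    focal = (start + end) // 2
    dist = np.abs(spos - focal)
    ll_neutral = site_log_likelihood(p1, k2, m2, model, np.ones_like(p1)).sum()
    best, s_hat = -np.inf, np.nan
    for s in model.s_grid:
        c = escape_probability(dist, s, model)
        ll = site_log_likelihood(p1, k2, m2, model, c).sum()
        if ll > best:
            best, s_hat = ll, s
    clr = 2.0 * max(0.0, best - ll_neutral)
    return XpclrScore(chrom, start, end, float(clr), float(s_hat), len(p1))


def xpclr_scan(
    gm: GenotypeMatrix,
    windows: pd.DataFrame,
    pop_ref: str,
    pop_obj: str,
    model: XpclrModel | None = None,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> pd.DataFrame:
    """Score every window; omega is estimated genome-wide unless given.

    Returns the windows table with ``xpclr``, ``xpclr_s_hat`` and
    ``xpclr_n_snps`` columns appended.
    """
    if model is None:
        omega = estimate_omega(gm, pop_ref, pop_obj)
        model = XpclrModel(omega=omega)
    out = windows.copy()
    n_win = len(windows)

    # gather sites of all scoreable windows into flat arrays so the likelihood
    # evaluations run as a handful of large vectorized operations
    k1a, m1a = gm.allele_counts(pop_ref)
    k2a, m2a = gm.allele_counts(pop_obj)
    parts, win_of_site = [], []
    n_used = np.zeros(n_win, dtype=int)
    for i, w in enumerate(windows.itertuples(index=False)):
        cidx = gm.chrom_sites(w.chrom)
        pos = gm.pos[cidx]
        lo = np.searchsorted(pos, int(w.start), side="left")
        hi = np.searchsorted(pos, int(w.end), side="left")
        idx = cidx[lo:hi]
        ok = (m1a[idx] > 0) & (m2a[idx] > 0)
        idx = idx[ok]
        n_used[i] = len(idx)
        if len(idx) < min_snps:
            continue
        focal = (int(w.start) + int(w.end)) // 2
        parts.append((idx, np.abs(gm.pos[idx] - focal)))
        win_of_site.append(np.full(len(idx), i))

    clr = np.full(n_win, np.nan)
    s_hat = np.full(n_win, np.nan)
    if parts:
        idx = np.concatenate([p[0] for p in parts])
        dist = np.concatenate([p[1] for p in parts])
        wid = np.concatenate(win_of_site)
        p1 = (k1a[idx] + 0.5) / (m1a[idx] + 1.0)
        k2, m2 = k2a[idx], m2a[idx]
        ll_neut = np.bincount(
            wid, weights=site_log_likelihood(p1, k2, m2, model,
                                             np.ones_like(p1)),
            minlength=n_win)
        best = np.full(n_win, -np.inf)
        arg = np.full(n_win, np.nan)
        for s in model.s_grid:
            c = escape_probability(dist, s, model)
            ll = np.bincount(wid,
                             weights=site_log_likelihood(p1, k2, m2, model, c),
                             minlength=n_win)
            better = ll > best
            best[better] = ll[better]
            arg[better] = s
        scored = n_used >= min_snps
        clr[scored] = 2.0 * np.maximum(0.0, (best - ll_neut)[scored])
        s_hat[scored] = arg[scored]

    out["xpclr"] = clr
    out["xpclr_s_hat"] = s_hat
    out["xpclr_n_snps"] = n_used
    return out
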