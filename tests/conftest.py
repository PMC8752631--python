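"""Shared fixtures and oracle helpers for the test suite.

Simulated fixtures are session-scoped (they are the expensive part); tests
that modify a matrix must work on a copy (``gm.take`` copies).
"""

from __future__ import annotations

import numpy as np
import pytest

from sweepscan.simulate import (SimConfig, genotype_matrix_from_sim, simulate)
from sweepscan.variant_io import GenotypeMatrix, apply_site_filters


def gm_from_haps(haps, pops=None, chrom="chr1", pos=None, qual=60.0, dp=20):
    """Build a GenotypeMatrix from a (n_sites, n_haps) 0/1/-1 array.

    Consecutive haplotype columns are paired into diploid samples.
    """
    haps = np.asarray(haps, dtype=np.int8)
    n_sites, n_haps = haps.shape
    assert n_haps % 2 == 0
    n_samples = n_haps // 2
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    if pos is None:
        pos = np.arange(n_sites, dtype=np.int64) * 100 + 100
    if pops is None:
        pops = {"pop1": list(range(n_samples))}
    if np.isscalar(chrom):
        chrom = np.full(n_sites, chrom, dtype=object)
    else:
        chrom = np.asarray(chrom, dtype=object)
    return GenotypeMatrix(
        samples=samples,
        chrom=chrom,
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        qual=np.full(n_sites, float(qual)),
        haps=haps.reshape(n_sites, n_samples, 2),
        dp=np.full((n_sites, n_samples), dp, dtype=np.int32),
        biallelic=np.ones(n_sites, dtype=bool),
        pops=pops,
    )


def brute_force_pi(haps, span):
    """Mean pairwise Hamming distance over haplotype pairs, per bp.

    Independent oracle for nucleotide diversity: at each site every pair of
    non-missing haplotypes is compared directly.
    """
    haps = np.asarray(haps)
    total = 0.0
    for site in haps:
        called = site[site >= 0]
        n = len(called)
        if n < 2:
            continue
        diff = 0
        for i in range(n):
            for j in range(i + 1, n):
                diff += called[i] != called[j]
        total += diff / (n * (n - 1) / 2)
    return total / span


def tajima_constants_oracle(n):
    """Tajima's D constants by literal summation (independent of the package)."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return a1, a2, e1, e2


@pytest.fixture(scope="session")
def sweep_sim():
    """Small two-chromosome simulation with one strong implanted sweep."""
    cfg = SimConfig(n_chrom=2, chrom_length=500_000, seed=11,
                    sweep_loci=((0, 250_000, 1.0),))
    return cfg, simulate(cfg)


@pytest.fixture(scope="session")
def sweep_gm(sweep_sim):
    _cfg, res = sweep_sim
    gm = genotype_matrix_from_sim(res)
    gm_f, _ = apply_site_filters(gm)
    return gm_f


@pytest.fixture(scope="session")
def neutral_single_deme_sim():
    """Neutral, panmictic wild source; used for equilibrium expectations."""
    cfg = SimConfig(n_chrom=1, chrom_length=300_000, seed=23,
                    n_wild_demes=1, sweep_loci=())
    return cfg, simulate(cfg)
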