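"""Windowed diversity statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_pi, gm_from_haps, tajima_constants_oracle
from sweepscan import window_stats as ws


# ---------------------------------------------------------------------- windows

def test_window_enumeration_100kb():
    w = ws.make_windows({"chr1": 100_000})
    assert list(w["start"]) == [0, 20_000, 40_000, 60_000, 80_000]
    assert list(w["end"])[-1] == 100_000  # last window truncated


def test_window_enumeration_50kb():
    w = ws.make_windows({"chr1": 50_000})
    assert list(w[["start", "end"]].itertuples(index=False, name=None)) == [
        (0, 50_000), (20_000, 50_000), (40_000, 50_000)]


def test_short_chromosome_single_window():
    w = ws.make_windows({"chr1": 10})
    assert list(w.itertuples(index=False, name=None)) == [("chr1", 0, 10)]


def test_invalid_window_geometry_rejected():
    with pytest.raises(ValueError):
        ws.make_windows({"chr1": 1000}, size=10, step=20)


# --------------------------------------------------------------------------- pi

def test_pi_single_site_example():
    # 4 haplotypes split 2/2 in a 10-kb window: 2*0.25*(4/3) = 2/3 per site
    gm = gm_from_haps([[0, 0, 1, 1]], pos=[500])
    pi = ws.nucleotide_diversity(gm, ("chr1", 0, 10_000), "pop1")
    assert pi == pytest.approx((2 / 3) / 10_000)
    # equals mean pairwise differences 4/6 over C(4,2) pairs
    assert pi == pytest.approx(brute_force_pi([[0, 0, 1, 1]], 10_000))


def test_pi_two_haplotypes_k_over_l():
    haps = np.zeros((7, 2), dtype=int)
    haps[:4, 1] = 1  # k = 4 differing sites
    gm = gm_from_haps(haps, pos=np.arange(7) * 10)
    assert ws.nucleotide_diversity(gm, ("chr1", 0, 1000), "pop1") == \
        pytest.approx(4 / 1000)


def test_pi_no_segregating_sites_is_zero():
    gm = gm_from_haps(np.zeros((3, 8), dtype=int))
    assert ws.nucleotide_diversity(gm, ("chr1", 0, 1000), "pop1") == 0.0


def test_pi_matches_brute_force_on_random_matrices():
    """Frequency-formula pi == pairwise-Hamming average, incl. missing data."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        n_sites = rng.integers(1, 12)
        n_haps = 2 * rng.integers(2, 7)
        haps = rng.integers(0, 2, size=(n_sites, n_haps))
        miss = rng.random(haps.shape) < 0.15
        haps = np.where(miss, -1, haps)
        gm = gm_from_haps(haps, pos=np.sort(
            rng.choice(5000, size=n_sites, replace=False)))
        pi = ws.nucleotide_diversity(gm, ("chr1", 0, 5000), "pop1")
        expected = brute_force_pi(haps, 5000)
        assert pi == pytest.approx(expected, abs=1e-12)


# ------------------------------------------------------------------------ theta

def test_wattersons_theta_examples():
    gm0 = gm_from_haps(np.zeros((2, 4), dtype=int))
    assert ws.wattersons_theta(gm0, ("chr1", 0, 1000), "pop1") == 0.0

    gm2 = gm_from_haps([[0, 1], [0, 1]], pos=[10, 20])  # n=2: a1 = 1
    assert ws.wattersons_theta(gm2, ("chr1", 0, 1000), "pop1") == \
        pytest.approx(2 / 1000)

    haps = np.zeros((3, 4), dtype=int)
    haps[:, 0] = 1  # 3 segregating sites, n = 4
    gm4 = gm_from_haps(haps, pos=[10, 20, 30])
    a1 = 1 + 1 / 2 + 1 / 3
    assert ws.wattersons_theta(gm4, ("chr1", 0, 1000), "pop1") == \
        pytest.approx(3 / a1 / 1000)
    assert 3 / a1 / 1000 == pytest.approx(1.636e-3, rel=1e-3)


# --------------------------------------------------------------------- tajima d

def test_tajimas_d_four_haplotype_singletons():
    """n = 4 with 3 singletons: D ~ -0.75 per constant-by-constant evaluation."""
    haps = np.zeros((3, 4), dtype=int)
    haps[0, 0] = haps[1, 1] = haps[2, 2] = 1
    gm = gm_from_haps(haps, pos=[10, 20, 30])
    d = ws.tajimas_d(gm, ("chr1", 0, 1000), "pop1")

    a1, a2, e1, e2 = tajima_constants_oracle(4)
    s = 3
    pi_sum = 3 * (2 * 1 * 3 / (4 * 3))  # three singletons
    expected = (pi_sum - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))
    assert d == pytest.approx(expected, abs=1e-12)
    assert d == pytest.approx(-0.75, abs=0.01)


def test_tajimas_d_zero_when_pi_equals_watterson():
    # n = 4: 8 singletons (0.5 each) + 3 doubletons (2/3 each) give
    # Pi = 6 = S/a1 = 11/(11/6) exactly
    haps = np.zeros((11, 4), dtype=int)
    for i in range(8):
        haps[i, i % 4] = 1
    haps[8:, :2] = 1
    gm = gm_from_haps(haps, pos=np.arange(11) * 10 + 10)
    assert ws.tajimas_d(gm, ("chr1", 0, 1000), "pop1") == pytest.approx(0.0,
                                                                        abs=1e-12)


def test_tajimas_d_sign_structure():
    n = 8
    singles = np.zeros((6, n), dtype=int)
    for i in range(6):
        singles[i, i % n] = 1
    inter = np.zeros((6, n), dtype=int)
    inter[:, : n // 2] = 1
    gm_s = gm_from_haps(singles, pos=np.arange(6) * 10 + 10)
    gm_i = gm_from_haps(inter, pos=np.arange(6) * 10 + 10)
    d_s = ws.tajimas_d(gm_s, ("chr1", 0, 1000), "pop1")
    d_i = ws.tajimas_d(gm_i, ("chr1", 0, 1000), "pop1")
    assert d_s < 0 < d_i


def test_tajimas_d_undefined_when_no_segregating_sites():
    gm = gm_from_haps(np.zeros((2, 8), dtype=int))
    assert np.isnan(ws.tajimas_d(gm, ("chr1", 0, 1000), "pop1"))


# -------------------------------------------------------------------------- fst

def wc84_oracle(n1, p1, h1, n2, p2, h2):
    """Literal transcription of the two-population WC84 component formulas."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                     / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def test_fst_fixed_difference_is_one():
    haps = np.array([[0] * 20 + [1] * 20])
    gm = gm_from_haps(haps, pops={"A": list(range(10)),
                                  "B": list(range(10, 20))}, pos=[50])
    assert ws.weir_cockerham_fst(gm, ("chr1", 0, 100), "A", "B") == \
        pytest.approx(1.0)


def test_fst_identical_populations_not_positive():
    rng = np.random.default_rng(3)
    block = rng.integers(0, 2, size=(5, 12))
    haps = np.concatenate([block, block], axis=1)
    gm = gm_from_haps(haps, pops={"A": list(range(6)),
                                  "B": list(range(6, 12))},
                      pos=np.arange(5) * 10 + 10)
    fst = ws.weir_cockerham_fst(gm, ("chr1", 0, 100), "A", "B")
    assert fst <= 1e-12


def test_fst_matches_hand_evaluated_components():
    """Unequal sample sizes, two sites, vs a step-by-step WC84 transcription."""
    # pop A: 4 diploids, pop B: 7 diploids
    a_gts = [
        [(0, 1), (0, 1), (1, 1), (0, 0)],
        [(0, 0), (0, 1), (0, 0), (0, 0)],
    ]
    b_gts = [
        [(1, 1), (1, 1), (0, 1), (1, 1), (1, 1), (0, 1), (1, 1)],
        [(0, 1), (0, 0), (0, 0), (0, 1), (0, 0), (0, 0), (0, 1)],
    ]
    haps = np.array([[al for gt in site_a + site_b for al in gt]
                     for site_a, site_b in zip(a_gts, b_gts)])
    gm = gm_from_haps(haps, pops={"A": list(range(4)),
                                  "B": list(range(4, 11))}, pos=[10, 20])
    got = ws.weir_cockerham_fst(gm, ("chr1", 0, 100), "A", "B")

    num = den = 0.0
    for site_a, site_b in zip(a_gts, b_gts):
        p1 = sum(sum(gt) for gt in site_a) / (2 * len(site_a))
        p2 = sum(sum(gt) for gt in site_b) / (2 * len(site_b))
        h1 = sum(gt[0] != gt[1] for gt in site_a) / len(site_a)
        h2 = sum(gt[0] != gt[1] for gt in site_b) / len(site_b)
        a, b, c = wc84_oracle(len(site_a), p1, h1, len(site_b), p2, h2)
        num += a
        den += a + b + c
    assert got == pytest.approx(num / den, abs=1e-12)


def test_fst_undefined_without_usable_variation():
    gm = gm_from_haps(np.zeros((1, 8), dtype=int),
                      pops={"A": [0, 1], "B": [2, 3]}, pos=[10])
    assert np.isnan(ws.weir_cockerham_fst(gm, ("chr1", 0, 100), "A", "B"))


# -------------------------------------------------------------------------- sfs

def test_folded_sfs_bin_placement():
    n = 8
    single = np.zeros((1, n), dtype=int)
    single[0, 0] = 1
    gm = gm_from_haps(single, pos=[10])
    sfs = ws.folded_sfs(gm, "pop1")
    assert len(sfs) == n // 2 and sfs[0] == 1 and sfs.sum() == 1

    half = np.zeros((1, n), dtype=int)
    half[0, : n // 2] = 1
    sfs2 = ws.folded_sfs(gm_from_haps(half, pos=[10]), "pop1")
    assert sfs2[n // 2 - 1] == 1 and sfs2.sum() == 1


def test_folded_sfs_counts_polymorphic_sites():
    rng = np.random.default_rng(5)
    haps = rng.integers(0, 2, size=(40, 12))
    gm = gm_from_haps(haps, pos=np.arange(40) * 10 + 10)
    sfs = ws.folded_sfs(gm, "pop1")
    k = haps.sum(axis=1)
    assert sfs.sum() == int(((k > 0) & (k < 12)).sum())


def test_folded_sfs_rejects_tiny_n():
    gm = gm_from_haps(np.zeros((1, 4), dtype=int), pos=[10])
    with pytest.raises(ValueError):
        ws.folded_sfs(gm, "pop1", n=1)


# --------------------------------------------------------------------------- ld

def test_ld_duplicated_site_r2_is_one():
    rng = np.random.default_rng(9)
    col = rng.integers(0, 2, size=40)
    haps = np.stack([col, col])
    gm = gm_from_haps(haps, pos=[100, 200])
    out = ws.ld_decay(gm, "pop1", max_dist=1000, n_bins=1)
    assert out["mean_r2"].iloc[0] == pytest.approx(1.0)
    assert out["n_pairs"].iloc[0] == 1


def test_ld_independent_sites_small_sample_bias():
    """Dosage r^2 between independent sites averages ~ 1/(n_ind - 1)."""
    rng = np.random.default_rng(11)
    n_ind, n_sites = 100, 600
    dosage_p = 0.4
    haps = (rng.random((n_sites, 2 * n_ind)) < dosage_p).astype(int)
    gm = gm_from_haps(haps, pos=np.arange(n_sites) + 1)
    out = ws.ld_decay(gm, "pop1", max_dist=2, n_bins=1)  # adjacent pairs only
    expected = 1 / (n_ind - 1)
    assert out["mean_r2"].iloc[0] == pytest.approx(expected, rel=0.25)


# ------------------------------------------------------------------------ dates

@pytest.mark.parametrize("ks,r,expected", [
    (0.0, 1e-8, 0.0),
    (0.2, 1e-8, 1.0e7),
    (0.35, 4.175e-9, 0.35 / (2 * 4.175e-9)),
])
def test_divergence_date(ks, r, expected):
    assert ws.divergence_date(ks, r) == pytest.approx(expected)


def test_divergence_date_rejects_nonpositive_rate():
    with pytest.raises(ValueError):
        ws.divergence_date(0.1, 0.0)


# --------------------------------------------------------------- invariances

def test_window_stats_invariant_to_sample_and_site_order(sweep_gm):
    gm = sweep_gm
    win = ("chr1", 100_000, 150_000)
    base = (ws.nucleotide_diversity(gm, win, "wild"),
            ws.tajimas_d(gm, win, "cultivar"),
            ws.weir_cockerham_fst(gm, win, "wild", "cultivar"))

    rng = np.random.default_rng(0)
    perm = rng.permutation(gm.n_samples)
    import dataclasses
    gm2 = dataclasses.replace(
        gm, haps=gm.haps[:, perm, :], dp=gm.dp[:, perm],
        samples=[gm.samples[i] for i in perm],
        pops={p: sorted(int(np.nonzero(perm == i)[0][0]) for i in idx)
              for p, idx in gm.pops.items()},
    )
    shuffled = (ws.nucleotide_diversity(gm2, win, "wild"),
                ws.tajimas_d(gm2, win, "cultivar"),
                ws.weir_cockerham_fst(gm2, win, "wild", "cultivar"))
    assert shuffled == pytest.approx(base, nan_ok=True)


def test_build_window_table_flags_sparse_windows(sweep_gm):
    win = pd.DataFrame({"chrom": ["chr1", "chr1"],
                        "start": [0, 0], "end": [50_000, 200]})
    tab = ws.build_window_table(sweep_gm, win, "wild", "cultivar", min_snps=10)
    assert bool(tab["defined"].iloc[0])
    assert not bool(tab["defined"].iloc[1])
    assert np.isnan(tab["fst"].iloc[1])
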