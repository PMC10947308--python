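import itertools

import numpy as np
import pandas as pd
import pytest

from snapmap import qtlscan
from snapmap.core_io import GeneticMap, MISSING
from snapmap.qtlscan import (fit_qtl, genotype_probs, lod_interval,
                             permutation_threshold, project_intervals,
                             qtl_overlap_binomial, scan_trait, scanone,
                             stepwise_additive)


def make_map(positions, group=1):
    rows = [(f"m{j}", group, float(cm), f"Chr{group}", j)
            for j, cm in enumerate(positions)]
    return GeneticMap(pd.DataFrame(
        rows, columns=["marker", "group", "cm", "chrom", "bp"]), 6.0, 10.0)


def random_codes(rng, positions, n):
    """F2 species codes for markers at the given cM positions (one group)."""
    pos = np.asarray(positions, dtype=float)
    g = []
    for _ in range(2 * n):
        n_x = rng.poisson(pos.max() / 100)
        breaks = np.sort(rng.uniform(0, pos.max(), n_x))
        start = rng.integers(2)
        g.append((start + np.searchsorted(breaks, pos)) % 2)
    g = np.array(g)
    codes = (g[:n] + g[n:]).astype(np.int8).T  # (markers, n)
    return {f"m{j}": codes[j] for j in range(len(pos))}


# ---------------------------------------------------------------------------
# genotype probabilities


def test_typed_marker_probability_one_at_zero_eps():
    gmap = make_map([0.0, 10.0])
    codes = {"m0": np.array([0, 1, 2], dtype=np.int8),
             "m1": np.array([2, 1, 0], dtype=np.int8)}
    gp = genotype_probs(gmap, codes, step=1.0, eps=0.0)
    pos = gp.positions[0]
    for mj, cm in ((0, 0.0), (1, 10.0)):
        pi = np.nonzero((pos == cm) & gp.is_marker[0])[0][0]
        for i, g in enumerate(codes[f"m{mj}"]):
            assert gp.probs[0][i, pi, g] == pytest.approx(1.0)


def test_all_missing_returns_prior():
    gmap = make_map([0.0, 10.0])
    codes = {"m0": np.full(4, MISSING, dtype=np.int8),
             "m1": np.full(4, MISSING, dtype=np.int8)}
    gp = genotype_probs(gmap, codes)
    assert np.allclose(gp.probs[0], [0.25, 0.5, 0.25])


def test_midpoint_between_opposite_homozygotes_is_het():
    gmap = make_map([0.0, 20.0])
    codes = {"m0": np.array([0], dtype=np.int8),
             "m1": np.array([2], dtype=np.int8)}
    gp = genotype_probs(gmap, codes, step=1.0, eps=0.0)
    pos = gp.positions[0]
    pi = np.nonzero(pos == 10.0)[0][0]
    p = gp.probs[0][0, pi]
    assert p[1] == max(p)


def test_probabilities_sum_to_one_and_match_marker_data():
    rng = np.random.default_rng(0)
    positions = [0, 7, 18, 33, 50]
    codes = random_codes(rng, positions, 80)
    gp = genotype_probs(make_map(positions), codes)
    assert np.allclose(gp.probs[0].sum(axis=2), 1.0)
    # at eps=0.001 the typed genotype dominates at its own marker
    pos = gp.positions[0]
    for j, cm in enumerate(positions):
        pi = np.nonzero((pos == cm) & gp.is_marker[0])[0][0]
        g = codes[f"m{j}"]
        assert (gp.probs[0][np.arange(80), pi, g] > 0.95).all()


# ---------------------------------------------------------------------------
# scanone


def anova_lod(x, z, y):
    """Direct regression oracle: LOD = (n/2) log10(RSS0/RSS1)."""
    n = len(y)
    X1 = np.column_stack([np.ones(n), x, z])
    rss1 = np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2)
    rss0 = np.sum((y - y.mean()) ** 2)
    return (n / 2) * np.log10(rss0 / rss1)


def test_scanone_matches_regression_oracle_at_markers():
    rng = np.random.default_rng(1)
    positions = [0, 10, 25, 40]
    codes = random_codes(rng, positions, 120)
    gp = genotype_probs(make_map(positions), codes, eps=0.0)
    y = rng.normal(size=120) + 0.8 * (codes["m2"] - 1)
    lod = scanone(gp, y)
    pos = gp.positions[0]
    for j, cm in enumerate(positions):
        pi = np.nonzero((pos == cm) & gp.is_marker[0])[0][0]
        g = codes[f"m{j}"]
        x = (g == 0).astype(float) - (g == 2).astype(float)
        z = (g == 1).astype(float)
        assert lod[pi] == pytest.approx(anova_lod(x, z, y), abs=1e-8)


def test_scanone_null_trait_small_lod():
    rng = np.random.default_rng(2)
    positions = np.linspace(0, 50, 11)
    codes = random_codes(rng, positions, 200)
    gp = genotype_probs(make_map(positions), codes)
    y = rng.normal(size=200)
    lod = scanone(gp, y)
    assert lod.max() < 3.5


def test_scanone_rejects_constant_or_nan_phenotype():
    rng = np.random.default_rng(3)
    codes = random_codes(rng, [0, 10], 20)
    gp = genotype_probs(make_map([0, 10]), codes)
    with pytest.raises(ValueError):
        scanone(gp, np.zeros(20))
    y = rng.normal(size=20)
    y[0] = np.nan
    with pytest.raises(ValueError):
        scanone(gp, y)


def test_scanone_matrix_matches_columnwise():
    rng = np.random.default_rng(4)
    positions = [0, 15, 30]
    codes = random_codes(rng, positions, 100)
    gp = genotype_probs(make_map(positions), codes)
    Y = rng.normal(size=(100, 3))
    lod_mat = scanone(gp, Y)
    for k in range(3):
        assert np.allclose(lod_mat[:, k], scanone(gp, Y[:, k]))


# ---------------------------------------------------------------------------
# permutations


def test_permutation_threshold_reproducible_and_alpha_one():
    rng = np.random.default_rng(5)
    positions = [0, 12, 30]
    codes = random_codes(rng, positions, 80)
    gp = genotype_probs(make_map(positions), codes)
    y = rng.normal(size=80)
    t1 = permutation_threshold(gp, y, n_perm=200, alpha=0.05, seed=9)
    t2 = permutation_threshold(gp, y, n_perm=200, alpha=0.05, seed=9)
    assert t1 == t2
    tmin = permutation_threshold(gp, y, n_perm=200, alpha=1.0, seed=9)
    assert tmin <= t1


def test_permutation_threshold_grows_with_marker_count():
    rng = np.random.default_rng(6)
    y = rng.normal(size=150)
    few = random_codes(np.random.default_rng(7), [0, 50], 150)
    many = random_codes(np.random.default_rng(7), np.linspace(0, 50, 26), 150)
    t_few = permutation_threshold(
        genotype_probs(make_map([0, 50]), few), y, 400, 0.05, seed=1)
    t_many = permutation_threshold(
        genotype_probs(make_map(np.linspace(0, 50, 26)), many), y, 400, 0.05,
        seed=1)
    assert t_many > t_few


# ---------------------------------------------------------------------------
# model fitting and stepwise search


def two_group_gp(rng, n=216, effect=None):
    positions = np.linspace(0, 50, 11)
    codes1 = random_codes(rng, positions, n)
    codes2 = {f"n{j}": v for j, (k, v) in
              enumerate(random_codes(rng, positions, n).items())}
    rows = [(f"m{j}", 1, float(cm), "Chr1", j)
            for j, cm in enumerate(positions)]
    rows += [(f"n{j}", 2, float(cm), "Chr2", j)
             for j, cm in enumerate(positions)]
    gmap = GeneticMap(pd.DataFrame(
        rows, columns=["marker", "group", "cm", "chrom", "bp"]), 6.0, 10.0)
    return gmap, {**codes1, **codes2}


def test_fit_noiseless_monogenic_pve_total_one():
    rng = np.random.default_rng(8)
    positions = [0, 10, 25, 40]
    codes = random_codes(rng, positions, 150)
    gp = genotype_probs(make_map(positions), codes, eps=0.0)
    y = (codes["m1"] == 0) * 1.0 - (codes["m1"] == 2) * 1.0
    fit = fit_qtl(gp, [(1, 10.0)], y)
    assert fit["pve_total"] == pytest.approx(1.0, abs=1e-9)
    assert fit["additive"][0] == pytest.approx(1.0, abs=1e-9)


def test_fit_full_dominance_heterozygote_equals_bb():
    rng = np.random.default_rng(9)
    positions = [0, 10, 25, 40]
    codes = random_codes(rng, positions, 400)
    gp = genotype_probs(make_map(positions), codes, eps=0.0)
    g = codes["m2"]
    value = {0: 1.0, 1: 1.0, 2: -1.0}  # b fully dominant
    y = np.array([value[int(v)] for v in g]) + rng.normal(0, 0.3, 400)
    fit = fit_qtl(gp, [(1, 25.0)], y)
    # with a = d, the heterozygote mean equals the bb mean
    assert fit["additive"][0] == pytest.approx(fit["dominance"][0], abs=0.1)


def test_fit_rejects_collinear_positions():
    rng = np.random.default_rng(10)
    codes = random_codes(rng, [0, 10], 50)
    gp = genotype_probs(make_map([0, 10]), codes)
    with pytest.raises(ValueError, match="collinear"):
        fit_qtl(gp, [(1, 5.0), (1, 5.5)], rng.normal(size=50))


def test_fit_drop_one_pve_decomposes_total_for_orthogonal_qtl():
    # balanced 9-way factorial of the two QTL genotypes: the design columns
    # of the two loci are exactly orthogonal, so the drop-one variance
    # contributions must partition the joint PVE exactly
    combos = np.array([(a, b) for a in (0, 1, 2) for b in (0, 1, 2)])
    codes = {"m0": np.repeat(combos[:, 0], 24).astype(np.int8),
             "n0": np.repeat(combos[:, 1], 24).astype(np.int8)}
    rows = [("m0", 1, 25.0, "Chr1", 0), ("n0", 2, 25.0, "Chr2", 0)]
    gmap = GeneticMap(pd.DataFrame(
        rows, columns=["marker", "group", "cm", "chrom", "bp"]), 6.0, 10.0)
    gp = genotype_probs(gmap, codes, eps=0.0)
    rng = np.random.default_rng(11)
    y = (0.7 * (codes["m0"] - 1.0) + 0.6 * (codes["n0"] - 1.0)
         + rng.normal(0, 1, 216))
    fit = fit_qtl(gp, [(1, 25.0), (2, 25.0)], y)
    assert sum(fit["pve"]) == pytest.approx(fit["pve_total"], abs=1e-10)
    assert 0 < fit["pve_total"] < 1


def test_stepwise_recovers_two_unlinked_qtl():
    rng = np.random.default_rng(12)
    gmap, codes = two_group_gp(rng)
    gp = genotype_probs(gmap, codes)
    y = (0.8 * (codes["m5"] - 1) + 0.7 * (codes["n5"] - 1)
         + rng.normal(0, 1, 216))
    model = stepwise_additive(gp, y, threshold=3.5)
    assert sorted(g for g, _ in model) == [1, 2]
    for g, cm in model:
        assert abs(cm - 25.0) < 12


def test_stepwise_opposite_signs_recoverable():
    rng = np.random.default_rng(13)
    gmap, codes = two_group_gp(rng)
    gp = genotype_probs(gmap, codes)
    y = (0.8 * (codes["m5"] - 1) - 0.8 * (codes["n5"] - 1)
         + rng.normal(0, 1, 216))
    model = stepwise_additive(gp, y, threshold=3.5)
    assert sorted(g for g, _ in model) == [1, 2]
    fit = fit_qtl(gp, model, y)
    signs = sorted(np.sign(fit["additive"][np.argsort([g for g, _ in model])]))
    assert signs == [-1.0, 1.0]


def test_stepwise_null_trait_usually_empty():
    rng = np.random.default_rng(14)
    gmap, codes = two_group_gp(rng)
    gp = genotype_probs(gmap, codes)
    empty = 0
    for rep in range(20):
        y = rng.normal(size=216)
        thr = permutation_threshold(gp, y, 200, 0.05, seed=rep)
        if not stepwise_additive(gp, y, thr):
            empty += 1
    assert empty >= 16  # ~95% expected


# ---------------------------------------------------------------------------
# intervals


def test_lod_interval_symmetric_profile():
    pos = np.linspace(0, 20, 21)
    lod = 5.0 - 0.1 * (pos - 10) ** 2
    lo, hi = lod_interval(pos, lod, peak=10, drop=1)
    assert lo == pytest.approx(20 - hi)
    assert lo <= 10 - np.sqrt(10) + 1 <= hi


def test_lod_interval_clipped_at_end():
    pos = np.linspace(0, 20, 21)
    lod = pos * 0.2
    lo, hi = lod_interval(pos, lod, peak=20, drop=2)
    assert hi == 20.0 and lo < 20.0


def test_lod_interval_nesting():
    rng = np.random.default_rng(15)
    pos = np.linspace(0, 30, 31)
    lod = np.abs(np.cumsum(rng.normal(size=31)))
    peak = int(np.argmax(lod))
    lo1, hi1 = lod_interval(pos, lod, peak, drop=1)
    lo2, hi2 = lod_interval(pos, lod, peak, drop=2)
    assert lo2 <= lo1 and hi2 >= hi1


def test_lod_interval_rejects_other_drops():
    with pytest.raises(ValueError):
        lod_interval(np.arange(3.0), np.zeros(3), 1, drop=3)


# ---------------------------------------------------------------------------
# scan_trait integration


def test_scan_trait_full_pipeline():
    rng = np.random.default_rng(16)
    gmap, codes = two_group_gp(rng)
    gp = genotype_probs(gmap, codes)
    y = 0.9 * (codes["m5"] - 1) + rng.normal(0, 1, 216)
    res = scan_trait(gp, y, "T", n_perm=300, seed=17)
    assert res.trait == "T"
    assert len(res.qtl) >= 1
    q = res.qtl[0]
    assert q.group == 1 and abs(q.pos_cm - 25.0) < 12
    assert q.interval_2lod[0] <= q.pos_cm <= q.interval_2lod[1]
    i1, i2 = q.interval_1lod, q.interval_2lod
    assert i2[0] <= i1[0] and i2[1] >= i1[1]
    assert 0 < res.pve_total < 1


# ---------------------------------------------------------------------------
# overlap test


def enumeration_oracle(k, n, p):
    total = 0.0
    for bits in itertools.product((0, 1), repeat=n):
        s = sum(bits)
        if s >= k:
            total += p ** s * (1 - p) ** (n - s)
    return total


def test_overlap_three_of_five():
    p = qtl_overlap_binomial(3, 5, 0.115)
    assert p == pytest.approx(0.0127, abs=5e-4)
    assert round(p, 2) == 0.01


def test_overlap_one_of_one_trichome():
    coverage = 10 / (60 / 0.115)
    assert coverage == pytest.approx(0.019167, abs=1e-5)
    p = qtl_overlap_binomial(1, 1, coverage)
    assert round(p, 2) == 0.02


def test_overlap_k_zero_is_one():
    assert qtl_overlap_binomial(0, 7, 0.3) == 1.0


@pytest.mark.parametrize("n", [1, 4, 7, 10])
def test_overlap_matches_enumeration(n):
    rng = np.random.default_rng(n)
    p = float(rng.uniform(0.05, 0.5))
    for k in range(n + 1):
        assert qtl_overlap_binomial(k, n, p) == pytest.approx(
            enumeration_oracle(k, n, p), abs=1e-12)


def test_overlap_validates_inputs():
    with pytest.raises(ValueError):
        qtl_overlap_binomial(6, 5, 0.1)
    with pytest.raises(ValueError):
        qtl_overlap_binomial(1, 5, 1.5)


def test_project_intervals():
    ref = [("Chr1", 0.0, 30.0), ("Chr1", 20.0, 40.0), ("Chr2", 0.0, 20.0)]
    qtl = [("Chr1", 40.0), ("Chr1", 10.0), ("Chr2", 25.0), ("Chr3", 5.0)]
    k, cov = project_intervals(qtl, ref, genome_length=521.7)
    # merged: Chr1 [0,40), Chr2 [0,20) -> 60 units; boundary 40.0 is outside
    assert k == 1
    assert cov == pytest.approx(60 / 521.7)
    assert cov == pytest.approx(0.115, abs=1e-3)
    k0, cov0 = project_intervals(qtl, [], genome_length=100.0)
    assert k0 == 0 and cov0 == 0.0
    k_edge, _ = project_intervals([("Chr2", 0.0)], ref, 100.0)
    assert k_edge == 1  # start boundary inside (half-open convention)
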