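from itertools import permutations

import numpy as np
import pytest
from scipy import stats

from slickmap.assoc import (
    HaplotypeBlock,
    adaptive_permutation,
    detect_blocks,
    dprime_ci,
    ld_r2_em,
    make_trend_stat,
    mixed_model_assoc,
    pattern_assoc,
)
from slickmap.intervals import GenomicInterval
from slickmap.io import (
    MISSING,
    GenotypeMatrix,
    HaplotypeSet,
    make_sample_table,
    make_variant_table,
)
from slickmap.popstruct import KinshipMatrix, kinship


def _gm(calls):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypeMatrix(
        make_sample_table([f"s{i}" for i in range(n)]),
        make_variant_table([f"v{j}" for j in range(m)], ["1"] * m,
                           np.arange(1, m + 1) * 1000, ["A"] * m, ["G"] * m),
        calls,
    )


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------


def test_identity_kinship_reduces_to_ols(rng):
    n, m = 40, 30
    calls = rng.integers(0, 3, (n, m)).astype(np.int8)
    y = rng.random(n)
    gm = _gm(calls)
    K = KinshipMatrix(gm.sample_ids(), np.eye(n), "grm")
    res = mixed_model_assoc(gm, y, K)
    for j in range(m):
        g = calls[:, j].astype(float)
        if np.ptp(g) == 0:
            assert np.isnan(res.p_asymptotic[j])
            continue
        slope, intercept, r, p, se = stats.linregress(g, y)
        assert res.p_asymptotic[j] == pytest.approx(p, abs=1e-6)
        assert res.beta[j] == pytest.approx(slope, abs=1e-8)


def test_mixed_model_invariant_to_joint_sample_reorder(rng):
    n, m = 30, 20
    calls = rng.integers(0, 3, (n, m)).astype(np.int8)
    y = rng.integers(0, 2, n).astype(float)
    y[0], y[1] = 0, 1  # non-constant
    gm = _gm(calls)
    K = kinship(gm, "grm")
    res = mixed_model_assoc(gm, y, K)
    perm = rng.permutation(n)
    gm_p = gm.subset(sample_idx=perm)
    K_p = kinship(gm_p, "grm")
    res_p = mixed_model_assoc(gm_p, y[perm], K_p)
    assert np.allclose(res_p.p_asymptotic, res.p_asymptotic, atol=1e-8, equal_nan=True)


def test_mixed_model_input_validation(rng):
    gm = _gm(rng.integers(0, 3, (10, 5)).astype(np.int8))
    K = KinshipMatrix(gm.sample_ids(), np.eye(10), "grm")
    with pytest.raises(ValueError, match="constant"):
        mixed_model_assoc(gm, np.ones(10), K)
    K_bad = KinshipMatrix(list("abcdefghij"), np.eye(10), "grm")
    with pytest.raises(ValueError, match="aligned"):
        mixed_model_assoc(gm, np.arange(10.0), K_bad)


def test_causal_locus_tops_scan_with_kinship_correction(small_cohort):
    gm = small_cohort.genotypes
    y = (gm.samples["phenotype"] == "slick").to_numpy().astype(float)
    K = kinship(gm, "grm")
    res = mixed_model_assoc(gm, y, K)
    top = np.nanargmin(res.p_asymptotic)
    assert abs(top - small_cohort.truth["causal_index"]) <= 5


# ---------------------------------------------------------------------------
# adaptive permutation
# ---------------------------------------------------------------------------


def test_permutation_add_one_rule(rng):
    # an observed statistic larger than anything attainable -> p = 1/(n+1)
    calls = rng.integers(0, 3, (12, 4)).astype(np.int8)
    gm = _gm(calls)
    y = rng.integers(0, 2, 12).astype(float)
    y[:2] = [0, 1]
    obs = np.full(4, 1e12)
    p, done = adaptive_permutation(gm, y, obs, max_perm=999, seed=1)
    assert np.allclose(p, 1.0 / 1000)
    assert (done == 999).all()


def test_permutation_matches_exhaustive_enumeration_n6(rng):
    # n=6, 3 cases: all 20 label assignments enumerable exactly
    calls = rng.integers(0, 3, (6, 5)).astype(np.int8)
    gm = _gm(calls)
    y = np.array([1.0, 1, 1, 0, 0, 0])
    stat = make_trend_stat(gm)
    obs = stat(y)
    exact_counts = np.zeros(5)
    perms = set(permutations(y))
    for lab in perms:
        s = stat(np.array(lab))
        exact_counts += s >= obs - 1e-12
    exact_p = exact_counts / len(perms)
    p, done = adaptive_permutation(
        gm, y, obs, max_perm=40000, drop_count=10**9, seed=3
    )
    assert np.allclose(p, exact_p, atol=0.02)


def test_permutation_constant_phenotype_and_bad_args(rng):
    gm = _gm(rng.integers(0, 3, (6, 2)).astype(np.int8))
    with pytest.raises(ValueError):
        adaptive_permutation(gm, np.ones(6), np.ones(2), max_perm=10)
    with pytest.raises(ValueError):
        adaptive_permutation(gm, np.array([0, 1, 0, 1, 0, 1.0]), np.ones(2), max_perm=0)


def test_permutation_early_drop_reduces_work(rng):
    calls = rng.integers(0, 3, (40, 10)).astype(np.int8)
    gm = _gm(calls)
    y = rng.integers(0, 2, 40).astype(float)
    y[:2] = [0, 1]
    stat = make_trend_stat(gm)
    obs = stat(rng.permutation(y))  # null observations -> quickly dropped
    p, done = adaptive_permutation(gm, y, obs, max_perm=50000, batch=200, seed=5)
    assert (done < 50000).any()
    assert (p >= 1.0 / (done + 1)).all()


# ---------------------------------------------------------------------------
# EM linkage disequilibrium
# ---------------------------------------------------------------------------


def test_em_r2_perfect_ld():
    g = np.array([0, 0, 1, 1, 2, 2, 1, 0, 2], dtype=np.int8)
    res = ld_r2_em(g, g)
    assert res.r2 == pytest.approx(1.0, abs=1e-6)
    assert abs(res.dprime) == pytest.approx(1.0, abs=1e-6)


def test_em_r2_independent_columns(rng):
    n = 500
    g1 = rng.binomial(2, 0.4, n).astype(np.int8)
    g2 = rng.binomial(2, 0.5, n).astype(np.int8)
    res = ld_r2_em(g1, g2)
    assert res.r2 < 0.02


def test_em_monomorphic_rejected():
    with pytest.raises(ValueError):
        ld_r2_em(np.zeros(10, dtype=np.int8), np.ones(10, dtype=np.int8))


def _loglik(T, hap):
    """Independent likelihood oracle for two-locus genotype counts."""
    p11, p10, p01, p00 = hap
    P = np.zeros((3, 3))
    for a1, b1, f1 in ((1, 1, p11), (1, 0, p10), (0, 1, p01), (0, 0, p00)):
        for a2, b2, f2 in ((1, 1, p11), (1, 0, p10), (0, 1, p01), (0, 0, p00)):
            P[a1 + a2, b1 + b2] += f1 * f2
    return float((T * np.log(np.clip(P, 1e-300, None))).sum())


def test_em_beats_random_grid_likelihood(rng):
    from slickmap.assoc import _pair_counts

    for rep in range(50):
        p1, p2 = rng.uniform(0.2, 0.8, 2)
        corr = rng.uniform(-0.5, 0.5)
        n = 120
        h1 = rng.binomial(1, p1, (n, 2))
        h2 = np.where(rng.random((n, 2)) < abs(corr), h1, rng.binomial(1, p2, (n, 2)))
        g1 = h1.sum(axis=1).astype(np.int8)
        g2 = h2.sum(axis=1).astype(np.int8)
        if len(np.unique(g1)) < 2 or len(np.unique(g2)) < 2:
            continue
        res = ld_r2_em(g1, g2)
        T = _pair_counts(g1, g2)
        ll_em = _loglik(T, res.hap_freqs)
        for _ in range(200):
            q = rng.dirichlet([1, 1, 1, 1])
            assert ll_em >= _loglik(T, q) - 1e-6


def test_em_agrees_with_phased_count_r2(small_cohort):
    # with no double heterozygotes the phase is unambiguous and the genotype
    # ML solution must equal the phased haplotype counts exactly; with double
    # heterozygotes the EM solution may legitimately differ a little
    H = small_cohort.haplotypes.haplotypes
    rng = np.random.default_rng(0)
    checked_exact = 0
    for i, j in rng.integers(0, H.shape[1] - 1, size=(60, 2)):
        if i == j:
            continue
        a, b = H[:, i].astype(float), H[:, j].astype(float)
        if a.std() == 0 or b.std() == 0:
            continue
        r2_true = np.corrcoef(a, b)[0, 1] ** 2
        g1 = (H[0::2, i] + H[1::2, i]).astype(np.int8)
        g2 = (H[0::2, j] + H[1::2, j]).astype(np.int8)
        if len(np.unique(g1)) < 2 or len(np.unique(g2)) < 2:
            continue
        res = ld_r2_em(g1, g2)
        if not ((g1 == 1) & (g2 == 1)).any():
            assert res.r2 == pytest.approx(r2_true, abs=1e-6)
            checked_exact += 1
        else:
            assert res.r2 == pytest.approx(r2_true, abs=0.12)
    assert checked_exact >= 1


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------


def test_complete_ld_run_forms_single_block(rng):
    col = rng.binomial(2, 0.5, 40).astype(np.int8)
    while len(np.unique(col)) < 3:
        col = rng.binomial(2, 0.5, 40).astype(np.int8)
    calls = np.tile(col[:, None], (1, 5))
    blocks = detect_blocks(_gm(calls))
    assert len(blocks) == 1
    assert (blocks[0].start_idx, blocks[0].end_idx) == (0, 4)
    assert blocks[0].n_snps == 5


def test_unlinked_snps_make_no_blocks(rng):
    calls = rng.binomial(2, 0.5, (60, 8)).astype(np.int8)
    blocks = detect_blocks(_gm(calls))
    assert blocks == []


def test_block_decision_matches_manual_ci_rule(rng):
    # 3 SNPs: 1-2 in complete LD, 3 independent; manual application of the
    # CI rule says {1,2} is a block and 3 stays out
    col = rng.binomial(2, 0.5, 80).astype(np.int8)
    indep = rng.binomial(2, 0.5, 80).astype(np.int8)
    calls = np.stack([col, col, indep], axis=1)
    gm = _gm(calls)
    lo12, hi12 = dprime_ci(calls[:, 0], calls[:, 1])
    lo13, hi13 = dprime_ci(calls[:, 0], calls[:, 2])
    assert lo12 >= 0.70 and hi12 >= 0.98  # strong LD by the CI rule
    assert hi13 < 0.98
    blocks = detect_blocks(gm)
    assert len(blocks) == 1 and (blocks[0].start_idx, blocks[0].end_idx) == (0, 1)


def test_distant_pairs_skipped(rng):
    col = rng.binomial(2, 0.5, 50).astype(np.int8)
    calls = np.stack([col, col], axis=1)
    n, m = calls.shape
    gm = GenotypeMatrix(
        make_sample_table([f"s{i}" for i in range(n)]),
        make_variant_table(["a", "b"], ["1", "1"], [1, 2_000_001], ["A", "A"], ["G", "G"]),
        calls,
    )
    assert detect_blocks(gm, max_pair_dist_kb=1000) == []


# ---------------------------------------------------------------------------
# pattern association
# ---------------------------------------------------------------------------


def _hapset(H, n_samples):
    H = np.asarray(H, dtype=np.int8)
    m = H.shape[1]
    variants = make_variant_table(
        [f"v{j}" for j in range(m)], ["1"] * m, np.arange(1, m + 1) * 1000,
        ["A"] * m, ["G"] * m,
    )
    return HaplotypeSet(H, [f"s{i}" for i in range(n_samples)], variants)


def test_pattern_chi2_worked_example():
    # 10 case chromosomes all carry the pattern, 10 control none -> chi2 = 20
    H = np.zeros((20, 3), dtype=np.int8)
    H[:10] = 1
    hs = _hapset(H, 10)
    y = np.array([1] * 5 + [0] * 5)
    blocks = [HaplotypeBlock(1, 0, 2, GenomicInterval("1", 1000, 3000))]
    pats = pattern_assoc(hs, blocks, y, n_perm=200, seed=0)
    target = [p for p in pats if p.allele_string == "GGG"][0]
    assert target.chi2 == pytest.approx(20.0)
    assert target.p_asymptotic == pytest.approx(7.74e-6, rel=1e-3)
    assert target.freq_case == 1.0 and target.freq_control == 0.0


def test_pattern_frequencies_sum_to_one(small_cohort):
    hs = small_cohort.haplotypes
    y = (small_cohort.samples["phenotype"] == "slick").to_numpy().astype(int)
    blocks = [HaplotypeBlock(1, 10, 14, GenomicInterval("20", 1, 2))]
    blocks[0].interval = GenomicInterval(
        "20",
        int(hs.variants["pos_bp"].iloc[10]),
        int(hs.variants["pos_bp"].iloc[14]),
    )
    pats = pattern_assoc(hs, blocks, y, n_perm=0)
    assert sum(p.freq_total for p in pats) == pytest.approx(1.0)
    assert sum(p.freq_case for p in pats) == pytest.approx(1.0)


def test_pattern_permutation_p_valid_and_uniformish(rng):
    # identical case/control composition -> permuted p well away from 0
    H = rng.binomial(1, 0.5, (24, 4)).astype(np.int8)
    hs = _hapset(H, 12)
    y = np.array([1, 0] * 6)
    blocks = [HaplotypeBlock(1, 0, 3, GenomicInterval("1", 1000, 4000))]
    pats = pattern_assoc(hs, blocks, y, n_perm=99, seed=2)
    for p in pats:
        assert p.p_permuted >= 1.0 / 100


def test_per_snp_reml_agrees_with_approximation(rng):
    # exact per-SNP REML and the fixed-null approximation agree closely when
    # single SNPs explain little variance; exactly equal under identity K
    n, m = 35, 12
    calls = rng.integers(0, 3, (n, m)).astype(np.int8)
    gm = _gm(calls)
    y = rng.random(n)
    K_id = KinshipMatrix(gm.sample_ids(), np.eye(n), "grm")
    a = mixed_model_assoc(gm, y, K_id)
    b = mixed_model_assoc(gm, y, K_id, per_snp_reml=True)
    assert np.allclose(a.p_asymptotic, b.p_asymptotic, atol=1e-5, equal_nan=True)
    K = kinship(gm, "grm")
    c = mixed_model_assoc(gm, y, K)
    d = mixed_model_assoc(gm, y, K, per_snp_reml=True)
    ok = np.isfinite(c.p_asymptotic)
    assert np.corrcoef(np.log(c.p_asymptotic[ok]), np.log(d.p_asymptotic[ok]))[0, 1] > 0.95
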