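import numpy as np
import pytest

from slickmap.sim import (
    BreedConfig,
    CrossDesign,
    Population,
    SimulationConfig,
    _gamete,
    breed_forward,
    assign_phenotypes,
    make_cross,
    plant_causal_haplotype,
    simulate_cohort,
    simulate_founders,
)
from tests.conftest import small_config


def _two_breed_config(F=0.2, seed=0, n_snps=2000, n_founders=60):
    return SimulationConfig(
        seed=seed,
        n_snps=n_snps,
        chrom_length_bp=n_snps * 10_000,
        breeds=[
            BreedConfig("P1", n_samples=5, divergence_F=F, n_founder_haplotypes=n_founders),
            BreedConfig("P2", n_samples=5, divergence_F=F, n_founder_haplotypes=n_founders),
        ],
    )


def test_founders_deterministic_under_seed():
    cfg = _two_breed_config(seed=11)
    a = simulate_founders(cfg)
    b = simulate_founders(cfg)
    for name in ("P1", "P2"):
        assert np.array_equal(a.pools[name], b.pools[name])


def test_founder_freqs_approach_ancestral_as_F_vanishes():
    # Beta mean equals the ancestral frequency; at tiny F the draws concentrate
    reps = []
    for seed in range(200):
        cfg = _two_breed_config(F=1e-3, seed=seed, n_snps=50, n_founders=10)
        pools = simulate_founders(cfg)
        reps.append(np.mean(np.abs(pools.breed_freq["P1"] - pools.ancestral_freq)))
    assert np.mean(reps) < 0.02


def _hudson_fst(p1, p2, n1, n2):
    """Hudson FST estimator (sample-size corrected), averaged over SNPs."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())


def test_divergence_matches_hudson_fst_oracle():
    cfg = _two_breed_config(F=0.2, seed=3)
    pools = simulate_founders(cfg)
    H1, H2 = pools.pools["P1"], pools.pools["P2"]
    fst = _hudson_fst(H1.mean(axis=0), H2.mean(axis=0), H1.shape[0], H2.shape[0])
    assert abs(fst - 0.2) < 0.05


def test_invalid_divergence_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(
            n_snps=10, breeds=[BreedConfig("X", 2, divergence_F=1.5)]
        )


def test_planting_shared_origin():
    cfg = small_config(5)
    rng = np.random.default_rng(5)
    pools = simulate_founders(cfg, rng)
    pools = plant_causal_haplotype(pools, cfg, rng)
    ci = cfg.causal_index
    for b in cfg.breeds:
        H = pools.pools[b.name]
        if b.carrier:
            carriers = H[H[:, ci] == 1]
            assert len(carriers) >= 1
            # single shared origin: all carrier haplotypes identical genome-wide
            assert (carriers == carriers[0]).all()
        else:
            assert (H[:, ci] == 0).all()


def test_planting_refuses_segregating_control_allele():
    cfg = small_config(6)
    rng = np.random.default_rng(6)
    pools = simulate_founders(cfg, rng)
    pools.pools["NA"][:, cfg.causal_index] = 1
    with pytest.raises(ValueError, match="control pool"):
        plant_causal_haplotype(pools, cfg, rng, clear_existing=False)


def test_independent_origin_mode():
    cfg = small_config(7, causal_origin="independent")
    rng = np.random.default_rng(7)
    pools = plant_causal_haplotype(simulate_founders(cfg, rng), cfg, rng)
    ci = cfg.causal_index
    ca = pools.pools["CA"][pools.pools["CA"][:, ci] == 1]
    cb = pools.pools["CB"][pools.pools["CB"][:, ci] == 1]
    assert len(ca) and len(cb)
    # different founder backgrounds across breeds
    assert not np.array_equal(ca[0], cb[0])


def test_gamete_without_recombination_copies_parent(rng):
    cfg = small_config(0, recomb_rate_cm_per_mb=0.0)
    pos = cfg.positions_bp()
    h1 = rng.integers(0, 2, cfg.n_snps).astype(np.int8)
    h2 = rng.integers(0, 2, cfg.n_snps).astype(np.int8)
    for _ in range(10):
        g = _gamete(h1, h2, rng, cfg.map_length_morgans, pos, cfg.chrom_length_bp)
        assert np.array_equal(g, h1) or np.array_equal(g, h2)


def test_crossover_count_is_poisson_with_map_length(rng):
    # 40 Mb at 1 cM/Mb -> 0.4 Morgans -> mean 0.4 crossovers per meiosis
    cfg = SimulationConfig(n_snps=100, chrom_length_bp=40_000_000, breeds=[])
    pos = cfg.positions_bp()
    h1 = np.zeros(100, dtype=np.int8)
    h2 = np.ones(100, dtype=np.int8)
    switches = []
    for _ in range(2000):
        g = _gamete(h1, h2, rng, cfg.map_length_morgans, pos, cfg.chrom_length_bp)
        switches.append(int((np.diff(g) != 0).sum()))
    mean = np.mean(switches)
    se = np.std(switches) / np.sqrt(len(switches))
    # observable switches undercount crossovers slightly (pairs can cancel
    # between adjacent SNPs); allow 3 SE around the Poisson mean minus a
    # small cancellation allowance
    assert 0.3 < mean < 0.4 + 3 * se


def test_gametes_are_mendelian(rng):
    cfg = small_config(0)
    pos = cfg.positions_bp()
    h1 = rng.integers(0, 2, cfg.n_snps).astype(np.int8)
    h2 = rng.integers(0, 2, cfg.n_snps).astype(np.int8)
    for _ in range(20):
        g = _gamete(h1, h2, rng, 2.0, pos, cfg.chrom_length_bp)
        assert ((g == h1) | (g == h2)).all()


def test_breed_forward_zero_recombination_outputs_founder_copies(rng):
    cfg = small_config(0, recomb_rate_cm_per_mb=0.0, pop_size=10)
    pool = rng.integers(0, 2, (20, cfg.n_snps)).astype(np.int8)
    pop = breed_forward(pool, 5, 20, cfg, rng)
    founders = {h.tobytes() for h in pool}
    for ind in pop.haps:
        assert ind[0].tobytes() in founders and ind[1].tobytes() in founders


def test_shared_segment_shrinks_with_generations():
    cfg = small_config(9)
    base_rng = np.random.default_rng(99)
    # founder pool: half copies of one carrier haplotype, half unique
    founder = base_rng.integers(0, 2, cfg.n_snps).astype(np.int8)
    ci = cfg.causal_index
    founder[ci] = 1
    others = base_rng.integers(0, 2, (20, cfg.n_snps)).astype(np.int8)
    others[:, ci] = 0
    pool = np.concatenate([np.tile(founder, (20, 1)), others])
    lengths = []
    for gens in (2, 10, 30):
        rng = np.random.default_rng(7)
        pop = breed_forward(pool, gens, 40, cfg, rng)
        H = pop.haps.reshape(-1, cfg.n_snps)
        carriers = H[H[:, ci] == 1]
        ref = founder
        # median maximal run of identity with the founder-representative
        spans = []
        for h in carriers:
            eq = h == ref
            left = ci
            while left > 0 and eq[left - 1]:
                left -= 1
            right = ci
            while right < len(eq) - 1 and eq[right + 1]:
                right += 1
            spans.append(right - left + 1)
        lengths.append(np.median(spans))
    assert lengths[0] >= lengths[1] >= lengths[2]


def test_backcross_donor_fraction():
    cfg = small_config(4)
    rng = np.random.default_rng(42)
    pools = plant_causal_haplotype(simulate_founders(cfg, rng), cfg, rng)
    pops = {
        b.name: breed_forward(pools.pools[b.name], 4, 2 * b.n_samples, cfg, rng, name=b.name)
        for b in cfg.breeds
    }
    f1 = make_cross(pops, CrossDesign("CA", "NA", 1, 50, select_carriers=False), cfg, rng)
    fr = np.mean([c.donor_fraction for c in f1])
    assert abs(fr - 0.5) < 0.1
    bc4 = make_cross(pops, CrossDesign("CA", "NA", 4, 50, select_carriers=False), cfg, rng)
    fr4 = np.mean([c.donor_fraction for c in bc4])
    # expected 1/16 donor genome, i.e. ~94% recipient — inside the 40-97% range
    assert abs(fr4 - 0.0625) < 0.05
    assert 0.40 <= 1 - fr4 <= 0.97


def test_backcross_carrier_selection_retains_allele():
    cfg = small_config(8)
    coh = simulate_cohort(cfg)
    st = coh.samples
    carr = coh.truth["carrier_counts"]
    cross_idx = np.where(st["breed_code"] == "CX")[0]
    assert (carr[cross_idx] >= 1).all()


def test_unknown_breed_in_cross_design_rejected():
    cfg = small_config(3)
    rng = np.random.default_rng(3)
    pools = plant_causal_haplotype(simulate_founders(cfg, rng), cfg, rng)
    pops = {"CA": breed_forward(pools.pools["CA"], 2, 10, cfg, rng)}
    with pytest.raises(KeyError):
        make_cross(pops, CrossDesign("CA", "NOPE", 2, 5), cfg, rng)


def test_phenotypes_full_penetrance_equal_carrier_status(rng):
    counts = np.array([0, 1, 2, 1, 0, 2])
    ph = assign_phenotypes(counts, 1.0, rng)
    assert (ph == np.where(counts >= 1, "slick", "nonslick")).all()


def test_phenotypes_partial_penetrance_binomial(rng):
    counts = np.ones(1000, dtype=int)
    ph = assign_phenotypes(counts, 0.8, rng)
    frac = (ph == "slick").mean()
    se = np.sqrt(0.8 * 0.2 / 1000)
    assert abs(frac - 0.8) < 3 * se


def test_dominance_hom_and_het_carriers_equivalent(rng):
    het = assign_phenotypes(np.ones(2000, dtype=int), 0.7, np.random.default_rng(0))
    hom = assign_phenotypes(np.full(2000, 2), 0.7, np.random.default_rng(0))
    assert abs((het == "slick").mean() - (hom == "slick").mean()) < 0.05


def test_cohort_determinism_and_dimension_stability():
    a = simulate_cohort(small_config(21))
    b = simulate_cohort(small_config(21))
    c = simulate_cohort(small_config(22))
    assert np.array_equal(a.haplotypes.haplotypes, b.haplotypes.haplotypes)
    assert a.samples.equals(b.samples)
    # different seed: same shape, different data
    assert c.genotypes.calls.shape == a.genotypes.calls.shape
    assert not np.array_equal(c.genotypes.calls, a.genotypes.calls)


def test_phenotype_matches_carrier_truth(small_cohort):
    st = small_cohort.samples
    carr = small_cohort.truth["carrier_counts"]
    assert ((st["phenotype"] == "slick").to_numpy() == (carr >= 1)).all()


def test_missingness_injection():
    coh = simulate_cohort(small_config(13, missing_rate=0.05))
    frac = (coh.haplotypes.haplotypes == -1).mean()
    assert 0.03 < frac < 0.07


def test_causal_heterozygosity_among_affected_soft_range():
    # dominant locus managed at intermediate frequency: most affected animals
    # are heterozygous, matching ~0.6-0.7 observed in real carrier breeds
    fracs = []
    for seed in range(10):
        coh = simulate_cohort(small_config(seed))
        st = coh.samples
        carr = coh.truth["carrier_counts"]
        within = st["breed_code"].isin(["CA", "CB"]).to_numpy()
        slick = (st["phenotype"] == "slick").to_numpy()
        sel = within & slick
        fracs.append((carr[sel] == 1).mean())
    assert 0.45 < np.mean(fracs) < 0.85
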