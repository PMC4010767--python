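"""Forward-in-time multi-breed cohort simulator with a planted dominant haplotype.

The generator emulates the study design this package targets: several diverged
cattle-like breeds (Balding–Nichols allele-frequency divergence around a shared
ancestral frequency), three of which segregate a fully dominant causal allele
that entered each breed on a single long founder haplotype, plus backcross
lineages produced by repeatedly mating carriers to a non-carrier recipient
breed while selecting for the trait.

Model summary
-------------
* Ancestral allele frequencies ``p ~ Uniform(0.05, 0.95)`` per SNP; per-breed
  frequencies ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` (Balding–Nichols with
  divergence ``F``).
* Founder haplotypes are drawn site-wise from the breed frequencies and then
  partially smoothed by copying random segments from a small per-breed pool of
  template haplotypes, which induces local LD on top of the LD later generated
  by drift in the finite forward-bred population.
* Meiosis follows a Haldane map (no interference): crossovers per gamete are
  Poisson with mean equal to the map length in Morgans; breakpoints are
  uniform on the (constant cM/Mb) genetic map.
* The causal haplotype has a single origin shared by every carrier breed by
  default; an independent-origins mode plants a separate mutation per breed.
* The causal haplotype is planted at low founder frequency (default 0.05) and
  carrier breeds are bred forward under a smooth breeder-selection controller
  that prefers carrier parents while the allele is below a managed frequency
  band (default 0.45–0.65) and relaxes inside it. This reproduces the
  selective sweep that raised a visible dominant trait to intermediate
  frequency: long shared flanking haplotypes that decay with distance from
  the locus. A breed whose final frequency misses the band is redrawn.

Everything is a deterministic function of ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    GenotypeMatrix,
    HaplotypeSet,
    make_sample_table,
    make_variant_table,
)


@dataclass
class BreedConfig:
    name: str
    n_samples: int
    n_founder_haplotypes: int = 80
    divergence_F: float = 0.15
    carrier: bool = False


@dataclass
class CrossDesign:
    """Backcross lineage: donor (dam) carriers repeatedly crossed to the recipient (sire) breed.

    ``n_backcross_generations`` counts meioses separating the lineage from the
    pure donor: 1 is the F1, 4 leaves an expected donor-genome fraction of
    1/16 (~94% recipient ancestry).
    """

    dam_breed: str
    sire_breed: str
    n_backcross_generations: int
    n_samples: int
    name: str = ""
    select_carriers: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"{self.dam_breed}x{self.sire_breed}"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_snps: int = 4000
    chrom_length_bp: int = 40_000_000
    chrom_name: str = "20"
    recomb_rate_cm_per_mb: float = 1.0
    breeds: list[BreedConfig] = field(default_factory=list)
    cross_designs: list[CrossDesign] = field(default_factory=list)
    causal_index: int | None = None  # default: middle SNP
    generations: int = 40
    pop_size: int = 200  # diploid individuals per breed during forward breeding
    penetrance: float = 1.0
    founder_pool_size: int = 8
    smooth_prob: float = 0.5
    smooth_segment_snps: int | None = None  # default n_snps // 20
    carrier_founder_freq: float = 0.05
    causal_freq_band: tuple[float, float] | None = (0.45, 0.65)
    selection_s: float = 0.5  # breeder preference for carriers below the band
    causal_origin: str = "shared"  # or "independent"
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.causal_index is None:
            self.causal_index = self.n_snps // 2
        if not 0 <= self.causal_index < self.n_snps:
            raise ValueError("causal_index out of range")
        for b in self.breeds:
            if not 0.0 < b.divergence_F < 1.0:
                raise ValueError(
                    f"divergence_F for breed {b.name} must be in (0,1), got {b.divergence_F}"
                )
        if self.causal_origin not in ("shared", "independent"):
            raise ValueError("causal_origin must be 'shared' or 'independent'")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0,1]")

    @property
    def map_length_morgans(self) -> float:
        return self.chrom_length_bp / 1e6 * self.recomb_rate_cm_per_mb / 100.0

    def positions_bp(self) -> np.ndarray:
        pos = np.round(np.linspace(1, self.chrom_length_bp, self.n_snps)).astype(np.int64)
        if np.any(np.diff(pos) <= 0):
            raise ValueError("n_snps too dense for chrom_length_bp (positions collide)")
        return pos

    def breed(self, name: str) -> BreedConfig:
        for b in self.breeds:
            if b.name == name:
                return b
        raise KeyError(f"unknown breed {name!r}")


def default_config(seed: int = 0) -> SimulationConfig:
    """The default study-design: three carrier breeds, five non-carrier
    ancestral control breeds, and two carrier backcross lineages (~120 samples,
    4,000 SNPs on a 40 Mb chromosome)."""
    return SimulationConfig(
        seed=seed,
        breeds=[
            BreedConfig("SE", n_samples=34, carrier=True),
            BreedConfig("CR", n_samples=12, carrier=True),
            BreedConfig("RS", n_samples=6, carrier=True),
            BreedConfig("RP", n_samples=14),
            BreedConfig("ND", n_samples=10),
            BreedConfig("AN", n_samples=12),
            BreedConfig("BS", n_samples=10),
            BreedConfig("HO", n_samples=10),
        ],
        cross_designs=[
            CrossDesign("SE", "HO", n_backcross_generations=4, n_samples=8, name="SHO"),
            CrossDesign("RS", "AN", n_backcross_generations=2, n_samples=6, name="RAN"),
        ],
    )


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

@dataclass
class FounderPools:
    pools: dict[str, np.ndarray]  # breed -> (n_founder_haplotypes, n_snps) int8
    ancestral_freq: np.ndarray
    breed_freq: dict[str, np.ndarray]
    founder_haplotype: dict[str, int] = field(default_factory=dict)  # carrier origin rows


def simulate_founders(config: SimulationConfig, rng: np.random.Generator | None = None) -> FounderPools:
    """Draw per-breed founder haplotype pools under Balding–Nichols divergence."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.n_snps
    p_anc = rng.uniform(0.05, 0.95, size=m)
    seg = config.smooth_segment_snps or max(2, config.n_snps // 20)
    pools: dict[str, np.ndarray] = {}
    freqs: dict[str, np.ndarray] = {}
    for b in config.breeds:
        F = b.divergence_F
        a = p_anc * (1 - F) / F
        bb = (1 - p_anc) * (1 - F) / F
        pb = rng.beta(a, bb)
        freqs[b.name] = pb
        # template pool for LD smoothing
        templates = (rng.random((config.founder_pool_size, m)) < pb).astype(np.int8)
        H = (rng.random((b.n_founder_haplotypes, m)) < pb).astype(np.int8)
        # partial segment-copy smoothing: ~smooth_prob of each haplotype's
        # material is replaced by long segments from the template pool
        starts = rng.random((b.n_founder_haplotypes, m)) < (1.0 / seg)
        starts[:, 0] = True
        seg_id = np.cumsum(starts, axis=1) - 1
        for i in range(b.n_founder_haplotypes):
            n_seg = seg_id[i, -1] + 1
            copy_seg = rng.random(n_seg) < config.smooth_prob
            donor = rng.integers(0, config.founder_pool_size, size=n_seg)
            mask = copy_seg[seg_id[i]]
            H[i, mask] = templates[donor[seg_id[i]], np.arange(m)][mask]
        pools[b.name] = H
    return FounderPools(pools, p_anc, freqs)


def plant_causal_haplotype(
    pools: FounderPools,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    clear_existing: bool = True,
) -> FounderPools:
    """Insert the dominant causal allele on a founder haplotype.

    In ``shared`` mode one founder haplotype (from the first carrier breed) is
    copied whole into every carrier breed's pool at frequency
    ``carrier_founder_freq``; in ``independent`` mode each carrier breed gets
    its own mutated founder. Non-carrier pools end with derived-allele
    frequency 0 at the causal site.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ci = config.causal_index
    carriers = [b for b in config.breeds if b.carrier]
    if not carriers:
        raise ValueError("no carrier breeds configured")
    controls = [b for b in config.breeds if not b.carrier]
    if clear_existing:
        for b in config.breeds:
            pools.pools[b.name][:, ci] = 0
    else:
        for b in controls:
            if pools.pools[b.name][:, ci].any():
                raise ValueError(
                    f"causal allele already segregating in control pool {b.name}"
                )
        for b in carriers:
            pools.pools[b.name][:, ci] = 0

    def _plant(breed: BreedConfig, founder: np.ndarray) -> None:
        H = pools.pools[breed.name]
        n = H.shape[0]
        k = max(1, int(round(config.carrier_founder_freq * n)))
        rows = rng.choice(n, size=k, replace=False)
        H[rows] = founder
        pools.founder_haplotype[breed.name] = int(rows[0])

    if config.causal_origin == "shared":
        src = carriers[0]
        row = int(rng.integers(0, pools.pools[src.name].shape[0]))
        founder = pools.pools[src.name][row].copy()
        founder[ci] = 1
        for b in carriers:
            _plant(b, founder)
        pools.founder_haplotype["__origin__"] = row
    else:
        for b in carriers:
            row = int(rng.integers(0, pools.pools[b.name].shape[0]))
            founder = pools.pools[b.name][row].copy()
            founder[ci] = 1
            _plant(b, founder)
    return pools


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _gamete(
    h1: np.ndarray,
    h2: np.ndarray,
    rng: np.random.Generator,
    map_morgans: float,
    positions: np.ndarray,
    chrom_length: int,
    l1: np.ndarray | None = None,
    l2: np.ndarray | None = None,
):
    """One meiosis: Haldane crossovers, uniform breakpoints on the map.

    Returns the gamete (and its ancestry-label array when labels are given).
    """
    k = rng.poisson(map_morgans)
    start = int(rng.integers(2))
    if k == 0:
        g = (h1 if start == 0 else h2).copy()
        if l1 is None:
            return g
        return g, (l1 if start == 0 else l2).copy()
    bp = np.sort(rng.uniform(0, chrom_length, size=k))
    idx = np.searchsorted(positions, bp)
    use_h2 = np.zeros(len(positions), dtype=bool)
    cur = bool(start)
    prev = 0
    for cut in list(idx) + [len(positions)]:
        use_h2[prev:cut] = cur
        cur = not cur
        prev = cut
    g = np.where(use_h2, h2, h1).astype(np.int8)
    if l1 is None:
        return g
    lab = np.where(use_h2, l2, l1)
    return g, lab


@dataclass
class Population:
    """A generation of diploid individuals (N, 2, m) with ids and pedigree."""

    haps: np.ndarray  # (N, 2, m) int8
    ids: list[str]
    pedigree: list[tuple[str, str, str]] = field(default_factory=list)  # child, dam, sire


def breed_forward(
    pool: np.ndarray,
    generations: int,
    n_out: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    condition: Callable[[np.ndarray], bool] | None = None,
    parent_weights: Callable[[np.ndarray], np.ndarray] | None = None,
    name: str = "POP",
    max_tries: int = 30,
) -> Population:
    """Random-mating forward simulation from a founder haplotype pool.

    Founders are paired into diploids; each later generation draws a dam and a
    sire per child and transmits one recombinant gamete from each. When a
    *parent_weights* callback is given it returns per-individual sampling
    weights (breeder selection, e.g. preferring carriers of a visible trait);
    when a *condition* predicate is given (e.g. causal-frequency band
    conditioning) each generation is redrawn until it satisfies it, up to
    ``max_tries``, after which the last attempt is kept.
    """
    if pool.shape[0] < 2:
        raise ValueError("founder pool must contain at least 2 haplotypes")
    positions = config.positions_bp()
    L = config.map_length_morgans
    n0 = pool.shape[0] - (pool.shape[0] % 2)
    haps = pool[:n0].reshape(n0 // 2, 2, -1).copy()
    ids = [f"{name}_g0_{i}" for i in range(n0 // 2)]
    pedigree: list[tuple[str, str, str]] = []
    N = max(config.pop_size, (n_out + 1) // 2)
    for g in range(1, generations + 1):
        if parent_weights is not None:
            w = np.asarray(parent_weights(haps), dtype=np.float64)
            w = w / w.sum()
        else:
            w = None
        best = None
        for attempt in range(max_tries):
            new = np.empty((N, 2, haps.shape[2]), dtype=np.int8)
            parents = []
            for i in range(N):
                dam, sire = rng.choice(len(ids), size=2, replace=False, p=w)
                new[i, 0] = _gamete(haps[dam, 0], haps[dam, 1], rng, L, positions, config.chrom_length_bp)
                new[i, 1] = _gamete(haps[sire, 0], haps[sire, 1], rng, L, positions, config.chrom_length_bp)
                parents.append((ids[dam], ids[sire]))
            best = (new, parents)
            if condition is None or condition(new):
                break
        new, parents = best
        new_ids = [f"{name}_g{g}_{i}" for i in range(N)]
        pedigree.extend(
            (cid, dam, sire) for cid, (dam, sire) in zip(new_ids, parents)
        )
        haps, ids = new, new_ids
    return Population(haps, ids, pedigree)


def _carrier_selection(config: SimulationConfig) -> Callable[[np.ndarray], np.ndarray]:
    """Breeder-selection controller for a visible dominant trait.

    While the causal allele frequency is below the management band, carrier
    parents are preferred (weight 1+s); above the band they are avoided;
    inside it mating is random. This reproduces the selective sweep that
    carried the trait haplotype up in frequency, then holds it intermediate.
    """
    lo, hi = config.causal_freq_band or (0.0, 1.0)
    target = (lo + hi) / 2.0
    s = config.selection_s
    ci = config.causal_index

    def weights(haps: np.ndarray) -> np.ndarray:
        f = (haps[:, :, ci] == 1).mean()
        carrier = (haps[:, :, ci] == 1).any(axis=1)
        # smooth proportional preference: strong when far below target,
        # fading to neutral as the band is reached (avoids overshoot cycles
        # that would select against the locus while sparing its flanks)
        k = s * np.clip(target - f, -0.25, 1.0) / 0.25
        return np.where(carrier, np.exp(k), 1.0)

    return weights


# ---------------------------------------------------------------------------
# crosses
# ---------------------------------------------------------------------------

@dataclass
class CrossSample:
    hap_a: np.ndarray
    hap_b: np.ndarray
    donor_fraction: float  # realized donor-genome fraction (SNP-weighted)
    carrier: bool


def make_cross(
    populations: dict[str, Population],
    design: CrossDesign,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[CrossSample]:
    """Produce one backcross lineage with ancestry tracking.

    Starting from a carrier donor individual, each backcross generation mates
    the current (carrier-selected) animal to a fresh recipient individual.
    After ``g`` generations the expected donor-genome fraction is ``2**-g``.
    """
    for breed in (design.dam_breed, design.sire_breed):
        if breed not in populations:
            raise KeyError(f"cross design references unknown breed {breed!r}")
    donor = populations[design.dam_breed]
    recip = populations[design.sire_breed]
    positions = config.positions_bp()
    L = config.map_length_morgans
    ci = config.causal_index
    m = config.n_snps
    carriers_idx = [
        i for i in range(donor.haps.shape[0]) if donor.haps[i, :, ci].any()
    ]
    if design.select_carriers and not carriers_idx:
        raise ValueError(f"donor breed {design.dam_breed} has no carriers to cross")
    out: list[CrossSample] = []
    for _ in range(design.n_samples):
        for _try in range(200):
            i = int(rng.choice(carriers_idx if design.select_carriers else range(donor.haps.shape[0])))
            cur = (donor.haps[i, 0].copy(), donor.haps[i, 1].copy())
            cur_lab = (np.ones(m, dtype=np.int8), np.ones(m, dtype=np.int8))
            ok = True
            for _g in range(design.n_backcross_generations):
                ga, la = _gamete(cur[0], cur[1], rng, L, positions, config.chrom_length_bp, cur_lab[0], cur_lab[1])
                j = int(rng.integers(recip.haps.shape[0]))
                k = int(rng.integers(2))
                gb = recip.haps[j, k].copy()
                lb = np.zeros(m, dtype=np.int8)
                cur, cur_lab = (ga, gb), (la, lb)
                if design.select_carriers and not (cur[0][ci] or cur[1][ci]):
                    ok = False
                    break
            if ok:
                break
        frac = float((cur_lab[0].mean() + cur_lab[1].mean()) / 2.0)
        out.append(
            CrossSample(cur[0], cur[1], frac, bool(cur[0][ci] or cur[1][ci]))
        )
    return out


# ---------------------------------------------------------------------------
# phenotype + cohort assembly
# ---------------------------------------------------------------------------

def assign_phenotypes(
    carrier_counts: np.ndarray, penetrance: float, rng: np.random.Generator
) -> np.ndarray:
    """Dominant penetrance model: P(slick | >=1 causal allele) = penetrance."""
    carrier = np.asarray(carrier_counts) >= 1
    express = rng.random(len(carrier)) < penetrance
    return np.where(carrier & express, "slick", "nonslick")


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    haplotypes: HaplotypeSet
    truth: dict

    @property
    def samples(self) -> pd.DataFrame:
        return self.genotypes.samples


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the full generator: founders -> plant -> forward breeding -> crosses."""
    rng = np.random.default_rng(config.seed)
    pools = simulate_founders(config, rng)
    pools = plant_causal_haplotype(pools, config, rng)
    ci = config.causal_index
    populations: dict[str, Population] = {}
    for b in config.breeds:
        if b.carrier:
            pw = _carrier_selection(config)
            lo, hi = config.causal_freq_band or (0.0, 1.0)
            pop = None
            for _try in range(20):
                pop = breed_forward(
                    pools.pools[b.name], config.generations, 2 * b.n_samples,
                    config, rng, parent_weights=pw, name=b.name,
                )
                f = (pop.haps[:, :, ci] == 1).mean()
                if lo <= f <= hi:
                    break
            populations[b.name] = pop
        else:
            populations[b.name] = breed_forward(
                pools.pools[b.name], config.generations, 2 * b.n_samples,
                config, rng, name=b.name,
            )
    hap_rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    breed_codes: list[str] = []
    donor_fracs: list[float] = []
    source_ids: list[str] = []  # internal pedigree id each sample was drawn from
    for b in config.breeds:
        pop = populations[b.name]
        idx = rng.choice(pop.haps.shape[0], size=b.n_samples, replace=False)
        for rank, i in enumerate(idx):
            sid = f"{b.name}{rank + 1:03d}"
            sample_ids.append(sid)
            breed_codes.append(b.name)
            source_ids.append(pop.ids[i])
            hap_rows.append(pop.haps[i, 0])
            hap_rows.append(pop.haps[i, 1])
            donor_fracs.append(np.nan)
    for d in config.cross_designs:
        xs = make_cross(populations, d, config, rng)
        for rank, cs in enumerate(xs):
            sid = f"{d.name}{rank + 1:03d}"
            sample_ids.append(sid)
            breed_codes.append(d.name)
            source_ids.append(sid)
            hap_rows.append(cs.hap_a)
            hap_rows.append(cs.hap_b)
            donor_fracs.append(cs.donor_fraction)
    H = np.stack(hap_rows).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(H.shape) < config.missing_rate
        H = np.where(miss, MISSING, H).astype(np.int8)
    carrier_counts = (H[0::2, ci] == 1).astype(int) + (H[1::2, ci] == 1).astype(int)
    phenotypes = assign_phenotypes(carrier_counts, config.penetrance, rng)
    roles = np.where(phenotypes == "slick", "case", "control")
    samples = make_sample_table(sample_ids, breed_codes, list(phenotypes), list(roles))
    positions = config.positions_bp()
    variants = make_variant_table(
        [f"snp{j:05d}" for j in range(config.n_snps)],
        [config.chrom_name] * config.n_snps,
        positions,
        ["A"] * config.n_snps,
        ["G"] * config.n_snps,
    )
    hs = HaplotypeSet(H, sample_ids, variants, samples)
    gm = hs.to_genotypes()
    truth = {
        "causal_index": ci,
        "causal_pos_bp": int(positions[ci]),
        "carrier_counts": carrier_counts,
        "founder_haplotype_id": pools.founder_haplotype,
        "donor_fraction": np.array(donor_fracs),
        "source_ids": source_ids,
        "pedigree": [p for pop in populations.values() for p in pop.pedigree],
        "breed_freq": pools.breed_freq,
    }
    return SimulatedCohort(gm, hs, truth)
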