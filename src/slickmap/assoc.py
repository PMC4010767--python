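"""Kinship-corrected association, permutation testing, LD, haplotype blocks.

The single-SNP test is the EMMAX approximation to a linear mixed model: the
null model ``y = mu + g + e`` with ``g ~ N(0, sigma_g^2 K)`` and
``e ~ N(0, sigma_e^2 I)`` is fitted once by REML (1-D optimization over the
variance ratio ``delta = sigma_e^2 / sigma_g^2`` on the eigenbasis of K), and
every SNP is then tested by generalized least squares with the null variance
components held fixed. Case/control status is coded 0/1 and analysed as a
quantitative trait, as the approximation intends.

Pairwise LD is estimated by the usual two-locus EM over the double-
heterozygote phase ambiguity; haplotype blocks follow the Gabriel
confidence-interval rule on D' (profile-likelihood CIs on a grid), and block
allele patterns are tested case-vs-control by 2x2 chi-square with a
sample-level permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .intervals import GenomicInterval
from .io import MISSING, GenotypeMatrix, HaplotypeSet
from .popstruct import KinshipMatrix

# ---------------------------------------------------------------------------
# mixed model (EMMAX approximation)
# ---------------------------------------------------------------------------


@dataclass
class AssocResult:
    variants: pd.DataFrame
    beta: np.ndarray
    stat: np.ndarray  # t statistic
    p_asymptotic: np.ndarray
    sigma_g2: float
    sigma_e2: float
    delta: float
    p_permuted: np.ndarray | None = None
    n_perm: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.variants[["variant_id", "chrom", "pos_bp"]].copy()
        out["beta"] = self.beta
        out["stat"] = self.stat
        out["p"] = self.p_asymptotic
        with np.errstate(divide="ignore"):
            out["neglog10_p"] = -np.log10(self.p_asymptotic)
        if self.p_permuted is not None:
            out["p_perm"] = self.p_permuted
            out["n_perm"] = self.n_perm
        return out


def _reml_neg_loglik(log_delta, lam, Xt, yt):
    delta = np.exp(log_delta)
    w = 1.0 / (lam + delta)
    xx = (w * Xt * Xt).sum()
    xy = (w * Xt * yt).sum()
    yy = (w * yt * yt).sum()
    Q = yy - xy * xy / xx
    n, q = len(yt), 1
    if Q <= 0:
        return np.inf
    return (n - q) * np.log(Q) + np.log(lam + delta).sum() + np.log(xx)


def _fit_null(lam, Xt, yt):
    grid = np.linspace(-10, 10, 41)
    vals = [_reml_neg_loglik(g, lam, Xt, yt) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(lam, Xt, yt), method="bounded"
    )
    delta = float(np.exp(res.x))
    w = 1.0 / (lam + delta)
    xx = (w * Xt * Xt).sum()
    xy = (w * Xt * yt).sum()
    yy = (w * yt * yt).sum()
    Q = yy - xy * xy / xx
    sigma_g2 = float(Q / (len(yt) - 1))
    return delta, sigma_g2, delta * sigma_g2


def _reml_neg_loglik_multi(log_delta, lam, Xt, yt):
    """REML criterion for a multi-column (rotated) design matrix."""
    delta = np.exp(log_delta)
    w = 1.0 / (lam + delta)
    XtW = Xt * w[:, None]
    XX = XtW.T @ Xt
    Xy = XtW.T @ yt
    yy = (w * yt * yt).sum()
    try:
        beta = np.linalg.solve(XX, Xy)
    except np.linalg.LinAlgError:
        return np.inf
    Q = yy - Xy @ beta
    n, q = len(yt), Xt.shape[1]
    sign, logdet = np.linalg.slogdet(XX)
    if Q <= 0 or sign <= 0:
        return np.inf
    return (n - q) * np.log(Q) + np.log(lam + delta).sum() + logdet


def _exact_snp_test(lam, Xt, yt):
    """Per-SNP REML: refit delta with the SNP in the design, then Wald t."""
    grid = np.linspace(-10, 10, 21)
    vals = [_reml_neg_loglik_multi(g, lam, Xt, yt) for g in grid]
    k = int(np.argmin(vals))
    res = optimize.minimize_scalar(
        _reml_neg_loglik_multi,
        bounds=(grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]),
        args=(lam, Xt, yt),
        method="bounded",
    )
    delta = float(np.exp(res.x))
    w = 1.0 / (lam + delta)
    XtW = Xt * w[:, None]
    XX = XtW.T @ Xt
    Xy = XtW.T @ yt
    beta = np.linalg.solve(XX, Xy)
    n, q = len(yt), Xt.shape[1]
    Q = (w * yt * yt).sum() - Xy @ beta
    sigma2 = Q / (n - q)
    cov = sigma2 * np.linalg.inv(XX)
    t = beta[1] / np.sqrt(cov[1, 1])
    p = 2.0 * stats.t.sf(abs(t), n - q)
    return float(beta[1]), float(t), float(p)


def mixed_model_assoc(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    K: KinshipMatrix,
    jitter: float = 1e-6,
    per_snp_reml: bool = False,
) -> AssocResult:
    """Per-SNP mixed-model association with variance components fixed from the null.

    Missing genotypes are mean-imputed per SNP for testing; constant SNPs get
    NaN statistics. K must be aligned to the samples of ``gm``. With
    ``per_snp_reml=True`` the variance ratio is refitted for every SNP with
    the SNP in the design (exact but far slower; intended for validation).
    """
    y = np.asarray(phenotype, dtype=np.float64)
    if len(y) != gm.n_samples:
        raise ValueError("phenotype length does not match samples")
    if np.all(y == y[0]):
        raise ValueError("phenotype is constant")
    if K.sample_ids != gm.sample_ids():
        raise ValueError("kinship matrix not aligned to genotype samples")
    Kv = (K.values + K.values.T) / 2.0
    lam, U = np.linalg.eigh(Kv)
    if lam.min() < -1e-8:
        Kv = Kv + (jitter - lam.min()) * np.eye(len(y))
        lam, U = np.linalg.eigh(Kv)
        if lam.min() < -1e-8:
            raise ValueError("kinship matrix is not positive semi-definite")
    lam = np.maximum(lam, 0.0)
    X = np.ones((len(y), 1))
    Xt = (U.T @ X).ravel()
    yt = U.T @ y
    delta, sigma_g2, sigma_e2 = _fit_null(lam, Xt, yt)

    # whiten with the fixed null covariance (sigma_g2 cancels in t statistics)
    d = 1.0 / np.sqrt(lam + delta)
    yw = d * yt
    xw = d * Xt
    calls = gm.calls.astype(np.float64)
    obs = gm.calls != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        col_mean = np.where(obs, calls, 0).sum(axis=0) / np.maximum(n_obs, 1)
    G = np.where(obs, calls, col_mean)
    if per_snp_reml:
        m = gm.n_variants
        beta = np.full(m, np.nan)
        t = np.full(m, np.nan)
        p = np.full(m, np.nan)
        for j in range(m):
            g = G[:, j]
            if np.ptp(g) <= 1e-12:
                continue
            X2t = U.T @ np.column_stack([np.ones(len(y)), g])
            beta[j], t[j], p[j] = _exact_snp_test(lam, X2t, yt)
        return AssocResult(gm.variants, beta, t, p, sigma_g2, sigma_e2, delta)
    Gw = (U.T @ G) * d[:, None]

    # residualize out the (whitened) intercept
    xx = (xw * xw).sum()
    yr = yw - xw * ((xw @ yw) / xx)
    Gr = Gw - np.outer(xw, (xw @ Gw) / xx)
    gg = (Gr * Gr).sum(axis=0)
    gy = Gr.T @ yr
    n = len(y)
    dof = n - 2
    const = gg <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = (yr * yr).sum() - beta * gy
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / dof / gg)
        t = beta / se
    t[const] = np.nan
    beta[const] = np.nan
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return AssocResult(gm.variants, beta, t, p, sigma_g2, sigma_e2, delta)


# ---------------------------------------------------------------------------
# adaptive permutation
# ---------------------------------------------------------------------------


def make_trend_stat(gm: GenotypeMatrix):
    """Default permutation statistic: per-SNP t^2 of the allelic trend test."""
    calls = gm.calls.astype(np.float64)
    obs = gm.calls != MISSING
    n_obs = obs.sum(axis=0)
    col_mean = np.where(obs, calls, 0).sum(axis=0) / np.maximum(n_obs, 1)
    G = np.where(obs, calls, col_mean)
    Gc = G - G.mean(axis=0)
    gg = (Gc * Gc).sum(axis=0)
    n = gm.n_samples

    def stat(y: np.ndarray) -> np.ndarray:
        yc = y - y.mean()
        yy = (yc * yc).sum()
        if yy == 0:
            raise ValueError("phenotype is constant")
        gy = Gc.T @ yc
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (gy * gy) / (gg * yy)
            r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
            t2 = r2 * (n - 2) / (1.0 - r2)
        t2[gg <= 1e-12] = np.nan
        return t2

    return stat


def adaptive_permutation(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    observed: np.ndarray,
    max_perm: int = 1_000_000,
    drop_count: int = 10,
    batch: int = 1000,
    seed: int = 0,
    stat_fun=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Label-permutation p-values with early dropping of clearly null SNPs.

    Permuted statistics are compared as ``>= observed``; the add-one rule
    ``p = (1 + count) / (1 + n_done)`` guarantees valid p-values. A SNP stops
    permuting once its exceedance count reaches *drop_count* (sequential
    stopping in the style of PLINK's adaptive mode): its p-value is already
    determined to the precision that matters.

    Returns (p_permuted, n_perm_done) per SNP.
    """
    if max_perm < 1:
        raise ValueError("max_perm must be >= 1")
    y = np.asarray(phenotype, dtype=np.float64)
    if np.all(y == y[0]):
        raise ValueError("phenotype is constant")
    if stat_fun is None:
        stat_fun = make_trend_stat(gm)
    rng = np.random.default_rng(seed)
    m = len(observed)
    obs = np.asarray(observed, dtype=np.float64)
    active = np.isfinite(obs)
    counts = np.zeros(m, dtype=np.int64)
    done = np.zeros(m, dtype=np.int64)
    n_run = 0
    while n_run < max_perm and active.any():
        b = min(batch, max_perm - n_run)
        for _ in range(b):
            perm = rng.permutation(y)
            s = stat_fun(perm)
            counts[active] += s[active] >= obs[active] - 1e-12
        n_run += b
        done[active] = n_run
        active &= counts < drop_count
    done[done == 0] = n_run if n_run else 1
    p = (1.0 + counts) / (1.0 + done)
    p[~np.isfinite(obs)] = np.nan
    return p, done


# ---------------------------------------------------------------------------
# two-locus EM and D' confidence intervals
# ---------------------------------------------------------------------------


@dataclass
class LDResult:
    r2: float
    dprime: float
    hap_freqs: np.ndarray  # [p11, p10, p01, p00] for alleles (alt, ref)
    iterations: int
    converged: bool
    n_pairs: int


def _pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts over pairwise-complete observations."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    a, b = g1[ok].astype(int), g2[ok].astype(int)
    T = np.zeros((3, 3), dtype=np.int64)
    np.add.at(T, (a, b), 1)
    return T


def _em_hap_freqs(T: np.ndarray, tol: float = 1e-8, max_iter: int = 1000):
    """ML haplotype frequencies (p11, p10, p01, p00) by EM; allele 1 = alt."""
    n = T.sum()
    pA = (T[1].sum() + 2 * T[2].sum()) / (2 * n)
    pB = (T[:, 1].sum() + 2 * T[:, 2].sum()) / (2 * n)
    p = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    p = np.clip(p, 1e-12, None)
    p /= p.sum()
    dh = T[1, 1]  # double heterozygotes: phase-ambiguous
    # fixed haplotype contributions from unambiguous genotype classes
    base = np.zeros(4)
    base[0] = 2 * T[2, 2] + T[2, 1] + T[1, 2]  # 1-1
    base[1] = 2 * T[2, 0] + T[2, 1] + T[1, 0]  # 1-0
    base[2] = 2 * T[0, 2] + T[0, 1] + T[1, 2]  # 0-1
    base[3] = 2 * T[0, 0] + T[0, 1] + T[1, 0]  # 0-0
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        denom = p[0] * p[3] + p[1] * p[2]
        x = 0.5 if denom == 0 else p[0] * p[3] / denom
        counts = base + dh * np.array([x, 1 - x, 1 - x, x])
        new = counts / (2 * n)
        if np.abs(new - p).max() < tol:
            p = new
            converged = True
            break
        p = new
    return p, it, converged


def ld_r2_em(g1: np.ndarray, g2: np.ndarray) -> LDResult:
    """EM-based r^2 and D' between two genotype columns (alt-dosage coded)."""
    for g in (g1, g2):
        vals = np.unique(g[g != MISSING])
        if len(vals) < 2:
            raise ValueError("ld_r2_em requires polymorphic columns")
    T = _pair_counts(g1, g2)
    p, it, conv = _em_hap_freqs(T)
    pA = p[0] + p[1]
    pB = p[0] + p[2]
    D = p[0] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = 0.0 if denom == 0 else float(D * D / denom)
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = 0.0 if dmax == 0 else float(D / dmax)
    return LDResult(min(r2, 1.0), float(np.clip(dprime, -1, 1)), p, it, conv, int(T.sum()))


def _geno_class_probs(p: np.ndarray) -> np.ndarray:
    """3x3 genotype-pair probabilities from haplotype freqs [p11,p10,p01,p00]."""
    h = {(1, 1): p[0], (1, 0): p[1], (0, 1): p[2], (0, 0): p[3]}
    P = np.zeros((3, 3))
    for a1 in (0, 1):
        for b1 in (0, 1):
            for a2 in (0, 1):
                for b2 in (0, 1):
                    P[a1 + a2, b1 + b2] += h[(a1, b1)] * h[(a2, b2)]
    return P


def dprime_ci(
    g1: np.ndarray, g2: np.ndarray, grid_points: int = 101, alpha: float = 0.05
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for |D'| on a grid.

    Allele frequencies are fixed at their EM estimates; the likelihood of the
    observed genotype pairs is evaluated along |D'| in [0, 1] (on the ML sign
    of D), normalized, and the central interval read off the CDF.
    """
    T = _pair_counts(g1, g2)
    res = ld_r2_em(g1, g2)
    p = res.hap_freqs
    pA = p[0] + p[1]
    pB = p[0] + p[2]
    D = p[0] - pA * pB
    sign = 1.0 if D >= 0 else -1.0
    if sign > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    grid = np.linspace(0.0, 1.0, grid_points)
    ll = np.full(grid_points, -np.inf)
    for k, dpr in enumerate(grid):
        Dk = sign * dpr * dmax
        hk = np.array(
            [
                pA * pB + Dk,
                pA * (1 - pB) - Dk,
                (1 - pA) * pB - Dk,
                (1 - pA) * (1 - pB) + Dk,
            ]
        )
        if (hk < -1e-12).any():
            continue
        hk = np.clip(hk, 1e-12, None)
        P = _geno_class_probs(hk)
        ll[k] = (T * np.log(np.clip(P, 1e-300, None))).sum()
    like = np.exp(ll - ll.max())
    cdf = np.cumsum(like) / like.sum()
    lo = float(grid[int(np.searchsorted(cdf, alpha))])
    hi = float(grid[min(int(np.searchsorted(cdf, 1 - alpha)), grid_points - 1)])
    return lo, hi


# ---------------------------------------------------------------------------
# haplotype blocks (Gabriel rule)
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeBlock:
    block_id: int
    start_idx: int
    end_idx: int
    interval: GenomicInterval

    @property
    def n_snps(self) -> int:
        return self.end_idx - self.start_idx + 1


def detect_blocks(
    gm: GenotypeMatrix,
    max_pair_dist_kb: float = 1000.0,
    strong_ci_low: float = 0.70,
    strong_ci_high: float = 0.98,
    recomb_ci_high: float = 0.90,
    min_strong_fraction: float = 0.95,
    max_block_snps: int = 120,
) -> list[HaplotypeBlock]:
    """Gabriel confidence-interval haplotype blocks.

    A pair is "strong LD" when its D' CI satisfies lower >= 0.70 and upper
    >= 0.98, and "strong recombination" when upper < 0.90; other pairs are
    uninformative. A candidate region whose endpoint pair is strong LD
    becomes a block when at least 95% of its informative pairs are strong LD.
    Candidates are accepted greedily, longest (bp) first, non-overlapping.
    Pairs farther apart than ``max_pair_dist_kb`` are skipped.
    """
    m = gm.n_variants
    if m < 2:
        raise ValueError("detect_blocks needs at least 2 variants")
    pos = gm.variants["pos_bp"].to_numpy()
    maf = gm.maf()
    informative_site = np.nan_to_num(maf, nan=0.0) > 0
    ci_cache: dict[tuple[int, int], tuple[float, float] | None] = {}

    def ci(i: int, j: int):
        key = (i, j)
        if key not in ci_cache:
            if (pos[j] - pos[i]) > max_pair_dist_kb * 1000 or not (
                informative_site[i] and informative_site[j]
            ):
                ci_cache[key] = None
            else:
                ci_cache[key] = dprime_ci(gm.calls[:, i], gm.calls[:, j])
        return ci_cache[key]

    def classify(c):
        if c is None:
            return "skip"
        lo, hi = c
        if lo >= strong_ci_low and hi >= strong_ci_high:
            return "strong"
        if hi < recomb_ci_high:
            return "recomb"
        return "other"

    candidates = []
    for i in range(m):
        for j in range(i + 1, min(i + max_block_snps, m)):
            if classify(ci(i, j)) == "strong":
                candidates.append((i, j))
    candidates.sort(key=lambda ij: (pos[ij[1]] - pos[ij[0]], ij[1] - ij[0]), reverse=True)
    chrom = gm.variants["chrom"].iloc[0]
    used = np.zeros(m, dtype=bool)
    blocks: list[HaplotypeBlock] = []
    for i, j in candidates:
        if used[i : j + 1].any():
            continue
        strong = 0
        informative = 0
        for a in range(i, j + 1):
            for b in range(a + 1, j + 1):
                cls = classify(ci(a, b))
                if cls == "strong":
                    strong += 1
                    informative += 1
                elif cls == "recomb":
                    informative += 1
        if informative == 0 or strong / informative < min_strong_fraction:
            continue
        used[i : j + 1] = True
        blocks.append(
            HaplotypeBlock(0, i, j, GenomicInterval(chrom, int(pos[i]), int(pos[j])))
        )
    blocks.sort(key=lambda b: b.start_idx)
    for k, b in enumerate(blocks):
        b.block_id = k + 1
    return blocks


# ---------------------------------------------------------------------------
# haplotype pattern association
# ---------------------------------------------------------------------------


@dataclass
class PatternAssociation:
    block_id: int
    interval: GenomicInterval
    allele_string: str
    freq_total: float
    freq_case: float
    freq_control: float
    chi2: float
    p_asymptotic: float
    p_permuted: float | None = None

    @property
    def block_distance_bp(self) -> int:
        return self.interval.span_bp


def _chi2_2x2(a, b, c, d) -> float:
    """Pearson chi-square without continuity correction for [[a,b],[c,d]]."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def pattern_assoc(
    haps: HaplotypeSet,
    blocks: list[HaplotypeBlock],
    phenotype: np.ndarray,
    n_perm: int = 100_000,
    seed: int = 0,
    report_threshold_perm_p: float | None = None,
) -> list[PatternAssociation]:
    """Per-block haplotype pattern tests, pattern-vs-rest, with permutation.

    Each sample contributes both chromosomes; permutation shuffles sample
    labels so the two chromosomes of an individual always move together.
    Patterns containing missing calls exclude those chromosomes. Allele
    strings use the ref/alt letter codes of the variant table.
    """
    y = np.asarray(phenotype).astype(int)
    if len(y) != haps.n_samples:
        raise ValueError("phenotype must be per sample")
    H = haps.haplotypes
    chrom_y = np.repeat(y, 2)
    ref = haps.variants["allele_ref"].to_numpy()
    alt = haps.variants["allele_alt"].to_numpy()
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(y) for _ in range(n_perm)]
    out: list[PatternAssociation] = []
    for blk in blocks:
        W = H[:, blk.start_idx : blk.end_idx + 1]
        valid = (W != MISSING).all(axis=1)
        if not valid.any():
            import warnings

            warnings.warn(f"block {blk.block_id}: all chromosomes missing; skipped")
            continue
        Wv = W[valid]
        keys, inv = np.unique(Wv, axis=0, return_inverse=True)
        n_pat = len(keys)
        is_case = chrom_y[valid] == 1
        n_case = is_case.sum()
        n_ctrl = (~is_case).sum()
        case_counts = np.bincount(inv[is_case], minlength=n_pat)
        ctrl_counts = np.bincount(inv[~is_case], minlength=n_pat)
        tot_counts = case_counts + ctrl_counts
        obs_chi2 = np.array(
            [
                _chi2_2x2(
                    case_counts[k],
                    n_case - case_counts[k],
                    ctrl_counts[k],
                    n_ctrl - ctrl_counts[k],
                )
                for k in range(n_pat)
            ]
        )
        exceed = np.zeros(n_pat, dtype=np.int64)
        if n_perm > 0:
            pat_onehot = np.zeros((valid.sum(), n_pat))
            pat_onehot[np.arange(valid.sum()), inv] = 1.0
            for yp in perms:
                cy = np.repeat(yp, 2)[valid] == 1
                cc = pat_onehot[cy].sum(axis=0)
                nc = cy.sum()
                tc = tot_counts - cc
                ncase_other = nc - cc
                nctrl_other = (len(cy) - nc) - tc
                chi = np.array(
                    [
                        _chi2_2x2(cc[k], nc - cc[k], tc[k], (len(cy) - nc) - tc[k])
                        for k in range(n_pat)
                    ]
                )
                exceed += chi >= obs_chi2 - 1e-12
        for k in range(n_pat):
            letters = "".join(
                alt[blk.start_idx + t] if keys[k, t] == 1 else ref[blk.start_idx + t]
                for t in range(keys.shape[1])
            )
            p_perm = (1.0 + exceed[k]) / (1.0 + n_perm) if n_perm > 0 else None
            pa = PatternAssociation(
                blk.block_id,
                blk.interval,
                letters,
                tot_counts[k] / (n_case + n_ctrl),
                case_counts[k] / n_case if n_case else np.nan,
                ctrl_counts[k] / n_ctrl if n_ctrl else np.nan,
                float(obs_chi2[k]),
                float(stats.chi2.sf(obs_chi2[k], 1)),
                p_perm,
            )
            out.append(pa)
    if report_threshold_perm_p is not None:
        out = [
            pa
            for pa in out
            if pa.p_permuted is not None and pa.p_permuted < report_threshold_perm_p
        ]
    return out


def pattern_assoc_frame(patterns: list[PatternAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "block_id": p.block_id,
                "start_bp": p.interval.start_bp,
                "end_bp": p.interval.end_bp,
                "block_distance_bp": p.block_distance_bp,
                "haplotype": p.allele_string,
                "freq_total": p.freq_total,
                "freq_slick": p.freq_case,
                "freq_nonslick": p.freq_control,
                "chi2": p.chi2,
                "p_value": p.p_asymptotic,
                "p_perm": p.p_permuted,
            }
            for p in patterns
        ]
    )
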