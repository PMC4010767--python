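"""Extended haplotype homozygosity (EHH) and the integrated haplotype score.

EHH at flanking site x, for the chromosomes carrying a given core allele, is
the probability that two randomly drawn carrier chromosomes are identical over
the whole stretch core..x:

    EHH(x) = sum_h C(n_h, 2) / C(n, 2)

over the distinct extended haplotypes h, where n is the number of carrier
chromosomes still informative at x (a chromosome with a missing call anywhere
in the span is excluded from that extension outward).

iHH integrates EHH over physical distance (trapezoid rule) away from the core
in both directions, truncating at the first of: EHH below a cutoff (default
0.05), a maximum extension (default 5 Mb), or the chromosome end. The
unstandardized score is iHS = ln(iHH_ancestral / iHH_derived); standardization
is performed within derived-allele-frequency bins so that scores are
comparable across frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import HAVE_NUMBA, _ihh_side_kernel
from .io import MISSING, HaplotypeSet


@dataclass
class EHHCurve:
    core: int
    allele: int
    direction: int  # +1 right, -1 left
    indices: np.ndarray  # flanking variant indices, starting at the core
    ehh: np.ndarray  # EHH value at each index (1.0 at the core)
    n_carriers: int


def ehh(haps: HaplotypeSet | np.ndarray, core: int, allele: int, direction: int) -> EHHCurve:
    """EHH curve from the core outward in one direction (+1 right / -1 left)."""
    H = haps.haplotypes if isinstance(haps, HaplotypeSet) else np.asarray(haps)
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    carriers = np.where(H[:, core] == allele)[0]
    if len(carriers) < 2:
        raise ValueError(
            f"need >=2 chromosomes carrying allele {allele} at core {core}, got {len(carriers)}"
        )
    sub = H[carriers]
    m = H.shape[1]
    stop = m if direction == 1 else -1
    idxs = range(core, stop, direction)
    gid = np.zeros(len(carriers), dtype=np.int64)
    valid = np.ones(len(carriers), dtype=bool)
    out_idx: list[int] = []
    out_ehh: list[float] = []
    for x in idxs:
        col = sub[:, x]
        valid &= col != MISSING
        n = int(valid.sum())
        if n < 2:
            break
        comb = gid[valid] * 2 + col[valid]
        _, inv, counts = np.unique(comb, return_inverse=True, return_counts=True)
        gid[valid] = inv
        gid[~valid] = -1
        hom = (counts * (counts - 1)).sum() / (n * (n - 1))
        out_idx.append(x)
        out_ehh.append(float(hom))
    return EHHCurve(core, allele, direction, np.array(out_idx), np.array(out_ehh), len(carriers))


@dataclass
class IHSRecord:
    core: int
    ihh_anc: float
    ihh_der: float
    ihs: float  # ln(iHH_anc / iHH_der); NaN when undefined
    derived_freq: float
    truncation: dict = field(default_factory=dict)


_REASONS = {0: "chromosome_end", 1: "max_extend", 2: "ehh_cutoff"}


def _ihh_one_side(H, core, allele, positions, direction, max_extend_bp, ehh_cutoff):
    if HAVE_NUMBA:
        ihh, code = _ihh_side_kernel(
            np.ascontiguousarray(H, dtype=np.int8),
            core,
            allele,
            positions.astype(np.float64),
            direction,
            float(max_extend_bp),
            float(ehh_cutoff),
        )
        return float(ihh), _REASONS[int(code)]
    return _ihh_one_side_py(H, core, allele, positions, direction, max_extend_bp, ehh_cutoff)


def _ihh_one_side_py(H, core, allele, positions, direction, max_extend_bp, ehh_cutoff):
    curve = ehh(H, core, allele, direction)
    pos = positions[curve.indices].astype(np.float64)
    vals = curve.ehh
    limit = positions[core] + direction * max_extend_bp
    reason = "chromosome_end"
    keep = len(vals)
    for k in range(len(vals)):
        if (direction == 1 and pos[k] > limit) or (direction == -1 and pos[k] < limit):
            keep = k
            reason = "max_extend"
            break
        if vals[k] < ehh_cutoff:
            keep = k + 1  # include the first sub-cutoff point, then stop
            reason = "ehh_cutoff"
            break
    pos, vals = pos[:keep], vals[:keep]
    if len(vals) < 2:
        return 0.0, reason
    ihh = float(np.trapezoid(vals, np.abs(pos - pos[0])))
    return ihh, reason


def ihs_unstandardized(
    haps: HaplotypeSet | np.ndarray,
    core: int,
    ancestral_allele: int,
    max_extend_bp: float = 5_000_000,
    ehh_cutoff: float = 0.05,
    positions: np.ndarray | None = None,
) -> IHSRecord:
    """iHH for both alleles at the core and their log-ratio iHS."""
    if isinstance(haps, HaplotypeSet):
        H = haps.haplotypes
        positions = haps.variants["pos_bp"].to_numpy()
    else:
        H = np.asarray(haps)
        if positions is None:
            raise ValueError("positions required when passing a bare array")
    anc = int(ancestral_allele)
    der = 1 - anc
    col = H[:, core]
    n_obs = int((col != MISSING).sum())
    n_der = int((col == der).sum())
    if (col == anc).sum() < 2 or n_der < 2:
        raise ValueError("both alleles need >=2 carriers at the core")
    trunc = {}
    ihh = {}
    for allele, tag in ((anc, "anc"), (der, "der")):
        total = 0.0
        for direction in (-1, +1):
            part, reason = _ihh_one_side(
                H, core, allele, positions, direction, max_extend_bp, ehh_cutoff
            )
            total += part
            trunc[f"{tag}_{'right' if direction == 1 else 'left'}"] = reason
        ihh[tag] = total
    if ihh["anc"] <= 0 or ihh["der"] <= 0:
        ihs = float("nan")
    else:
        ihs = float(np.log(ihh["anc"] / ihh["der"]))
    return IHSRecord(core, ihh["anc"], ihh["der"], ihs, n_der / n_obs, trunc)


def ancestral_by_group_freq(
    haps: HaplotypeSet | np.ndarray,
    group_rows: np.ndarray,
) -> np.ndarray:
    """Per-variant ancestral-allele call from a designated chromosome group.

    For each variant the allele with the higher frequency among the group's
    chromosomes is labelled ancestral; exact ties break toward the whole-panel
    major allele (and toward allele 0 if that is tied too).
    """
    H = haps.haplotypes if isinstance(haps, HaplotypeSet) else np.asarray(haps)
    group_rows = np.asarray(group_rows)
    if len(group_rows) == 0:
        raise ValueError("ancestral_by_group_freq requires a non-empty group")
    sub = H[group_rows]
    obs = sub != MISSING
    n1 = np.where(obs, sub, 0).sum(axis=0)
    nt = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        f1 = np.where(nt > 0, n1 / np.maximum(nt, 1), 0.5)
    anc = np.where(f1 > 0.5, 1, 0).astype(np.int8)
    ties = f1 == 0.5
    if ties.any():
        obs_all = H != MISSING
        f1_all = np.where(obs_all, H, 0).sum(axis=0) / np.maximum(obs_all.sum(axis=0), 1)
        anc[ties] = (f1_all[ties] > 0.5).astype(np.int8)
    return anc


def standardize_ihs(
    ihs: np.ndarray,
    derived_freq: np.ndarray,
    n_bins: int = 20,
    min_bin_size: int = 5,
) -> np.ndarray:
    """|iHS| standardized within equal-width derived-allele-frequency bins.

    Bins with fewer than *min_bin_size* defined scores are merged with their
    nearest lower neighbour (the first bin merges upward). Returns absolute
    standardized scores; NaN inputs stay NaN.
    """
    ihs = np.asarray(ihs, dtype=np.float64)
    freq = np.asarray(derived_freq, dtype=np.float64)
    ok = np.isfinite(ihs)
    if ok.sum() < n_bins:
        if ok.sum() == 0:
            raise ValueError("no defined iHS values to standardize")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_id = np.clip(np.digitize(freq, edges[1:-1]), 0, n_bins - 1)
    # merge sparse bins into neighbours
    remap = np.arange(n_bins)
    counts = np.bincount(bin_id[ok], minlength=n_bins)
    for b in range(n_bins):
        cur = remap[b]
        if counts[cur] < min_bin_size:
            neigh = None
            for d in range(1, n_bins):
                for cand in (b - d, b + d):
                    if 0 <= cand < n_bins and remap[cand] != cur and counts[remap[cand]] > 0:
                        neigh = remap[cand]
                        break
                if neigh is not None:
                    break
            if neigh is not None:
                counts[neigh] += counts[cur]
                counts[cur] = 0
                remap[remap == cur] = neigh
    bin_id = remap[bin_id]
    out = np.full_like(ihs, np.nan)
    for b in np.unique(bin_id[ok]):
        sel = ok & (bin_id == b)
        vals = ihs[sel]
        sd = vals.std(ddof=0)
        if sd == 0:
            out[sel] = 0.0
        else:
            out[sel] = np.abs((vals - vals.mean()) / sd)
    return out


def window_average(track: np.ndarray, window: int = 30) -> np.ndarray:
    """Centered moving mean over defined values; truncated windows at the edges."""
    s = pd.Series(np.asarray(track, dtype=np.float64))
    if window > len(s):
        raise ValueError("window exceeds track length")
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def ihs_scan(
    haps: HaplotypeSet,
    ancestral: np.ndarray,
    max_extend_bp: float = 5_000_000,
    ehh_cutoff: float = 0.05,
    min_maf: float = 0.05,
    n_bins: int = 20,
    window: int = 30,
    core_step: int = 1,
) -> pd.DataFrame:
    """Chromosome-wide |iHS| scan: per-core iHH, standardized |iHS|, window mean."""
    H = haps.haplotypes
    positions = haps.variants["pos_bp"].to_numpy()
    m = H.shape[1]
    ihs_vals = np.full(m, np.nan)
    dfreq = np.full(m, np.nan)
    for core in range(0, m, core_step):
        col = H[:, core]
        obs = col != MISSING
        n = obs.sum()
        if n == 0:
            continue
        f1 = (col[obs] == 1).mean()
        if min(f1, 1 - f1) < min_maf:
            continue
        try:
            rec = ihs_unstandardized(
                H, core, int(ancestral[core]), max_extend_bp, ehh_cutoff, positions
            )
        except ValueError:
            continue
        ihs_vals[core] = rec.ihs
        dfreq[core] = rec.derived_freq
    std = standardize_ihs(ihs_vals, np.nan_to_num(dfreq, nan=0.5), n_bins=n_bins)
    win = window_average(std, window=window)
    return pd.DataFrame(
        {
            "variant_id": haps.variants["variant_id"],
            "chrom": haps.variants["chrom"],
            "pos_bp": positions,
            "derived_freq": dfreq,
            "ihs": ihs_vals,
            "abs_ihs_std": std,
            "window_mean": win,
        }
    )
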