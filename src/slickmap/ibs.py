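"""Windowed identity-by-state haplotype scanning and consensus regions.

The chromosome is partitioned (step 1 by default) into windows of w SNPs;
within each window chromosomes are grouped by exact allele-string identity.
A window supports a phenotype-bound consensus haplotype when some pattern
reaches a minimum frequency among the in-group chromosomes (default 0.4, the
expectation for a dominant trait segregating at intermediate frequency) while
staying at or below a maximum frequency among the out-group (default 0 —
never seen in non-affected animals). Passing windows over a range of window
sizes are merged into maximal consensus regions.

Chromosomes with a missing call anywhere in a window are excluded from that
window (conservative: missing never wildcard-matches).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from ._kernels import HAVE_NUMBA, _ibs_window_kernel, window_codes
from .intervals import GenomicInterval, merge_overlapping
from .io import MISSING, HaplotypeSet


@dataclass
class WindowMatch:
    start_idx: int
    w: int
    allele_string: str
    freq: dict[str, float]  # group name -> exact-match frequency


@dataclass
class ConsensusRegion:
    interval: GenomicInterval
    window_sizes: list[int]
    max_in_freq: float
    max_out_freq: float


def _window_group_ids(H: np.ndarray, w: int) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
    """Yield (start, pattern_id per chromosome, valid mask) for every window.

    Pattern ids are computed incrementally column-by-column and relabelled per
    window so they stay small; invalid (missing-containing) chromosomes get
    id -1.
    """
    n, m = H.shape
    if w < 1 or w > m:
        raise ValueError(f"window size {w} out of range for {m} variants")
    missing = H == MISSING
    # rolling count of missing calls per window
    cum = np.cumsum(missing, axis=1)
    for s in range(m - w + 1):
        n_miss = cum[:, s + w - 1] - (cum[:, s - 1] if s > 0 else 0)
        valid = n_miss == 0
        W = H[:, s : s + w]
        gid = np.full(n, -1, dtype=np.int64)
        if valid.any():
            sub = W[valid]
            _, inv = np.unique(sub, axis=0, return_inverse=True)
            gid[valid] = inv
        yield s, gid, valid


def window_haplotype_freqs(
    haps: HaplotypeSet | np.ndarray,
    groups: dict[str, np.ndarray],
    w: int,
    step: int = 1,
) -> Iterator[list[WindowMatch]]:
    """Stream per-window pattern frequencies for each chromosome group.

    ``groups`` maps a group name to haplotype-row indices. For every window
    position (stride *step*) yields one :class:`WindowMatch` per distinct
    pattern observed among the union of groups, with per-group frequencies
    computed over that group's non-excluded chromosomes.
    """
    H = haps.haplotypes if isinstance(haps, HaplotypeSet) else np.asarray(haps)
    alphabet = "01"
    for s, gid, valid in _window_group_ids(H, w):
        if s % step:
            continue
        n_pat = gid.max() + 1
        matches: list[WindowMatch] = []
        if n_pat > 0:
            per_group = {}
            for name, rows in groups.items():
                rows = np.asarray(rows)
                v = rows[valid[rows]]
                cnt = np.bincount(gid[v], minlength=n_pat).astype(float)
                denom = max(len(v), 1)
                per_group[name] = (cnt / denom, len(v))
            # reconstruct one representative string per pattern id
            rep_rows = {}
            vrows = np.where(valid)[0]
            for r in vrows:
                rep_rows.setdefault(gid[r], r)
            for pid in range(n_pat):
                r = rep_rows[pid]
                string = "".join(alphabet[a] for a in H[r, s : s + w])
                matches.append(
                    WindowMatch(
                        s, w, string, {g: per_group[g][0][pid] for g in groups}
                    )
                )
        yield matches


def _window_pass(
    H: np.ndarray,
    in_rows: np.ndarray,
    out_rows: np.ndarray,
    w: int,
    f_in_min: float,
    f_out_max: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window support test for one window size.

    Returns (pass mask over window starts, best in-group freq, matching
    out-group freq of the best in-group pattern).
    """
    if HAVE_NUMBA and w <= 62:
        codes, nmiss = window_codes(H, w)
        return _ibs_window_kernel(
            codes,
            nmiss,
            np.asarray(in_rows, dtype=np.int64),
            np.asarray(out_rows, dtype=np.int64),
            float(f_in_min),
            float(f_out_max),
            0,
        )
    m = H.shape[1]
    n_win = m - w + 1
    ok = np.zeros(n_win, dtype=bool)
    best_in = np.zeros(n_win)
    best_out = np.zeros(n_win)
    in_rows = np.asarray(in_rows)
    out_rows = np.asarray(out_rows)
    for s, gid, valid in _window_group_ids(H, w):
        vi = in_rows[valid[in_rows]]
        vo = out_rows[valid[out_rows]]
        if len(vi) == 0:
            continue
        n_pat = gid.max() + 1
        ci = np.bincount(gid[vi], minlength=n_pat) / len(vi)
        co = (
            np.bincount(gid[vo], minlength=n_pat) / len(vo)
            if len(vo)
            else np.zeros(n_pat)
        )
        passing = (ci >= f_in_min) & (co <= f_out_max)
        k = int(np.argmax(ci))
        best_in[s] = ci[k]
        best_out[s] = co[k]
        ok[s] = bool(passing.any())
    return ok, best_in, best_out


def consensus_regions(
    haps: HaplotypeSet,
    in_rows: Sequence[int],
    out_rows: Sequence[int],
    w_range: Iterable[int] = range(1, 51),
    f_in_min: float = 0.4,
    f_out_max: float = 0.0,
) -> list[ConsensusRegion]:
    """Consensus haplotype regions bound to the in-group phenotype.

    A window of size w supports consensus when some pattern has in-group
    frequency >= ``f_in_min`` (>= per the boundary convention) and out-group
    frequency <= ``f_out_max``. Passing windows across all window sizes are
    merged into maximal regions.
    """
    w_list = sorted(set(int(w) for w in w_range))
    if not w_list:
        raise ValueError("empty window-size range")
    in_rows = np.asarray(list(in_rows))
    out_rows = np.asarray(list(out_rows))
    if len(in_rows) == 0 or len(out_rows) == 0:
        raise ValueError("in/out chromosome groups must be non-empty")
    if np.intersect1d(in_rows, out_rows).size:
        raise ValueError("in/out groups must be disjoint")
    H = haps.haplotypes
    pos = haps.variants["pos_bp"].to_numpy()
    chrom = haps.variants["chrom"].iloc[0]
    intervals: list[GenomicInterval] = []
    meta: list[tuple[GenomicInterval, int, float, float]] = []
    for w in w_list:
        if w > H.shape[1]:
            raise ValueError(f"window size {w} exceeds variant count {H.shape[1]}")
        ok, best_in, best_out = _window_pass(H, in_rows, out_rows, w, f_in_min, f_out_max)
        for s in np.where(ok)[0]:
            iv = GenomicInterval(chrom, int(pos[s]), int(pos[s + w - 1]))
            intervals.append(iv)
            meta.append((iv, w, best_in[s], best_out[s]))
    if not intervals:
        return []
    merged = merge_overlapping(intervals)
    regions = []
    for reg in merged:
        ws = sorted({w for iv, w, _, _ in meta if iv.overlaps(reg)})
        max_in = max(bi for iv, _, bi, _ in meta if iv.overlaps(reg))
        max_out = max(bo for iv, _, _, bo in meta if iv.overlaps(reg))
        regions.append(ConsensusRegion(reg, ws, float(max_in), float(max_out)))
    return regions


@dataclass
class SharedRegion:
    interval: GenomicInterval
    max_w: int


def shared_between_groups(
    haps: HaplotypeSet,
    rows_a: Sequence[int],
    rows_b: Sequence[int],
    w: int,
    min_freq_each: float,
) -> list[SharedRegion]:
    """Regions where one identical pattern reaches *min_freq_each* in both groups.

    Merged passing windows are annotated with the maximal window size at which
    sharing persists (tested by re-running at increasing w inside each region).
    """
    rows_a = np.asarray(list(rows_a))
    rows_b = np.asarray(list(rows_b))
    if len(rows_a) == 0 or len(rows_b) == 0:
        raise ValueError("both groups must be non-empty")
    H = haps.haplotypes
    pos = haps.variants["pos_bp"].to_numpy()
    chrom = haps.variants["chrom"].iloc[0]

    def passing_windows(width: int) -> list[GenomicInterval]:
        ivs = []
        if HAVE_NUMBA and width <= 62:
            codes, nmiss = window_codes(H, width)
            ok, _, _ = _ibs_window_kernel(
                codes,
                nmiss,
                rows_a.astype(np.int64),
                rows_b.astype(np.int64),
                float(min_freq_each),
                0.0,
                1,
            )
            return [
                GenomicInterval(chrom, int(pos[s]), int(pos[s + width - 1]))
                for s in np.where(ok)[0]
            ]
        for s, gid, valid in _window_group_ids(H, width):
            va = rows_a[valid[rows_a]]
            vb = rows_b[valid[rows_b]]
            if len(va) == 0 or len(vb) == 0:
                continue
            n_pat = gid.max() + 1
            if n_pat <= 0:
                continue
            ca = np.bincount(gid[va], minlength=n_pat) / len(va)
            cb = np.bincount(gid[vb], minlength=n_pat) / len(vb)
            if ((ca >= min_freq_each) & (cb >= min_freq_each)).any():
                ivs.append(GenomicInterval(chrom, int(pos[s]), int(pos[s + width - 1])))
        return ivs

    base = passing_windows(w)
    if not base:
        return []
    out = []
    for reg in merge_overlapping(base):
        max_w = w
        width = w + 1
        while width <= H.shape[1]:
            wins = [iv for iv in passing_windows(width) if iv.overlaps(reg)]
            if not wins:
                break
            max_w = width
            width += 1
        out.append(SharedRegion(reg, max_w))
    return out


@dataclass
class HomozygoteConsensus:
    interval: GenomicInterval
    allele_string: str
    alternatives: list[GenomicInterval] = field(default_factory=list)


def homozygote_consensus(
    haps: HaplotypeSet,
    sample_ids: Sequence[str],
    region_hint: GenomicInterval,
) -> HomozygoteConsensus:
    """Maximal interval where the named homozygous samples share one haplotype.

    Every named sample must be homozygous throughout the hint region (a
    heterozygous call raises, naming sample and position). If the samples'
    homozygous haplotypes disagree inside the hint, the hint splits at the
    disagreeing SNPs and the longest side is returned, with all candidate
    sides reported as alternatives. The returned interval is extended outward
    beyond the hint while all samples stay homozygous and identical.
    """
    pos = haps.variants["pos_bp"].to_numpy()
    chrom = haps.variants["chrom"].iloc[0]
    if region_hint.chrom != chrom:
        raise ValueError("region hint on a different chromosome")
    lo = int(np.searchsorted(pos, region_hint.start_bp, side="left"))
    hi = int(np.searchsorted(pos, region_hint.end_bp, side="right")) - 1
    if hi < lo:
        raise ValueError("region hint contains no variants")
    rows = []
    for sid in sample_ids:
        a, b = haps.rows_of_sample(sid)
        ha, hb = haps.haplotypes[a], haps.haplotypes[b]
        het = np.where((ha != hb) & (ha != MISSING) & (hb != MISSING))[0]
        het = het[(het >= lo) & (het <= hi)]
        if het.size:
            raise ValueError(
                f"sample {sid} heterozygous at {chrom}:{pos[het[0]]} inside the hint region"
            )
        rows.append(a)
    H = haps.haplotypes[rows]
    agree = (H == H[0]).all(axis=0) & (H != MISSING).all(axis=0)
    # split the hint at disagreement points; candidate = maximal agreeing runs
    runs: list[tuple[int, int]] = []
    start = None
    for j in range(lo, hi + 1):
        if agree[j]:
            if start is None:
                start = j
        else:
            if start is not None:
                runs.append((start, j - 1))
                start = None
    if start is not None:
        runs.append((start, hi))
    if not runs:
        raise ValueError("no position in the hint region is shared by all samples")
    runs.sort(key=lambda se: (pos[se[1]] - pos[se[0]]), reverse=True)
    s, e = runs[0]
    # extend outward while agreement persists
    if s == lo:
        while s > 0 and agree[s - 1]:
            s -= 1
    if e == hi:
        while e < len(pos) - 1 and agree[e + 1]:
            e += 1
    string = "".join(str(int(a)) for a in H[0, s : e + 1])
    alts = [
        GenomicInterval(chrom, int(pos[a]), int(pos[b]))
        for a, b in runs[1:]
    ]
    return HomozygoteConsensus(GenomicInterval(chrom, int(pos[s]), int(pos[e])), string, alts)
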