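"""Runs of homozygosity: detection, per-locus frequency track, peak interval.

A run is a stretch of consecutive homozygous genotypes in one individual.
Runs are called in SNP-index space (thresholds are SNP counts, not bp); the
physical interval is reported alongside. By default runs are strict — zero
heterozygous and zero missing calls — but both tolerances are parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import MISSING, GenotypeMatrix


@dataclass
class ROHSegment:
    sample_id: str
    start_idx: int  # variant indices, inclusive
    end_idx: int
    interval: GenomicInterval

    @property
    def n_snps(self) -> int:
        return self.end_idx - self.start_idx + 1


def _sample_runs(hom: np.ndarray, bad_het: np.ndarray, bad_mis: np.ndarray,
                 L: int, het_tol: int, mis_tol: int):
    """Greedy left-to-right maximal runs with bounded het/missing slippage.

    Yields non-overlapping (start, end) index pairs; each run is extended as
    far right as its tolerances allow and the next run starts after it.
    """
    m = len(hom)
    runs = []
    i = 0
    while i < m:
        if not hom[i]:
            i += 1
            continue
        hets = 0
        mis = 0
        j = i
        end = i
        while j < m:
            if bad_het[j]:
                hets += 1
                if hets > het_tol:
                    break
            elif bad_mis[j]:
                mis += 1
                if mis > mis_tol:
                    break
            if hom[j]:
                end = j
            j += 1
        if end - i + 1 >= L:
            runs.append((i, end))
        i = end + 1
    return runs


def detect_roh(
    gm: GenotypeMatrix,
    L: int,
    het_tolerance: int = 0,
    missing_tolerance: int = 0,
) -> list[ROHSegment]:
    """Call ROH of at least *L* consecutive homozygous SNPs per sample.

    Requires a single chromosome. With the default zero tolerances any
    heterozygous or missing call breaks a run. Runs are trimmed to start and
    end on homozygous calls.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    chroms = gm.variants["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("detect_roh expects a single chromosome; subset first")
    chrom = chroms[0]
    pos = gm.variants["pos_bp"].to_numpy()
    if L > gm.n_variants:
        import warnings

        warnings.warn(f"L={L} exceeds variant count {gm.n_variants}; no runs possible")
        return []
    segments: list[ROHSegment] = []
    calls = gm.calls
    hom = (calls == 0) | (calls == 2)
    het = calls == 1
    mis = calls == MISSING
    for i, sid in enumerate(gm.sample_ids()):
        for s, e in _sample_runs(
            hom[i], het[i], mis[i], L, het_tolerance, missing_tolerance
        ):
            segments.append(
                ROHSegment(sid, s, e, GenomicInterval(chrom, int(pos[s]), int(pos[e])))
            )
    return segments


@dataclass
class ROHTrack:
    threshold_L: int
    variants: pd.DataFrame
    frequency: np.ndarray  # per-variant fraction of subset samples in a run
    n_subset: int

    def to_frame(self) -> pd.DataFrame:
        out = self.variants[["variant_id", "chrom", "pos_bp"]].copy()
        out[f"roh_freq_L{self.threshold_L}"] = self.frequency
        return out


def roh_frequency(
    segments: list[ROHSegment],
    subset_sample_ids: list[str],
    gm: GenotypeMatrix,
    L: int,
) -> ROHTrack:
    """Per-variant fraction of *subset* samples whose ROH (>= L SNPs) covers it."""
    subset = list(subset_sample_ids)
    if not subset:
        raise ValueError("roh_frequency requires a non-empty sample subset")
    subset_set = set(subset)
    m = gm.n_variants
    covered: dict[str, np.ndarray] = {s: np.zeros(m, dtype=bool) for s in subset}
    for seg in segments:
        if seg.sample_id in subset_set and seg.n_snps >= L:
            covered[seg.sample_id][seg.start_idx : seg.end_idx + 1] = True
    counts = np.zeros(m, dtype=np.int64)
    for s in subset:
        counts += covered[s]
    return ROHTrack(L, gm.variants, counts / len(subset), len(subset))


def peak_interval(track: ROHTrack, fraction_of_max: float = 0.9) -> GenomicInterval:
    """Smallest interval containing every variant within *fraction_of_max* of the peak."""
    freq = track.frequency
    fmax = np.nanmax(freq)
    if not np.isfinite(fmax) or fmax <= 0:
        raise ValueError("flat zero ROH track has no peak")
    hit = np.where(freq >= fraction_of_max * fmax)[0]
    pos = track.variants["pos_bp"].to_numpy()
    chrom = track.variants["chrom"].iloc[0]
    return GenomicInterval(chrom, int(pos[hit[0]]), int(pos[hit[-1]]))


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.interval.chrom,
                "start_bp": s.interval.start_bp,
                "end_bp": s.interval.end_bp,
                "n_snps": s.n_snps,
            }
            for s in segments
        ]
    )
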