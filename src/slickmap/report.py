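"""Evidence integration, pattern-table arithmetic, and the pipeline driver.

Each analysis contributes an evidence interval on the candidate chromosome.
Tracks are integrated in two tiers: *span* tracks (the association interval
and the ROH autozygosity peak) are intersected to form the consensus locus,
while *support* tracks (the |iHS| peak, IBS consensus regions) are checked
for overlap but do not constrain the interval — they are typically points or
narrow sub-intervals and would otherwise collapse the consensus to nothing.
A strict mode that intersects every track is available behind a flag.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, intersect

TRACK_NAMES = {"gwas", "roh", "ihs", "ibs", "other"}


@dataclass
class EvidenceInterval:
    track: str  # gwas | roh | ihs | ibs | other
    kind: str  # "span" | "support"
    interval: GenomicInterval
    score: float | None = None

    def __post_init__(self) -> None:
        if self.track not in TRACK_NAMES:
            raise ValueError(f"unknown track {self.track!r}")
        if self.kind not in ("span", "support"):
            raise ValueError(f"kind must be 'span' or 'support', got {self.kind!r}")


@dataclass
class ConsensusLocus:
    interval: GenomicInterval | None  # None = no consensus (disjoint spans)
    span_tracks: list[EvidenceInterval]
    supports_overlapping: list[EvidenceInterval] = field(default_factory=list)
    supports_failing: list[EvidenceInterval] = field(default_factory=list)

    @property
    def length_mb(self) -> float | None:
        return None if self.interval is None else self.interval.span_mb


def integrate_consensus(
    evidence: list[EvidenceInterval], strict: bool = False
) -> ConsensusLocus:
    """Intersect span evidence into a consensus locus; classify support tracks.

    With ``strict=True`` support tracks join the intersection as well. An
    empty intersection returns a no-consensus result rather than raising.
    """
    spans = [e for e in evidence if e.kind == "span"]
    supports = [e for e in evidence if e.kind == "support"]
    if strict:
        spans, supports = spans + supports, []
    if not spans:
        raise ValueError("integrate_consensus requires at least one span track")
    chroms = {e.interval.chrom for e in evidence}
    if len(chroms) > 1:
        raise ValueError(f"evidence intervals span multiple chromosomes: {sorted(chroms)}")
    consensus = intersect([e.interval for e in spans])
    if consensus is None:
        return ConsensusLocus(None, spans, [], supports)
    overlapping = [s for s in supports if s.interval.overlaps(consensus)]
    failing = [s for s in supports if not s.interval.overlaps(consensus)]
    return ConsensusLocus(consensus, spans, overlapping, failing)


# ---------------------------------------------------------------------------
# pattern tables
# ---------------------------------------------------------------------------

PATTERN_COLUMNS = [
    "block_id",
    "start_bp",
    "end_bp",
    "block_distance_bp",
    "haplotype",
    "freq_total",
    "freq_slick",
    "freq_nonslick",
    "p_value",
]


def load_pattern_table(path) -> pd.DataFrame:
    """Read and validate a TSV pattern table (one row per block allele pattern)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PATTERN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pattern table missing columns: {sorted(missing)}")
    validate_pattern_table(df)
    return df


def load_bundled_pattern_table() -> pd.DataFrame:
    """The packaged pattern table of slick-associated haplotype blocks (BTA20)."""
    with importlib.resources.files("slickmap.data").joinpath(
        "slick_pattern_table.tsv"
    ).open() as fh:
        return load_pattern_table(fh)


def validate_pattern_table(df: pd.DataFrame) -> None:
    if df.empty:
        raise ValueError("pattern table is empty")
    bad = df["block_distance_bp"] != df["end_bp"] - df["start_bp"]
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"row {row} (block {df.loc[row, 'block_id']}): block_distance_bp "
            "does not equal end_bp - start_bp"
        )
    for col in ("freq_total", "freq_slick", "freq_nonslick"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")


def pattern_table_stats(df: pd.DataFrame) -> dict:
    """Summary arithmetic over a pattern table.

    Control-associated patterns are those more frequent in non-slick than in
    slick chromosomes; zero-control patterns never occur in non-slick
    chromosomes; the max-increase pattern maximizes freq_slick - freq_nonslick.
    """
    validate_pattern_table(df)
    by_block = df.drop_duplicates("block_id")
    longest = by_block.loc[by_block["block_distance_bp"].idxmax()]
    shortest = by_block.loc[by_block["block_distance_bp"].idxmin()]
    inc = df["freq_slick"] - df["freq_nonslick"]
    top = df.loc[inc.idxmax()]
    return {
        "n_patterns": int(len(df)),
        "n_distinct_blocks": int(df["block_id"].nunique()),
        "longest_block_id": int(longest["block_id"]),
        "longest_block_distance_bp": int(longest["block_distance_bp"]),
        "longest_block_n_snps": int(
            df.loc[df["block_id"] == longest["block_id"], "haplotype"]
            .str.len()
            .iloc[0]
        ),
        "shortest_block_id": int(shortest["block_id"]),
        "shortest_block_distance_bp": int(shortest["block_distance_bp"]),
        "n_zero_control_patterns": int((df["freq_nonslick"] == 0).sum()),
        "n_control_associated_patterns": int(
            (df["freq_nonslick"] > df["freq_slick"]).sum()
        ),
        "max_freq_increase": float(inc.max()),
        "max_freq_increase_block_id": int(top["block_id"]),
        "max_freq_increase_haplotype": str(top["haplotype"]),
        "max_freq_increase_freq_slick": float(top["freq_slick"]),
        "max_freq_increase_freq_nonslick": float(top["freq_nonslick"]),
    }


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    consensus: ConsensusLocus
    assoc_frame: pd.DataFrame
    top_variant: pd.Series
    roh_peak: GenomicInterval
    evidence: list[EvidenceInterval]
    ihs_frame: pd.DataFrame | None = None
    ibs_regions: list | None = None
    patterns: pd.DataFrame | None = None


def run_pipeline(
    cohort,
    assoc_p_threshold: float = 1e-6,
    roh_L: int = 50,
    roh_peak_rule: float = 0.75,
    ibs_w_list: tuple[int, ...] = (5, 10, 20, 30, 50),
    ibs_f_in_min: float = 0.4,
    ibs_f_out_max: float = 0.0,
    run_ihs: bool = True,
    run_ibs: bool = True,
    run_patterns: bool = False,
    pattern_n_perm: int = 2000,
    seed: int = 0,
) -> PipelineResult:
    """Full multi-evidence scan of a (simulated or real) cohort.

    Span evidence: the interval spanned by SNPs passing ``assoc_p_threshold``
    in the kinship-corrected association (falling back to the top 0.1% of
    SNPs when nothing passes), and the ROH frequency peak among affected
    samples. Support evidence: the |iHS| window-average peak and IBS
    consensus regions.
    """
    from . import assoc as assoc_mod
    from . import ibs as ibs_mod
    from . import popstruct, roh, selscan

    gm = cohort.genotypes
    haps = cohort.haplotypes
    st = gm.samples
    y = (st["phenotype"] == "slick").to_numpy().astype(float)
    chrom = gm.variants["chrom"].iloc[0]
    pos = gm.variants["pos_bp"].to_numpy()

    K = popstruct.kinship(gm, mode="grm")
    res = assoc_mod.mixed_model_assoc(gm, y, K)
    af = res.to_frame()
    finite = af["p"].notna()
    top = af.loc[af.loc[finite, "p"].idxmin()]
    sig = af.loc[finite & (af["p"] < assoc_p_threshold)]
    if sig.empty:
        cut = af.loc[finite, "p"].quantile(0.001)
        sig = af.loc[finite & (af["p"] <= cut)]
    assoc_iv = GenomicInterval(chrom, int(sig["pos_bp"].min()), int(sig["pos_bp"].max()))

    slick_ids = st.loc[st["phenotype"] == "slick", "sample_id"].tolist()
    segs = roh.detect_roh(gm, L=roh_L)
    track = roh.roh_frequency(segs, slick_ids, gm, L=roh_L)
    roh_iv = roh.peak_interval(track, roh_peak_rule)

    evidence = [
        EvidenceInterval("gwas", "span", assoc_iv, float(-np.log10(top["p"]))),
        EvidenceInterval("roh", "span", roh_iv, float(np.max(track.frequency))),
    ]

    ihs_df = None
    if run_ihs:
        slick_rows = np.where(np.repeat(y, 2) == 1)[0]
        anc = selscan.ancestral_by_group_freq(haps, slick_rows)
        ihs_df = selscan.ihs_scan(haps, anc)
        wm = ihs_df["window_mean"].to_numpy()
        if np.isfinite(wm).any():
            k = int(np.nanargmax(wm))
            evidence.append(
                EvidenceInterval(
                    "ihs",
                    "support",
                    GenomicInterval(chrom, int(pos[k]), int(pos[k])),
                    float(wm[k]),
                )
            )

    regions = None
    if run_ibs:
        case_samples = np.where(y == 1)[0]
        ctrl_samples = np.where(y == 0)[0]
        in_rows = np.concatenate([[2 * i, 2 * i + 1] for i in case_samples])
        out_rows = np.concatenate([[2 * i, 2 * i + 1] for i in ctrl_samples])
        regions = ibs_mod.consensus_regions(
            haps, in_rows, out_rows, ibs_w_list, ibs_f_in_min, ibs_f_out_max
        )
        for reg in regions:
            evidence.append(
                EvidenceInterval("ibs", "support", reg.interval, reg.max_in_freq)
            )

    patterns = None
    if run_patterns:
        lo = int(np.searchsorted(pos, assoc_iv.start_bp))
        hi = int(np.searchsorted(pos, assoc_iv.end_bp, side="right"))
        sub = gm.subset(variant_idx=np.arange(lo, hi))
        blocks = assoc_mod.detect_blocks(sub)
        for b in blocks:
            b.start_idx += lo
            b.end_idx += lo
        pats = assoc_mod.pattern_assoc(
            haps, blocks, y.astype(int), n_perm=pattern_n_perm, seed=seed
        )
        patterns = assoc_mod.pattern_assoc_frame(pats)

    consensus = integrate_consensus(evidence)
    return PipelineResult(
        consensus, af, top, roh_iv, evidence, ihs_df, regions, patterns
    )


def manifest(seed: int, config_repr: str) -> str:
    import hashlib

    from . import __version__

    return json.dumps(
        {
            "seed": seed,
            "config_sha1": hashlib.sha1(config_repr.encode()).hexdigest(),
            "version": __version__,
        },
        indent=2,
    )
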