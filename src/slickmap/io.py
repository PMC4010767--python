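"""Genotype / haplotype containers, file I/O and QC filtering.

Genotypes are stored as alt-allele dosage (0/1/2) in an ``int8`` matrix of
shape (n_samples, n_variants); missing calls use the sentinel :data:`MISSING`
(-1) and are never conflated with homozygous-reference 0. Phased haplotypes
use two rows per sample (0/1 alleles, :data:`MISSING` for unknown).

Supported on-disk formats: VCF 4.x (GT field; phase bars honoured) and PLINK
text PED/MAP. Variant records are sorted by (chrom, pos) on read.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

VARIANT_COLUMNS = ["variant_id", "chrom", "pos_bp", "allele_ref", "allele_alt"]
SAMPLE_COLUMNS = ["sample_id", "breed_code", "phenotype", "role"]

PHENOTYPES = {"slick", "nonslick", "unknown"}
ROLES = {"case", "control", "excluded"}


class ParseError(ValueError):
    """Raised for malformed genotype files, naming the offending line."""


def make_variant_table(
    variant_id, chrom, pos_bp, allele_ref, allele_alt
) -> pd.DataFrame:
    """Assemble and validate a variant table."""
    vt = pd.DataFrame(
        {
            "variant_id": list(variant_id),
            "chrom": list(chrom),
            "pos_bp": np.asarray(pos_bp, dtype=np.int64),
            "allele_ref": list(allele_ref),
            "allele_alt": list(allele_alt),
        }
    )
    validate_variant_table(vt)
    return vt


def validate_variant_table(vt: pd.DataFrame) -> None:
    if vt["variant_id"].duplicated().any():
        dup = vt.loc[vt["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValueError(f"duplicate variant id: {dup}")
    if (vt["pos_bp"] < 1).any():
        raise ValueError("variant positions must be 1-based positive integers")
    for _, sub in vt.groupby("chrom", sort=False):
        d = np.diff(sub["pos_bp"].to_numpy())
        if (d <= 0).any():
            raise ValueError("positions must be strictly increasing within a chromosome")
    same = vt["allele_ref"] == vt["allele_alt"]
    if same.any():
        raise ValueError(f"ref and alt alleles identical at {vt.loc[same, 'variant_id'].iloc[0]}")


def make_sample_table(
    sample_id, breed_code=None, phenotype=None, role=None
) -> pd.DataFrame:
    n = len(sample_id)
    st = pd.DataFrame(
        {
            "sample_id": list(sample_id),
            "breed_code": list(breed_code) if breed_code is not None else [""] * n,
            "phenotype": list(phenotype) if phenotype is not None else ["unknown"] * n,
            "role": list(role) if role is not None else ["excluded"] * n,
        }
    )
    validate_sample_table(st)
    return st


def validate_sample_table(st: pd.DataFrame) -> None:
    if st["sample_id"].duplicated().any():
        dup = st.loc[st["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id: {dup}")
    bad = set(st["phenotype"]) - PHENOTYPES
    if bad:
        raise ValueError(f"unknown phenotype codes: {sorted(bad)}")
    bad = set(st["role"]) - ROLES
    if bad:
        raise ValueError(f"unknown role codes: {sorted(bad)}")
    # a case with a known phenotype must be slick (dominant-trait convention)
    conflict = (st["role"] == "case") & (st["phenotype"] == "nonslick")
    if conflict.any():
        raise ValueError(
            f"sample {st.loc[conflict, 'sample_id'].iloc[0]} is a case but phenotyped nonslick"
        )


@dataclass
class GenotypeMatrix:
    """Diploid genotypes: samples x variants alt-allele dosage with missing sentinel."""

    samples: pd.DataFrame
    variants: pd.DataFrame
    calls: np.ndarray  # (n_samples, n_variants) int8, values {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("genotype calls must be in {0,1,2,MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            self.samples.iloc[si].reset_index(drop=True),
            self.variants.iloc[vi].reset_index(drop=True),
            self.calls[np.ix_(si, vi)],
        )

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls (NaN if none)."""
        calls = self.calls
        obs = calls != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class HaplotypeSet:
    """Phased alleles: two rows per sample, aligned to a variant table."""

    haplotypes: np.ndarray  # (2*n_samples, n_variants) int8 in {0,1,MISSING}
    sample_ids: list[str]
    variants: pd.DataFrame
    samples: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype rows must be 2 x n_samples")
        if self.haplotypes.shape[1] != len(self.variants):
            raise ValueError("haplotype columns inconsistent with variant table")
        if not np.isin(self.haplotypes, (0, 1, MISSING)).all():
            raise ValueError("haplotype alleles must be in {0,1,MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_of_haplotype(self, row: int) -> str:
        return self.sample_ids[row // 2]

    def rows_of_sample(self, sample_id: str) -> tuple[int, int]:
        i = self.sample_ids.index(sample_id)
        return 2 * i, 2 * i + 1

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse row pairs by summation; missing in either row -> MISSING."""
        a = self.haplotypes[0::2]
        b = self.haplotypes[1::2]
        calls = np.where((a == MISSING) | (b == MISSING), MISSING, a + b).astype(np.int8)
        samples = (
            self.samples
            if self.samples is not None
            else make_sample_table(self.sample_ids)
        )
        return GenotypeMatrix(samples.reset_index(drop=True), self.variants, calls)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotypes(path: str, format: str = "vcf", split_multiallelic: bool = False):
    """Read genotypes from ``vcf`` or ``ped_map``.

    For ``ped_map``, *path* is the PED file; the MAP file is found by swapping
    the extension. Multi-allelic VCF sites raise unless ``split_multiallelic``
    (which keeps the first alt and codes others missing).
    """
    if format == "vcf":
        return _read_vcf(path, split_multiallelic)[0]
    if format == "ped_map":
        return _read_ped_map(path)
    raise ValueError(f"unknown format {format!r}; expected 'vcf' or 'ped_map'")


def read_haplotypes(path: str) -> HaplotypeSet:
    """Read a fully phased VCF into a :class:`HaplotypeSet`.

    Every genotype must be phased ('|'); unphased heterozygotes raise.
    """
    gm, haps, fully_phased = _read_vcf(path, split_multiallelic=False)
    if not fully_phased:
        raise ParseError(f"{path}: contains unphased heterozygous genotypes")
    return haps


def _read_vcf(path: str, split_multiallelic: bool):
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    call_cols, hap_cols = [], []
    fully_phased = True
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            if not split_multiallelic:
                raise ParseError(
                    f"{path}: multi-allelic record at line for {rec.CHROM}:{rec.POS}"
                )
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0] if rec.ALT else ".")
        gt = np.array(rec.genotype.array(), dtype=np.int16)  # (n, ploidy+1); last col phase
        a0 = gt[:, 0].astype(np.int16)
        a1 = gt[:, 1].astype(np.int16)
        phased = gt[:, 2].astype(bool)
        a0 = np.where(a0 < 0, MISSING, np.minimum(a0, 1))
        a1 = np.where(a1 < 0, MISSING, np.minimum(a1, 1))
        het = (a0 != a1) & (a0 != MISSING) & (a1 != MISSING)
        if (het & ~phased).any():
            fully_phased = False
        col = np.where((a0 == MISSING) | (a1 == MISSING), MISSING, a0 + a1)
        call_cols.append(col.astype(np.int8))
        hap_cols.append(np.stack([a0, a1], axis=1).astype(np.int8))
    if not ids:
        raise ParseError(f"{path}: no variant records")
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate variant ids")
    variants = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chroms,
            "pos_bp": np.array(poss, dtype=np.int64),
            "allele_ref": refs,
            "allele_alt": alts,
        }
    )
    order = np.lexsort((variants["pos_bp"].to_numpy(), variants["chrom"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    validate_variant_table(variants)
    calls = np.stack(call_cols, axis=1)[:, order]
    haps = np.stack(hap_cols, axis=2)[:, :, order]  # (n, 2, m)
    hap_mat = haps.reshape(2 * n, len(ids))
    samples = make_sample_table(sample_ids)
    gm = GenotypeMatrix(samples, variants, calls)
    hs = HaplotypeSet(hap_mat, sample_ids, variants, samples)
    return gm, hs, fully_phased


def write_vcf(path: str, gm: GenotypeMatrix) -> None:
    """Write unphased genotypes as a minimal VCF 4.2 text file."""
    _write_vcf(path, gm.variants, gm.sample_ids(), calls=gm.calls)


def write_haplotypes(path: str, hs: HaplotypeSet) -> None:
    """Write phased haplotypes as a VCF 4.2 text file ('|' separators)."""
    _write_vcf(path, hs.variants, list(hs.sample_ids), haps=hs.haplotypes)


def _write_vcf(path, variants, sample_ids, calls=None, haps=None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(variants["chrom"]):
            maxpos = int(variants.loc[variants["chrom"] == chrom, "pos_bp"].max())
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for j in range(len(variants)):
            v = variants.iloc[j]
            if haps is not None:
                a = haps[0::2, j]
                b = haps[1::2, j]
                gts = [
                    "./."
                    if a[i] == MISSING or b[i] == MISSING
                    else f"{a[i]}|{b[i]}"
                    for i in range(len(sample_ids))
                ]
            else:
                code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [code[int(c)] for c in calls[:, j]]
            fh.write(
                f"{v.chrom}\t{v.pos_bp}\t{v.variant_id}\t{v.allele_ref}\t"
                f"{v.allele_alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def _map_path_for(ped_path: str) -> str:
    base, _ = os.path.splitext(ped_path)
    return base + ".map"


def _read_ped_map(ped_path: str) -> GenotypeMatrix:
    map_path = _map_path_for(ped_path)
    ids, chroms, poss = [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 columns")
            chroms.append(fields[0])
            ids.append(fields[1])
            poss.append(int(fields[3]))
    if len(set(ids)) != len(ids):
        raise ParseError(f"{map_path}: duplicate variant ids")
    m = len(ids)
    sample_ids, pheno, rows, allele_rows = [], [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            pheno.append(fields[5])
            allele_rows.append(fields[6:])
    # PED carries letter pairs with no ref/alt orientation; orient
    # deterministically (ref = lexicographically smaller allele) so that
    # read -> write -> read is the identity
    alleles = np.array(allele_rows, dtype="U4").reshape(len(sample_ids), m, 2)
    ref_codes = np.full(m, "", dtype="U4")
    alt_codes = np.full(m, "", dtype="U4")
    calls = np.full((len(sample_ids), m), MISSING, dtype=np.int8)
    for j in range(m):
        site = alleles[:, j, :]
        seen = sorted(a for a in pd.unique(site.ravel()) if a != "0")
        if len(seen) > 2:
            raise ParseError(f"{ped_path}: more than two alleles at {ids[j]}")
        ref = seen[0] if seen else "A"
        alt = seen[1] if len(seen) > 1 else ("B" if ref != "B" else "C")
        ref_codes[j], alt_codes[j] = ref, alt
        miss = (site == "0").any(axis=1)
        dose = (site == alt).sum(axis=1).astype(np.int8)
        calls[:, j] = np.where(miss, MISSING, dose)
    variants = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chroms,
            "pos_bp": np.array(poss, dtype=np.int64),
            "allele_ref": ref_codes,
            "allele_alt": alt_codes,
        }
    )
    order = np.lexsort((variants["pos_bp"].to_numpy(), variants["chrom"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    validate_variant_table(variants)
    phen_map = {"2": "slick", "1": "nonslick"}
    samples = make_sample_table(
        sample_ids, phenotype=[phen_map.get(p, "unknown") for p in pheno]
    )
    return GenotypeMatrix(samples, variants, calls[:, order])


def write_ped_map(ped_path: str, gm: GenotypeMatrix) -> None:
    map_path = _map_path_for(ped_path)
    with open(map_path, "w") as fh:
        for _, v in gm.variants.iterrows():
            fh.write(f"{v.chrom}\t{v.variant_id}\t0\t{v.pos_bp}\n")
    ref = gm.variants["allele_ref"].to_numpy()
    alt = gm.variants["allele_alt"].to_numpy()
    phen_code = {"slick": "2", "nonslick": "1", "unknown": "0"}
    with open(ped_path, "w") as fh:
        for i in range(gm.n_samples):
            s = gm.samples.iloc[i]
            lead = [s.sample_id, s.sample_id, "0", "0", "0", phen_code[s.phenotype]]
            pairs = []
            for j in range(gm.n_variants):
                c = gm.calls[i, j]
                if c == MISSING:
                    pairs += ["0", "0"]
                elif c == 0:
                    pairs += [ref[j], ref[j]]
                elif c == 1:
                    pairs += [ref[j], alt[j]]
                else:
                    pairs += [alt[j], alt[j]]
            fh.write(" ".join(lead + pairs) + "\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_samples_in: int
    n_variants_in: int
    samples_removed: list[str]
    variants_removed_call_rate: list[str]
    variants_removed_maf: list[str]
    order: str = "samples -> variant call rate -> MAF (recomputed); passes repeated to fixed point"

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - len(self.samples_removed)

    @property
    def n_variants_out(self) -> int:
        return (
            self.n_variants_in
            - len(self.variants_removed_call_rate)
            - len(self.variants_removed_maf)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("sample", s, "call_rate") for s in self.samples_removed]
            + [("variant", v, "call_rate") for v in self.variants_removed_call_rate]
            + [("variant", v, "maf") for v in self.variants_removed_maf]
        )
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])


def qc_filter(
    gm: GenotypeMatrix,
    min_variant_call: float = 0.90,
    min_maf: float = 0.05,
    min_sample_call: float = 0.95,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply call-rate and MAF filters with strict (>) thresholds.

    Order within a pass: samples failing call rate are dropped first (their
    removal changes variant call rates), then variants failing call rate,
    then MAF is recomputed on the survivors and low-MAF variants dropped.
    Passes repeat until nothing more is removed (each removal can change the
    other dimension's call rates), which makes the filter idempotent.
    """
    if gm.n_samples == 0 or gm.n_variants == 0:
        raise ValueError("qc_filter requires a non-empty genotype matrix")
    removed_samples: list[str] = []
    removed_call: list[str] = []
    removed_maf: list[str] = []
    n_samples_in, n_variants_in = gm.n_samples, gm.n_variants
    while True:
        changed = False
        obs = gm.calls != MISSING
        keep_s = obs.mean(axis=1) > min_sample_call
        if not keep_s.all():
            changed = True
            removed_samples += [s for s, k in zip(gm.sample_ids(), keep_s) if not k]
            gm = gm.subset(sample_idx=np.where(keep_s)[0])
            if gm.n_samples == 0:
                raise ValueError("qc_filter removed every sample")
        keep_v = (gm.calls != MISSING).mean(axis=0) > min_variant_call
        if not keep_v.all():
            changed = True
            removed_call += gm.variants.loc[~keep_v, "variant_id"].tolist()
            gm = gm.subset(variant_idx=np.where(keep_v)[0])
        if gm.n_variants:
            keep_maf = np.nan_to_num(gm.maf(), nan=-1.0) > min_maf
            if not keep_maf.all():
                changed = True
                removed_maf += gm.variants.loc[~keep_maf, "variant_id"].tolist()
                gm = gm.subset(variant_idx=np.where(keep_maf)[0])
        if gm.n_variants == 0:
            raise ValueError("qc_filter removed every variant")
        if not changed:
            break
    report = QCReport(
        n_samples_in, n_variants_in, removed_samples, removed_call, removed_maf
    )
    return gm, report
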