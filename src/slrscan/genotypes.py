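"""Population genotypes: SEMS classification and exact sex association.

The decisive screen for a fully sex-linked SNP is the *SEMS* pattern ("SNP
exactly matching with sexes"): under male heterogamety (XY) every female is
homozygous and every male heterozygous at the site; under female heterogamety
(ZW) the mirror holds.  Because perfect genotype/sex separation is the
criterion, the association statistic used here is the two-sided Fisher exact
test on the 2x2 (heterozygote carrier) x (sex) table; a perfectly separating
site attains the minimum p-value for its sample split.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# genotype codes (int8)
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


@dataclass(frozen=True)
class SexTable:
    """Sample -> sex ('F' or 'M') phenotype table."""

    entries: Mapping[str, str]

    def __post_init__(self):
        bad = {s for s, x in self.entries.items() if x not in ("F", "M")}
        if bad:
            raise ValueError(f"sex must be 'F' or 'M'; offending samples: {sorted(bad)}")
        sexes = set(self.entries.values())
        if sexes != {"F", "M"}:
            raise ValueError("need at least one sample of each sex")

    @property
    def females(self) -> list[str]:
        return [s for s, x in self.entries.items() if x == "F"]

    @property
    def males(self) -> list[str]:
        return [s for s, x in self.entries.items() if x == "M"]

    def __contains__(self, sample: str) -> bool:
        return sample in self.entries

    def sex_of(self, sample: str) -> str:
        return self.entries[sample]

    def masks(self, samples: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (female, male) masks aligned to ``samples``."""
        sex = np.array([self.entries[s] for s in samples])
        return sex == "F", sex == "M"

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SexTable":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "sex"],
                         dtype=str, comment="#")
        if df["sample"].duplicated().any():
            dup = df.loc[df["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate sample ids in sex table: {dup}")
        return cls(dict(zip(df["sample"], df["sex"])))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, x in self.entries.items():
                fh.write(f"{s}\t{x}\n")


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls, sites x samples.

    ``sites`` holds chrom / pos0 (0-based) / ref / alt; ``calls`` is an int8
    array with codes HOM_REF=0, HET=1, HOM_ALT=2, MISSING=-1, columns ordered
    as ``samples``.
    """

    sites: pd.DataFrame
    calls: np.ndarray
    samples: list[str]

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError("calls shape does not match sites x samples")
        if len(self.sites):
            key = self.sites[["chrom", "pos0"]]
            if key.duplicated().any():
                raise ValueError("duplicate sites")
            srt = key.sort_values(["chrom", "pos0"])
            if not (srt.index == key.index).all():
                raise ValueError("sites must be sorted by (chrom, pos0)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sites.iloc[idx].reset_index(drop=True),
                              self.calls[idx], list(self.samples))

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.samples == other.samples
                and self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True))
                and np.array_equal(self.calls, other.calls))


@dataclass
class SEMSRecord:
    """One site whose genotype pattern exactly matches the sexes."""

    site_index: int
    chrom: str
    pos0: int
    ref: str
    alt: str
    pattern: str                      # 'XY' or 'ZW'
    n_conforming_f: int
    n_conforming_m: int
    n_missing_f: int
    n_missing_m: int
    in_slr: bool
    p_exact: float
    crossmap_suspect: bool | None = None   # set by the similarity screen


def read_genotypes(vcf_path: str | Path, sex_table: SexTable) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF; non-SNP / multiallelic records dropped.

    Every VCF sample must appear in ``sex_table``.  Unparsable genotypes
    become MISSING.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    missing_samples = [s for s in vcf.samples if s not in sex_table]
    if missing_samples:
        raise ValueError(f"VCF samples absent from sex table: {missing_samples}")
    samples = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_dropped = 0
    bases = {"A", "C", "G", "T"}
    for v in vcf:
        if (len(v.ALT) != 1 or len(v.REF) != 1 or v.REF not in bases
                or len(v.ALT[0]) != 1 or v.ALT[0] not in bases):
            n_dropped += 1
            continue
        gt = np.asarray(v.gt_types, dtype=np.int8)  # 0 hom_ref, 1 het, 2 hom_alt, 3 unknown
        gt[gt == 3] = MISSING
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(gt)
    if n_dropped:
        logger.info("read_genotypes: dropped %d non-biallelic/non-SNP records", n_dropped)
    sites = pd.DataFrame({"chrom": chroms, "pos0": poss, "ref": refs, "alt": alts})
    calls = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    order = np.lexsort((sites["pos0"].to_numpy(), sites["chrom"].to_numpy())) if len(sites) else []
    sites = sites.iloc[order].reset_index(drop=True) if len(sites) else sites
    calls = calls[order] if len(sites) else calls
    return GenotypeMatrix(sites, calls, samples)


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Emit a minimal VCFv4.2 (GT only, biallelic SNPs, 1-based POS)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=slrscan\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        chroms = matrix.sites["chrom"].to_numpy()
        poss = matrix.sites["pos0"].to_numpy()
        refs = matrix.sites["ref"].to_numpy()
        alts = matrix.sites["alt"].to_numpy()
        for i in range(matrix.n_sites):
            gts = "\t".join(_GT_STRING[int(g)] for g in matrix.calls[i])
            fh.write(f"{chroms[i]}\t{poss[i] + 1}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t.\tGT\t{gts}\n")


def filter_sites(matrix: GenotypeMatrix, maf_min: float = 0.05,
                 max_missing: float = 0.1) -> GenotypeMatrix:
    """plink-style site filter: MAF >= maf_min and missing fraction <= max_missing.

    MAF is computed from genotype-derived allele counts over non-missing
    calls; fully sex-linked sites violate HWE by construction, so no HWE
    assumption is made.
    """
    if matrix.n_sites == 0:
        return matrix
    nm = matrix.calls >= 0
    n_nm = nm.sum(axis=1)
    alt = ((matrix.calls == HET).sum(axis=1) + 2 * (matrix.calls == HOM_ALT).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(n_nm > 0, alt / (2.0 * n_nm), 0.0)
    maf = np.minimum(af, 1.0 - af)
    miss_frac = 1.0 - n_nm / matrix.n_samples
    keep = (maf >= maf_min) & (miss_frac <= max_missing) & (n_nm > 0)
    out = matrix.take_sites(np.flatnonzero(keep))
    if out.n_sites == 0:
        logger.warning("filter_sites removed all %d sites", matrix.n_sites)
    return out


def _in_interval(sites: pd.DataFrame, slr: tuple[str, int, int] | None) -> np.ndarray:
    if slr is None:
        return np.zeros(len(sites), dtype=bool)
    chrom, start, end = slr
    return ((sites["chrom"] == chrom)
            & (sites["pos0"] >= start) & (sites["pos0"] < end)).to_numpy()


def classify_sems(matrix: GenotypeMatrix, sex_table: SexTable,
                  patterns: Iterable[str] = ("XY", "ZW"),
                  min_callrate_per_sex: float = 0.9,
                  strict_hom_class: bool = False,
                  strict_no_missing: bool = False,
                  slr: tuple[str, int, int] | None = None,
                  compute_p: bool = True) -> list[SEMSRecord]:
    """Find sites whose genotypes exactly match the sexes.

    XY pattern: every non-missing female homozygous (HOM_REF/HOM_ALT mix
    allowed unless ``strict_hom_class``), every non-missing male HET, and
    per-sex call rate >= ``min_callrate_per_sex`` (``strict_no_missing``
    forbids any missing call).  ZW is the mirror.  A site matches at most one
    pattern.
    """
    f_mask, m_mask = sex_table.masks(matrix.samples)
    n_f, n_m = int(f_mask.sum()), int(m_mask.sum())
    cf, cm = matrix.calls[:, f_mask], matrix.calls[:, m_mask]

    def _sex_counts(c):
        nm = (c >= 0).sum(axis=1)
        hom = ((c == HOM_REF) | (c == HOM_ALT)).sum(axis=1)
        het = (c == HET).sum(axis=1)
        homref = (c == HOM_REF).sum(axis=1)
        homalt = (c == HOM_ALT).sum(axis=1)
        return nm, hom, het, homref, homalt

    nm_f, hom_f, het_f, homref_f, homalt_f = _sex_counts(cf)
    nm_m, hom_m, het_m, homref_m, homalt_m = _sex_counts(cm)

    if strict_no_missing:
        callrate_ok = (nm_f == n_f) & (nm_m == n_m)
    else:
        callrate_ok = ((nm_f >= min_callrate_per_sex * n_f)
                       & (nm_m >= min_callrate_per_sex * n_m))
    informative = (nm_f > 0) & (nm_m > 0) & callrate_ok

    def _uniform_hom(homref, homalt, nm):
        return (homref == nm) | (homalt == nm)

    xy = informative & (hom_f == nm_f) & (het_m == nm_m)
    zw = informative & (hom_m == nm_m) & (het_f == nm_f)
    if strict_hom_class:
        xy &= _uniform_hom(homref_f, homalt_f, nm_f)
        zw &= _uniform_hom(homref_m, homalt_m, nm_m)
    # a site where both hold would need every sample both hom and het
    both = xy & zw
    if both.any():  # pragma: no cover - impossible with >=1 call per sex
        xy &= ~both
        zw &= ~both

    in_slr = _in_interval(matrix.sites, slr)
    pvals = exact_association(matrix, sex_table) if compute_p else None

    records: list[SEMSRecord] = []
    sites = matrix.sites
    for pat, mask in (("XY", xy), ("ZW", zw)):
        if pat not in patterns:
            continue
        for i in np.flatnonzero(mask):
            conf_f = int(hom_f[i] if pat == "XY" else het_f[i])
            conf_m = int(het_m[i] if pat == "XY" else hom_m[i])
            records.append(SEMSRecord(
                site_index=int(i),
                chrom=str(sites["chrom"].iloc[i]),
                pos0=int(sites["pos0"].iloc[i]),
                ref=str(sites["ref"].iloc[i]),
                alt=str(sites["alt"].iloc[i]),
                pattern=pat,
                n_conforming_f=conf_f,
                n_conforming_m=conf_m,
                n_missing_f=int(n_f - nm_f[i]),
                n_missing_m=int(n_m - nm_m[i]),
                in_slr=bool(in_slr[i]),
                p_exact=float(pvals[i]) if pvals is not None else math.nan,
            ))
    records.sort(key=lambda r: r.site_index)
    return records


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     _cache: dict = {}) -> float:
    """Two-sided Fisher exact p for table [[a, b], [c, d]] (cached)."""
    key = (a, b, c, d)
    p = _cache.get(key)
    if p is None:
        if min(a + b, c + d, a + c, b + d) == 0:
            p = 1.0
        else:
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        _cache[key] = p
    return min(p, 1.0)


def exact_association(matrix: GenotypeMatrix, sex_table: SexTable) -> np.ndarray:
    """Per-site two-sided Fisher exact p on (HET carrier) x (sex).

    The table is built over non-missing calls; a degenerate table (any zero
    margin) yields p = 1.
    """
    f_mask, m_mask = sex_table.masks(matrix.samples)
    cf, cm = matrix.calls[:, f_mask], matrix.calls[:, m_mask]
    het_f = (cf == HET).sum(axis=1)
    nm_f = (cf >= 0).sum(axis=1)
    het_m = (cm == HET).sum(axis=1)
    nm_m = (cm >= 0).sum(axis=1)
    p = np.ones(matrix.n_sites)
    for i in range(matrix.n_sites):
        p[i] = fisher_exact_2x2(int(het_f[i]), int(nm_f[i] - het_f[i]),
                                int(het_m[i]), int(nm_m[i] - het_m[i]))
    return p


def bonferroni_cutoff(alpha: float, n_tests: int) -> float:
    """Family-wise p-value cutoff alpha / n_tests."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


@dataclass(frozen=True)
class HeterogametyCall:
    system: str            # 'XY', 'ZW' or 'undetermined'
    n_xy: int
    n_zw: int


def infer_heterogamety(sems: Sequence[SEMSRecord],
                       majority_ratio: float = 2.0) -> HeterogametyCall:
    """Call the heterogametic system from the SEMS pattern majority.

    Returns XY (male heterogamety) or ZW when the majority pattern outnumbers
    the minority by at least ``majority_ratio``; otherwise undetermined.
    """
    n_xy = sum(1 for r in sems if r.pattern == "XY")
    n_zw = sum(1 for r in sems if r.pattern == "ZW")
    major, minor = max(n_xy, n_zw), min(n_xy, n_zw)
    if major == 0 or (minor > 0 and major < majority_ratio * minor):
        system = "undetermined"
    else:
        system = "XY" if n_xy > n_zw else ("ZW" if n_zw > n_xy else "undetermined")
    return HeterogametyCall(system, n_xy, n_zw)


def write_sems_tsv(records: Sequence[SEMSRecord], path: str | Path) -> None:
    """SEMS table with 1-based positions."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tpattern\tn_conf_F\tn_conf_M\tp_exact\t"
                 "in_slr\tcrossmap_suspect\n")
        for r in records:
            cs = "" if r.crossmap_suspect is None else str(int(r.crossmap_suspect))
            fh.write(f"{r.chrom}\t{r.pos0 + 1}\t{r.ref}\t{r.alt}\t{r.pattern}\t"
                     f"{r.n_conforming_f}\t{r.n_conforming_m}\t{r.p_exact:.6g}\t"
                     f"{int(r.in_slr)}\t{cs}\n")


def write_manhattan_tsv(matrix: GenotypeMatrix, pvalues: np.ndarray,
                        path: str | Path) -> None:
    """Per-site -log10 p, 1-based positions."""
    neg = -np.log10(np.maximum(np.asarray(pvalues, dtype=float), 1e-300))
    df = pd.DataFrame({"chrom": matrix.sites["chrom"],
                       "pos": matrix.sites["pos0"] + 1,
                       "neg_log10_p": np.round(neg, 6)})
    df.to_csv(path, sep="\t", index=False)
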