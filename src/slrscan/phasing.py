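"""Trio-based reconstruction of the X and Y haplotypes across the SLR.

A sequenced male who inherited his X chromosome from a sequenced mother
lets his SLR genotypes be split into the X-borne and Y-borne alleles: at
sites where the son is heterozygous and the mother homozygous, the maternal
allele is the X allele and the other is the Y allele.  Sites where both are
heterozygous carry no phase information from genotypes alone (the SLR does
not recombine, but unphased genotype codes cannot propagate phase without
read-backed evidence), so they are reported ambiguous rather than guessed.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import HOM_REF, HET, HOM_ALT, MISSING

STATUS_PHASED = "phased"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_CONFLICT = "mendel_conflict"
STATUS_MISSING = "missing"

_IUPAC = {frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
          frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M"}


@dataclass
class TrioInput:
    """Mother and son genotype calls at the same SLR sites.

    ``sites`` columns: chrom, pos0, ref, alt; call codes as in
    GenotypeMatrix (0 hom-ref, 1 het, 2 hom-alt, -1 missing).
    """

    slr_interval: tuple[str, int, int]
    sites: pd.DataFrame
    mother_calls: np.ndarray
    son_calls: np.ndarray

    def __post_init__(self):
        self.mother_calls = np.asarray(self.mother_calls, dtype=np.int8)
        self.son_calls = np.asarray(self.son_calls, dtype=np.int8)
        n = len(self.sites)
        if self.mother_calls.shape != (n,) or self.son_calls.shape != (n,):
            raise ValueError("call arrays must match the site list")
        chrom, start, end = self.slr_interval
        pos = self.sites["pos0"]
        if len(pos) and ((pos < start) | (pos >= end)).any():
            raise ValueError("sites must lie within the SLR interval")


@dataclass
class PhasedHaplotypes:
    """Per-site X/Y allele assignment with a phasing status."""

    sites: pd.DataFrame
    x_allele: np.ndarray          # dtype '<U1'; '.' where unassigned
    y_allele: np.ndarray
    status: np.ndarray            # dtype object / str

    def summary(self) -> dict[str, int]:
        vals, counts = np.unique(self.status, return_counts=True)
        out = {s: 0 for s in (STATUS_PHASED, STATUS_AMBIGUOUS,
                              STATUS_CONFLICT, STATUS_MISSING)}
        out.update(dict(zip(vals.tolist(), counts.tolist())))
        return out

    def to_frame(self) -> pd.DataFrame:
        df = self.sites.copy()
        df["x_allele"] = self.x_allele
        df["y_allele"] = self.y_allele
        df["status"] = self.status
        return df

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["pos"] = df.pop("pos0") + 1
        df[["chrom", "pos", "ref", "alt", "x_allele", "y_allele", "status"]].to_csv(
            path, sep="\t", index=False)


def phase_slr(trio: TrioInput) -> PhasedHaplotypes:
    """Assign each SLR site's son alleles to the X and Y haplotypes.

    Rules (biallelic codes): son homozygous -> X = Y = that allele (a
    homozygous mother lacking the allele is a Mendelian conflict); son het
    with homozygous mother -> X = maternal allele, Y = the other; son het
    with het mother -> ambiguous; any missing call -> missing.  Phased
    alleles always come from the son's genotype — phasing never invents an
    allele.
    """
    n = len(trio.sites)
    if n == 0:
        raise ValueError("empty site list")
    ref = trio.sites["ref"].to_numpy(dtype=object)
    alt = trio.sites["alt"].to_numpy(dtype=object)
    mo, so = trio.mother_calls, trio.son_calls
    x = np.full(n, ".", dtype=object)
    y = np.full(n, ".", dtype=object)
    status = np.full(n, STATUS_MISSING, dtype=object)

    missing = (mo == MISSING) | (so == MISSING)

    son_hom_ref = ~missing & (so == HOM_REF)
    son_hom_alt = ~missing & (so == HOM_ALT)
    conflict = (son_hom_ref & (mo == HOM_ALT)) | (son_hom_alt & (mo == HOM_REF))
    status[conflict] = STATUS_CONFLICT
    for hom, allele in ((son_hom_ref, ref), (son_hom_alt, alt)):
        ok = hom & ~conflict
        x[ok] = allele[ok]
        y[ok] = allele[ok]
        status[ok] = STATUS_PHASED

    son_het = ~missing & (so == HET)
    informative_ref = son_het & (mo == HOM_REF)   # X = ref, Y = alt
    informative_alt = son_het & (mo == HOM_ALT)   # X = alt, Y = ref
    x[informative_ref] = ref[informative_ref]
    y[informative_ref] = alt[informative_ref]
    x[informative_alt] = alt[informative_alt]
    y[informative_alt] = ref[informative_alt]
    status[informative_ref | informative_alt] = STATUS_PHASED
    status[son_het & (mo == HET)] = STATUS_AMBIGUOUS

    return PhasedHaplotypes(trio.sites.reset_index(drop=True), x, y, status)


def conflict_rate(phased: PhasedHaplotypes) -> float:
    """Fraction of non-missing sites with a Mendelian conflict (a high rate
    signals a sample mix-up)."""
    s = phased.summary()
    denom = s[STATUS_PHASED] + s[STATUS_AMBIGUOUS] + s[STATUS_CONFLICT]
    return s[STATUS_CONFLICT] / denom if denom else 0.0


def emit_haplotype_fasta(phased: PhasedHaplotypes, slr_reference: str,
                         slr_start: int = 0, name: str = "SLR"
                         ) -> dict[str, str]:
    """Substitute phased alleles into the SLR reference sequence.

    Returns two records (suffixes ``_SLR-X`` / ``_SLR-Y``).  Ambiguous sites
    become the two-base IUPAC code of ref+alt; conflict or missing sites
    become N.  Site alleles must be consistent with the site's ref/alt.
    """
    xb = list(slr_reference.upper())
    yb = list(slr_reference.upper())
    pos = phased.sites["pos0"].to_numpy()
    ref = phased.sites["ref"].to_numpy(dtype=object)
    alt = phased.sites["alt"].to_numpy(dtype=object)
    for i in range(len(pos)):
        off = int(pos[i]) - slr_start
        if not (0 <= off < len(xb)):
            raise ValueError(f"site at pos0={pos[i]} outside the SLR reference")
        if xb[off] != ref[i]:
            raise ValueError(
                f"reference base {xb[off]!r} at pos0={pos[i]} does not match site ref {ref[i]!r}")
        st = phased.status[i]
        if st == STATUS_PHASED:
            for arr, allele in ((xb, phased.x_allele[i]), (yb, phased.y_allele[i])):
                if allele not in (ref[i], alt[i]):
                    raise ValueError(f"allele {allele!r} inconsistent with site ref/alt")
                arr[off] = allele
        elif st == STATUS_AMBIGUOUS:
            code = _IUPAC.get(frozenset((ref[i], alt[i])), "N")
            xb[off] = code
            yb[off] = code
        else:  # conflict or missing
            xb[off] = "N"
            yb[off] = "N"
    return {f"{name}_SLR-X": "".join(xb), f"{name}_SLR-Y": "".join(yb)}
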