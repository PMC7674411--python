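"""Windowed read-coverage scan for sex-specific hemizygous regions.

Read depth in 100-bp windows is collapsed to three categories (0 = no read,
1 = depth 1-2, 2 = depth >= 3, i.e. reliably covered), and windows whose
presence/absence exactly separates the sexes are merged into candidate
hemizygous regions: sequence carried only by the Y haplotype is covered in
every male and empty in every female once the Y haplotype is in the
reference.  A relaxed mode replaces exact matching with a per-window Fisher
exact test on presence/absence, Bonferroni-corrected genome-wide.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import SexTable, bonferroni_cutoff, fisher_exact_2x2

logger = logging.getLogger(__name__)

FLAG_NONE = 0
FLAG_MALE = 1
FLAG_FEMALE = 2
_FLAG_NAME = {FLAG_NONE: "none", FLAG_MALE: "male_specific", FLAG_FEMALE: "female_specific"}


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping windows tiling each chromosome from 0 (last may be short)."""

    chrom_lengths: Mapping[str, int]
    window_size: int = 100

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def n_windows_of(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.window_size)

    @property
    def n_windows(self) -> int:
        return sum(self.n_windows_of(c) for c in self.chrom_lengths)

    def offsets(self) -> dict[str, int]:
        """Row offset of each chromosome's first window."""
        out, k = {}, 0
        for c in self.chrom_lengths:
            out[c] = k
            k += self.n_windows_of(c)
        return out

    def table(self) -> pd.DataFrame:
        rows = []
        for c, ln in self.chrom_lengths.items():
            starts = np.arange(0, ln, self.window_size)
            ends = np.minimum(starts + self.window_size, ln)
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def window_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global row indices [i, j) of windows overlapping [start, end)."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"chromosome {chrom!r} not on grid")
        off = self.offsets()[chrom]
        i = max(0, start // self.window_size)
        j = min(self.n_windows_of(chrom), -(-end // self.window_size))
        return off + i, off + max(i, j)


@dataclass
class CoverageMatrix:
    grid: WindowGrid
    depths: np.ndarray           # (n_windows, n_samples) non-negative ints
    samples: list[str]

    def __post_init__(self):
        self.depths = np.asarray(self.depths)
        if self.depths.shape != (self.grid.n_windows, len(self.samples)):
            raise ValueError("depths shape does not match grid x samples")


@dataclass
class CategoryMatrix:
    grid: WindowGrid
    categories: np.ndarray       # (n_windows, n_samples) in {0,1,2}
    samples: list[str]

    def __post_init__(self):
        self.categories = np.asarray(self.categories, dtype=np.int8)
        if self.categories.shape != (self.grid.n_windows, len(self.samples)):
            raise ValueError("categories shape does not match grid x samples")
        if self.categories.size and (self.categories.min() < 0 or self.categories.max() > 2):
            raise ValueError("categories must be in {0, 1, 2}")


@dataclass
class SexSpecificRegion:
    """A merged run of windows present in one sex and absent in the other."""

    chrom: str
    start: int                   # 0-based half-open
    end: int
    specificity: str             # 'male_specific' or 'female_specific'
    n_windows: int
    min_present_fraction: float = float("nan")
    max_absent_leak: float = float("nan")
    score: float = float("nan")  # max -log10 p over member windows (relaxed mode)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class WindowFlags:
    grid: WindowGrid
    flags: np.ndarray            # int8: 0 none, 1 male_specific, 2 female_specific
    pvalues: np.ndarray | None = None


def categorize(coverage: CoverageMatrix) -> CategoryMatrix:
    """Three-level coding of window depth: 0 -> 0; 1-2 -> 1; >=3 -> 2."""
    d = coverage.depths
    if d.size and d.min() < 0:
        raise ValueError("negative depth")
    cats = np.where(d == 0, 0, np.where(d < 3, 1, 2)).astype(np.int8)
    return CategoryMatrix(coverage.grid, cats, list(coverage.samples))


def window_sex_match(categories: CategoryMatrix, sex: SexTable,
                     mode: str = "strict", alpha: float = 0.01,
                     min_present_fraction: float = 0.9,
                     max_absent_leak: float = 0.1) -> WindowFlags:
    """Flag windows whose coverage presence/absence separates the sexes.

    strict: male_specific iff every male is category 2 and every female
    category 0 (mirror for female_specific).  relaxed: categories collapse to
    present (>=1) / absent (0); a two-sided Fisher exact p is computed per
    window and windows passing the Bonferroni cutoff are flagged if the
    presence sex has >= ``min_present_fraction`` of samples at category 2 and
    the absent sex has <= ``max_absent_leak`` of samples above category 0.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    f_mask, m_mask = sex.masks(categories.samples)
    cf = categories.categories[:, f_mask]
    cm = categories.categories[:, m_mask]
    n_f, n_m = cf.shape[1], cm.shape[1]
    flags = np.zeros(categories.grid.n_windows, dtype=np.int8)

    if mode == "strict":
        flags[np.all(cm == 2, axis=1) & np.all(cf == 0, axis=1)] = FLAG_MALE
        flags[np.all(cf == 2, axis=1) & np.all(cm == 0, axis=1)] = FLAG_FEMALE
        return WindowFlags(categories.grid, flags, None)

    pres_f = (cf >= 1).sum(axis=1)
    pres_m = (cm >= 1).sum(axis=1)
    cutoff = bonferroni_cutoff(alpha, categories.grid.n_windows)
    pvals = np.ones(categories.grid.n_windows)
    candidate = np.flatnonzero(pres_f * n_m != pres_m * n_f)  # skip symmetric windows
    for i in candidate:
        pvals[i] = fisher_exact_2x2(int(pres_f[i]), int(n_f - pres_f[i]),
                                    int(pres_m[i]), int(n_m - pres_m[i]))
    sig = pvals <= cutoff
    solid_m = (cm == 2).sum(axis=1) / n_m
    solid_f = (cf == 2).sum(axis=1) / n_f
    leak_f = pres_f / n_f
    leak_m = pres_m / n_m
    male_dir = pres_m / n_m > pres_f / n_f
    flags[sig & male_dir & (solid_m >= min_present_fraction) & (leak_f <= max_absent_leak)] = FLAG_MALE
    flags[sig & ~male_dir & (solid_f >= min_present_fraction) & (leak_m <= max_absent_leak)] = FLAG_FEMALE
    return WindowFlags(categories.grid, flags, pvals)


def merge_regions(window_flags: WindowFlags, max_gap_windows: int = 0,
                  min_windows: int = 1,
                  categories: CategoryMatrix | None = None,
                  sex: SexTable | None = None) -> list[SexSpecificRegion]:
    """Merge same-specificity flagged windows into maximal regions.

    Runs may bridge up to ``max_gap_windows`` unflagged windows; runs shorter
    than ``min_windows`` flagged windows are dropped.  Region coordinates span
    from the first to the last flagged window.  Output is sorted and disjoint.
    """
    grid = window_flags.grid
    flags = window_flags.flags
    tab = grid.table()
    starts = tab["start"].to_numpy()
    ends = tab["end"].to_numpy()
    offsets = grid.offsets()
    regions: list[SexSpecificRegion] = []

    if categories is not None and sex is not None:
        f_mask, m_mask = sex.masks(categories.samples)
        cf = categories.categories[:, f_mask]
        cm = categories.categories[:, m_mask]

    for chrom in grid.chroms:
        off = offsets[chrom]
        n = grid.n_windows_of(chrom)
        for code in (FLAG_MALE, FLAG_FEMALE):
            idx = np.flatnonzero(flags[off:off + n] == code)
            if idx.size == 0:
                continue
            run = [idx[0]]
            groups = []
            for w in idx[1:]:
                if w - run[-1] - 1 <= max_gap_windows:
                    run.append(w)
                else:
                    groups.append(run)
                    run = [w]
            groups.append(run)
            for g in groups:
                if len(g) < min_windows:
                    continue
                rows = off + np.asarray(g)
                reg = SexSpecificRegion(
                    chrom=chrom,
                    start=int(starts[rows[0]]),
                    end=int(ends[rows[-1]]),
                    specificity=_FLAG_NAME[code],
                    n_windows=len(g),
                )
                if categories is not None and sex is not None:
                    pres, absent = (cm, cf) if code == FLAG_MALE else (cf, cm)
                    reg.min_present_fraction = float(
                        np.min((pres[rows] == 2).mean(axis=1)))
                    reg.max_absent_leak = float(
                        np.max((absent[rows] > 0).mean(axis=1)))
                if window_flags.pvalues is not None:
                    pmin = float(np.min(window_flags.pvalues[rows]))
                    reg.score = float(-np.log10(max(pmin, 1e-300)))
                regions.append(reg)
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


@dataclass
class ReferenceComparison:
    """Pairing of region calls made under two reference genomes."""

    pairs: pd.DataFrame          # one row per region with status
    known: pd.DataFrame | None   # per truth-known interval: detectability


def compare_references(regions_a: Sequence[SexSpecificRegion],
                       regions_b: Sequence[SexSpecificRegion],
                       samples_a: Sequence[str], samples_b: Sequence[str],
                       lift_b_to_a=None,
                       labels: tuple[str, str] = ("female", "y_substituted"),
                       known_intervals: Sequence[tuple[str, int, int]] | None = None
                       ) -> ReferenceComparison:
    """Label each region reference-independent (found under both references)
    or reference-dependent.

    ``lift_b_to_a`` maps a (chrom, pos) from reference B's coordinates to
    reference A's, returning None where no image exists (e.g. inside a
    hemizygous insertion absent from reference A).  ``known_intervals`` are
    truth intervals in B coordinates; for each, the comparison records in
    which reference system it was detectable.
    """
    if set(samples_a) != set(samples_b):
        raise ValueError("reference runs used different sample sets")

    def _image(reg: SexSpecificRegion):
        if lift_b_to_a is None:
            return reg.chrom, reg.start, reg.end
        a = lift_b_to_a(reg.chrom, reg.start)
        b = lift_b_to_a(reg.chrom, reg.end - 1)
        if a is None or b is None:
            return None
        return reg.chrom, a[1], b[1] + 1

    def _overlaps(c, s, e, regs):
        return any(r.chrom == c and r.start < e and r.end > s for r in regs)

    rows = []
    images_b = [(r, _image(r)) for r in regions_b]
    for r in regions_a:
        hit = any(im is not None and im[0] == r.chrom and im[1] < r.end and im[2] > r.start
                  for _, im in images_b)
        rows.append({"reference": labels[0], "chrom": r.chrom, "start": r.start,
                     "end": r.end, "specificity": r.specificity,
                     "status": "reference_independent" if hit else "reference_dependent"})
    for r, im in images_b:
        if im is None:
            status = "reference_dependent_no_counterpart_coordinates"
        elif _overlaps(im[0], im[1], im[2], list(regions_a)):
            status = "reference_independent"
        else:
            status = "reference_dependent"
        rows.append({"reference": labels[1], "chrom": r.chrom, "start": r.start,
                     "end": r.end, "specificity": r.specificity, "status": status})
    pairs = pd.DataFrame(rows, columns=["reference", "chrom", "start", "end",
                                        "specificity", "status"])

    known = None
    if known_intervals is not None:
        krows = []
        for (c, s, e) in known_intervals:
            det_b = any(r.chrom == c and r.start < e and r.end > s for r in regions_b)
            if lift_b_to_a is not None:
                a1, a2 = lift_b_to_a(c, s), lift_b_to_a(c, e - 1)
                mappable = a1 is not None and a2 is not None
            else:
                mappable = True
            det_a = mappable and any(
                r.chrom == c and r.start < e and r.end > s for r in regions_a)
            krows.append({"chrom": c, "start": s, "end": e,
                          "detectable_" + labels[0]: det_a,
                          "detectable_" + labels[1]: det_b,
                          "in_" + labels[0] + "_grid": mappable})
        known = pd.DataFrame(krows)
    return ReferenceComparison(pairs, known)


def read_coverage_tsv(path: str | Path, window_size: int = 100,
                      chrom_lengths: Mapping[str, int] | None = None) -> CoverageMatrix:
    """Read long-format coverage (`chrom start end sample depth`, BED-style
    0-based half-open windows) into a matrix."""
    df = pd.read_csv(path, sep="\t")
    expected = ["chrom", "start", "end", "sample", "depth"]
    if list(df.columns[:5]) != expected:
        raise ValueError(f"coverage TSV must have columns {expected}")
    if chrom_lengths is None:
        chrom_lengths = df.groupby("chrom", sort=False)["end"].max().to_dict()
    grid = WindowGrid(dict(chrom_lengths), window_size)
    samples = list(dict.fromkeys(df["sample"]))
    sample_col = pd.Categorical(df["sample"], categories=samples).codes
    offsets = grid.offsets()
    row = (df["chrom"].map(offsets).to_numpy()
           + df["start"].to_numpy() // window_size)
    depths = np.zeros((grid.n_windows, len(samples)), dtype=np.int64)
    depths[row, sample_col] = df["depth"].to_numpy()
    return CoverageMatrix(grid, depths, samples)


def write_coverage_tsv(coverage: CoverageMatrix, path: str | Path) -> None:
    tab = coverage.grid.table()
    n_w = len(tab)
    frames = []
    for j, s in enumerate(coverage.samples):
        frames.append(pd.DataFrame({"chrom": tab["chrom"], "start": tab["start"],
                                    "end": tab["end"], "sample": s,
                                    "depth": coverage.depths[:, j]}))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: Sequence[SexSpecificRegion], path: str | Path) -> None:
    """6-column BED; name = specificity, score = -log10 p capped at 999."""
    with open(path, "w") as fh:
        for r in regions:
            score = 0 if np.isnan(r.score) else min(int(round(r.score)), 999)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.specificity}\t{score}\t.\n")


def write_window_manhattan_tsv(window_flags: WindowFlags, path: str | Path) -> None:
    if window_flags.pvalues is None:
        raise ValueError("window p-values only exist in relaxed mode")
    tab = window_flags.grid.table()
    neg = -np.log10(np.maximum(window_flags.pvalues, 1e-300))
    pd.DataFrame({"chrom": tab["chrom"], "pos": tab["start"] + 1,
                  "neg_log10_p": np.round(neg, 6)}).to_csv(path, sep="\t", index=False)
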