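"""Synthetic dioecious populations with a planted sex-linked region.

The generator emits everything the discovery pipeline consumes — two
reference genomes, population genotype calls, windowed read depth and sex
labels — together with complete ground truth.  The planted structure mirrors
a young XY system: a peritelomeric non-recombining sex-linked region (SLR)
with diverged X/Y haplotypes, hemizygous Y-only insertions (YHS), and
autosomal paralogs of YHS sequence that attract cross-mapped reads when the
reference genome lacks their source, producing spurious male-heterozygous
calls (the false-SEMS artifact).

Coordinates
-----------
Canonical coordinates are those of the *Y-substituted* assembly (YHS
present).  The SLR sits at the high-coordinate (telomeric) end of the sex
chromosome, so every position outside the SLR is numerically identical in
both references; ``lift_to_female`` maps canonical sex-chromosome positions
onto the female (X-carrying) reference, returning None inside a YHS.

Mapping and variant calling are not simulated at the read level: the
pipeline consumes only genotype codes and window depths, so their outcome
statistics are drawn directly (window depth ~ Poisson(mean_depth * c / 2)
with c the copy number relative to the chosen reference; cross-mapped depth
~ Poisson(mu * mean_depth / 2) at paralog targets in carrier-sex samples
under the source-less reference).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import (GenotypeMatrix, SexTable, HOM_REF, HET, HOM_ALT,
                        MISSING)
from .covscan import CoverageMatrix, WindowGrid

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# paper-scale SLR architecture: 299-kb X haplotype; YHS insertions of
# 34.8 kb, 4.3 kb and 100 bp carried only by the Y haplotype
_DEFAULT_SEX_CHROM_LEN = 1_200_000
_DEFAULT_YHS_SIZES = (34_800, 4_300, 100)
_DEFAULT_SLR_LEN_X = 299_000


def _default_chrom_lengths() -> dict[str, int]:
    return {"chr19": _DEFAULT_SEX_CHROM_LEN, "chr04": 800_000, "chr08": 800_000}


def _default_slr() -> tuple[int, int]:
    total = _DEFAULT_SLR_LEN_X + sum(_DEFAULT_YHS_SIZES)
    return (_DEFAULT_SEX_CHROM_LEN - total, _DEFAULT_SEX_CHROM_LEN)


def _default_yhs() -> list[tuple[int, int]]:
    s = _default_slr()[0]
    return [(s + 50_000, s + 50_000 + 34_800),
            (s + 150_000, s + 150_000 + 4_300),
            (s + 250_000, s + 250_000 + 100)]


def _default_paralogs() -> list[tuple[tuple[int, int], tuple[str, int, int], float]]:
    y0 = _default_yhs()[0][0]
    return [((y0, y0 + 2_000), ("chr04", 400_000, 402_000), 0.95)]


@dataclass
class SimConfig:
    """Scenario parameters for the synthetic population.

    Defaults are the study's operating point: 49 females + 46 males, 100-bp
    windows, ~40 reads per diploid window (>= 20x base coverage with typical
    short-read lengths), a 299-kb X-haplotype SLR carrying three Y-hemizygous
    insertions of 34.8 kb / 4.3 kb / 100 bp, and one 2-kb autosomal paralog
    of YHS sequence at 95% identity.  Genome scale is desk-sized
    (configurable); population, depth and SLR architecture are not scaled.
    """

    n_females: int = 49
    n_males: int = 46
    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    sex_chrom: str = "chr19"
    slr_interval: tuple[int, int] = field(default_factory=_default_slr)
    yhs_intervals: list[tuple[int, int]] = field(default_factory=_default_yhs)
    paralog_map: list[tuple[tuple[int, int], tuple[str, int, int], float]] = \
        field(default_factory=_default_paralogs)
    snp_density: float = 0.005
    xy_divergence: float = 0.002
    mean_depth: float = 40.0          # expected reads per 100-bp diploid window
    mismap_fraction: float = 0.0      # mu: fraction of source reads hitting the paralog
    missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    window_size: int = 100
    seed: int = 0
    heterogametic_sex: str = "M"      # 'M' (XY system) or 'F' (ZW mirror)
    min_alt_reads: int = 2            # cross-mapped reads needed for a het call
    nb_dispersion: float | None = None  # negative-binomial overdispersion (None = Poisson)
    per_sample_depth_scale: dict[str, float] | None = None

    def validate(self) -> None:
        if self.n_females < 1 or self.n_males < 1:
            raise ValueError("need at least one sample of each sex")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        for name in ("mismap_fraction", "missing_rate", "genotype_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.heterogametic_sex not in ("M", "F"):
            raise ValueError("heterogametic_sex must be 'M' or 'F'")
        if self.sex_chrom not in self.chrom_lengths:
            raise ValueError(f"sex_chrom {self.sex_chrom!r} not in chrom_lengths")
        L = self.chrom_lengths[self.sex_chrom]
        s, e = self.slr_interval
        if not (0 <= s < e <= L):
            raise ValueError(f"slr_interval {self.slr_interval} outside chromosome")
        prev_end = -1
        for (a, b) in sorted(self.yhs_intervals):
            if not (s <= a < b <= e):
                raise ValueError(f"yhs interval ({a}, {b}) outside the SLR")
            if a < prev_end:
                raise ValueError("yhs intervals overlap")
            prev_end = b
        seen: list[tuple[str, int, int]] = []
        for (src, tgt, ident) in self.paralog_map:
            if not any(y0 <= src[0] < src[1] <= y1 for (y0, y1) in self.yhs_intervals):
                raise ValueError(f"paralog source {src} not inside a YHS interval")
            tc, ts, te = tgt
            if tc == self.sex_chrom:
                raise ValueError("paralog target must be autosomal")
            if not (0 <= ts < te <= self.chrom_lengths[tc]):
                raise ValueError(f"paralog target {tgt} outside chromosome")
            if te - ts != src[1] - src[0]:
                raise ValueError("paralog source and target lengths differ")
            for (oc, os_, oe) in seen:
                if oc == tc and ts < oe and te > os_:
                    raise ValueError("paralog target intervals overlap")
            seen.append((tc, ts, te))
            if not (0.0 < ident <= 1.0):
                raise ValueError(f"identity_fraction must be in (0, 1], got {ident}")

    @property
    def carrier_sex(self) -> str:
        """The heterogametic sex: carries the hemizygous haplotype."""
        return self.heterogametic_sex

    def sample_ids(self) -> list[str]:
        f = [f"F{i + 1:02d}" for i in range(self.n_females)]
        m = [f"M{i + 1:02d}" for i in range(self.n_males)]
        return f + m

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "slr_interval" in d:
            d["slr_interval"] = tuple(d["slr_interval"])
        if "yhs_intervals" in d:
            d["yhs_intervals"] = [tuple(x) for x in d["yhs_intervals"]]
        if "paralog_map" in d:
            d["paralog_map"] = [((p[0][0], p[0][1]), (p[1][0], p[1][1], p[1][2]), p[2])
                                for p in d["paralog_map"]]
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class TruthSet:
    """Ground truth of one simulated scenario.

    ``true_sems`` lists the fully sex-linked sites (columns: chrom, pos
    [canonical coords], pos_female, x_allele, y_allele); ``artifact_sites``
    the autosomal positions where cross-mapping induces spurious carrier-sex
    heterozygosity under the source-less reference (columns: chrom, pos, ref,
    alt); ``true_yhs`` the planted hemizygous intervals in canonical
    coordinates.  x/y haplotypes are named for the XY case; under a ZW
    scenario x = Z (homogametic) and y = W (hemizygous carrier) haplotype.
    """

    sex_of: dict[str, str]
    true_sems: pd.DataFrame
    artifact_sites: pd.DataFrame
    true_yhs: list[tuple[str, int, int]]
    x_haplotype: str
    y_haplotype: str
    mother_id: str
    son_id: str
    config: SimConfig

    @property
    def slr_interval_female(self) -> tuple[int, int]:
        """The SLR interval on the female (source-less) reference."""
        s, e = self.config.slr_interval
        dele = sum(b - a for (a, b) in self.config.yhs_intervals)
        return (s, e - dele)

    def write_json(self, path: str | Path) -> None:
        payload = {
            "sex_of": self.sex_of,
            "true_sems": self.true_sems.to_dict(orient="list"),
            "artifact_sites": self.artifact_sites.to_dict(orient="list"),
            "true_yhs": [list(x) for x in self.true_yhs],
            "x_haplotype": self.x_haplotype,
            "y_haplotype": self.y_haplotype,
            "mother_id": self.mother_id,
            "son_id": self.son_id,
            "config": _config_to_jsonable(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)


def _config_to_jsonable(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["slr_interval"] = list(d["slr_interval"])
    d["yhs_intervals"] = [list(x) for x in d["yhs_intervals"]]
    d["paralog_map"] = [[list(src), list(tgt), ident]
                        for (src, tgt, ident) in cfg.paralog_map]
    return d


def lift_to_female(config: SimConfig, chrom: str, pos: int) -> tuple[str, int] | None:
    """Map a canonical (Y-substituted) position to the female reference.

    Positions inside a YHS interval have no image (None); other sex-
    chromosome positions shift down by the total YHS length preceding them.
    """
    if chrom != config.sex_chrom:
        return (chrom, pos)
    shift = 0
    for (a, b) in sorted(config.yhs_intervals):
        if pos >= b:
            shift += b - a
        elif pos >= a:
            return None
    return (chrom, pos - shift)


def lift_to_carrier(config: SimConfig, chrom: str, pos: int) -> tuple[str, int]:
    """Inverse of :func:`lift_to_female` for positions on the female reference."""
    if chrom != config.sex_chrom:
        return (chrom, pos)
    shift = 0
    for (a, b) in sorted(config.yhs_intervals):
        if pos + shift >= a:
            shift += b - a
    return (chrom, pos + shift)


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, *key]))


def _random_other_base(rng: np.random.Generator, codes: np.ndarray) -> np.ndarray:
    """Substitute each base (0..3 index into ACGT) with a different one."""
    return (codes + rng.integers(1, 4, size=codes.shape)) % 4


def build_references(config: SimConfig
                     ) -> tuple[dict[str, str], dict[str, str], TruthSet]:
    """Build the female and Y-substituted references plus ground truth.

    The female reference carries the X haplotype in the SLR (YHS absent);
    the Y-substituted reference is identical except that the SLR is replaced
    by the Y haplotype (YHS present).  Autosomal paralog targets are copies
    of their YHS source at the configured identity in *both* references.
    """
    config.validate()
    rng = _rng(config, 0)
    # canonical genome (carries the Y haplotype in the SLR), as 0..3 codes
    genome = {c: rng.integers(0, 4, size=ln, dtype=np.uint8)
              for c, ln in config.chrom_lengths.items()}

    # plant paralogs: overwrite the autosomal target with a mutated copy of
    # the YHS source; the mutated positions are the artifact sites
    art_rows = []
    for (src, (tc, ts, te), ident) in config.paralog_map:
        src_seq = genome[config.sex_chrom][src[0]:src[1]].copy()
        n = len(src_seq)
        n_sub = int(round((1.0 - ident) * n))
        sub_pos = np.sort(rng.choice(n, size=n_sub, replace=False))
        planted = src_seq.copy()
        planted[sub_pos] = _random_other_base(rng, src_seq[sub_pos])
        genome[tc][ts:te] = planted
        for p in sub_pos:
            art_rows.append({"chrom": tc, "pos": int(ts + p),
                             "ref": "ACGT"[planted[p]],
                             "alt": "ACGT"[src_seq[p]]})
    artifact_sites = pd.DataFrame(art_rows, columns=["chrom", "pos", "ref", "alt"])
    if len(artifact_sites):
        artifact_sites = artifact_sites.sort_values(["chrom", "pos"]).reset_index(drop=True)

    # X haplotype: Y haplotype minus YHS, substituted at xy_divergence sites
    s, e = config.slr_interval
    y_hap = genome[config.sex_chrom][s:e].copy()
    yhs_rel = [(a - s, b - s) for (a, b) in sorted(config.yhs_intervals)]
    in_yhs = np.zeros(e - s, dtype=bool)
    for (a, b) in yhs_rel:
        in_yhs[a:b] = True
    eligible = np.flatnonzero(~in_yhs)
    div_mask = rng.random(eligible.size) < config.xy_divergence
    div_rel = eligible[div_mask]                       # relative to SLR start, Y coords
    x_on_y = y_hap.copy()
    x_on_y[div_rel] = _random_other_base(rng, y_hap[div_rel])
    x_hap = x_on_y[~in_yhs]                            # YHS deleted

    sems_rows = []
    for p in div_rel:
        pos_y = int(s + p)
        lifted = lift_to_female(config, config.sex_chrom, pos_y)
        assert lifted is not None
        sems_rows.append({"chrom": config.sex_chrom, "pos": pos_y,
                          "pos_female": int(lifted[1]),
                          "x_allele": "ACGT"[x_on_y[p]],
                          "y_allele": "ACGT"[y_hap[p]]})
    true_sems = pd.DataFrame(sems_rows,
                             columns=["chrom", "pos", "pos_female", "x_allele", "y_allele"])

    def _decode(codes: np.ndarray) -> str:
        return _BASES[codes].tobytes().decode()

    y_ref = {c: _decode(v) for c, v in genome.items()}
    female = dict(y_ref)
    fem_sex = np.concatenate([genome[config.sex_chrom][:s], x_hap,
                              genome[config.sex_chrom][e:]])
    female[config.sex_chrom] = _decode(fem_sex)

    samples = config.sample_ids()
    sex_of = {sid: ("F" if sid.startswith("F") else "M") for sid in samples}
    truth = TruthSet(
        sex_of=sex_of,
        true_sems=true_sems,
        artifact_sites=artifact_sites,
        true_yhs=[(config.sex_chrom, a, b) for (a, b) in sorted(config.yhs_intervals)],
        x_haplotype=_decode(x_hap),
        y_haplotype=_decode(y_hap),
        mother_id="F01",
        son_id="M01",
        config=config,
    )
    truth._refs = (female, y_ref)  # cache to spare regeneration downstream
    return female, y_ref, truth


def _carrier_mask(config: SimConfig, samples: Sequence[str],
                  sex_of: Mapping[str, str]) -> np.ndarray:
    """True for samples of the heterogametic (hemizygous-carrier) sex."""
    return np.array([sex_of[s] == config.carrier_sex for s in samples])


def simulate_population(config: SimConfig, truth: TruthSet, reference_mode: str
                        ) -> tuple[GenotypeMatrix, CoverageMatrix, SexTable]:
    """Draw genotype calls and windowed coverage under one reference.

    ``reference_mode`` is 'female' (reference lacks the hemizygous
    insertions; cross-mapping active) or 'y_substituted' (reference carries
    them; hemizygous windows are covered in carriers only).  Background SNPs
    outside the SLR are identical between modes, so positions there line up
    across references.  Deterministic given the config seed.
    """
    if reference_mode not in ("female", "y_substituted"):
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    if truth.config != config:
        raise ValueError("truth was generated from a different config")
    config.validate()
    samples = config.sample_ids()
    sex = SexTable(dict(truth.sex_of))
    carrier = _carrier_mask(config, samples, truth.sex_of)
    n_samples = len(samples)
    n_carrier = int(carrier.sum())

    # ---- genotypes -------------------------------------------------------
    # background SNPs: shared between modes (seeded independently of mode)
    rng_bg = _rng(config, 1)
    excl = {c: [] for c in config.chrom_lengths}
    excl[config.sex_chrom].append(tuple(config.slr_interval))
    for (_, (tc, ts, te), _i) in config.paralog_map:
        excl[tc].append((ts, te))
    bg_frames = []
    for chrom, ln in config.chrom_lengths.items():
        u = rng_bg.random(ln)
        mask = u < config.snp_density
        for (a, b) in excl[chrom]:
            mask[a:b] = False
        pos = np.flatnonzero(mask)
        af = rng_bg.uniform(0.1, 0.9, size=pos.size)
        alt_base = rng_bg.integers(1, 4, size=pos.size)  # offset from ref base
        geno = rng_bg.binomial(2, af[:, None], size=(pos.size, n_samples)).astype(np.int8)
        bg_frames.append((chrom, pos, alt_base, geno))

    female_mode = reference_mode == "female"
    refs = getattr(truth, "_refs", None)
    if refs is None:  # regenerate deterministically if the cache is absent
        female_ref, y_ref, _ = build_references(config)
    else:
        female_ref, y_ref = refs
    ref = female_ref if female_mode else y_ref

    site_chrom: list[str] = []
    site_pos: list[int] = []
    site_ref: list[str] = []
    site_alt: list[str] = []
    call_rows: list[np.ndarray] = []

    for chrom, pos, alt_off, geno in bg_frames:
        seq = ref[chrom]
        for k in range(pos.size):
            p = int(pos[k])
            if female_mode and chrom == config.sex_chrom:
                p = lift_to_female(config, chrom, p)[1]  # outside SLR: never None
            rb = seq[p]
            ab = "ACGT"[("ACGT".index(rb) + int(alt_off[k])) % 4]
            site_chrom.append(chrom)
            site_pos.append(p)
            site_ref.append(rb)
            site_alt.append(ab)
        call_rows.extend(geno)

    # fully sex-linked sites: carriers HET, non-carriers homozygous
    ts = truth.true_sems
    for k in range(len(ts)):
        if female_mode:
            pos, rb, ab = int(ts["pos_female"].iloc[k]), ts["x_allele"].iloc[k], ts["y_allele"].iloc[k]
            noncarrier_code = HOM_REF
        else:
            pos, rb, ab = int(ts["pos"].iloc[k]), ts["y_allele"].iloc[k], ts["x_allele"].iloc[k]
            noncarrier_code = HOM_ALT
        row = np.full(n_samples, noncarrier_code, dtype=np.int8)
        row[carrier] = HET
        site_chrom.append(str(ts["chrom"].iloc[k]))
        site_pos.append(pos)
        site_ref.append(str(rb))
        site_alt.append(str(ab))
        call_rows.append(row)

    # cross-mapping artifact: only when the reference lacks the YHS source
    if female_mode and len(truth.artifact_sites) and config.mismap_fraction > 0:
        rng_art = _rng(config, 2)
        lam = config.mismap_fraction * config.mean_depth / 2.0
        arts = truth.artifact_sites
        xreads = rng_art.poisson(lam, size=(len(arts), n_carrier))
        het = xreads >= config.min_alt_reads
        for k in range(len(arts)):
            row = np.full(n_samples, HOM_REF, dtype=np.int8)
            row[np.flatnonzero(carrier)[het[k]]] = HET
            site_chrom.append(str(arts["chrom"].iloc[k]))
            site_pos.append(int(arts["pos"].iloc[k]))
            site_ref.append(str(arts["ref"].iloc[k]))
            site_alt.append(str(arts["alt"].iloc[k]))
            call_rows.append(row)

    sites = pd.DataFrame({"chrom": site_chrom, "pos0": site_pos,
                          "ref": site_ref, "alt": site_alt})
    calls = (np.vstack(call_rows) if call_rows
             else np.empty((0, n_samples), dtype=np.int8))
    order = np.lexsort((sites["pos0"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    calls = calls[order]

    # corruption: miscalls first, then missingness (missing overrides)
    rng_noise = _rng(config, 3, 0 if female_mode else 1)
    if config.genotype_error_rate > 0 and calls.size:
        err = rng_noise.random(calls.shape) < config.genotype_error_rate
        shift = rng_noise.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if config.missing_rate > 0 and calls.size:
        miss = rng_noise.random(calls.shape) < config.missing_rate
        calls = np.where(miss, MISSING, calls).astype(np.int8)

    genotypes = GenotypeMatrix(sites, calls, samples)

    # ---- coverage --------------------------------------------------------
    chrom_lengths = {c: len(ref[c]) for c in config.chrom_lengths}
    grid = WindowGrid(chrom_lengths, config.window_size)
    tab = grid.table()
    starts = tab["start"].to_numpy()
    ends = tab["end"].to_numpy()
    chroms = tab["chrom"].to_numpy()

    copy = np.full((grid.n_windows, n_samples), 2.0)
    if not female_mode:
        # hemizygous windows: carrier c=1, non-carrier c=0 (overlap-weighted)
        off = grid.offsets()[config.sex_chrom]
        for (c, a, b) in truth.true_yhs:
            i, j = grid.window_range(c, a, b)
            ov = (np.minimum(ends[i:j], b) - np.maximum(starts[i:j], a)) \
                / (ends[i:j] - starts[i:j])
            copy[i:j, :] = 2.0 * (1.0 - ov[:, None])
            copy[i:j, carrier] += 1.0 * ov[:, None]

    lam = config.mean_depth * copy / 2.0
    # short terminal windows see proportionally fewer reads
    wfrac = (ends - starts) / config.window_size
    lam = lam * wfrac[:, None]
    if config.per_sample_depth_scale:
        scale = np.array([config.per_sample_depth_scale.get(s, 1.0) for s in samples])
        lam = lam * scale[None, :]

    rng_cov = _rng(config, 4, 0 if female_mode else 1)
    if config.nb_dispersion:
        # gamma-poisson mixture with shape r: variance lam + lam^2 / r
        r = config.nb_dispersion
        lam_draw = rng_cov.gamma(r, 1.0 / r, size=lam.shape) * lam
        depths = rng_cov.poisson(lam_draw)
    else:
        depths = rng_cov.poisson(lam)

    if female_mode and config.mismap_fraction > 0:
        lam_x = config.mismap_fraction * config.mean_depth / 2.0
        for (_, (tc, a, b), _i) in config.paralog_map:
            i, j = grid.window_range(tc, a, b)
            ov = (np.minimum(ends[i:j], b) - np.maximum(starts[i:j], a)) \
                / (ends[i:j] - starts[i:j])
            extra = rng_cov.poisson(lam_x * ov[:, None], size=(j - i, n_carrier))
            depths[i:j, carrier] += extra

    coverage = CoverageMatrix(grid, depths, samples)
    return genotypes, coverage, sex


def make_chimeric_duplicate(segments: Sequence[tuple[str, tuple[int, int], str]],
                            order: Sequence[int],
                            mutation_rate: float = 0.0,
                            rng: np.random.Generator | None = None
                            ) -> tuple[str, pd.DataFrame]:
    """Concatenate labeled source segments (repeats allowed) into a chimera.

    ``segments`` are (source_sequence, (start, end), label); ``order`` indexes
    into them and may repeat.  With ``mutation_rate`` > 0 the concatenation is
    point-mutated.  Returns the chimera and a layout table with exact
    breakpoints (chim_start, chim_end, label, src_start, src_end).
    """
    if not segments:
        raise ValueError("empty segment list")
    for (src, (a, b), label) in segments:
        if not (0 <= a < b <= len(src)):
            raise ValueError(f"interval ({a}, {b}) invalid for segment {label!r}")
    parts, rows, at = [], [], 0
    for idx in order:
        src, (a, b), label = segments[idx]
        sub = src[a:b]
        rows.append({"chim_start": at, "chim_end": at + len(sub),
                     "label": label, "src_start": a, "src_end": b})
        parts.append(sub)
        at += len(sub)
    chimera = "".join(parts)
    if mutation_rate > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        codes = np.frombuffer(chimera.encode(), dtype=np.uint8).copy()
        lut = np.zeros(256, dtype=np.uint8)
        for i, c in enumerate(b"ACGT"):
            lut[c] = i
        idx = np.flatnonzero(rng.random(len(codes)) < mutation_rate)
        mut = _random_other_base(rng, lut[codes[idx]])
        codes[idx] = _BASES[mut]
        chimera = codes.tobytes().decode()
    layout = pd.DataFrame(rows, columns=["chim_start", "chim_end", "label",
                                         "src_start", "src_end"])
    return chimera, layout


def simulate_trio(truth: TruthSet, mother_het: float = 0.0, seed: int = 0,
                  missing_rate: float = 0.0):
    """Mother/son genotype calls across the SLR for trio phasing.

    Sites are the X/Y-divergent positions on the female reference (ref = X
    allele, alt = Y allele).  The mother is heterozygous at a Bernoulli
    (``mother_het``) subset of sites, modelled as one maternal X carrying the
    Y-like allele; the son inherits the reference-like X plus the truth Y, so
    he is heterozygous at every site.  The double-heterozygote (phase-
    ambiguous) fraction therefore equals the mother's SLR heterozygosity.
    """
    from .phasing import TrioInput

    cfg = truth.config
    ts = truth.true_sems
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 77]))
    n = len(ts)
    mother = np.full(n, HOM_REF, dtype=np.int8)
    mother[rng.random(n) < mother_het] = HET
    son = np.full(n, HET, dtype=np.int8)
    if missing_rate > 0:
        mother[rng.random(n) < missing_rate] = MISSING
        son[rng.random(n) < missing_rate] = MISSING
    sites = pd.DataFrame({"chrom": ts["chrom"], "pos0": ts["pos_female"],
                          "ref": ts["x_allele"], "alt": ts["y_allele"]}
                         ).reset_index(drop=True)
    s, e = truth.slr_interval_female
    return TrioInput(slr_interval=(cfg.sex_chrom, s, e), sites=sites,
                     mother_calls=mother, son_calls=son)


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
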