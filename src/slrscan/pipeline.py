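"""End-to-end dual-reference orchestration.

The full analysis runs every screen under both reference genomes — the
female (X-carrying) assembly and the Y-substituted assembly — and compares
them: fully sex-linked SNPs inside the declared SLR persist under both,
while non-SLR SEMS produced by cross-mapping of Y-only reads vanish once
the Y haplotype is present in the reference.  Those eliminated SEMS are
additionally screened for sequence similarity with the SLR-Y (the
cross-mapping diagnostic), and hemizygous regions are called from windowed
coverage under each reference.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import (GenotypeMatrix, SexTable, SEMSRecord, classify_sems,
                        exact_association, filter_sites, infer_heterogamety,
                        write_manhattan_tsv, write_sems_tsv)
from .covscan import (CategoryMatrix, CoverageMatrix, categorize,
                      merge_regions, window_sex_match, write_regions_bed,
                      write_window_manhattan_tsv, SexSpecificRegion)
from .localalign import flag_crossmap_sems

logger = logging.getLogger(__name__)

MODES = ("female", "y_substituted")


@dataclass
class Thresholds:
    """Every tunable of the dual-reference run (no hidden defaults)."""

    maf_min: float = 0.05
    max_missing: float = 0.1
    min_callrate_per_sex: float = 0.9
    strict_hom_class: bool = False
    strict_no_missing: bool = False
    cov_mode: str = "strict"          # 'strict' or 'relaxed'
    cov_alpha: float = 0.01
    min_present_fraction: float = 0.9
    max_absent_leak: float = 0.1
    max_gap_windows: int = 1          # bridge single-window dropouts in long tracts
    min_windows: int = 1
    crossmap_flank: int = 500
    crossmap_min_identity: float = 0.9
    crossmap_site_margin: int = 50
    aligner_k: int = 13
    majority_ratio: float = 2.0


@dataclass
class ModeInput:
    """Inputs for one reference system."""

    genotypes: GenotypeMatrix
    coverage: CoverageMatrix
    sex: SexTable
    slr: tuple[str, int, int]
    reference: Mapping[str, str] | None = None


@dataclass
class RunReport:
    sems_counts: dict
    regions: dict
    heterogamety: dict
    eliminated_sems: list
    phasing_summary: dict | None
    provenance: dict
    sems_records: dict = field(default_factory=dict, repr=False)
    region_objects: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {"sems_counts": self.sems_counts,
                "regions": self.regions,
                "heterogamety": self.heterogamety,
                "eliminated_sems": self.eliminated_sems,
                "phasing_summary": self.phasing_summary,
                "provenance": self.provenance}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def analyze_dual_reference(inputs: Mapping[str, ModeInput],
                           slr_y_sequence: str,
                           thresholds: Thresholds | None = None,
                           seed: int | None = None) -> RunReport:
    """Run SEMS + coverage discovery under both references and reconcile.

    ``inputs`` maps 'female' and 'y_substituted' to their data.  Positions
    outside the SLR are assumed identical between the two references (the
    hemizygous insertions sit inside the SLR), so eliminated SEMS are
    matched by exact (chrom, pos).
    """
    th = thresholds or Thresholds()
    for mode in MODES:
        if mode not in inputs:
            raise ValueError(f"missing input for reference mode {mode!r}")
    if set(inputs["female"].sex.entries) != set(inputs["y_substituted"].sex.entries):
        raise ValueError("sample sets differ between references")

    sems: dict[str, list[SEMSRecord]] = {}
    regions: dict[str, list[SexSpecificRegion]] = {}
    window_flags = {}
    pvalues = {}
    for mode in MODES:
        mi = inputs[mode]
        filt = filter_sites(mi.genotypes, th.maf_min, th.max_missing)
        sems[mode] = classify_sems(
            filt, mi.sex, min_callrate_per_sex=th.min_callrate_per_sex,
            strict_hom_class=th.strict_hom_class,
            strict_no_missing=th.strict_no_missing, slr=mi.slr)
        pvalues[mode] = (filt, exact_association(filt, mi.sex))
        cats = categorize(mi.coverage)
        flags = window_sex_match(cats, mi.sex, mode=th.cov_mode,
                                 alpha=th.cov_alpha,
                                 min_present_fraction=th.min_present_fraction,
                                 max_absent_leak=th.max_absent_leak)
        window_flags[mode] = flags
        regions[mode] = merge_regions(flags, th.max_gap_windows, th.min_windows,
                                      cats, mi.sex)

    # cross-mapping similarity screen on the discovery (female) reference
    if inputs["female"].reference is not None:
        flag_crossmap_sems([r for r in sems["female"] if not r.in_slr],
                           inputs["female"].reference, slr_y_sequence,
                           flank=th.crossmap_flank,
                           min_identity=th.crossmap_min_identity,
                           k=th.aligner_k, site_margin=th.crossmap_site_margin)

    y_positions = {(r.chrom, r.pos0) for r in sems["y_substituted"]}
    eliminated = [r for r in sems["female"]
                  if not r.in_slr and (r.chrom, r.pos0) not in y_positions]

    def _counts(records):
        non_slr = [r for r in records if not r.in_slr]
        return {"total": len(records),
                "in_slr": sum(1 for r in records if r.in_slr),
                "non_slr": len(non_slr),
                "crossmap_suspect": sum(1 for r in non_slr if r.crossmap_suspect)}

    het = {mode: asdict(infer_heterogamety(sems[mode], th.majority_ratio))
           for mode in MODES}
    het["call"] = het["y_substituted"]["system"]

    report = RunReport(
        sems_counts={m: _counts(sems[m]) for m in MODES},
        regions={m: [asdict(r) for r in regions[m]] for m in MODES},
        heterogamety=het,
        eliminated_sems=[{"chrom": r.chrom, "pos": r.pos0 + 1, "ref": r.ref,
                          "alt": r.alt,
                          "crossmap_suspect": r.crossmap_suspect}
                         for r in eliminated],
        phasing_summary=None,
        provenance={"package": "slrscan", "version": __version__,
                    "seed": seed, "thresholds": asdict(th)},
        sems_records=sems,
        region_objects=regions,
    )
    report._pvalues = pvalues           # retained for Manhattan output
    report._window_flags = window_flags
    return report


@dataclass
class RunConfig:
    """File-path configuration for a dual-reference run."""

    vcf: dict                       # mode -> path
    coverage: dict                  # mode -> path
    sex_table: str
    reference: dict                 # mode -> FASTA path
    slr: dict                       # mode -> [chrom, start, end]
    outdir: str
    seed: int = 0
    window_size: int = 100
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        th = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=th, **raw)


def run_dual_reference(config: RunConfig) -> RunReport:
    """Execute the full file-based dual-reference analysis and write outputs."""
    from .genotypes import read_genotypes
    from .covscan import read_coverage_tsv
    from .simgen import read_fasta

    for mode in MODES:
        for group in (config.vcf, config.coverage, config.reference, config.slr):
            if mode not in group:
                raise ValueError(f"config missing entry for mode {mode!r}")
    for p in [config.sex_table, *config.vcf.values(), *config.coverage.values(),
              *config.reference.values()]:
        if not Path(p).exists():
            raise FileNotFoundError(p)

    sex = SexTable.read_tsv(config.sex_table)
    inputs = {}
    refs = {}
    for mode in MODES:
        refs[mode] = read_fasta(config.reference[mode])
        genotypes = read_genotypes(config.vcf[mode], sex)
        chrom_lengths = {c: len(s) for c, s in refs[mode].items()}
        coverage = read_coverage_tsv(config.coverage[mode], config.window_size,
                                     chrom_lengths)
        slr = tuple(config.slr[mode])
        inputs[mode] = ModeInput(genotypes, coverage, sex, (slr[0], int(slr[1]), int(slr[2])),
                                 reference=refs[mode])
    sc, ss, se = inputs["y_substituted"].slr
    slr_y_seq = refs["y_substituted"][sc][ss:se]

    report = analyze_dual_reference(inputs, slr_y_seq, config.thresholds,
                                    seed=config.seed)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for mode in MODES:
        p = outdir / f"sems_{mode}.tsv"
        write_sems_tsv(report.sems_records[mode], p)
        written.append(p.name)
        filt, pv = report._pvalues[mode]
        p = outdir / f"manhattan_snp_{mode}.tsv"
        write_manhattan_tsv(filt, pv, p)
        written.append(p.name)
        p = outdir / f"regions_{mode}.bed"
        write_regions_bed(report.region_objects[mode], p)
        written.append(p.name)
        if report._window_flags[mode].pvalues is not None:
            p = outdir / f"manhattan_window_{mode}.tsv"
            write_window_manhattan_tsv(report._window_flags[mode], p)
            written.append(p.name)
    (outdir / "report.json").write_text(report.to_json())
    written.append("report.json")
    manifest = {"outputs": sorted(written), "seed": config.seed,
                "version": __version__,
                "thresholds": asdict(config.thresholds)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    return report


def check_region_presence(regions: Sequence[SexSpecificRegion],
                          categories: CategoryMatrix, sex: SexTable
                          ) -> tuple[pd.DataFrame, dict]:
    """In-silico presence/absence validation on a hold-out sample set.

    A sample 'carries' a region if any window inside it is category 2
    (reliably covered) — the analogue of a successful PCR amplification.
    Returns a per-(region, sample) table and a concordance summary against
    the region's specificity.
    """
    rows = []
    for reg in regions:
        if reg.chrom not in categories.grid.chrom_lengths:
            raise ValueError(f"region chromosome {reg.chrom!r} outside coverage grid")
        if reg.end > categories.grid.chrom_lengths[reg.chrom]:
            raise ValueError(f"region {reg.chrom}:{reg.start}-{reg.end} outside coverage grid")
        i, j = categories.grid.window_range(reg.chrom, reg.start, reg.end)
        present = (categories.categories[i:j] == 2).any(axis=0)
        expected_sex = "M" if reg.specificity == "male_specific" else "F"
        for s, pres in zip(categories.samples, present):
            sx = sex.sex_of(s)
            rows.append({"region": f"{reg.chrom}:{reg.start}-{reg.end}",
                         "specificity": reg.specificity, "sample": s, "sex": sx,
                         "present": bool(pres),
                         "concordant": bool(pres) == (sx == expected_sex)})
    table = pd.DataFrame(rows, columns=["region", "specificity", "sample",
                                        "sex", "present", "concordant"])
    summary = {"n": len(table),
               "n_concordant": int(table["concordant"].sum()) if len(table) else 0,
               "n_discordant": int((~table["concordant"]).sum()) if len(table) else 0}
    return table, summary


def simulate_and_run(sim_config, thresholds: Thresholds | None = None
                     ) -> tuple[RunReport, "object"]:
    """Convenience: generate a scenario and run the dual-reference analysis
    in memory.  Returns (report, truth)."""
    from .simgen import build_references, simulate_population

    female_ref, y_ref, truth = build_references(sim_config)
    inputs = {}
    for mode, ref in (("female", female_ref), ("y_substituted", y_ref)):
        genotypes, coverage, sex = simulate_population(sim_config, truth, mode)
        s, e = (truth.slr_interval_female if mode == "female"
                else sim_config.slr_interval)
        inputs[mode] = ModeInput(genotypes, coverage, sex,
                                 (sim_config.sex_chrom, s, e), reference=ref)
    report = analyze_dual_reference(inputs, truth.y_haplotype, thresholds,
                                    seed=sim_config.seed)
    return report, truth
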