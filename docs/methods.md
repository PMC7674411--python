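# Methods

This document describes the statistical model behind each component of
`slrscan`, every tunable parameter with its default and rationale, the scope
of the synthetic generator, the numerical choices, and known limitations.
It makes no empirical claims beyond what the test suite
(`tests/`) and the reproduction script (`scripts/acceptance.py`) compute.

## 1. Sex-matched SNP screening (SEMS)

### Definition

For a biallelic SNP genotyped in a sexed cohort, with calls coded
`0` (hom-ref), `1` (het), `2` (hom-alt), `-1` (missing):

- **XY pattern** — every called female is homozygous (all `0` or all `2`,
  one class) and every called male is heterozygous.
- **ZW pattern** — the mirror: every called male homozygous, every called
  female heterozygous.

A site matching either pattern is a SEMS. The match is *exact* by design:
inside a fully sex-linked region every male genuinely carries one X and one
Y allele, so requiring perfection costs little sensitivity there while
making the screen extremely specific elsewhere. Tolerance for imperfect
cohorts is provided through call-rate handling, not through pattern
relaxation:

| parameter | default | rationale |
|---|---|---|
| `min_callrate_per_sex` | 0.9 | a site must be called in ≥ 90 % of each sex; the pattern is then required only of the called samples, so sporadic missingness does not destroy a true SEMS |
| `strict_hom_class` | False | when True, all homozygous samples must share one class; the default allows either class because reference polarity at diverged sites is arbitrary |
| `strict_no_missing` | False | when True, any missing call disqualifies the site |
| `maf_min` | 0.05 | pre-filter; a true SEMS in a balanced cohort has allele frequency ≈ ¼ so this never removes signal, but it removes rare-variant noise |
| `max_missing` | 0.1 | pre-filter on overall call rate |

### Heterogamety call

The system is called XY if the XY-pattern count is at least `majority_ratio`
(default 2.0) times the ZW count (and vice versa); ties, empty counts or
smaller majorities yield `undetermined`. A genuine SLR produces hundreds of
one pattern and essentially zero of the other, so any ratio threshold well
above 1 is safe; 2.0 guards against small-count flukes.

### Association p-value

Each SEMS is annotated with a two-sided Fisher exact test on the 2×2 table
(sex × heterozygous/homozygous) over called samples. The two-sided p-value
sums, over one margin-fixed hypergeometric family, all table probabilities
≤ the observed table's probability — the standard conditional exact
definition. The implementation delegates to `scipy.stats.fisher_exact`
(degenerate tables with a zero margin return 1 directly) and the test suite
checks it against an independent exact-rational enumeration. With perfect separation at 49 females and 46
males the p-value is 1/C(95, 46) ≈ 3.24 × 10⁻²⁸. Multiple testing uses
Bonferroni: `bonferroni_cutoff(alpha, n_tests) = alpha / n_tests` computed
in floating point; for extreme inputs the quotient can differ from the
decimal result by 1 ulp (e.g. `1e-130 / 1e7` is 1 ulp away from `1e-137`),
which is irrelevant at the scale of the p-values involved.

## 2. The cross-mapping artifact and reference swapping

### Mechanism

Sequence present only on the Y (hemizygous in males, absent in females) is
missing from a female-derived assembly. Short reads from it mis-map to the
most similar sequence that *is* in the assembly — typically an autosomal or
pseudo-autosomal paralog. At positions where the Y copy differs from the
paralog, all males acquire apparent heterozygous calls (paralog allele +
Y allele) while females remain homozygous: a spurious SEMS at the paralog's
location, potentially on a different chromosome from the SLR.

In the read-depth model, a male's mis-mapped alternate-read count at such a
position is Poisson with mean `mismap_fraction × mean_depth / 2` (the Y is
haploid); the artifact heterozygous call is emitted when at least
`min_alt_reads` (default 2) alternate reads arrive, mirroring a standard
caller's minimum-evidence rule. With default depth 40 and
`mismap_fraction = 0.8` the per-male probability of the artifact call is
P(Poisson(16) ≥ 2) ≈ 1, so the artifact reproduces robustly; at
`mismap_fraction = 0` it cannot occur.

### Elimination

The screen is run twice: against the female reference and against a
*Y-substituted* reference in which the SLR interval carries the Y haplotype
(with its hemizygous insertions). Because the SLR sits at the telomeric end
of the sex chromosome, all non-SLR coordinates are identical between the two
assemblies, so elimination is exact `(chrom, pos)` set difference on
non-SLR SEMS: sites found under the female reference but absent under the
Y-substituted one are the artifact candidates. Under the Y-substituted
reference the mis-mapping source sequence has a true home, so the artifact
disappears while genuine SLR SEMS persist in both runs.

### Independent confirmation by flank alignment

Each eliminated (non-SLR) SEMS is checked by aligning `crossmap_flank`
(default 500) bp of flanking reference sequence around the site against the
SLR-Y haplotype with the built-in aligner. The site is flagged
`crossmap_suspect` iff a hit with identity ≥ `crossmap_min_identity`
(default 0.9) covers the site or ends within `crossmap_site_margin`
(default 50) bp of it. The margin exists because the evidence is similarity
of the *flanking* sequence: a maximal-scoring local alignment never ends on
a mismatch, and the suspect site is by construction a mismatch against the
Y copy, so a site at the very edge of a Y-similar tract can sit just outside
the trimmed alignment. 500 bp of flank is ample for a 13-mer-seeded
alignment while keeping the screen fast; 0.9 identity comfortably accepts
paralogs diverged a few percent while rejecting random similarity.

## 3. Windowed-coverage scan for hemizygous regions

Per-sample read depth is summed in fixed windows (`window_size` default
100 bp) and reduced to categories: `0` = no read, `1` = depth 1–2
(spillover/noise level), `2` = depth ≥ 3 (solid presence). The categories
deliberately discard quantitative depth: a Y-hemizygous window in a male has
half-diploid expected depth (20× at 40× diploid depth), which is still
unambiguously category 2, while female windows there receive no reads at
all — the contrast is categorical, not quantitative, and is robust to
per-sample depth variation.

Two decision modes:

- **strict** — a window is male-specific iff *every* male is category 2 and
  *every* female is category 0 (mirror for female-specific). Zero tolerance;
  appropriate for clean data and gives exact boundaries.
- **relaxed** — a window is sex-specific iff at least `min_present_fraction`
  (default 0.9) of one sex is category 2, at most `max_absent_leak`
  (default 0.1) of the other sex is non-zero, and the Fisher exact test of
  category (0 vs >0) against sex is significant at `cov_alpha` (default
  0.01) after Bonferroni correction over tested windows. The defaults
  tolerate ~10 % sporadic dropout/contamination per window while the exact
  test keeps genome-wide false positives controlled.

Flagged windows are merged into regions, bridging gaps of up to
`max_gap_windows` (default 1) unflagged windows — one window can fail by
chance in relaxed mode without splitting a real region — and regions with
fewer than `min_windows` (default 1) windows are dropped; the default keeps
single-window regions because a genuine hemizygous insertion can be as
short as one window.

The same machinery supports *presence checking*: given previously
discovered regions and a new cohort's category matrix,
`check_region_presence` reports per-sample presence concordance with
recorded region specificity.

## 4. Trio phasing of the SLR

For a mother–son pair genotyped at SLR sites (son XY):

- son heterozygous, mother homozygous → the maternal allele is the son's X
  allele, the other allele is the Y allele (**phased**);
- son heterozygous, mother heterozygous → either assignment is consistent
  (**ambiguous**);
- son homozygous → X and Y allele are identical at this site (**phased**,
  uninformative for divergence);
- genotypes that violate Mendelian transmission are reported as
  **conflict**; missing calls propagate as **missing**.

No imputation is attempted: the ambiguous fraction equals the mother's
heterozygosity at X-diverged sites by construction, and the component
reports it rather than guessing. Phased haplotypes can be emitted as FASTA
by substituting alleles into the reference SLR sequence (ambiguous sites
become IUPAC codes, missing become N).

## 5. Local aligner and chimera decomposition

A self-contained seed-and-extend local aligner:

| parameter | default | rationale |
|---|---|---|
| `k` | 13 | exact seed length; sensitive down to ~92 % identity over 150 bp while keeping random 13-mer hits rare in megabase targets |
| `match, mismatch, gap` | +1, −2, −2 | simple unit scoring; a hit's score is then `matches − 2·mismatches − 2·gapcols`, directly interpretable |
| `x_drop` | 40 | ungapped extension stops when the running score falls 40 below its maximum; at mismatch −2 this bridges runs of up to 20 consecutive mismatches (diverged patches) without extending through genuinely unrelated sequence |
| `min_len`, `min_identity` | 50, 0.8 | hit reporting filters |

Both strands are searched; seeds containing N never match. After ungapped
x-drop extension, hits containing mismatches or stopping short of the query
ends are refined by banded-window Smith–Waterman (own vectorized
implementation, verified against an independent reference implementation in
the tests). If the refined alignment ends on — or within
`x_drop / |mismatch|` columns of — the window boundary, the window is
doubled and refinement repeated (capped at a 2048 bp pad): an alignment
stopping near the edge may have been prevented from crossing a mismatch dip
whose score recovery lies beyond the window. Near-identical hits covered
> 90 % by a better hit are suppressed.

**Chimera decomposition.** To explain a sex-limited sequence stitched from
fragments of several progenitors, all hits of the chimera against each
progenitor are collected and the best consistent tiling is selected by
dynamic programming over hits ordered by query end: successive segments
must advance along the query and may overlap by at most `max_overlap`
(default 10) bp, with overlaps penalized at the match weight. Overlapping
adjacent segments are then trimmed to non-overlapping breakpoints by
re-scoring the boundary region. The output is an ordered list of labelled
source segments with query and source coordinates.

## 6. The synthetic generator

The generator is the validation instrument, not an afterthought: it
produces references, genotypes, coverage, trios and chimeras **with full
ground truth** so that every pipeline claim is checked against known
answers.

Default scenario (all overridable via `SimConfig` or YAML):

| parameter | default | meaning |
|---|---|---|
| `n_females`, `n_males` | 49, 46 | cohort size |
| `chrom_lengths` | chr19 1.2 Mb, chr04 0.8 Mb, chr08 0.8 Mb | genome |
| `slr_interval` | chr19:861,800–1,200,000 | SLR at the telomeric end (≈ 338 kb) |
| `yhs_intervals` | 34.8 kb, 4.3 kb, 100 bp | Y-hemizygous insertions inside the SLR |
| `paralog_map` | 2 kb of YHS copied to chr04 at 95 % identity | cross-mapping sink |
| `snp_density` | 0.005 | background SNPs per bp |
| `xy_divergence` | 0.002 | X/Y divergent sites per SLR bp (the true SEMS) |
| `mean_depth` | 40 | diploid sequencing depth; per-window depth is Poisson(`mean_depth`·c/2) for copy number c, with λ scaled for short terminal windows |
| `mismap_fraction` | 0.0 | fraction of YHS-derived reads mis-mapping to the paralog under the female reference |
| `missing_rate`, `genotype_error_rate` | 0, 0 | per-call noise |
| `min_alt_reads` | 2 | caller evidence threshold for the artifact call |
| `nb_dispersion`, `per_sample_depth_scale` | None | optional negative-binomial overdispersion and per-sample depth multipliers |
| `heterogametic_sex` | `M` | set `F` for the ZW mirror |

Everything is derived deterministically from `seed`: references, sample
haplotypes, depths, noise. `TruthSet` records the true SEMS (with X and Y
alleles in both coordinate systems), the artifact sites, the YHS intervals
and the haplotype sequences, plus exact coordinate lifting between the
female and Y-substituted assemblies.

### Generator scope

The generator models the artifact at the genotype/coverage level — it does
not simulate reads or run an external mapper and caller. Mis-mapping is
parameterized (`mismap_fraction`) rather than emergent from sequence
similarity; the paralog identity affects which sites become artifacts, not
how many reads mis-map. Linkage disequilibrium, recombination within the
SLR, structural variation beyond the planted insertions, mapping-quality
filters and multi-mapper ambiguity are out of scope. Consequently the
pipeline's quantitative behaviour under a real mapper must be established
on real data; what the synthetic results establish is the *logic* of the
screen, the elimination and the scans.

## 7. Numerical choices

- Exact-test p-values come from `scipy.stats.fisher_exact` (two-sided),
  clipped to [0, 1]; tables with a zero margin short-circuit to 1.
- Fisher p-values are cached per table since genotype screens re-test
  identical margins thousands of times.
- Genotype calls and coverage categories are int8; window depths int64.
- Derived RNG streams use `numpy.random.SeedSequence` spawned from the
  scenario seed with a distinct integer key per generator component, so one
  component's draws never perturb another's.
- Coordinates are 0-based half-open internally; TSV/BED/VCF output uses the
  conventional bases of each format.

## 8. Limitations

- The exact SEMS pattern loses sensitivity in cohorts with pervasive
  genotyping error; `min_callrate_per_sex` handles missingness but a single
  wrong call at a site removes it. This is deliberate — the screen is a
  high-precision discovery tool, not an estimator of sex-linkage strength.
- Strict coverage mode requires noiseless categories; with realistic error
  use relaxed mode, which trades exact boundary recovery for robustness
  (boundaries are still recovered to within about a window).
- Reference swapping as implemented assumes the two assemblies share
  coordinates outside the swapped interval; for assemblies differing by
  more than the SLR substitution, elimination would require lift-over.
- The aligner is designed for intra-genome similarity (paralogs, chimeras,
  flank checks) at moderate divergence; it is not a read mapper and makes
  no attempt at affine-gap optimality guarantees — the tests bound its
  score against true Smith–Waterman optima empirically.
- Trio phasing uses a single mother–son pair; sites where mother and son
  are both heterozygous remain ambiguous by design.
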