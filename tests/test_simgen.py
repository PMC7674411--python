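"""Synthetic genome generator: references, truth, population draws, chimeras."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slrscan.simgen import (SimConfig, build_references, simulate_population,
                            make_chimeric_duplicate, simulate_trio,
                            lift_to_female, lift_to_carrier, write_fasta,
                            read_fasta)
from slrscan.genotypes import HOM_REF, HET, HOM_ALT, MISSING

from conftest import small_config


class TestConfigValidation:
    def test_default_config_is_valid(self):
        SimConfig().validate()

    def test_yhs_outside_slr_rejected(self):
        with pytest.raises(ValueError, match="outside the SLR"):
            small_config(yhs_intervals=[(10_000, 12_000)]).validate()

    def test_paralog_source_outside_yhs_rejected(self):
        with pytest.raises(ValueError, match="not inside a YHS"):
            small_config(paralog_map=[((40_000, 41_000),
                                       ("chr04", 0, 1_000), 0.9)]).validate()

    def test_paralog_on_sex_chromosome_rejected(self):
        with pytest.raises(ValueError, match="autosomal"):
            small_config(paralog_map=[((35_000, 36_000),
                                       ("chr19", 0, 1_000), 0.9)]).validate()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            small_config(paralog_map=[((35_000, 36_000),
                                       ("chr04", 0, 900), 0.9)]).validate()

    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError, match="mismap_fraction"):
            small_config(mismap_fraction=1.5).validate()
        with pytest.raises(ValueError, match="heterogametic_sex"):
            small_config(heterogametic_sex="X").validate()


class TestCoordinateLift:
    def test_autosomes_unchanged(self):
        cfg = small_config()
        assert lift_to_female(cfg, "chr04", 123) == ("chr04", 123)
        assert lift_to_carrier(cfg, "chr04", 123) == ("chr04", 123)

    def test_yhs_positions_have_no_female_image(self):
        cfg = small_config()
        assert lift_to_female(cfg, "chr19", 36_000) is None
        assert lift_to_female(cfg, "chr19", 45_099) is None

    def test_round_trip_outside_yhs(self):
        cfg = small_config()
        for pos in (0, 29_999, 34_999, 40_000, 44_000, 59_999):
            lifted = lift_to_female(cfg, "chr19", pos)
            assert lifted is not None
            assert lift_to_carrier(cfg, *lifted) == ("chr19", pos)

    def test_shift_equals_preceding_yhs_length(self):
        cfg = small_config()
        assert lift_to_female(cfg, "chr19", 40_000) == ("chr19", 37_000)
        assert lift_to_female(cfg, "chr19", 50_000) == ("chr19", 46_900)


class TestBuildReferences:
    def test_deterministic(self):
        cfg = small_config(seed=9)
        a = build_references(cfg)
        b = build_references(small_config(seed=9))
        assert a[0] == b[0] and a[1] == b[1]
        assert a[2].true_sems.equals(b[2].true_sems)
        assert a[2].artifact_sites.equals(b[2].artifact_sites)

    def test_length_difference_is_total_hemizygous_sequence(self, small_scenario):
        cfg, female, y_sub, _ = small_scenario
        yhs_total = sum(b - a for (a, b) in cfg.yhs_intervals)
        assert len(y_sub["chr19"]) - len(female["chr19"]) == yhs_total == 3_100
        assert female["chr04"] == y_sub["chr04"]

    def test_without_yhs_references_differ_only_at_divergent_sites(self):
        cfg = small_config(yhs_intervals=[], paralog_map=[])
        female, y_sub, truth = build_references(cfg)
        diff = [i for i, (a, b) in enumerate(zip(female["chr19"], y_sub["chr19"]))
                if a != b]
        assert diff == sorted(truth.true_sems["pos"].tolist())
        s, e = cfg.slr_interval
        assert all(s <= p < e for p in diff)

    def test_true_sems_alleles_match_references(self, small_scenario):
        cfg, female, y_sub, truth = small_scenario
        for row in truth.true_sems.itertuples():
            assert y_sub["chr19"][row.pos] == row.y_allele
            assert female["chr19"][row.pos_female] == row.x_allele
            assert row.x_allele != row.y_allele

    def test_paralog_target_carries_source_at_configured_identity(self, small_scenario):
        cfg, female, y_sub, truth = small_scenario
        (src, (tc, ts, te), ident) = cfg.paralog_map[0]
        src_seq = y_sub["chr19"][src[0]:src[1]]
        tgt_seq = y_sub[tc][ts:te]
        mismatches = sum(a != b for a, b in zip(src_seq, tgt_seq))
        assert mismatches == round((1 - ident) * (src[1] - src[0]))
        assert len(truth.artifact_sites) == mismatches
        for row in truth.artifact_sites.itertuples():
            assert y_sub[tc][row.pos] == row.ref
            assert y_sub["chr19"][src[0] + (row.pos - ts)] == row.alt

    def test_identity_one_gives_exact_copy_and_no_artifacts(self):
        cfg = small_config(paralog_map=[((35_000, 36_000),
                                         ("chr04", 10_000, 11_000), 1.0)])
        female, y_sub, truth = build_references(cfg)
        assert y_sub["chr04"][10_000:11_000] == y_sub["chr19"][35_000:36_000]
        assert len(truth.artifact_sites) == 0

    def test_haplotypes_consistent_with_references(self, small_scenario):
        cfg, female, y_sub, truth = small_scenario
        s, e = cfg.slr_interval
        assert truth.y_haplotype == y_sub["chr19"][s:e]
        fs, fe = truth.slr_interval_female
        assert truth.x_haplotype == female["chr19"][fs:fe]


class TestSimulatePopulation:
    def test_deterministic_per_mode(self, small_scenario):
        cfg, _, _, truth = small_scenario
        a = simulate_population(cfg, truth, "female")
        b = simulate_population(cfg, truth, "female")
        assert a[0] == b[0]
        assert np.array_equal(a[1].depths, b[1].depths)

    def test_bad_mode_and_mismatched_truth_rejected(self, small_scenario):
        cfg, _, _, truth = small_scenario
        with pytest.raises(ValueError, match="reference_mode"):
            simulate_population(cfg, truth, "male")
        other = small_config(seed=123)
        with pytest.raises(ValueError, match="different config"):
            simulate_population(other, truth, "female")

    def test_background_sites_shared_between_modes(self, small_scenario):
        cfg, _, _, truth = small_scenario
        gf, _, _ = simulate_population(cfg, truth, "female")
        gy, _, _ = simulate_population(cfg, truth, "y_substituted")
        sems_f = set(zip(truth.true_sems["chrom"], truth.true_sems["pos_female"]))
        sems_y = set(zip(truth.true_sems["chrom"], truth.true_sems["pos"]))
        art = set(zip(truth.artifact_sites["chrom"], truth.artifact_sites["pos"]))
        bg_f = {t for t in zip(gf.sites["chrom"], gf.sites["pos0"])
                if t not in sems_f and t not in art}
        bg_y = {t for t in zip(gy.sites["chrom"], gy.sites["pos0"])
                if t not in sems_y}
        assert bg_f == bg_y     # identical coordinates outside SLR by design

    def test_sex_linked_sites_follow_the_carrier_pattern(self, small_scenario):
        cfg, _, _, truth = small_scenario
        for mode, poscol, noncarrier in (("female", "pos_female", HOM_REF),
                                         ("y_substituted", "pos", HOM_ALT)):
            g, _, sex = simulate_population(cfg, truth, mode)
            f_mask, m_mask = sex.masks(g.samples)
            key = {(c, p): i for i, (c, p) in
                   enumerate(zip(g.sites["chrom"], g.sites["pos0"]))}
            for row in truth.true_sems.itertuples():
                i = key[(row.chrom, getattr(row, poscol))]
                assert (g.calls[i, m_mask] == HET).all()
                assert (g.calls[i, f_mask] == noncarrier).all()

    def test_artifact_heterozygosity_matches_poisson_tail(self):
        # cross-mapped alt reads ~ Poisson(mu * mean_depth / 2); a het call
        # needs >= min_alt_reads of them
        cfg = small_config(mismap_fraction=0.1, seed=5)
        _, _, truth = build_references(cfg)
        g, _, sex = simulate_population(cfg, truth, "female")
        _, m_mask = sex.masks(g.samples)
        key = {(c, p): i for i, (c, p) in
               enumerate(zip(g.sites["chrom"], g.sites["pos0"]))}
        hets = []
        for row in truth.artifact_sites.itertuples():
            i = key[(row.chrom, row.pos)]
            hets.extend((g.calls[i, m_mask] == HET).tolist())
        lam = cfg.mismap_fraction * cfg.mean_depth / 2.0
        p_het = float(1.0 - stats.poisson.cdf(cfg.min_alt_reads - 1, lam))
        n = len(hets)
        assert n >= 300
        se = (p_het * (1 - p_het) / n) ** 0.5
        assert abs(np.mean(hets) - p_het) < 4.5 * se

    def test_no_artifacts_without_mismapping(self, small_scenario):
        cfg, _, _, truth = small_scenario
        quiet = small_config(mismap_fraction=0.0)
        g, _, _ = simulate_population(quiet, truth_of(quiet), "female")
        art = set(zip(truth.artifact_sites["chrom"], truth.artifact_sites["pos"]))
        present = set(zip(g.sites["chrom"], g.sites["pos0"]))
        assert not (art & present)

    def test_diploid_depth_is_poisson_mean_depth(self):
        cfg = small_config(mismap_fraction=0.0, seed=2)
        truth = truth_of(cfg)
        _, cov, _ = simulate_population(cfg, truth, "female")
        d = cov.depths
        assert d.shape[0] == cov.grid.n_windows
        mean = d.mean()
        n = d.size
        assert abs(mean - cfg.mean_depth) < 4 * (cfg.mean_depth / n) ** 0.5
        # Poisson: variance equals the mean
        assert abs(d.var() / cfg.mean_depth - 1.0) < 0.1

    def test_hemizygous_windows_half_depth_in_carriers_zero_elsewhere(self):
        cfg = small_config(mismap_fraction=0.0, seed=3)
        truth = truth_of(cfg)
        _, cov, sex = simulate_population(cfg, truth, "y_substituted")
        f_mask, m_mask = sex.masks(cov.samples)
        i, j = cov.grid.window_range("chr19", 35_000, 38_000)
        block = cov.depths[i:j]
        assert (block[:, f_mask] == 0).all()
        male = block[:, m_mask]
        assert abs(male.mean() - cfg.mean_depth / 2) \
            < 4 * (cfg.mean_depth / 2 / male.size) ** 0.5

    def test_cross_mapped_reads_raise_carrier_depth_at_the_paralog(self):
        cfg = small_config(mismap_fraction=0.8, seed=4)
        truth = truth_of(cfg)
        _, cov, sex = simulate_population(cfg, truth, "female")
        f_mask, m_mask = sex.masks(cov.samples)
        i, j = cov.grid.window_range("chr04", 10_000, 11_000)
        male = cov.depths[i:j][:, m_mask].mean()
        female = cov.depths[i:j][:, f_mask].mean()
        expected_extra = cfg.mismap_fraction * cfg.mean_depth / 2
        assert male - female == pytest.approx(expected_extra, abs=3.0)

    def test_genotype_error_and_missing_rates(self):
        cfg = small_config(genotype_error_rate=0.05, missing_rate=0.1, seed=6)
        clean = small_config(seed=6)
        truth = truth_of(clean)
        g_clean, _, _ = simulate_population(clean, truth, "y_substituted")
        noisy_truth = truth_of(cfg)
        g_noisy, _, _ = simulate_population(cfg, noisy_truth, "y_substituted")
        assert g_clean.sites.equals(g_noisy.sites)
        miss = (g_noisy.calls == MISSING).mean()
        assert abs(miss - cfg.missing_rate) < 0.01
        both = (g_clean.calls >= 0) & (g_noisy.calls >= 0)
        err = (g_clean.calls != g_noisy.calls)[both].mean()
        assert abs(err - cfg.genotype_error_rate) < 0.01

    def test_per_sample_depth_scale(self):
        scale = {"F01": 0.5}
        cfg = small_config(mismap_fraction=0.0, per_sample_depth_scale=scale)
        truth = truth_of(cfg)
        _, cov, _ = simulate_population(cfg, truth, "female")
        j = cov.samples.index("F01")
        k = cov.samples.index("F02")
        assert cov.depths[:, j].mean() == pytest.approx(
            0.5 * cov.depths[:, k].mean(), rel=0.1)

    def test_negative_binomial_overdisperses(self):
        cfg = small_config(mismap_fraction=0.0, nb_dispersion=2.0, seed=8)
        truth = truth_of(cfg)
        _, cov, _ = simulate_population(cfg, truth, "female")
        mu = cfg.mean_depth
        # variance mu + mu^2 / r  >> mu
        assert cov.depths.var() > mu + mu * mu / 2.0 * 0.7


def truth_of(cfg):
    return build_references(cfg)[2]


class TestChimera:
    def test_exact_concatenation_and_layout(self):
        rng = np.random.default_rng(0)
        src_a = "".join(rng.choice(list("ACGT"), size=500))
        src_b = "".join(rng.choice(list("ACGT"), size=300))
        segs = [(src_a, (0, 100), "A"), (src_a, (200, 350), "A"),
                (src_b, (50, 120), "B")]
        chim, layout = make_chimeric_duplicate(segs, [0, 2, 1, 0])
        assert chim == src_a[0:100] + src_b[50:120] + src_a[200:350] + src_a[0:100]
        assert layout["label"].tolist() == ["A", "B", "A", "A"]
        assert layout["chim_start"].tolist() == [0, 100, 170, 320]
        assert layout["chim_end"].tolist() == [100, 170, 320, 420]

    def test_mutation_rate(self):
        rng = np.random.default_rng(1)
        src = "".join(rng.choice(list("ACGT"), size=4000))
        chim, _ = make_chimeric_duplicate([(src, (0, 4000), "A")], [0],
                                          mutation_rate=0.05,
                                          rng=np.random.default_rng(2))
        diff = sum(a != b for a, b in zip(chim, src))
        assert 120 < diff < 280       # ~0.05 * 4000 = 200

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            make_chimeric_duplicate([], [])
        with pytest.raises(ValueError, match="invalid"):
            make_chimeric_duplicate([("ACGT", (0, 10), "A")], [0])


class TestTrioGenerator:
    def test_homozygous_mother_everywhere_when_het_zero(self, small_scenario):
        cfg, _, _, truth = small_scenario
        trio = simulate_trio(truth, mother_het=0.0, seed=1)
        assert (trio.mother_calls == HOM_REF).all()
        assert (trio.son_calls == HET).all()
        assert len(trio.sites) == len(truth.true_sems)

    def test_mother_heterozygosity_fraction(self, small_scenario):
        cfg, _, _, truth = small_scenario
        trio = simulate_trio(truth, mother_het=0.4, seed=2)
        frac = (trio.mother_calls == HET).mean()
        n = len(trio.sites)
        assert abs(frac - 0.4) < 3 * (0.4 * 0.6 / n) ** 0.5 + 0.05

    def test_sites_use_female_coordinates_and_truth_alleles(self, small_scenario):
        cfg, female, _, truth = small_scenario
        trio = simulate_trio(truth, seed=0)
        assert trio.sites["pos0"].tolist() == truth.true_sems["pos_female"].tolist()
        for row in trio.sites.itertuples():
            assert female["chr19"][row.pos0] == row.ref


class TestFastaIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        seqs = {"a": "".join(rng.choice(list("ACGT"), size=203)),
                "b": "ACGT" * 10}
        p = tmp_path / "x.fa"
        write_fasta(seqs, p, width=50)
        assert read_fasta(p) == seqs
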