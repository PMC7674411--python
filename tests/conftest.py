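"""Shared fixtures: a desk-scale scenario and reusable oracle helpers."""
from __future__ import annotations

import numpy as np
import pytest

from slrscan import SimConfig, build_references


def small_config(**overrides) -> SimConfig:
    """A miniature genome (~90 kb) with the same planted structure as the
    default scenario: SLR at the telomeric end of the sex chromosome, two
    YHS insertions, one 95%-identity autosomal paralog of YHS sequence."""
    base = dict(
        n_females=8,
        n_males=7,
        chrom_lengths={"chr19": 60_000, "chr04": 30_000},
        sex_chrom="chr19",
        slr_interval=(30_000, 60_000),
        yhs_intervals=[(35_000, 38_000), (45_000, 45_100)],
        paralog_map=[((35_000, 36_000), ("chr04", 10_000, 11_000), 0.95)],
        snp_density=0.01,
        xy_divergence=0.005,
        mean_depth=40.0,
        window_size=100,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return small_config(mismap_fraction=0.8)


@pytest.fixture(scope="session")
def small_scenario(small_cfg):
    """(config, female_ref, y_ref, truth) for the miniature genome."""
    female, y_sub, truth = build_references(small_cfg)
    return small_cfg, female, y_sub, truth


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
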