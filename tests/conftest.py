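"""Shared fixtures: a small planted-feature genome reused across modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitocharter import synthio
from mitocharter.synthio import ReadParams, SimConfig

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_sim():
    """4 chromosomes (~100 kb) with planted genes, repeats and dispersed
    copies — the shared detection fixture."""
    cfg = SimConfig(
        n_chromosomes=4,
        chrom_length_range=(20_000, 30_000),
        n_genes_per_chrom=2,
        ssr_plan=[("A", 12), ("AC", 6), ("AGC", 5), ("TTTG", 4), ("AGAGG", 3)],
        tandem_plan=[(9, 4, 0), (20, 3, 1), (15, 5, 1)],
        dispersed_plan=[(30, 1.0, "forward"), (100, 0.95, "palindromic"),
                        (300, 0.93, "forward"), (60, 1.0, "palindromic")],
        plastid_insert_spec=[(5_000, 1.0), (500, 0.90), (30, 1.0), (2_000, 0.85)],
        rng_seed=42,
    )
    chroms, genes, manifest = synthio.generate_mitogenome(cfg)
    return cfg, chroms, genes, manifest


@pytest.fixture(scope="session")
def companion(small_sim):
    cfg, chroms, _genes, _manifest = small_sim
    plastome, nuclear, tmanifest = synthio.generate_companion_genomes(chroms, cfg)
    return plastome, nuclear, tmanifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


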