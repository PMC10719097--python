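"""Shared fixtures: small scaffolds and quartet factories."""

import numpy as np
import pytest
from hypothesis import settings

import haplarith as h

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_probe_map():
    """Three chromosomes at 800 SNPs each — enough for band structure."""
    return h.make_probe_map(snps_per_chrom=800, chromosomes=["1", "2", "3"])


@pytest.fixture(scope="session")
def quartet_factory(small_probe_map):
    """Simulate a quartet on the small scaffold with sensible defaults."""

    def make(spec=None, baf_sd=0.0, logr_sd=0.0, contamination=0.0, seed=7,
             probe_map=small_probe_map, xo=(0.5, 0.5), **kwargs):
        spec = spec or h.AberrationSpec(type="none")
        noise = h.NoiseModel(
            baf_sd=baf_sd, logr_sd=logr_sd,
            maternal_contamination=contamination, seed=seed,
        )
        return h.simulate_quartet(
            spec, probe_map=probe_map, noise=noise, seed=seed,
            crossover_arm_fractions=xo, **kwargs,
        )

    return make


@pytest.fixture(scope="session")
def euploid_quartet(quartet_factory):
    q, _ = quartet_factory()
    return q


@pytest.fixture(scope="session")
def maternal_trisomy_quartet(quartet_factory):
    """Noise-free non-mosaic maternal mitotic trisomy of chromosome 2."""
    spec = h.AberrationSpec(
        type="trisomy", chromosome="2", parent_of_origin="maternal",
        segregational_origin="mitotic",
    )
    q, _ = quartet_factory(spec)
    return q


def chrom_interval(probe_map, chrom):
    pos = probe_map.position[probe_map.chrom_mask(chrom)]
    return int(pos[0]), int(pos[-1])
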