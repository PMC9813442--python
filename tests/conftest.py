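"""Shared fixtures: one desk-scale simulated scenario reused across tests."""

import pytest
from hypothesis import HealthCheck, settings

from methylseed.dmr import call_dmrs
from methylseed.io import aggregate_windows
from methylseed.simulate import GenomeSpec, simulate_scenario

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_spec() -> GenomeSpec:
    """Two 200-kb chromosomes + 20-kb spike-in: large enough for thousands of
    CG windows, small enough for a seconds-scale build."""
    return GenomeSpec(
        n_chroms=2,
        chrom_length=200_000,
        n_genes_per_chrom=40,
        n_tes_per_chrom=12,
        n_dme_targets_per_chrom=16,
        spike_length=20_000,
    )


@pytest.fixture(scope="session")
def scen(small_spec):
    return simulate_scenario(spec=small_spec, seed=11)


@pytest.fixture(scope="session")
def pooled_windows(scen):
    """CG window tables of the pooled methylomes, keyed by (tissue, genotype)."""
    return {
        key: aggregate_windows(counts["pooled"], context="CG")
        for key, counts in scen["counts"].items()
    }


@pytest.fixture(scope="session")
def dmr_sets(pooled_windows):
    """Embryo-vs-endosperm DMRs per genotype (sample A = embryo)."""
    return {
        genotype: call_dmrs(
            pooled_windows[("embryo", genotype)], pooled_windows[("endosperm", genotype)]
        )
        for genotype in ("wt", "h1")
    }
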