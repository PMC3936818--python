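import pytest

from patchlift.simulate import SimConfig, simulate, write_fixture_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """Small two-variety dataset with engineered-effect ground truth."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def big_bundle():
    """~10,000-variant dataset for round-trip and recovery statistics."""
    return simulate(
        SimConfig(
            seed=5,
            chrom_lengths=(1_500_000, 1_500_000),
            snp_rate=3.4e-3,
            indel_rate=4e-4,
        )
    )


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """The default fixture bundle written to disk once per session."""
    out = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(SimConfig(seed=11), out)
    return out
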