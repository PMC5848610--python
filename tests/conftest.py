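import pytest

from promoter_architect.synthetic_data import SimConfig, generate


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study bundle (400 promoters, 2 × 2 Mb)."""
    return generate(SimConfig())


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced bundle for IO round-trips and pipeline smoke tests."""
    cfg = SimConfig(
        seed=7,
        n_chroms=2,
        chrom_length=400_000,
        n_promoters=40,
        n_distal_enhancer=6,
        n_distal_insulator=4,
        n_distal_other=4,
        n_redundant=5,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    """The small bundle written out as files."""
    outdir = tmp_path_factory.mktemp("bundle")
    from promoter_architect.synthetic_data import write_bundle

    paths = write_bundle(small_bundle, outdir)
    return outdir, paths
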