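import pytest

from asbind.synthetic_data import SimulationConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A 500-SNP, 5-dataset bundle exercising CNVs, masks and catalogs."""
    return generate_bundle(SimulationConfig(seed=11, n_snps=500, n_datasets=5))


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """The same kind of bundle written to disk through variant_io."""
    from asbind.synthetic_data import emit_fixture_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    emit_fixture_bundle(outdir, SimulationConfig(seed=11, n_snps=500, n_datasets=5))
    return outdir
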