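import pytest

from polyorf.core import Transcript
from polyorf.simulate import SimConfig, VariantSpec, simulate_bundle, write_fixture_bundle


@pytest.fixture(scope="session")
def toy_transcript() -> Transcript:
    """Minimal dual-coding transcript: canonical CDS spans the whole
    sequence, one nested altORF in frame offset 1 ([4, 13), protein MD)."""
    return Transcript(id="toy", gene_id="TOYG", sequence="ATGCATGGATTGATATAA", cds=(0, 18))


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=42,
        n_transcripts=6,
        n_lncrna=2,
        length_range=(900, 1800),
        variants=VariantSpec(n_per_transcript=30, enrichment_factor=2.0),
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


@pytest.fixture(scope="session")
def bundle_dir(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(small_config, outdir)
    return paths
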