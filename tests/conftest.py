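import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from whichtf import FixtureSpec, RunConfig, generate_fixture, run_single
from whichtf.pipeline import load_library, load_reference

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def bundle_config(bundle, **overrides) -> RunConfig:
    kwargs = dict(
        query=bundle.query,
        tfbs_dir=bundle.tfbs_dir,
        genes=bundle.genes,
        annotations=bundle.annotations,
        ontology=bundle.ontology,
        chrom_sizes=bundle.chrom_sizes,
        gaps=bundle.gaps,
        tf_gene_map=bundle.tf_gene_map,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Default synthetic bundle: planted dominant TF at concentration 0.8."""
    out = tmp_path_factory.mktemp("fixture_default")
    return generate_fixture(FixtureSpec(), out)


@pytest.fixture(scope="session")
def default_config(default_bundle):
    return bundle_config(default_bundle)


@pytest.fixture(scope="session")
def default_refs(default_config):
    return load_reference(default_config)


@pytest.fixture(scope="session")
def default_lib(default_config):
    return load_library(default_config)


@pytest.fixture(scope="session")
def default_ranking(default_config, default_refs, default_lib):
    return run_single(default_config, refs=default_refs, tfbs_lib=default_lib)


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
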