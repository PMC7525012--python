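import warnings

import pytest

from lncseed import io as lio
from lncseed.cerna import InteractionTable
from lncseed.integration import run_pipeline
from lncseed.synthetic_data import SyntheticConfig, generate_all

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def default_cfg():
    return SyntheticConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def dataset(default_cfg, tmp_path_factory):
    """Default-size synthetic instance: (paths, ground truth)."""
    outdir = tmp_path_factory.mktemp("synth")
    paths, truth = generate_all(default_cfg, outdir)
    return paths, truth


@pytest.fixture(scope="session")
def annotation(dataset):
    paths, _ = dataset
    return lio.read_gtf(paths["annotation"])


@pytest.fixture(scope="session")
def variants(dataset):
    paths, _ = dataset
    return lio.read_variants_bed(paths["variants"])


@pytest.fixture(scope="session")
def expression(dataset):
    paths, _ = dataset
    return lio.read_expression(paths["expression"], paths["samples"])


@pytest.fixture(scope="session")
def interactions(dataset):
    paths, _ = dataset
    return InteractionTable.from_tsv(paths["interactions"])


@pytest.fixture(scope="session")
def pipeline_result(dataset):
    """Full pipeline run on the default fixture (shared; treat as read-only)."""
    paths, _ = dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(
            paths["annotation"],
            paths["variants"],
            paths["expression"],
            paths["samples"],
            paths["interactions"],
            paths["pathways"],
            paths["drugs"],
        )
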