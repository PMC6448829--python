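import numpy as np
import pandas as pd
import pytest

from mrebs.pipeline import run_pipeline
from mrebs.synthetic_data import SimConfig, end_to_end_fixture


def tiny_config(seed: int = 11, **overrides) -> SimConfig:
    """A small, fast study configuration for unit tests."""
    base = dict(
        genome_length=40_000,
        chrom_count=1,
        diff_block_count=4,
        mrebs_molecules=60,
        wgbs_depth=8.0,
        rrbs_depth=8.0,
    )
    base.update(overrides)
    return SimConfig(seed=seed, **base)


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """One full default-configuration study, simulated and analysed once.

    Returns (bundle_dir, pipeline_result, truth_delta) shared by the
    end-to-end tests.
    """
    bundle = tmp_path_factory.mktemp("study")
    end_to_end_fixture(SimConfig(seed=1), bundle)
    result = run_pipeline(bundle)
    truth = pd.read_csv(bundle / "truth.tsv", sep="\t").set_index(["chrom", "pos"])
    return bundle, result, truth["delta"]


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    bundle = tmp_path_factory.mktemp("tiny")
    paths = end_to_end_fixture(tiny_config(), bundle)
    return bundle, paths
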