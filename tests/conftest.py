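import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from ulameeg.classify import SVMConfig
from ulameeg.pipeline import PipelineConfig
from ulameeg.synthetic import make_fixture


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory) -> Path:
    """On-disk 'tiny' fixture: 2 subjects/class, 2 segments each."""
    d = tmp_path_factory.mktemp("tiny") / "data"
    make_fixture("tiny", d, seed=7)
    return d


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def reduced_config(data_dir, out_dir, seed=0, **overrides) -> PipelineConfig:
    """Small-image pipeline profile for fast end-to-end tests."""
    kwargs = dict(
        data_dir=data_dir,
        out_dir=out_dir,
        image_size=45,
        patch_n=15,
        relieff_m=500,
        cv_seed=seed,
        relieff_seed=seed,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


def tiny_config(data_dir, out_dir, seed=0) -> PipelineConfig:
    """Profile sized for the 8-segment tiny fixture."""
    return reduced_config(
        data_dir,
        out_dir,
        seed=seed,
        relieff_k=1,
        relieff_m=50,
        cv_folds=2,
        svm=SVMConfig(inner_folds=2),
    )
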