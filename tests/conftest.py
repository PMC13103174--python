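import numpy as np
import pytest
from hypothesis import settings

from phimprint import simulator as sim

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def forced_dataset(tmp_path_factory):
    """A small evaluation-style split where every imprint keeps its
    accompanying signal word; shared by pipeline and evaluation tests."""
    out = tmp_path_factory.mktemp("forced_ds")
    config = sim.default_test_config(seed=11, n_images=40,
                                     force_accompanying=True)
    manifest = sim.render_dataset(config, out)
    _, records = sim.load_dataset(out)
    return {"dir": out, "config": config, "manifest": manifest,
            "records": records,
            "gt": {k: r["labels"] for k, r in records.items()}}
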