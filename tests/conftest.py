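import numpy as np
import pytest

from fewtex import io
from fewtex.phantom import DEFAULT_PRESETS, generate_cohort

COHORT_SEED = 11
N_PER_CLASS = 33


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Default well-separated 3-class phantom cohort, 33 per class, fixed seed."""
    out = tmp_path_factory.mktemp("cohort")
    specs = [DEFAULT_PRESETS[k] for k in ("homogeneous", "directional", "heterogeneous")]
    generate_cohort(specs, N_PER_CLASS, out, seed=COHORT_SEED)
    manifest, images = io.read_manifest(out / "manifest.csv")
    return {"dir": out, "manifest": manifest, "images": images}


@pytest.fixture(scope="session")
def feature_table(cohort):
    """33-feature table of the session cohort (computed once; ~20 s)."""
    return io.extract_feature_table(cohort["images"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
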