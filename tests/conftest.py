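import numpy as np
import pytest

from fedcrt.preprocess import cohort_window, patches_from_manifest
from fedcrt.synthetic import (
    desk_scale_phantom,
    desk_scale_sites,
    desk_scale_test_site,
    generate_cohort,
)


@pytest.fixture(scope="session")
def desk_manifest(tmp_path_factory):
    """A small four-site phantom cohort on disk (3 training sites + test site)."""
    out = tmp_path_factory.mktemp("cohort")
    sites = desk_scale_sites((12, 8, 8)) + [desk_scale_test_site(10)]
    return generate_cohort(sites, desk_scale_phantom(), seed=123, out_dir=out)


@pytest.fixture(scope="session")
def desk_patches(desk_manifest):
    """Preprocessed 16^3 patches for the whole small cohort."""
    window = cohort_window(desk_manifest)
    x, y, sites, ids = patches_from_manifest(desk_manifest, size=16, window=window)
    return {"x": x, "y": y, "sites": sites, "ids": ids, "window": window}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
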