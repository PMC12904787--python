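import numpy as np
import pandas as pd
import pytest

import morphoscreen as ms


@pytest.fixture(scope="session")
def atlas():
    return ms.make_reference_atlas(n_regions=6, markers_per_region=10, n_genes=200, seed=1)


@pytest.fixture(scope="session")
def dose_response_screen(atlas):
    """Single-morphogen dose ladder plus control, one positive beta."""
    design = [ms.ConditionSpec("control")] + [
        ms.ConditionSpec(f"SHH_{s}", ("SHH",), (s,)) for s in ms.synthetic.DOSE_LADDER
    ]
    effects = ms.ScreenEffects(beta={("region1", "SHH"): 4.0})
    adata, hashed, truth = ms.simulate_screen(design, atlas, 300, effects, seed=2)
    adata = ms.lognormalize(adata)
    return adata, hashed, truth


@pytest.fixture(scope="session")
def small_screen(atlas):
    """Tiny two-condition screen for fast structural tests."""
    design = [
        ms.ConditionSpec("control"),
        ms.ConditionSpec("BMP_c3", ("BMP4",), ("c3",)),
    ]
    adata, hashed, truth = ms.simulate_screen(design, atlas, 80, seed=3)
    return ms.lognormalize(adata), hashed, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
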