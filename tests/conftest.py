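import numpy as np
import pytest

from alpscog import (
    EffectSpec,
    PhantomSpec,
    fit_tensor,
    make_cohort,
    make_phantom,
    tensor_scalars,
)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom (truth ALPS = 1.5) with fitted tensors."""
    dwi, truth = make_phantom(PhantomSpec(noise="none"))
    tensors = fit_tensor(dwi)
    fa, md, ad, rd = tensor_scalars(tensors)
    return {"dwi": dwi, "truth": truth, "tensors": tensors,
            "fa": fa, "md": md, "ad": ad, "rd": rd}


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort: 45 patients + 41 controls, planted effects."""
    return make_cohort(EffectSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
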