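import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nuccas import library_design as ld
from nuccas import read_processing as rp

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_library() -> ld.Library:
    """Full default design: three motifs tiled everywhere + control + fillers."""
    return ld.default_design()


@pytest.fixture(scope="session")
def toy_library() -> ld.Library:
    """20-member library: one forward motif over 19 positions + control."""
    rng = np.random.default_rng(3)
    motif = ld.TargetMotif("".join(rng.choice(list("ACGT"), 20)), "TGG")
    return ld.build_library([motif], windows=[(60, 79)], n_fillers=0, seed=5)


@pytest.fixture(scope="session")
def toy_params() -> rp.PipelineParams:
    """Published pipeline thresholds with the default backbone's primers."""
    return rp.PipelineParams(
        primer_5=ld.DEFAULT_BACKBONE[:20], primer_3=ld.DEFAULT_BACKBONE[-20:]
    )
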