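import numpy as np
import pytest

from stripefit.model import ExtrusionParams, Roadblock, RoadblockSet
from stripefit.profiles import RatioProfile, ratio
from stripefit.synthetic import SyntheticSpec, synth_profile_counts


@pytest.fixture(scope="session")
def arm_terminal() -> RoadblockSet:
    """Block-free roadblock set with the standard 500 kb arm end."""
    return RoadblockSet((), 500.0)


def merged_ratio(spec: SyntheticSpec) -> RatioProfile:
    """Per-replicate viewpoint/control ratios, then the pointwise mean —
    the default replicate handling of the pipeline."""
    import warnings

    pairs = synth_profile_counts(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = np.nanmean([ratio(v, c).values for v, c in pairs], axis=0)
    return RatioProfile(pairs[0][0].distances, vals)


@pytest.fixture(scope="session")
def async_re_ratio() -> RatioProfile:
    """Merged synthetic ratio at the asynchronous-RE condition."""
    return merged_ratio(
        SyntheticSpec(ExtrusionParams(150.0, 0.06), seed=11)
    )


@pytest.fixture(scope="session")
def cen_block_ratio() -> RatioProfile:
    """Merged synthetic ratio with a partial (centromere-like) roadblock."""
    return merged_ratio(
        SyntheticSpec(
            ExtrusionParams(170.0, 0.08), RoadblockSet([Roadblock(120.0, 0.45)]), seed=3
        )
    )
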