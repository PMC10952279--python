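import hypothesis
import numpy as np
import pytest

from megabn.normative import AbnormalityMap

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_abnormality(scores: dict[str, float], subject: str = "p") -> AbnormalityMap:
    """Abnormality map from a {region: max_abs_z} dict (delta argmax throughout)."""
    regions = list(scores)
    return AbnormalityMap(
        subject_id=subject,
        region_ids=regions,
        max_abs_z=np.array([scores[r] for r in regions], dtype=float),
        argmax_band=["delta"] * len(regions),
    )
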