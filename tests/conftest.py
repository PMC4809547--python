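import numpy as np
import pytest

from nucphase.io import FragmentRecord, SiteRecord
from nucphase.profile import DyadProfile


@pytest.fixture
def toy_sites() -> list[SiteRecord]:
    return [
        SiteRecord("chr1", 991, 1010, "+", name="a"),
        SiteRecord("chr1", 2991, 3010, "-", name="b"),
        SiteRecord("chr2", 4991, 5010, ".", name="c"),
    ]


@pytest.fixture
def toy_fragments() -> list[FragmentRecord]:
    return [
        FragmentRecord("chr1", 100, 248),
        FragmentRecord("chr1", 0, 147),
        FragmentRecord("chr2", 500, 660),
    ]


def make_profile(values, **kw) -> DyadProfile:
    """DyadProfile over a window inferred from the value vector length."""
    values = np.asarray(values, dtype=float)
    half_window = (values.size - 1) // 2
    defaults = dict(n_sites=1, total_fragments=values.size, smoothing_bp=0, rescaled_mean=1.0)
    defaults.update(kw)
    return DyadProfile(half_window=half_window, values=values, **defaults)


@pytest.fixture
def flat_profile() -> DyadProfile:
    return make_profile(np.ones(2001))
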