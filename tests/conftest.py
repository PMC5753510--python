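import math
from math import comb

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def exact_hypergeom_upper_tail(k: int, n: int, m: int, N: int) -> float:
    """Independent oracle: exact integer-arithmetic hypergeometric P[X >= k].

    Sums C(m,i) C(N-m, n-i) for i = k..min(m,n) with Python integers and
    divides once, so it shares no code path with the scipy log-gamma route.
    """
    num = sum(comb(m, i) * comb(N - m, n - i) for i in range(k, min(m, n) + 1))
    return num / comb(N, n)


@pytest.fixture
def exact_tail():
    return exact_hypergeom_upper_tail
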