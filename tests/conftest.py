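import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from npqkit.fluor_core import CF_IMAGER, DarkYields, FlashRecord, FluorescenceTrace

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_trace(f_m=1200.0, f_o=240.0, fm_primes=None, protocol=CF_IMAGER,
               disc_id="d1", metadata=None):
    """Trace with explicit F_m' values at the protocol's first flash times."""
    if fm_primes is None:
        fm_primes = [f_m / (1.0 + 0.1 * i) for i in range(len(protocol.flash_times_min))]
    flashes = tuple(
        FlashRecord(time_min=t, f_s=0.6 * fp, f_m_prime=fp)
        for t, fp in zip(protocol.flash_times_min, fm_primes)
    )
    return FluorescenceTrace(disc_id=disc_id, dark=DarkYields(f_o=f_o, f_m=f_m),
                             flashes=flashes, protocol=protocol,
                             metadata=metadata or {})


@pytest.fixture
def trace_factory():
    return make_trace
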