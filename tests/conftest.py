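import numpy as np
import pytest

from dcemri import (
    AcquisitionParams,
    PhantomSpec,
    qiba_v4_layout,
    qiba_v6_layout,
)


@pytest.fixture
def acq():
    """In-vivo-style DCE acquisition: TR 7.9 ms, flip 20 degrees."""
    return AcquisitionParams(tr=7.9e-3, flip_deg=20.0)


@pytest.fixture
def multiflip_acq():
    """Variable-flip-angle T1 protocol: 2-20 degrees in steps of 2."""
    return AcquisitionParams(tr=7.9e-3, flip_deg=np.arange(2.0, 21.0, 2.0))


def small_phantom_spec(**overrides):
    """A scaled-down phantom for fast tests: 2x2 patches, short series."""
    defaults = dict(
        ktrans_values=(0.02, 0.1, 0.35), ve_values=(0.05, 0.2),
        patch_shape=(2, 2), n_time=181, dt=1.0, oversample=4)
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture
def small_spec():
    return small_phantom_spec()


# Full-size noise-free validation runs are shared across the acceptance
# tests (they each take a few seconds).
@pytest.fixture(scope="session")
def standard_noise_free_run():
    import time

    from dcemri import run_validation

    t0 = time.perf_counter()
    report = run_validation(qiba_v6_layout())
    elapsed = time.perf_counter() - t0
    return report, elapsed


@pytest.fixture(scope="session")
def extended_noise_free_run():
    import time

    from dcemri import run_validation

    t0 = time.perf_counter()
    report = run_validation(qiba_v4_layout())
    elapsed = time.perf_counter() - t0
    return report, elapsed
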