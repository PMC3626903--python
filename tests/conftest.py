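import numpy as np
import pytest

from fesfatigue.params import FatigueParams, ForceMotionParams


@pytest.fixture(scope="session")
def fm_default() -> ForceMotionParams:
    """Representative force-motion parameter set (600 μs session)."""
    return ForceMotionParams(
        A90=2.10, a=-4.49e-4, b=3.44e-2, Km=3.52e-1, tau1=36.1, tau2=52.1,
        V1=3.71e-1, V2=2.29e-2, L_over_I=9.85, FM=247.5, lam=5.0)


@pytest.fixture(scope="session")
def fat_default(fm_default) -> FatigueParams:
    return FatigueParams(
        alphaA=-4.03e-7, alphaKm=-1.36e-8, alphaTau1=2.93e-5,
        tauFat_ms=99.4e3, betaTau1=8.54e-4, A90_0=fm_default.A90,
        Km1_0=fm_default.Km, tau1_0=fm_default.tau1,
        tau1_0_iso=fm_default.tau1)


@pytest.fixture(scope="session")
def load_N() -> float:
    return 4.54 * 9.81
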