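import numpy as np
import pytest

from meltfit import Baselines, KineticParams, SimSpec, ThermoParams
from meltfit.simulate import default_grid, simulate_curve


@pytest.fixture
def ratio_baselines() -> Baselines:
    """Ratio-like baselines: pre ≈ 0.8, post ≈ 0.95 near 330 K."""
    return Baselines(k_N=3e-4, b_N=0.80 - 3e-4 * 330.0, k_U=2e-4, b_U=0.95 - 2e-4 * 330.0)


@pytest.fixture
def thermo_params(ratio_baselines) -> ThermoParams:
    return ThermoParams(dHm=400_000.0, Tm=330.0, baselines=ratio_baselines)


@pytest.fixture
def kinetic_params(ratio_baselines) -> KineticParams:
    return KineticParams(Ea=300_000.0, Tf=350.0, v=1.0, baselines=ratio_baselines)


@pytest.fixture
def grid() -> np.ndarray:
    return default_grid()


@pytest.fixture
def clean_curve(thermo_params):
    """Noiseless equilibrium melting curve with known truth."""
    spec = SimSpec(dHm=thermo_params.dHm, Tm=thermo_params.Tm,
                   baselines=thermo_params.baselines, noise_sd=0.0, seed=0)
    curve, truth = simulate_curve(spec, sample_id="clean")
    return curve, truth


@pytest.fixture
def noisy_curve(thermo_params):
    """Equilibrium curve with 1%-of-transition-height Gaussian noise."""
    spec = SimSpec(dHm=thermo_params.dHm, Tm=thermo_params.Tm,
                   baselines=thermo_params.baselines, noise_sd=0.0015, seed=7)
    curve, truth = simulate_curve(spec, sample_id="noisy")
    return curve, truth
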