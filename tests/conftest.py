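import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from csptitr import build_csp_table, make_fixture_hfyn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_fixture():
    """Noiseless 11-step hFynSH3-mimic series with ground truth (K_D = 48 uM)."""
    return make_fixture_hfyn(seed=1, noiseless=True)


@pytest.fixture(scope="session")
def noisy_fixture():
    """Default-noise 11-step hFynSH3-mimic series with ground truth."""
    return make_fixture_hfyn(seed=1)


@pytest.fixture(scope="session")
def noiseless_table(noiseless_fixture):
    series, _ = noiseless_fixture
    return build_csp_table(series)


@pytest.fixture(scope="session")
def noisy_table(noisy_fixture):
    series, _ = noisy_fixture
    return build_csp_table(series)


def make_synthetic_pdb(resnums, resnames=None, b=0.0):
    """Minimal synthetic Calpha-trace PDB text (one atom per residue)."""
    resnames = resnames or ["ALA"] * len(resnums)
    lines = []
    for i, (num, name) in enumerate(zip(resnums, resnames), start=1):
        x, y, z = float(i), 0.0, 0.0
        lines.append(
            f"ATOM  {i:5d}  CA  {name:<3} A{num:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}          "
            f"{'C':>2}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture()
def synthetic_pdb_text():
    return make_synthetic_pdb


def mass_action_bound_fraction(alpha: float, beta: float) -> float:
    """Independent oracle: solve beta*f = (1-f)*(alpha-f) for f in [0, min(1, alpha)]
    by bracketing bisection (scipy brentq), no closed form."""
    from scipy.optimize import brentq

    if alpha == 0:
        return 0.0

    def g(f):
        return beta * f - (1.0 - f) * (alpha - f)

    hi = min(1.0, alpha)
    return brentq(g, 0.0, hi, xtol=1e-15, rtol=8.9e-16)
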