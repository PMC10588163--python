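import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pslca import simulate as sim


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scenario cohort (n=5000, seed 0) shared across tests."""
    spec = sim.tlgs_like(n=5000, seed=0)
    cohort, truth = sim.simulate_cohort(spec)
    return cohort, truth, spec


@pytest.fixture(scope="session")
def confounded_cohort():
    """Confounded-scenario cohort: gender drives both smoking and class."""
    spec = sim.tlgs_like(n=5000, seed=0, confounded=True)
    cohort, truth = sim.simulate_cohort(spec)
    return cohort, truth, spec


def align_to_truth(model, gamma_true, rho_true):
    """Max |γ̂−γ*| and |ρ̂−ρ*| under the best class permutation."""
    import itertools

    best = None
    C = len(gamma_true)
    for perm in itertools.permutations(range(C)):
        perm = list(perm)
        re = np.abs(model.rho[perm] - rho_true).max()
        ge = np.abs(model.gamma[perm] - gamma_true).max()
        if best is None or max(re, ge) < max(best):
            best = (re, ge)
    return best
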