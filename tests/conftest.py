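import numpy as np
import pytest

from phlinkage import KineticParams, ThermoCycle, simulate


@pytest.fixture(scope="session")
def reference_cycle() -> ThermoCycle:
    """Microscopic pKa 8.5 (closed) / 4.3 (open), K_D = 100."""
    return ThermoCycle(8.5, 4.3, 100.0)


@pytest.fixture(scope="session")
def random_cycles() -> list[ThermoCycle]:
    """200 cycles with pK values in [2, 12] and log10 K_D in [-3, 4]."""
    rng = np.random.default_rng(20121)
    out = []
    while len(out) < 200:
        pk_c, pk_o = rng.uniform(2.0, 12.0, size=2)
        kd = 10.0 ** rng.uniform(-3.0, 4.0)
        cyc = ThermoCycle(pk_c, pk_o, kd)
        # keep cycles with a resolvable transition for inflection tests
        if abs(cyc.kd / (1 + cyc.kd) - cyc.kh / (1 + cyc.kh)) > 1e-6:
            out.append(cyc)
    return out


@pytest.fixture(scope="session")
def equilibrated_trajectory(reference_cycle):
    """A 2e5-step run at pH 6.5, where both conformations are well populated."""
    return simulate(reference_cycle, 6.5, KineticParams(n_steps=200_000, seed=3))
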