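import numpy as np
import pytest
from hypothesis import settings

from stericscreen import (
    ActiveSiteSpec,
    Atom,
    CatalystStructure,
    Conformer,
    Scaffold,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def centered_carbon():
    """Probe center (excluded) plus one carbon exactly at the center."""
    conf = Conformer("cc", [Atom("C", (0.0, 0.0, 0.0)), Atom("C", (0.0, 0.0, 0.0))])
    return conf, ActiveSiteSpec(center_atom_index=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_cluster_conformer(rng, n_atoms=6, spread=2.5):
    """Random small structure for oracle comparisons: a probe-center atom
    at the origin plus n_atoms carbons scattered within ``spread`` A."""
    atoms = [Atom("C", (0.0, 0.0, 0.0))]
    for _ in range(n_atoms):
        atoms.append(Atom("C", tuple(rng.uniform(-spread, spread, size=3))))
    return Conformer("rand", atoms), ActiveSiteSpec(center_atom_index=0)


@pytest.fixture
def shell_catalyst_factory():
    def make(n_shell, seed=0, catalyst_id=None):
        from stericscreen import ShellCatalystSpec, make_shell_catalyst

        return make_shell_catalyst(
            ShellCatalystSpec(n_shell_atoms=n_shell, seed=seed),
            catalyst_id=catalyst_id,
        )

    return make
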