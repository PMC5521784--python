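import numpy as np
import pytest

from anaerobenet import AbundanceTable
from anaerobenet.synthetic import SimulationConfig

# A small gLV family that is dynamically stable in absolute units (no
# closure) yet informative enough for interaction recovery: strong effects,
# strong self-limitation, positive growth. Shared by the recovery and
# consensus tests so stochastic guards run under one set of conditions.
RECOVERY_DAYS = tuple(range(0, 24, 2))


def recovery_config(n_taxa=5, noise_sigma=0.0, seed=0, **overrides) -> SimulationConfig:
    base = dict(
        n_taxa=n_taxa,
        days=RECOVERY_DAYS,
        closure=False,
        interaction_density=0.5,
        interaction_scale=2.0,
        self_limitation=8.0,
        growth_rate_range=(0.2, 1.0),
        noise_sigma=noise_sigma,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def make_table(values, days=None, taxa=None, condition="") -> AbundanceTable:
    values = np.asarray(values, dtype=float)
    if days is None:
        days = list(range(values.shape[1]))
    if taxa is None:
        taxa = [f"tax{i}" for i in range(values.shape[0])]
    return AbundanceTable(taxa=list(taxa), days=list(days), values=values, condition=condition)


@pytest.fixture
def two_taxon_table() -> AbundanceTable:
    return make_table([[0.6, 0.4], [0.4, 0.6]], days=[18, 24], taxa=["a", "b"])
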