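import numpy as np
import pytest

from peptide_nanoform import (
    REPORTED_CROSS_SECTIONS,
    SaxsScenario,
    default_pka_table,
    enumerate_groups,
    gen_saxs,
)


@pytest.fixture(scope="session")
def pka_table():
    return default_pka_table()


@pytest.fixture(scope="session")
def f8_groups(pka_table):
    return enumerate_groups("FEFKFEFK", pka_table)


@pytest.fixture(scope="session")
def fp_groups(pka_table):
    return enumerate_groups("FEFKPEFK", pka_table)


@pytest.fixture(scope="session")
def kpe_params():
    return REPORTED_CROSS_SECTIONS[("KPE", 5)]


@pytest.fixture(scope="session")
def epk_params():
    return REPORTED_CROSS_SECTIONS[("EPK", 5)]


@pytest.fixture(scope="session")
def epk_model_curve(epk_params):
    """Noiseless elliptical-cylinder curve for the twisted-fibre geometry."""
    return gen_saxs(SaxsScenario(params=epk_params, noise="none", noise_level=0.0))


def random_group_sets(n_sets: int, seed: int):
    """Seeded random ionizable-group sets for oracle-equivalence checks."""
    from peptide_nanoform import IonizableGroup, IonizableGroupSet

    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        groups = []
        for k in range(rng.integers(1, 6)):
            sign = int(rng.choice([-1, 1]))
            pka = float(rng.uniform(1.5, 12.5))
            count = int(rng.integers(1, 4))
            groups.append(
                IonizableGroup("side-chain", f"G{k}", pka, sign, count)
            )
        sets.append(IonizableGroupSet(tuple(groups)))
    return sets
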