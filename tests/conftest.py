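import numpy as np
import pytest

from tetraltr import synth_genome as sg
from tetraltr.profiles import load_bundled_models


@pytest.fixture(scope="session")
def models():
    return load_bundled_models()


@pytest.fixture(scope="session")
def templates():
    return {t.name: t for t in sg.default_templates()}


@pytest.fixture(scope="session")
def small_genome():
    """200 kb genome, 4 families x 1 full copy at 1 My (shared across tests)."""
    tpls = sg.default_templates()
    plans = [sg.ImplantPlan(t, n_full=1, age_My=1.0) for t in tpls[:4]]
    return sg.implant(200_000, 0.45, plans, seed=101)


@pytest.fixture(scope="session")
def clustered_genome():
    """600 kb genome with 3 copies each of three families (for clustering)."""
    tpls = {t.name: t for t in sg.default_templates()}
    plans = [
        sg.ImplantPlan(tpls["V-clade1"], n_full=3, age_My=[0.5, 1.0, 2.0]),
        sg.ImplantPlan(tpls["Gmr1"], n_full=3, age_My=1.0),
        sg.ImplantPlan(tpls["Epsilon2"], n_full=3, age_My=[1.0, 1.5, 2.0]),
    ]
    return sg.implant(600_000, 0.45, plans, seed=202)


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))
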