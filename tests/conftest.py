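import numpy as np
import pytest

from mscflow import (TwoSpeciesModelSpec, two_species_model,
                     two_species_mscispec)

# the base-case study parameters: theta0 = 0.002 on thin branches,
# 5*theta0 on the recipient lineage, introgression at tauX = theta0 with
# probability 0.2 after divergence at tauR = 2*theta0
THETA0 = 0.002
THETA1 = 0.01


@pytest.fixture(scope="session")
def msci_base() -> TwoSpeciesModelSpec:
    return two_species_mscispec(0.2)


@pytest.fixture(scope="session")
def msci_base_model():
    return two_species_model(0.2)


@pytest.fixture(scope="session")
def im_base() -> TwoSpeciesModelSpec:
    # continuous-migration counterpart: M = 0.2 into a population of size
    # theta1 = 0.01, i.e. intensity w = 4M/thetaB = 80
    return TwoSpeciesModelSpec(family="IM", w=80.0, tauR=2 * THETA0,
                               thetaA=THETA0, thetaR=THETA0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def random_valid_spec(rng: np.random.Generator) -> TwoSpeciesModelSpec:
    """A random valid two-species spec, for property sweeps."""
    family = rng.choice(["MSCI", "IM", "IIM", "SC"])
    tauR = float(rng.uniform(0.001, 0.01))
    thetaA = float(rng.uniform(0.0005, 0.01))
    thetaR = float(rng.uniform(0.0005, 0.01))
    if family == "MSCI":
        return TwoSpeciesModelSpec(family="MSCI",
                                   phi=float(rng.uniform(0.05, 0.95)),
                                   tauX=float(rng.uniform(0.1, 0.9)) * tauR,
                                   tauR=tauR, thetaA=thetaA, thetaR=thetaR)
    kw = dict(w=float(rng.uniform(1.0, 300.0)), tauR=tauR,
              thetaA=thetaA, thetaR=thetaR)
    if family in ("IIM", "SC"):
        kw["tauT"] = float(rng.uniform(0.1, 0.9)) * tauR
    return TwoSpeciesModelSpec(family=str(family), **kw)
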