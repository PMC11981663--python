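import numpy as np
import pytest

from cartmac.model_core import (
    CartTumorParams,
    CytokineParams,
    DoseRegimen,
    ModelState,
)
from cartmac.synthetic_data import (
    ARCHETYPES,
    PatientArchetype,
    cd40_dominant_archetype,
    generate_patient,
)

NOISELESS_CV = {"cart": 0.0, "tumor": 0.0, "il6": 0.0}


def noiseless(label_or_arch):
    """Archetype copy with measurement noise switched off."""
    arch = (ARCHETYPES[label_or_arch] if isinstance(label_or_arch, str)
            else label_or_arch)
    return PatientArchetype(
        label=arch.label, ranges=arch.ranges, schedule=arch.schedule,
        cv=dict(NOISELESS_CV), cart_unit=arch.cart_unit,
        tumor_unit=arch.tumor_unit, il6_unit=arch.il6_unit,
        split_dose=arch.split_dose, antigen_negative=arch.antigen_negative,
        horizon=arch.horizon)


@pytest.fixture(scope="session")
def reference_params():
    """A well-characterised responder parameter set used across tests."""
    return CartTumorParams(eta=0.3, mu_I=1.0, kappa=1.2, mu_E=0.35,
                           epsilon=1e-3, mu_P=0.01, rho=0.1, gamma=1.2,
                           A=1e8, B=1e8)


@pytest.fixture(scope="session")
def reference_cytokine():
    return CytokineParams(sigma_M=1e8, delta_M=0.15, sigma_I=10.0,
                          delta_I=2.0, alpha=4e-8, beta_B=3e-12,
                          beta_K=1e-11, beta_C=3e-9)


@pytest.fixture(scope="session")
def reference_init():
    return ModelState(T_P=3e10, M_i=1e10, IL6=5.0)


@pytest.fixture(scope="session")
def reference_regimen():
    return DoseRegimen.single(1e8)


@pytest.fixture(scope="session")
def cr_patient_noiseless():
    return generate_patient(noiseless("responder_CR"), 1)


@pytest.fixture(scope="session")
def hcrs_patient_noiseless():
    return generate_patient(noiseless("high_CRS"), 2)


@pytest.fixture(scope="session")
def cd40_patient():
    return generate_patient(noiseless(cd40_dominant_archetype()), 0)
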