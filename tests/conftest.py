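import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from famnet import lmm, pedkin, simulate as sim

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def five_family_ped() -> pedkin.Pedigree:
    """Five families of 50 members each; shared across statistical tests."""
    cfg = sim.SimConfig(n_probes=10, modules=[], family_sizes=(50,) * 5, seed=11)
    return sim.simulate_pedigree(cfg)


@pytest.fixture(scope="session")
def five_family_kinship(five_family_ped) -> pedkin.KinshipMatrix:
    return pedkin.kinship_matrix(five_family_ped)


@pytest.fixture(scope="session")
def five_family_kernels(five_family_ped, five_family_kinship):
    ids = five_family_ped.individual_ids
    A = lmm.genetic_kernel(five_family_kinship, ids)
    B = lmm.family_block_kernel(five_family_ped, ids)
    return ids, A, B


@pytest.fixture(scope="session")
def genetic_chol(five_family_kernels):
    """Cholesky factor of the genetic kernel, for drawing polygenic effects."""
    _, A, _ = five_family_kernels
    return np.linalg.cholesky(A + 1e-9 * np.eye(A.shape[0]))


@pytest.fixture
def trio_ped() -> pedkin.Pedigree:
    return pedkin.Pedigree([
        pedkin.PedRecord("F1", "dad", None, None, 1),
        pedkin.PedRecord("F1", "mom", None, None, 2),
        pedkin.PedRecord("F1", "kid", "dad", "mom", 1),
    ])


def polygenic_trait(chol, rng, sigma_g2=1.0, sigma_e2=1.0):
    """Null trait with genetic + residual structure on the shared pedigree."""
    n = chol.shape[0]
    return (chol @ rng.normal(size=n)) * np.sqrt(sigma_g2) + rng.normal(
        0.0, np.sqrt(sigma_e2), size=n
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """Small 5-family scenario with a shared 60-gene module (session cache)."""
    cfg = sim.SimConfig(
        n_probes=300,
        modules=[
            sim.ModuleSpec(60, 0.8, True),
            sim.ModuleSpec(40, 0.7, True),
        ],
        family_sizes=(40, 40, 40, 40, 40),
        seed=5,
    )
    ped, expr, pheno, truth = sim.simulate_dataset(cfg)
    return ped, expr, pheno, truth


def frame(values, prefix="p", columns=None) -> pd.DataFrame:
    values = np.atleast_2d(values)
    return pd.DataFrame(
        values,
        index=pd.Index([f"{prefix}{i}" for i in range(values.shape[0])],
                       name="probe_id"),
        columns=columns,
    )
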