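import numpy as np
import pandas as pd
import pytest

from ddpgs import CohortConfig, GenotypeMatrix, generate_cohort
from ddpgs.task import IndifferenceProfile, TaskConfig


@pytest.fixture(scope="session")
def task_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort reused by read-only tests."""
    cfg = CohortConfig(
        n_subjects=800,
        n_sites=10,
        n_split_families=0,
        frac_missing_task=0.0,
        seed=20240901,
    )
    return generate_cohort(cfg)


def random_profile(rng, delays=(0.25, 1.0, 7.0, 30.0, 90.0, 365.0, 1825.0), A=100.0,
                   subject_id="s0") -> IndifferenceProfile:
    ips = rng.uniform(0.0, A, size=len(delays))
    return IndifferenceProfile(
        subject_id=subject_id,
        delays=np.asarray(delays, dtype=float),
        indifference_points=ips,
        delayed_amount=A,
    )


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    """Five subjects x four clean variants (non-ambiguous, common, HWE-ok)."""
    variants = pd.DataFrame(
        {
            "variant_id": ["rs1", "rs2", "rs3", "rs4"],
            "chrom": ["1", "1", "2", "2"],
            "pos": [100, 200, 300, 400],
            "allele1": ["A", "C", "G", "T"],
            "allele2": ["G", "T", "A", "C"],
        }
    )
    dosage = np.array(
        [
            [0.0, 1.0, 2.0, 0.0],
            [1.0, 1.0, 1.0, 1.0],
            [2.0, 0.0, 0.0, 2.0],
            [1.0, 2.0, 1.0, 0.0],
            [0.0, 1.0, 2.0, 1.0],
        ]
    )
    return GenotypeMatrix(
        subjects=[f"s{i}" for i in range(5)], variants=variants, dosage=dosage
    )
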