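import numpy as np
import pandas as pd
import pytest

import kinlong as kl

SEED = 20260927


def make_pedigree(rows) -> kl.PedigreeTable:
    return kl.PedigreeTable(
        pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"])
    )


@pytest.fixture(scope="session")
def trio() -> kl.PedigreeTable:
    return make_pedigree(
        [
            ("T", "dad", None, None, "male"),
            ("T", "mom", None, None, "female"),
            ("T", "kid", "dad", "mom", "male"),
        ]
    )


@pytest.fixture(scope="session")
def inbred_pedigree() -> kl.PedigreeTable:
    """Three generations, 20 members, one full-sib mating (inbred loop)."""
    rows = [
        ("F", "gp1", None, None, "male"),
        ("F", "gp2", None, None, "female"),
        ("F", "gp3", None, None, "male"),
        ("F", "gp4", None, None, "female"),
        ("F", "sp1", None, None, "female"),
        ("F", "sp2", None, None, "male"),
        ("F", "a1", "gp1", "gp2", "male"),
        ("F", "a2", "gp1", "gp2", "female"),
        ("F", "b1", "gp3", "gp4", "male"),
        ("F", "b2", "gp3", "gp4", "female"),
        # inbred loop: full siblings a1 x a2
        ("F", "i1", "a1", "a2", "male"),
        ("F", "i2", "a1", "a2", "female"),
        ("F", "c1", "a1", "b2", "male"),
        ("F", "c2", "a1", "b2", "female"),
        ("F", "c3", "b1", "sp1", "male"),
        ("F", "c4", "b1", "sp1", "female"),
        ("F", "c5", "sp2", "a2", "male"),
        ("F", "c6", "sp2", "a2", "female"),
        ("F", "c7", "b1", "sp1", "male"),
        ("F", "c8", "sp2", "a2", "female"),
    ]
    return make_pedigree(rows)


@pytest.fixture(scope="session")
def small_study():
    """A modest polygenic study reused by several read-only tests."""
    rng = np.random.default_rng(SEED)
    cfg = kl.SimConfig(
        n_pedigrees=40,
        pedigree_template="sibship(4)",
        mafs=tuple(rng.uniform(0.05, 0.5, size=50)),
        seed=SEED,
    )
    ped, K, geno, pheno, truth = kl.simulate_dataset(cfg, n_snps=50)
    return ped, K, geno, pheno, truth
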