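import numpy as np
import pandas as pd
import pytest

import standkin as sk


@pytest.fixture
def fig1_families():
    """Family spec covering the four relationship categories seen in the
    natural-regeneration pedigree: selfed parent-offspring, parent-
    offspring, full sibs, half sibs."""
    return {
        "A": {"parent_offspring": 1, "full_sib": 1, "half_sib": 1, "selfed": 1},
        "B": {"parent_offspring": 1, "full_sib": 1, "half_sib": 1},
    }


@pytest.fixture
def small_pedigree(fig1_families):
    return sk.build_pedigree(12, 10, fig1_families, seed=7)


@pytest.fixture
def tiny_genotypes():
    rng = np.random.default_rng(3)
    codes = rng.choice([-1.0, 0.0, 1.0], size=(8, 30))
    sites = pd.DataFrame(
        {
            "scaffold": ["sc1"] * 30,
            "pos": np.arange(30) * 500,
            "ref": ["A"] * 30,
            "alt": ["C"] * 30,
        }
    )
    return sk.GenotypeMatrix(codes=codes, samples=[f"s{i}" for i in range(8)], sites=sites)
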