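import numpy as np
import pytest

from bsaqtl.cross import (GenomeMap, PhenotypeModel, QtlEffect,
                          assign_phenotypes, select_pools, simulate_meiosis)


@pytest.fixture(scope="session")
def gmap():
    """Test-scale genome: 4 chromosomes x 500 kb, 1 SNP / 2 kb, 1 Morgan each."""
    return GenomeMap.regular()


@pytest.fixture(scope="session")
def demo_model():
    """Four planted QTLs, two favouring each parent, effects 25-40 %."""
    return PhenotypeModel(
        baseline=1.7,
        qtl_effects=(
            QtlEffect("chrI", 250_000, "A", 0.35),
            QtlEffect("chrII", 150_000, "A", 0.30),
            QtlEffect("chrIII", 350_000, "B", 0.25),
            QtlEffect("chrIV", 200_000, "B", 0.40),
        ),
        noise_cv=0.15,
    )


@pytest.fixture(scope="session")
def demo_cross(gmap, demo_model):
    """One full simulated cross with selected and random 24-member pools."""
    ss = np.random.SeedSequence(7).spawn(3)
    segs = simulate_meiosis(gmap, 574, np.random.default_rng(ss[0]))
    segs = assign_phenotypes(segs, demo_model, gmap, np.random.default_rng(ss[1]))
    superior, random_pool = select_pools(segs, 24, top_k=24,
                                         seed=np.random.default_rng(ss[2]))
    return segs, superior, random_pool
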