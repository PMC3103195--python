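import warnings

import numpy as np
import pytest
from hypothesis import settings

from pedphase import (SimConfig, TrainerConfig, harden_phase, phase_accuracy,
                      simulate_cross, train)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")

# the reduced-scale study conditions used throughout: a 5-generation cross,
# 20 founders (5 sires x 3 dams each), 8 offspring per mating, 2 chromosomes
# x 100 markers at 1 cM, clean genotypes
STUDY_SEED = 1


def small_cfg(**kw):
    """A fast 3-generation cross for unit tests."""
    base = dict(n_founders=8, founder_sires=2, generations=3,
                matings_per_sire=2, breeding_sires=2,
                breeding_matings_per_sire=1, offspring_per_mating=4,
                chromosomes=1, markers_per_chromosome=30, seed=7)
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cross():
    return simulate_cross(small_cfg())


@pytest.fixture(scope="session")
def small_trained(small_cross):
    ped, geno, truth, mmap = small_cross
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = train(ped, geno, mmap, TrainerConfig(max_iterations=12))
    return ped, geno, truth, mmap, res


@pytest.fixture(scope="session")
def study_run():
    """The scaled-down reproduction run: full default simulation design,
    10 training iterations with inversion enabled."""
    ped, geno, truth, mmap = simulate_cross(SimConfig(seed=STUDY_SEED))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = train(ped, geno, mmap, TrainerConfig(max_iterations=10))
    phased = harden_phase(res.skewness, geno)
    report = phase_accuracy(phased, truth, ped, mmap)
    return dict(ped=ped, geno=geno, truth=truth, mmap=mmap, res=res,
                phased=phased, report=report)


@pytest.fixture(scope="session")
def study_run_no_inversion(study_run):
    """The same cross trained with the inversion step disabled."""
    ped, geno, mmap = (study_run[k] for k in ("ped", "geno", "mmap"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = train(ped, geno, mmap,
                    TrainerConfig(max_iterations=25, inversion_enabled=False))
    return res


def random_context(rng, depth=3, n_markers=3, missing_prob=0.15):
    """Random analysis-context arrays (genotypes, presence, skewness)."""
    geno = np.zeros((7, n_markers, 2), dtype=np.uint8)
    n_memb = 3 if depth == 2 else 7
    present = np.zeros(7, bool)
    present[:n_memb] = rng.random(n_memb) > 0.2
    present[0] = True
    for k in range(n_memb):
        if not present[k]:
            continue
        for j in range(n_markers):
            if rng.random() < missing_prob:
                continue
            a, b = sorted(rng.integers(1, 3, 2))
            geno[k, j] = (a, b)
    skew = rng.random((7, n_markers))
    return geno, present, skew
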