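"""Shared fixtures: random pedigree factories and a small simulated cross."""

from __future__ import annotations

import numpy as np
import pytest

import crossblup as cb


def random_pedigree(rng: np.random.Generator, n_founders: int, n_total: int,
                    both_parents: bool = True) -> cb.Pedigree:
    """A random valid pedigree; non-founders draw parents among older animals.

    With ``both_parents=False`` some animals get a single known parent.
    """
    rows = [(i, 0, 0) for i in range(1, n_founders + 1)]
    for i in range(n_founders + 1, n_total + 1):
        s, d = rng.choice(np.arange(1, i), size=2, replace=False)
        if not both_parents and rng.random() < 0.2:
            d = 0
        rows.append((i, int(s), int(d)))
    return cb.validate_and_sort(rows)


def structured_breeds(rng: np.random.Generator, ped: cb.Pedigree, n_breeds: int = 3):
    """Random founder-breed assignment covering all breeds."""
    founders = ped.labels[ped.is_founder()]
    breeds = [chr(65 + j) for j in range(n_breeds)]
    assign = {int(f): breeds[j % n_breeds] for j, f in enumerate(founders)}
    # shuffle assignment for variety
    vals = list(assign.values())
    rng.shuffle(vals)
    return dict(zip(assign.keys(), vals))


@pytest.fixture(scope="session")
def tiny_dataset() -> cb.SimulatedDataset:
    """A small three-way cross (180 crossbreds, 200 SNPs) for pipeline tests."""
    cfg = cb.SimulationConfig(
        n_sires=20, n_a_grandsires=4, n_a_granddams=10,
        n_founders_b=10, n_founders_c=40,
        dams_per_sire=3, offspring_per_mating=3,
        n_snps=200, seed=7,
    )
    return cb.simulate_population(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
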