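"""Shared fixtures: toy databases and pedigree builders."""

from __future__ import annotations

import numpy as np
import pytest

from panelped import (
    CancerHistory, Individual, Pedigree, build_model_database,
    enumerate_genotypes, make_toy_database, mask_ages, simulate_family,
)


@pytest.fixture(scope="session")
def toy_db():
    """3 genes (BRCA1/BRCA2/ATM), 2 cancers (Breast, Ovarian)."""
    return make_toy_database(K=3, R=2, seed=0)


@pytest.fixture(scope="session")
def toy_db4():
    """4 genes (BRCA1/BRCA2/ATM/MSH2), 2 cancers."""
    return make_toy_database(K=4, R=2, seed=0)


@pytest.fixture(scope="session")
def toy_mdb(toy_db):
    return build_model_database(toy_db)


@pytest.fixture(scope="session")
def toy_space(toy_mdb):
    return enumerate_genotypes(toy_mdb.gene_variants, 2)


def nuclear_family(child_sexes=(0, 1, 1), proband_index=0, cancers=("BC", "OC")):
    """Two founder parents plus children; proband among the children."""
    members = [
        Individual(id=1, sex=0, cur_age=70,
                   cancers={c: CancerHistory() for c in cancers}),
        Individual(id=2, sex=1, cur_age=72,
                   cancers={c: CancerHistory() for c in cancers}),
    ]
    for i, sex in enumerate(child_sexes):
        members.append(Individual(
            id=3 + i, mother_id=1, father_id=2, sex=sex, cur_age=40 + i,
            is_proband=1 if i == proband_index else 0,
            cancers={c: CancerHistory() for c in cancers}))
    return Pedigree.from_members(members, cancers=list(cancers))


def random_family(db, rng, allow_twins=True, allow_germline=True,
                  allow_missing=True, max_members=7):
    """Random small simulated family for oracle-equivalence tests."""
    structures = [(1,), (2,), (3,), (1, 1), (2, 1), (2, 2), (3, 1), (4,)]
    sizes = {s: 2 + s[0] + (0 if len(s) == 1 else 1 + s[1]) for s in structures}
    choices = [s for s in structures if sizes[s] <= max_members]
    structure = choices[rng.integers(len(choices))]
    sim = simulate_family(structure, db, seed=int(rng.integers(2 ** 31)))
    ped = sim.pedigree
    if allow_twins and structure[0] >= 2 and rng.random() < 0.4:
        # female twin pair: forcing sex avoids sex-incompatible diagnoses
        sibs = [m for m in ped if m.mother_id == 1][:2]
        for m in sibs:
            m.sex = 0
            m.twin_group = 1
    if allow_germline and rng.random() < 0.4:
        member = list(ped)[rng.integers(len(ped))]
        genes = list(db.gene_variant_map)
        k = int(rng.integers(len(genes)))
        member.germline[genes[k]] = sim.true_genotypes[member.id][k]
    if allow_missing and rng.random() < 0.3:
        ped = mask_ages(ped, 0.3, seed=int(rng.integers(2 ** 31)))
    return ped, sim


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
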