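import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pedlink.types import (AFFECTED, FEMALE, MALE, UNAFFECTED, UNKNOWN,
                           DiseaseModel, GenotypeTable, Individual,
                           MarkerPanel, Pedigree)


@pytest.fixture
def trio():
    return Pedigree([
        Individual("f", None, None, MALE, AFFECTED),
        Individual("m", None, None, FEMALE, UNAFFECTED),
        Individual("c", "f", "m", MALE, AFFECTED),
    ])


@pytest.fixture
def nuclear4():
    """Two parents, two children."""
    return Pedigree([
        Individual("f", None, None, MALE, AFFECTED),
        Individual("m", None, None, FEMALE, UNAFFECTED),
        Individual("c1", "f", "m", MALE, AFFECTED),
        Individual("c2", "f", "m", FEMALE, UNAFFECTED),
    ])


def make_panel(n, chrom=1, spacing_cm=1.0, freq=0.3, start_bp=1_000_000,
               spacing_bp=1_000_000):
    rows = [{"marker": f"m{k + 1}", "chrom": chrom,
             "bp": start_bp + k * spacing_bp, "cm": k * spacing_cm,
             "a1": "A", "a2": "C", "freq": freq} for k in range(n)]
    return MarkerPanel(pd.DataFrame(rows))


def make_table(pedigree, markers, genotypes):
    """GenotypeTable from {iid: [(a, b) or None per marker]}."""
    ids = pedigree.members
    alle = np.full((len(ids), len(markers), 2), -1, dtype=np.int8)
    for i, iid in enumerate(ids):
        for m, g in enumerate(genotypes[iid]):
            if g is not None:
                alle[i, m] = g
    return GenotypeTable(ids, markers, alle)


def random_pedigree(rng, n_members):
    """Random loop-free pedigree of exactly n_members (3..6) individuals.

    Grows by either adding a founder couple's child or a child of an
    existing member with a new marry-in spouse.
    """
    inds = [Individual("p1", None, None, MALE, UNKNOWN),
            Individual("p2", None, None, FEMALE, UNKNOWN)]
    by_id = {i.iid: i for i in inds}
    couples = [("p1", "p2")]
    k = 2
    while len(inds) < n_members:
        k += 1
        if rng.random() < 0.6 or len(inds) + 2 > n_members:
            father, mother = couples[int(rng.integers(len(couples)))]
            child = Individual(f"p{k}", father, mother,
                               MALE if rng.random() < 0.5 else FEMALE, UNKNOWN)
            inds.append(child)
            by_id[child.iid] = child
        else:
            # marry an existing individual to a new founder
            cand = [i for i in inds]
            person = cand[int(rng.integers(len(cand)))]
            k2 = k
            spouse_sex = FEMALE if person.sex == MALE else MALE
            spouse = Individual(f"p{k2}", None, None, spouse_sex, UNKNOWN)
            inds.append(spouse)
            by_id[spouse.iid] = spouse
            if person.sex == MALE:
                couples.append((person.iid, spouse.iid))
            else:
                couples.append((spouse.iid, person.iid))
    for ind in inds:
        u = rng.random()
        ind.affection = AFFECTED if u < 0.4 else (UNAFFECTED if u < 0.8
                                                  else UNKNOWN)
    return Pedigree(inds)


def random_genotypes(rng, pedigree, freq=0.4, missing=0.1):
    """Mendelian-consistent random genotypes with some missingness."""
    hap = {}
    for iid in pedigree.topological_order():
        ind = pedigree[iid]
        if ind.is_founder:
            hap[iid] = (int(rng.random() < freq), int(rng.random() < freq))
        else:
            hap[iid] = (hap[ind.father][int(rng.integers(2))],
                        hap[ind.mother][int(rng.integers(2))])
    geno = {}
    for iid in pedigree.members:
        geno[iid] = None if rng.random() < missing else hap[iid]
    return geno
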