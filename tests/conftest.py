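import datetime as dt

import numpy as np
import pytest

from seldrift import Pedigree, PedigreeRecord


def make_record(aid, sire="", dam="", year=None, sex="unknown", line="", genotyped=False):
    return PedigreeRecord(
        aid, sire, dam, dt.date(year, 1, 1) if year else None, sex, line, genotyped
    )


@pytest.fixture
def trio_pedigree():
    """Founder pair and one child."""
    return Pedigree(
        [
            make_record("F", year=2000, sex="male"),
            make_record("M", year=2000, sex="female"),
            make_record("C", "F", "M", year=2002),
        ]
    )


@pytest.fixture
def fullsib_mating_pedigree():
    """Two founders, two full sibs, and their inbred offspring (F = 0.25)."""
    return Pedigree(
        [
            make_record("F", year=2000, sex="male"),
            make_record("M", year=2000, sex="female"),
            make_record("S1", "F", "M", year=2002, sex="male"),
            make_record("S2", "F", "M", year=2002, sex="female"),
            make_record("X", "S1", "S2", year=2004),
        ]
    )


def random_pedigree(rng, n_founders=20, n_descendants=80, genotyped=True):
    """Random overlapping-generation pedigree for property tests."""
    records = [
        make_record(f"F{k}", year=2000, sex="male" if k % 2 else "female", genotyped=genotyped)
        for k in range(n_founders)
    ]
    ids = [r.animal_id for r in records]
    sexes = {r.animal_id: r.sex for r in records}
    years = {r.animal_id: 2000 for r in records}
    for k in range(n_descendants):
        males = [i for i in ids if sexes[i] == "male"]
        females = [i for i in ids if sexes[i] == "female"]
        sire = males[rng.integers(len(males))]
        dam = females[rng.integers(len(females))]
        year = max(years[sire], years[dam]) + int(rng.integers(1, 3))
        sex = "male" if rng.random() < 0.5 else "female"
        aid = f"D{k}"
        records.append(make_record(aid, sire, dam, year=year, sex=sex, genotyped=genotyped))
        ids.append(aid)
        sexes[aid] = sex
        years[aid] = year
    return Pedigree(records)


def kinship_oracle(ped):
    """Recursive coancestry oracle, independent of the tabular method.

    f(i,i) = (1 + f(s_i, d_i)) / 2; f(i,j) for i later in topological order
    = (f(s_i, j) + f(d_i, j)) / 2, missing parents contributing 0 coancestry.
    A = 2f.
    """
    order = {a: k for k, a in enumerate(ped.animal_ids)}
    cache = {}

    def f(i, j):
        if order[i] < order[j]:
            i, j = j, i
        key = (i, j)
        if key in cache:
            return cache[key]
        ki = ped.index[i]
        s = ped.records[ped.sire_idx[ki]].animal_id if ped.sire_idx[ki] >= 0 else None
        d = ped.records[ped.dam_idx[ki]].animal_id if ped.dam_idx[ki] >= 0 else None
        if i == j:
            val = 0.5 * (1.0 + (f(s, d) if s and d else 0.0))
        else:
            val = 0.5 * ((f(s, j) if s else 0.0) + (f(d, j) if d else 0.0))
        cache[key] = val
        return val

    ids = ped.animal_ids
    A = np.array([[2.0 * f(i, j) for j in ids] for i in ids])
    return A
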