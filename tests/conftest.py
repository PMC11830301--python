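import numpy as np
import pandas as pd
import pytest

from pmdd.cohort import load_codesets


@pytest.fixture(scope="session")
def codesets():
    return load_codesets()


@pytest.fixture()
def toy_diagnoses():
    """Six persons covering every phenotype branch (hand-traced labels)."""
    rows = [
        (1, "F32.3", 30.0),              # psychotic MDD
        (2, "F33.3", 28.0), (2, "F20", 33.0),   # psychotic + SCZ
        (3, "F32.1", 25.0),              # non-psychotic MDD
        (4, "F33.1", 31.0), (4, "F31", 27.0),   # non-psychotic + BD
        (5, "F20", 24.0),                # SCZ only, no MDD
        (6, "F32.3", 29.0), (6, "F31", 35.0),   # psychotic + BD
    ]
    return pd.DataFrame(rows, columns=["person_id", "icd10", "age"])


@pytest.fixture()
def pedigree_12():
    """Three generations, 12 persons, pairs enumerable by hand.

    gen 0: 1 (M) x 2 (F) grandparents
    gen 1: 3, 4 their sons; 5, 6 spouses; 11 second spouse of 3
    gen 2: 7, 8 children of 3+5 (full sibs);
           9, 10 children of 4+6 (full sibs; cousins of 7, 8);
           12 child of 3+11 (half sib of 7, 8)
    """
    rows = [
        # person_id, family_id, sex, birth_year, father, mother, censor_age
        (1, 0, "M", 1930, None, None, None),
        (2, 0, "F", 1932, None, None, None),
        (3, 0, "M", 1958, 1, 2, None),
        (4, 0, "M", 1960, 1, 2, None),
        (5, 0, "F", 1959, None, None, None),
        (6, 0, "F", 1961, None, None, None),
        (11, 0, "F", 1963, None, None, None),
        (7, 0, "F", 1985, 3, 5, None),
        (8, 0, "M", 1987, 3, 5, None),
        (9, 0, "F", 1986, 4, 6, None),
        (10, 0, "M", 1997, 4, 6, None),   # 11 years after 9 -> sib pair dropped
        (12, 0, "F", 1990, 3, 11, None),
    ]
    df = pd.DataFrame(rows, columns=["person_id", "family_id", "sex", "birth_year",
                                     "father_id", "mother_id",
                                     "age_at_death_or_emigration"])
    df["father_id"] = df["father_id"].astype("Int64")
    df["mother_id"] = df["mother_id"].astype("Int64")
    return df


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250919)
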