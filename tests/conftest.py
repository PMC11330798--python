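import numpy as np
import pandas as pd
import pytest

from flockdiv.pedigree import load_pedigree


@pytest.fixture
def trio():
    """A, B founders; C their offspring."""
    return load_pedigree([("A", None, None, 2000, "F1", "m"),
                          ("B", None, None, 2000, "F1", "f"),
                          ("C", "A", "B", 2002, "F1", "m")])


@pytest.fixture
def full_sib_pedigree():
    """E is the offspring of full sibs C x D."""
    return load_pedigree([("A", None, None, 2000, "F1", "m"),
                          ("B", None, None, 2000, "F1", "f"),
                          ("C", "A", "B", 2002, "F1", "m"),
                          ("D", "A", "B", 2002, "F1", "f"),
                          ("E", "C", "D", 2004, "F1", "f")])


@pytest.fixture
def half_sib_pedigree():
    """E is the offspring of half sibs C x D (shared sire A)."""
    return load_pedigree([("A", None, None, 2000, "F1", "m"),
                          ("B", None, None, 2000, "F1", "f"),
                          ("B2", None, None, 2000, "F1", "f"),
                          ("C", "A", "B", 2002, "F1", "m"),
                          ("D", "A", "B2", 2002, "F1", "f"),
                          ("E", "C", "D", 2004, "F1", "f")])


def random_pedigree(n: int, n_founders: int = 20, seed: int = 0,
                    max_year_gap: int = 1):
    """Random deep pedigree: each non-founder draws parents from earlier animals."""
    rng = np.random.default_rng(seed)
    rows = []
    sex = []
    for i in range(n):
        aid = f"X{i:04d}"
        if i < n_founders:
            sx = "male" if i % 2 == 0 else "female"
            rows.append((aid, None, None, 2000 + i // 10, None, sx))
            sex.append(sx)
        else:
            males = [j for j in range(i) if sex[j] == "male"]
            females = [j for j in range(i) if sex[j] == "female"]
            sire = f"X{rng.choice(males):04d}" if males and rng.random() > 0.1 else None
            dam = f"X{rng.choice(females):04d}" if females and rng.random() > 0.1 else None
            sx = "male" if rng.random() < 0.5 else "female"
            rows.append((aid, sire, dam, 2000 + i // 10, None, sx))
            sex.append(sx)
    return load_pedigree(pd.DataFrame(
        rows, columns=["animal", "sire", "dam", "birth_year", "flock", "sex"]))
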