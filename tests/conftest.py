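import numpy as np
import pandas as pd
import pytest

from wheatlocust import synthetic_data as syn


@pytest.fixture
def small_config():
    """Reduced design: 3+3 accessions, 3 replicates, 2 cages per subspecies."""
    return syn.SimulationConfig(
        n_ancestral=3,
        n_modern=3,
        replicates_per_accession=3,
        herbivory_cages_per_subspecies=2,
        trials_per_pair=2,
        seed=11,
    )


@pytest.fixture
def study_config():
    """The study-scale design (10+10 accessions, 6 replicates, 12 cages)."""
    return syn.SimulationConfig(seed=5)


def make_fs_table(wins_by_pair: dict[tuple[str, str], tuple[int, int]]) -> pd.DataFrame:
    """Minimal FS table from {(wild, modern): (wins, total)} counts."""
    rows = []
    for (w, m), (k, n) in wins_by_pair.items():
        for i in range(n):
            chosen = 1.0 if i < k else 0.0
            rows.append(
                {
                    "wild_accession": w,
                    "modern_accession": m,
                    "fs_wild": 0.8 if chosen else 0.2,
                    "wild_chosen": chosen,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def two_accession_fs():
    return make_fs_table({("W", "M"): (35, 50)})


@pytest.fixture
def three_accession_fs():
    return make_fs_table({("W", "M1"): (14, 20), ("W", "M2"): (8, 20)})
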