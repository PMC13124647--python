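import numpy as np
import pandas as pd
import pytest

from limnotraj.io import AsvCountTable, TaxonomyTable, validate_metadata


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)


@pytest.fixture
def small_table():
    df = pd.DataFrame(
        [[6, 2, 0], [2, 2, 4], [1, 1, 1]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "a3"],
    )
    return AsvCountTable(df)


@pytest.fixture
def small_taxonomy():
    return TaxonomyTable(
        pd.DataFrame(
            {
                "kingdom": ["Eukaryota", "Eukaryota", ""],
                "supergroup": ["TSAR", "Obazoa", ""],
                "division": ["Alveolata", "Metazoa", ""],
                "class": ["Spirotrichea", "Arthropoda", ""],
            },
            index=["a1", "a2", "a3"],
        )
    )


def make_metadata(lakes, n_months, n_replicates=3, start=("2021", 6)):
    """Metadata grid mirroring the monthly three-water-column design."""
    rows = []
    year, month = int(start[0]), start[1]
    dates = []
    y, m = year, month
    for _ in range(n_months):
        dates.append(pd.Timestamp(year=y, month=m, day=15))
        m += 1
        if m > 12:
            m, y = 1, y + 1
    for lake in lakes:
        for t, date in enumerate(dates):
            for r in range(n_replicates):
                rows.append(
                    {
                        "sample_id": f"{lake}-M{t + 1:02d}-W{r + 1}",
                        "lake": lake,
                        "date": date.date().isoformat(),
                        "replicate": f"W{r + 1}",
                        "month_index": t + 1,
                    }
                )
    return validate_metadata(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def metadata_grid():
    return make_metadata
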