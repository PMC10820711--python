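import numpy as np
import pandas as pd
import pytest

from roastchem import worked_fixture
from roastchem.containers import SpectraSet, VolatileTable
from roastchem.simulate import fixture_design, ground_truth


@pytest.fixture(scope="session")
def fixture_data():
    """The shipped small roast study: (spectra, volatiles)."""
    return worked_fixture()


@pytest.fixture(scope="session")
def fixture_truth():
    """Per-compound ground truth of the worked fixture."""
    return ground_truth(fixture_design())


def toy_volatile_table(areas: np.ndarray, meta: pd.DataFrame | None = None,
                       classes: list[str] | None = None) -> VolatileTable:
    """Hand-built table: rows samples s1..sn, columns compounds v1..vm."""
    n, m = areas.shape
    sample_ids = [f"s{i + 1}" for i in range(n)]
    compound_ids = [f"v{j + 1}" for j in range(m)]
    if meta is None:
        meta = pd.DataFrame(
            {
                "origin": ["O1"] * n,
                "roast": ["light"] * n,
                "batch": [1] * n,
                "reading": list(range(1, n + 1)),
            },
            index=sample_ids,
        )
    else:
        meta = meta.set_axis(sample_ids)
    return VolatileTable(
        peak_areas=pd.DataFrame(areas, index=sample_ids, columns=compound_ids),
        compound_class=pd.Series(classes or ["other"] * m, index=compound_ids),
        sample_meta=meta,
    )


def toy_spectra(matrix: np.ndarray, wavelengths: np.ndarray,
                meta: pd.DataFrame | None = None) -> SpectraSet:
    n = matrix.shape[0]
    sample_ids = [f"s{i + 1}" for i in range(n)]
    if meta is None:
        meta = pd.DataFrame(
            {
                "origin": ["O1"] * n,
                "roast": ["light"] * n,
                "batch": [1] * n,
                "reading": list(range(1, n + 1)),
            },
            index=sample_ids,
        )
    else:
        meta = meta.set_axis(sample_ids)
    return SpectraSet(
        absorbance=pd.DataFrame(matrix, index=sample_ids, columns=wavelengths),
        sample_meta=meta,
    )
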