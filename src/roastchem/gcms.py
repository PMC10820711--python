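"""GC-MS peak-table quality filters and autoscaling.

Two filters clean the aligned peak table before chemometric analysis: an
abundance filter that removes compounds never rising above a noise floor
(default 50,000 area units), and a reproducibility filter that removes
compounds not present in at least 80% of the readings of any single
(origin x roast) replicate group.  Autoscaling (mean centering followed by
unit-variance standardisation, n-1 denominator) puts all compounds on a
comparable scale; its state can be re-applied to new data and inverted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import VolatileTable


def abundance_filter(
    table: VolatileTable, threshold: float = 50_000.0
) -> tuple[VolatileTable, list[str]]:
    """Drop compounds whose maximum observed area is below ``threshold``.

    The maximum (rather than the mean) is compared so that compounds absent
    in some roast degrees but strong in others survive; only peaks that
    never rise above the floor are treated as irregular noise.

    Returns the filtered table and the list of dropped compound ids.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    maxima = table.peak_areas.max(axis=0, skipna=True)
    keep = [c for c in table.compound_ids if maxima[c] >= threshold]
    dropped = [c for c in table.compound_ids if c not in set(keep)]
    if not keep:
        warnings.warn("abundance filter removed every compound", stacklevel=2)
    return table.subset_compounds(keep), dropped


def reproducibility_filter(
    table: VolatileTable,
    min_fraction: float = 0.8,
    group_keys: tuple[str, ...] = ("origin", "roast"),
) -> tuple[VolatileTable, list[str]]:
    """Drop compounds not reproducibly present in any replicate group.

    A compound is *present* in a reading when its area is non-missing and
    strictly positive.  It is retained iff in at least one replicate group
    (by default each origin x roast combination) it is present in at least
    ``min_fraction`` of that group's readings.  The any-group rule keeps
    markers that are genuinely absent at other roast degrees.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    present = table.peak_areas.notna() & (table.peak_areas > 0)
    groups = table.sample_meta.groupby(list(group_keys)).groups
    for key, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"replicate group {key} has no readings")
    keep_mask = pd.Series(False, index=table.peak_areas.columns)
    for key, idx in groups.items():
        frac = present.loc[idx].mean(axis=0)
        keep_mask |= frac >= min_fraction
    keep = [c for c in table.compound_ids if keep_mask[c]]
    dropped = [c for c in table.compound_ids if not keep_mask[c]]
    if not keep:
        warnings.warn("reproducibility filter removed every compound", stacklevel=2)
    return table.subset_compounds(keep), dropped


@dataclass
class ScalingState:
    """Column means and standard deviations captured on a calibration set."""

    mean: np.ndarray
    std: np.ndarray
    columns: list

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.mean) / self.std

    def invert(self, scaled: np.ndarray) -> np.ndarray:
        return np.asarray(scaled, dtype=float) * self.std + self.mean


def autoscale(
    matrix: pd.DataFrame | np.ndarray, columns: list | None = None
) -> tuple[np.ndarray, ScalingState]:
    """Mean-center each column and scale it to unit standard deviation (n-1).

    Raises if any column has zero variance, naming the offending compound.
    """
    if isinstance(matrix, pd.DataFrame):
        columns = list(matrix.columns)
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        if columns is None:
            columns = list(range(values.shape[1]))
    mean = values.mean(axis=0)
    std = values.std(axis=0, ddof=1)
    bad = np.flatnonzero(std <= 0)
    if bad.size:
        names = [columns[i] for i in bad]
        raise ValueError(f"zero-variance columns cannot be autoscaled: {names}")
    state = ScalingState(mean=mean, std=std, columns=columns)
    return state.apply(values), state
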