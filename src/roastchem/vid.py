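"""VID marker selection: correlation of each volatile with the PLS-DA
predicted class membership.

The variable identification (VID) coefficient of compound *c* for roast
class *k* is the Pearson correlation between the compound's abundance
vector and the model's continuous predicted membership column for that
class, computed on the calibration samples.  Coefficients lie in [-1, +1];
compounds with VID above +0.8 for a class are its key discriminatory
markers, and |VID| > 0.9 defines the compounds shown in the scaled-intensity
heatmap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import VolatileTable
from .gcms import autoscale


@dataclass
class VIDResult:
    """Compound x class VID coefficients plus the selection they induce."""

    coefficients: pd.DataFrame  # compound x class, NaN where undefined
    threshold: float
    signed: bool
    selected: dict[str, list[str]]  # class -> compounds, by descending |VID|
    undefined: list[str]  # zero-variance compounds

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: compound, class, vid, selected flag."""
        rows = []
        for cls in self.coefficients.columns:
            chosen = set(self.selected.get(cls, []))
            for comp, value in self.coefficients[cls].items():
                rows.append(
                    {"compound": comp, "class": cls, "vid": value, "selected": comp in chosen}
                )
        return pd.DataFrame(rows)


def _pearson_columns(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation of one vector against each column of Y (n-1)."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(Yc**2, axis=0))
    return (xc @ Yc) / (sx * sy)


def vid_scores(
    volatiles: VolatileTable,
    predicted_membership: pd.DataFrame | np.ndarray,
    classes: list[str] | None = None,
) -> VIDResult:
    """Pearson correlation of every compound with every predicted-membership
    column (VID = corr(x, y-hat)); zero-variance compounds get a flagged
    null coefficient rather than 0."""
    if isinstance(predicted_membership, pd.DataFrame):
        classes = list(predicted_membership.columns)
        if not predicted_membership.index.equals(volatiles.peak_areas.index):
            raise ValueError("membership rows do not match the volatile table samples")
        Y = predicted_membership.to_numpy(dtype=float)
    else:
        Y = np.asarray(predicted_membership, dtype=float)
        if Y.shape[0] != volatiles.n_samples:
            raise ValueError("membership rows do not match the volatile table samples")
        if classes is None:
            classes = [f"class{i}" for i in range(Y.shape[1])]

    X = np.nan_to_num(volatiles.peak_areas.to_numpy(dtype=float), nan=0.0)
    coeffs = np.full((volatiles.n_compounds, len(classes)), np.nan)
    undefined = []
    for j, comp in enumerate(volatiles.compound_ids):
        x = X[:, j]
        if np.ptp(x) == 0:
            undefined.append(comp)
            continue
        coeffs[j] = _pearson_columns(x, Y)

    result = VIDResult(
        coefficients=pd.DataFrame(coeffs, index=volatiles.compound_ids, columns=classes),
        threshold=np.nan,
        signed=True,
        selected={},
        undefined=undefined,
    )
    return result


def select_discriminant(
    vid: VIDResult, threshold: float = 0.8, signed: bool = True
) -> dict[str, list[str]]:
    """Select discriminant compounds per class.

    ``signed=True`` keeps VID > threshold (the 0.8 marker rule);
    ``signed=False`` keeps |VID| > threshold (the 0.9 heatmap rule).
    Lists are sorted by descending |VID|; the selection is also stored on
    the :class:`VIDResult`.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    selected: dict[str, list[str]] = {}
    eps = 1e-12
    for cls in vid.coefficients.columns:
        col = vid.coefficients[cls].dropna()
        value = col if signed else col.abs()
        # at threshold 1.0 keep exact (within rounding) unit correlations
        hits = col[value >= 1.0 - eps] if threshold >= 1.0 else col[value > threshold]
        selected[cls] = list(hits.abs().sort_values(ascending=False).index)
    if not any(selected.values()):
        warnings.warn("no compounds passed the VID threshold", stacklevel=2)
    vid.threshold = threshold
    vid.signed = signed
    vid.selected = selected
    return selected


def heatmap_matrix(
    volatiles: VolatileTable,
    vid: VIDResult,
    roast_order: list[str] | None = None,
) -> pd.DataFrame:
    """Roast-class means of autoscaled abundance for the VID-selected
    compounds, rows ordered by class membership then descending |VID|."""
    if not any(vid.selected.values()):
        raise ValueError("selection is empty; run select_discriminant first")
    roasts = vid.coefficients.columns if roast_order is None else roast_order
    scaled, _ = autoscale(volatiles.peak_areas.fillna(0.0))
    scaled = pd.DataFrame(
        scaled, index=volatiles.peak_areas.index, columns=volatiles.peak_areas.columns
    )
    roast_of = volatiles.sample_meta["roast"]

    rows, index = [], []
    seen = set()
    for cls in vid.coefficients.columns:
        for comp in vid.selected.get(cls, []):
            if comp in seen:
                continue
            seen.add(comp)
            means = [scaled.loc[roast_of == r, comp].mean() for r in roasts]
            rows.append(means)
            index.append(comp)
    return pd.DataFrame(rows, index=index, columns=list(roasts))
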