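"""NIR spectra preprocessing: EMSC, mean centering, replicate averaging.

Extended multiplicative signal correction (EMSC) models each spectrum as a
multiplicative copy of a reference spectrum plus a low-order polynomial
baseline in a rescaled wavelength coordinate,

    x ~= b * r + sum_k c_k * lambda^k,   lambda in [-1, 1],

and returns (x - baseline) / b, removing the scatter artifacts that make
diffuse-reflectance spectra curve and stretch.  The fitted state can be
re-applied to validation spectra so no information leaks from them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SpectraSet
from .simulate import rescale_wavelengths

logger = logging.getLogger(__name__)

B_FLOOR = 1e-8


@dataclass
class EMSCState:
    """Reference spectrum, polynomial order, and per-sample fit coefficients."""

    reference: np.ndarray
    wavelengths: np.ndarray
    poly_order: int
    b: pd.Series  # per-sample multiplicative coefficient
    coefs: pd.DataFrame  # per-sample additive coefficients c0..ck

    def apply(self, spectra: SpectraSet) -> "tuple[SpectraSet, EMSCState]":
        """Correct new spectra against the stored reference."""
        return emsc(spectra, reference=self.reference, poly_order=self.poly_order)


def _design_matrix(wavelengths: np.ndarray, reference: np.ndarray, poly_order: int) -> np.ndarray:
    lam = rescale_wavelengths(wavelengths)
    basis = np.vander(lam, poly_order + 1, increasing=True)
    return np.column_stack([reference, basis])


def emsc(
    spectra: SpectraSet,
    reference: np.ndarray | str = "mean",
    poly_order: int = 2,
) -> tuple[SpectraSet, EMSCState]:
    """Fit and remove multiplicative scatter and polynomial baseline.

    Parameters
    ----------
    spectra
        The spectra to correct.
    reference
        Reference spectrum on the same wavelength grid, or ``"mean"`` to use
        the mean spectrum of this set (the calibration-set default).
    poly_order
        Baseline polynomial order, 0–2.  Order 2 absorbs the curvature
        typical of scatter-affected diffuse-reflectance spectra.
    """
    if poly_order not in (0, 1, 2):
        raise ValueError("poly_order must be 0, 1 or 2")
    X = spectra.absorbance.to_numpy(dtype=float)
    wl = spectra.wavelengths
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError("reference must be an array or 'mean'")
        ref = X.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != wl.shape:
            raise ValueError("reference is not on the spectra's wavelength grid")
    if np.isnan(ref).any():
        raise ValueError("reference spectrum contains missing values")

    D = _design_matrix(wl, ref, poly_order)
    # one least-squares solve for all spectra at once
    coef, *_ = np.linalg.lstsq(D, X.T, rcond=None)
    b = coef[0]
    small = np.flatnonzero(np.abs(b) < B_FLOOR)
    if small.size:
        bad = [spectra.sample_ids[i] for i in small]
        raise ValueError(f"EMSC multiplicative coefficient ~0 for samples {bad}")
    baseline = (D[:, 1:] @ coef[1:]).T
    corrected = (X - baseline) / b[:, None]

    state = EMSCState(
        reference=ref,
        wavelengths=wl.copy(),
        poly_order=poly_order,
        b=pd.Series(b, index=spectra.absorbance.index, name="b"),
        coefs=pd.DataFrame(
            coef[1:].T,
            index=spectra.absorbance.index,
            columns=[f"c{k}" for k in range(poly_order + 1)],
        ),
    )
    return spectra.with_absorbance(corrected), state


def mean_center(
    spectra: SpectraSet, means: np.ndarray | None = None
) -> tuple[SpectraSet, np.ndarray]:
    """Subtract per-wavelength means (or supplied calibration means)."""
    X = spectra.absorbance.to_numpy(dtype=float)
    if means is None:
        means = X.mean(axis=0)
    return spectra.with_absorbance(X - means), means


def average_replicates(
    spectra: SpectraSet,
    level: tuple[str, ...] = ("origin", "roast", "batch"),
) -> SpectraSet:
    """Collapse analytical replicates to their arithmetic mean spectrum.

    ``level`` names the metadata keys defining a group; one spectrum per
    group is returned (singleton groups pass through unchanged), with a
    sample id joining the group keys and ``reading`` collapsed to 0.
    """
    meta = spectra.sample_meta
    for key in level:
        if key not in meta.columns:
            raise KeyError(f"grouping key {key!r} not in sample metadata")
    grouped = meta.groupby(list(level), sort=False)
    rows, new_meta = [], []
    for key, idx in grouped.groups.items():
        key = key if isinstance(key, tuple) else (key,)
        rows.append(spectra.absorbance.loc[idx].mean(axis=0))
        logger.debug("averaging group %s: %d readings", key, len(idx))
        rec = dict(zip(level, key))
        for col in ("origin", "roast", "batch"):
            rec.setdefault(col, meta.loc[idx[0], col])
        rec["reading"] = 0
        rec["sample_id"] = "_".join(str(k) for k in key)
        new_meta.append(rec)
    meta_df = pd.DataFrame(new_meta).set_index("sample_id")
    absorbance = pd.DataFrame(
        np.vstack([r.to_numpy() for r in rows]),
        index=meta_df.index,
        columns=spectra.absorbance.columns,
    )
    return SpectraSet(absorbance=absorbance, sample_meta=meta_df)
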