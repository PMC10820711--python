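"""Per-compound PLS regression: predicting volatile peak areas from NIR
spectra, calibrated on one origin and validated on the other.

Pairing between the two instruments is at batch level: analytical-replicate
NIR spectra are averaged per (origin, roast, batch) and matched to the
batch-mean GC-MS peak area of each target compound — the two instruments
measured different aliquots, so reading-level pairing is undefined.  For
each compound a PLS-R model is fitted on the calibration origin (LV count
chosen by Venetian-blinds cross-validation), then applied to the validation
origin.  Performance is summarised per compound by the coefficient of
determination R2 (1 - SSE/SST, SST centered on the evaluation set's own
mean) and the range-normalised root mean squared error NRMSE(P), both on
the raw peak-area scale; compounds with validation R2 strictly above a
screening threshold (default 0.75) pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SpectraSet, VolatileTable
from .nir import average_replicates, emsc
from .pls import CVResult, PLSModel, fit_pls, predict, venetian_blinds_cv


@dataclass
class PredictionMetrics:
    """Per-compound calibration/validation performance (one row each)."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["n_lv", "r2_cal", "nrmse_cal", "r2_val", "nrmsep_val", "passed"]
        )
    )
    r2_min: float = 0.75

    def add(self, compound: str, entry: dict) -> None:
        self.table.loc[compound] = entry

    def report(self) -> pd.DataFrame:
        """Validation-set report shaped like the published table:
        compound, NRMSEP, R2 Pred."""
        df = self.table.reset_index(names="compound")
        return df[["compound", "nrmsep_val", "r2_val"]].rename(
            columns={"nrmsep_val": "NRMSEP", "r2_val": "R2_pred"}
        )


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    sse = float(np.sum((y_true - y_pred) ** 2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    return 1.0 - sse / sst if sst > 0 else np.nan


def _nrmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    rng = float(np.ptp(y_true))
    if rng == 0:
        return np.nan
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2))) / rng


def fit_volatile_model(
    spectra_cal: SpectraSet,
    y_cal: np.ndarray | pd.Series,
    max_lv: int = 6,
    n_splits: int = 3,
) -> tuple[PLSModel, CVResult]:
    """Fit one compound's PLS-R on (preprocessed) calibration spectra.

    Spectra are mean-centered and the response autoscaled inside the model
    state; the LV count is the parsimonious RMSECV choice.
    """
    y = np.asarray(y_cal, dtype=float)
    X = spectra_cal.absorbance
    if X.shape[0] != y.shape[0]:
        raise ValueError("calibration spectra and abundances are not row-aligned")
    if X.shape[0] < 2 * n_splits:
        raise ValueError(
            f"need at least {2 * n_splits} calibration samples for {n_splits}-fold CV"
        )
    max_lv = min(max_lv, X.shape[0] - max(X.shape[0] // n_splits, 1) - 1, X.shape[1])
    cv = venetian_blinds_cv(
        X, y, max_lv=max_lv, n_splits=n_splits, x_scale="center", y_scale="autoscale"
    )
    model = fit_pls(X, y, cv.n_lv, x_scale="center", y_scale="autoscale")
    return model, cv


def validate(
    model: PLSModel,
    spectra_val: SpectraSet,
    y_val: np.ndarray | pd.Series,
) -> dict:
    """Validation-set metrics on the raw abundance scale."""
    y = np.asarray(y_val, dtype=float)
    pred = predict(model, spectra_val.absorbance).ravel()
    return {
        "r2_val": _r2(y, pred),
        "nrmsep_val": _nrmse(y, pred),
        "predictions": pred,
        "range_undefined": bool(np.ptp(y) == 0),
    }


def screen_compounds(metrics: PredictionMetrics, r2_min: float = 0.75) -> list[str]:
    """Compounds whose validation R2 strictly exceeds ``r2_min``."""
    metrics.r2_min = r2_min
    if metrics.table.empty:
        metrics.table["passed"] = pd.Series(dtype=bool)
        return []
    metrics.table["passed"] = metrics.table["r2_val"] > r2_min
    return list(metrics.table.index[metrics.table["passed"]])


def batch_mean_abundance(volatiles: VolatileTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Batch-mean peak areas: one row per (origin, roast, batch)."""
    keys = ["origin", "roast", "batch"]
    meta = volatiles.sample_meta
    grouped = meta.groupby(keys, sort=False).groups
    rows, recs = [], []
    for key, idx in grouped.items():
        rows.append(volatiles.peak_areas.loc[idx].mean(axis=0))
        rec = dict(zip(keys, key))
        rec["reading"] = 0
        rec["sample_id"] = "_".join(str(k) for k in key)
        recs.append(rec)
    meta_df = pd.DataFrame(recs).set_index("sample_id")
    values = pd.DataFrame(
        np.vstack([r.to_numpy() for r in rows]),
        index=meta_df.index,
        columns=volatiles.peak_areas.columns,
    )
    return values, meta_df


def cross_origin_prediction(
    spectra: SpectraSet,
    volatiles: VolatileTable,
    compounds: list[str],
    calibrate_origin: str,
    validate_origin: str,
    max_lv: int = 6,
    n_splits: int = 3,
    poly_order: int = 2,
    r2_min: float = 0.75,
) -> PredictionMetrics:
    """Full cross-origin study for a list of target compounds.

    Spectra are batch-averaged and EMSC-corrected against the calibration
    set's mean spectrum (the same state is applied to the validation
    origin); abundances are batch means.  One PLS-R model per compound is
    calibrated on ``calibrate_origin`` and validated on ``validate_origin``.
    """
    averaged = average_replicates(spectra, level=("origin", "roast", "batch"))
    cal_ids = [s for s in averaged.sample_ids if averaged.sample_meta.loc[s, "origin"] == calibrate_origin]
    val_ids = [s for s in averaged.sample_ids if averaged.sample_meta.loc[s, "origin"] == validate_origin]
    if not cal_ids or not val_ids:
        raise ValueError("calibration or validation origin has no spectra")
    spectra_cal = averaged.subset_samples(cal_ids)
    spectra_val = averaged.subset_samples(val_ids)

    spectra_cal, emsc_state = emsc(spectra_cal, reference="mean", poly_order=poly_order)
    spectra_val, _ = emsc_state.apply(spectra_val)

    areas, batch_meta = batch_mean_abundance(volatiles)

    def _y(origin_ids, spectra_set):
        key = spectra_set.sample_meta[["origin", "roast", "batch"]]
        batch_key = batch_meta[["origin", "roast", "batch"]]
        lookup = {tuple(v): i for i, v in zip(batch_meta.index, batch_key.values)}
        order = [lookup[tuple(v)] for v in key.values]
        return areas.loc[order]

    y_cal_all = _y(cal_ids, spectra_cal)
    y_val_all = _y(val_ids, spectra_val)

    metrics = PredictionMetrics(r2_min=r2_min)
    for comp in compounds:
        y_cal = y_cal_all[comp].to_numpy()
        y_val = y_val_all[comp].to_numpy()
        model, cv = fit_volatile_model(spectra_cal, y_cal, max_lv=max_lv, n_splits=n_splits)
        cal_pred = predict(model, spectra_cal.absorbance).ravel()
        val = validate(model, spectra_val, y_val)
        metrics.add(
            comp,
            {
                "n_lv": model.n_lv,
                "r2_cal": _r2(y_cal, cal_pred),
                "nrmse_cal": _nrmse(y_cal, cal_pred),
                "r2_val": val["r2_val"],
                "nrmsep_val": val["nrmsep_val"],
                "passed": False,
            },
        )
    screen_compounds(metrics, r2_min)
    return metrics
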