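"""End-to-end orchestration: simulate -> filter -> preprocess -> classify ->
VID -> predict, with serialized intermediates.

Two entry points mirror the staged analysis: :func:`run_classification`
executes the GC-MS branch (quality filters, autoscaling, exploratory PCA,
PLS-DA, VID selection, heatmap matrix) and the NIR branch (replicate
averaging, EMSC, mean centering, PLS-DA, LV1 loadings) separately per
origin; :func:`run_prediction` then fits per-compound PLS-R models for the
VID-selected markers of the calibration origin and validates them on the
other origin.  All stage outputs are written as delimited text under the
configured output directory, and every threshold lives in
:class:`PipelineConfig`, which round-trips through JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import SpectraSet, VolatileTable
from .gcms import abundance_filter, reproducibility_filter
from .nir import average_replicates, emsc, mean_center
from .pls import classification_metrics, pca, plsda_assign, plsda_fit, predict
from .predict_volatiles import cross_origin_prediction
from .simulate import RoastDesign, generate_spectra, generate_volatile_table
from .vid import heatmap_matrix, select_discriminant, vid_scores

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline settings and thresholds, serializable to JSON."""

    out_dir: str = "results"
    seed: int = 0
    # GC-MS filters
    abundance_threshold: float = 50_000.0
    reproducibility_fraction: float = 0.8
    # VID selection
    vid_marker_threshold: float = 0.8  # signed, defines prediction targets
    vid_heatmap_threshold: float = 0.9  # magnitude, defines the heatmap
    # classification CV
    max_lv: int = 10
    n_splits: int = 5
    # NIR preprocessing
    poly_order: int = 2
    average_level: Optional[tuple[str, ...]] = ("origin", "roast", "batch")
    crop_range: Optional[tuple[float, float]] = None
    # cross-origin prediction
    calibrate_origin: str = "Ethiopia"
    validate_origin: str = "Congo"
    pred_max_lv: int = 6
    pred_n_splits: int = 3
    r2_min: float = 0.75

    def __post_init__(self) -> None:
        if self.abundance_threshold < 0:
            raise ValueError("abundance_threshold must be >= 0")
        if not 0 < self.reproducibility_fraction <= 1:
            raise ValueError("reproducibility_fraction must be in (0, 1]")
        for thr in (self.vid_marker_threshold, self.vid_heatmap_threshold):
            if not 0 < thr <= 1:
                raise ValueError("VID thresholds must be in (0, 1]")
        if self.poly_order not in (0, 1, 2):
            raise ValueError("poly_order must be 0, 1 or 2")
        if self.average_level is not None:
            self.average_level = tuple(self.average_level)
        if self.crop_range is not None:
            self.crop_range = tuple(self.crop_range)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _crop(spectra: SpectraSet, crop_range: Optional[tuple[float, float]]) -> SpectraSet:
    if crop_range is None:
        return spectra
    lo, hi = crop_range
    cols = [c for c in spectra.absorbance.columns if lo <= c <= hi]
    return SpectraSet(
        absorbance=spectra.absorbance[cols].copy(), sample_meta=spectra.sample_meta.copy()
    )


def simulate_dataset(
    design: RoastDesign, out_dir: str | Path | None = None
) -> tuple[SpectraSet, VolatileTable]:
    """Generate the synthetic study and optionally write it to disk."""
    volatiles = generate_volatile_table(design)
    spectra = generate_spectra(design, volatiles)
    if out_dir is not None:
        volatiles.write(out_dir)
        spectra.write(out_dir)
    return spectra, volatiles


def _classify_volatiles(table: VolatileTable, origin: str, config: PipelineConfig) -> dict:
    """GC-MS branch for one origin: filters, PCA, PLS-DA, VID, heatmap."""
    sub = table.subset_samples(
        [s for s in table.sample_ids if table.sample_meta.loc[s, "origin"] == origin]
    )
    filtered, dropped_abundance = abundance_filter(sub, config.abundance_threshold)
    filtered, dropped_repro = reproducibility_filter(
        filtered, config.reproducibility_fraction, group_keys=("origin", "roast")
    )
    areas = filtered.peak_areas.fillna(0.0)

    scores, loadings, explained = pca(areas.to_numpy(), n_pc=min(3, min(areas.shape) - 1))
    labels = filtered.sample_meta["roast"].tolist()
    model, cv = plsda_fit(
        areas, labels, max_lv=config.max_lv, n_splits=config.n_splits, x_scale="autoscale"
    )
    membership = pd.DataFrame(
        predict(model, areas), index=areas.index, columns=model.classes
    )
    assigned, ties = plsda_assign(membership.to_numpy(), model.classes)
    metrics = classification_metrics(labels, assigned, membership.to_numpy(), model.classes)

    vid = vid_scores(filtered, membership)
    markers = select_discriminant(vid, config.vid_marker_threshold, signed=True)
    vid_heat = vid_scores(filtered, membership)
    select_discriminant(vid_heat, config.vid_heatmap_threshold, signed=False)
    heatmap = heatmap_matrix(filtered, vid_heat)

    return {
        "origin": origin,
        "table": filtered,
        "dropped_abundance": dropped_abundance,
        "dropped_reproducibility": dropped_repro,
        "pca_scores": pd.DataFrame(scores, index=areas.index),
        "pca_explained": explained,
        "model": model,
        "cv": cv,
        "membership": membership,
        "metrics": metrics,
        "vid": vid,
        "markers": markers,
        "heatmap": heatmap,
        "ties": int(ties.sum()),
    }


def _classify_spectra(spectra: SpectraSet, origin: str, config: PipelineConfig) -> dict:
    """NIR branch for one origin: average, EMSC, mean-center, PLS-DA."""
    sub = spectra.subset_samples(
        [s for s in spectra.sample_ids if spectra.sample_meta.loc[s, "origin"] == origin]
    )
    sub = _crop(sub, config.crop_range)
    if config.average_level is not None:
        sub = average_replicates(sub, level=config.average_level)
    corrected, emsc_state = emsc(sub, reference="mean", poly_order=config.poly_order)
    labels = corrected.sample_meta["roast"].tolist()
    # mean centering is captured inside the model state (per CV fold)
    model, cv = plsda_fit(
        corrected.absorbance, labels,
        max_lv=config.max_lv, n_splits=config.n_splits, x_scale="center",
    )
    membership = pd.DataFrame(
        predict(model, corrected.absorbance),
        index=corrected.absorbance.index,
        columns=model.classes,
    )
    assigned, ties = plsda_assign(membership.to_numpy(), model.classes)
    metrics = classification_metrics(labels, assigned, membership.to_numpy(), model.classes)
    lv1_loadings = pd.Series(
        model.x_loadings[:, 0], index=corrected.absorbance.columns, name="lv1_loading"
    )
    return {
        "origin": origin,
        "spectra": corrected,
        "emsc_state": emsc_state,
        "model": model,
        "cv": cv,
        "membership": membership,
        "metrics": metrics,
        "lv1_loadings": lv1_loadings,
        "ties": int(ties.sum()),
    }


def run_classification(
    config: PipelineConfig,
    spectra: SpectraSet,
    volatiles: VolatileTable,
) -> dict:
    """Stage (i) + (ii): roast-degree classification from volatiles and from
    NIR spectra, separately per origin.  Writes all tables under
    ``config.out_dir`` and returns the in-memory bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")

    origins = list(dict.fromkeys(volatiles.sample_meta["origin"]))
    bundle: dict = {"gcms": {}, "nir": {}, "origins": origins}
    for origin in origins:
        stage = f"GC-MS classification ({origin})"
        try:
            res = _classify_volatiles(volatiles, origin, config)
        except Exception as err:  # noqa: BLE001 - annotate with stage context
            raise RuntimeError(f"stage failed: {stage}: {err}") from err
        bundle["gcms"][origin] = res
        res["metrics"].to_frame().to_csv(out / f"gcms_class_metrics_{origin}.tsv", sep="\t")
        res["vid"].to_frame().to_csv(out / f"vid_{origin}.tsv", sep="\t", index=False)
        res["heatmap"].to_csv(out / f"heatmap_{origin}.tsv", sep="\t", index_label="compound")
        res["pca_scores"].to_csv(out / f"pca_scores_{origin}.tsv", sep="\t", index_label="sample_id")
        (out / f"dropped_{origin}.txt").write_text(
            "# abundance filter\n" + "\n".join(res["dropped_abundance"]) +
            "\n# reproducibility filter\n" + "\n".join(res["dropped_reproducibility"]) + "\n"
        )
        logger.info(
            "%s: %d LVs, CV error %.3f, %d compounds dropped",
            stage, res["cv"].n_lv, res["cv"].criterion[res["cv"].n_lv - 1],
            len(res["dropped_abundance"]) + len(res["dropped_reproducibility"]),
        )

        stage = f"NIR classification ({origin})"
        try:
            res = _classify_spectra(spectra, origin, config)
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"stage failed: {stage}: {err}") from err
        bundle["nir"][origin] = res
        res["metrics"].to_frame().to_csv(out / f"nir_class_metrics_{origin}.tsv", sep="\t")
        res["lv1_loadings"].to_csv(out / f"nir_lv1_loadings_{origin}.tsv", sep="\t",
                                   index_label="wavelength_nm")
    return bundle


def run_prediction(
    config: PipelineConfig,
    spectra: SpectraSet,
    volatiles: VolatileTable,
    classification: Optional[dict] = None,
    compounds: Optional[list[str]] = None,
) -> dict:
    """Stage (iii): per-compound NIR -> volatile PLS-R with cross-origin
    validation, restricted to the calibration origin's VID-selected markers
    (unless an explicit compound list is given)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if compounds is None:
        if classification is None:
            raise ValueError(
                "no VID selection available: run classification first or pass compounds"
            )
        markers = classification["gcms"][config.calibrate_origin]["markers"]
        compounds = sorted(
            {c for comps in markers.values() for c in comps},
            key=lambda c: list(volatiles.compound_ids).index(c),
        )
    metrics = cross_origin_prediction(
        spectra,
        volatiles,
        compounds,
        calibrate_origin=config.calibrate_origin,
        validate_origin=config.validate_origin,
        max_lv=config.pred_max_lv,
        n_splits=config.pred_n_splits,
        poly_order=config.poly_order,
        r2_min=config.r2_min,
    )
    metrics.table.to_csv(out / "prediction_metrics.tsv", sep="\t", index_label="compound")
    metrics.report().to_csv(out / "prediction_report.tsv", sep="\t", index=False)
    passed = list(metrics.table.index[metrics.table["passed"]])
    (out / "prediction_pass_list.txt").write_text("\n".join(passed) + "\n")
    logger.info("prediction: %d/%d compounds passed R2 > %.2f",
                len(passed), len(compounds), config.r2_min)
    return {"metrics": metrics, "passed": passed, "compounds": compounds}
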