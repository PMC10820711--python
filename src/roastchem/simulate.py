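"""Synthetic roast-study generator.

Emulates the data-generating structure the downstream chemometrics assumes:

* a GC-MS peak-area table over ``origins x roasts x batch replicates x
  readings``, where each compound belongs to a chemical class whose
  log-abundance follows a roast trend (furans/ketones/phenols/pyridines rise
  toward dark roasts, aldehydes/alkanes fall, imidazoles peak at medium),
  multiplied by lognormal replicate noise;
* NIR diffuse-reflectance spectra whose Gaussian absorption bands — several
  of them in the 500–1000 nm region — have weights linear in a low-rank
  projection of the batch-mean log volatile abundances, degraded by a
  per-sample multiplicative scatter factor, a polynomial baseline, and iid
  noise.

Everything is deterministic given ``RoastDesign.seed``; the spectral
generator can return its ground truth (scatter factors, baseline
coefficients, mixing matrices, artifact-free spectra) for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import SpectraSet, VolatileTable

VALID_TRENDS = ("increasing", "decreasing", "peak-at-medium", "flat")

#: roast trend and class-level effect size (log-units of peak area between
#: adjacent roast degrees) for the chemical classes the heatmap analysis
#: distinguishes: dark-roast markers rise, light-roast markers fall,
#: imidazoles peak at medium roast.
DEFAULT_CLASS_TRENDS: dict[str, tuple[str, float]] = {
    "furan": ("increasing", 1.0),
    "ketone": ("increasing", 1.0),
    "phenol": ("increasing", 1.0),
    "pyrrole": ("increasing", 1.0),
    "ester": ("increasing", 1.0),
    "pyridine": ("increasing", 1.0),
    "pyranone": ("increasing", 1.0),
    "imidazole": ("peak-at-medium", 1.5),
    "aldehyde": ("decreasing", 1.0),
    "alkane": ("decreasing", 1.0),
    "alkadiene": ("decreasing", 1.0),
}


def _default_wavelengths() -> np.ndarray:
    return np.arange(400.0, 2501.0, 2.0)


@dataclass
class RoastDesign:
    """Full factorial roast-study design and generator settings.

    The defaults mirror the study layout: two origins, three roast degrees,
    three batch replicates each, three GC-MS readings per batch (nine per
    roast level) and nine NIR readings per batch (twenty-seven per roast
    level), with 166 volatile compounds.
    """

    origins: tuple[str, ...] = ("Ethiopia", "Congo")
    roasts: tuple[str, ...] = ("light", "medium", "dark")
    batch_reps: int = 3
    gcms_readings_per_batch: int = 3
    nir_readings_per_batch: int = 9
    n_compounds: int = 166
    class_trend_map: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_TRENDS)
    )
    # compound-role mix: the remainder after these fractions is discriminant
    flat_fraction: float = 0.25
    irregular_fraction: float = 0.06
    sporadic_fraction: float = 0.06
    sporadic_presence: float = 0.6
    abundance_floor: float = 50_000.0
    # abundance model (natural-log peak-area scale)
    base_log_mean: float = float(np.log(3e6))
    base_log_sd: float = 1.0
    noise_cv: float = 0.10
    batch_sd: float = 0.05
    origin_abundance_shift: float = 0.03
    # spectral measurement model
    latent_rank: int = 3
    n_bands: int = 10
    wavelengths: Optional[np.ndarray] = None
    scatter_sd: float = 0.10
    baseline_sd: float = 0.05
    baseline_order: int = 2
    spectral_noise_sd: float = 0.01
    origin_spectral_shift: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for count in (
            self.batch_reps,
            self.gcms_readings_per_batch,
            self.nir_readings_per_batch,
            self.n_compounds,
            self.latent_rank,
            self.n_bands,
        ):
            if count < 1:
                raise ValueError("all design counts must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if len(self.roasts) < 2:
            raise ValueError("need at least two roast degrees")
        for cls, (trend, effect) in self.class_trend_map.items():
            if trend not in VALID_TRENDS:
                raise ValueError(
                    f"class {cls!r} has invalid trend {trend!r}; "
                    f"expected one of {VALID_TRENDS}"
                )
            if effect < 0:
                raise ValueError(f"class {cls!r} has negative effect size")
        if self.wavelengths is None:
            self.wavelengths = _default_wavelengths()
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)

    def trend_profile(self, trend: str, curvature: float = 0.0) -> np.ndarray:
        """Per-roast trend values on a unit scale, in roast order.

        ``curvature`` bows a monotone profile toward the early (< 0) or late
        (> 0) roast stages — some compounds surge only after the second
        crack while others accumulate gradually.  Monotonicity is preserved
        for |curvature| <= 0.5.
        """
        n = len(self.roasts)
        base = np.linspace(-1.0, 1.0, n)
        bump = 1.0 - base**2  # 0 at the extremes, 1 at the middle
        if trend == "increasing":
            return base - curvature * bump
        if trend == "decreasing":
            return -base + curvature * bump
        if trend == "peak-at-medium":
            return bump
        if trend == "flat":
            return np.zeros(n)
        raise ValueError(f"invalid trend label {trend!r}")


def ground_truth(design: RoastDesign) -> pd.DataFrame:
    """Per-compound ground truth: class, trend, effect size and role.

    Roles: ``discriminant`` compounds carry the roast trend and drive the
    spectra (``spectrally_linked``); ``flat`` compounds are pure replicate
    noise; ``irregular`` compounds sit below the abundance floor;
    ``sporadic`` compounds drop out of a fraction of readings.
    Deterministic given the design seed.
    """
    rng = np.random.default_rng([design.seed, 1])
    n = design.n_compounds
    n_irregular = int(round(design.irregular_fraction * n))
    n_sporadic = int(round(design.sporadic_fraction * n))
    n_flat = int(round(design.flat_fraction * n))
    n_special = n_irregular + n_sporadic + n_flat
    if n_special >= n:
        raise ValueError("role fractions leave no discriminant compounds")

    roles = np.array(
        ["discriminant"] * (n - n_special)
        + ["flat"] * n_flat
        + ["irregular"] * n_irregular
        + ["sporadic"] * n_sporadic
    )
    rng.shuffle(roles)

    trend_classes = [
        cls for cls, (trend, _) in design.class_trend_map.items() if trend != "flat"
    ]
    if not trend_classes:
        raise ValueError("class_trend_map defines no non-flat classes")

    ids = [f"c{i + 1:03d}" for i in range(n)]
    records = []
    cycle = 0
    for cid, role in zip(ids, roles):
        if role in ("discriminant", "irregular", "sporadic"):
            cls = trend_classes[cycle % len(trend_classes)]
            cycle += 1
            trend, class_effect = design.class_trend_map[cls]
            effect = class_effect * rng.uniform(0.7, 1.3)
            curvature = rng.uniform(-0.5, 0.5) if trend in ("increasing", "decreasing") else 0.0
        else:
            cls, trend, effect, curvature = "other", "flat", 0.0, 0.0
        if role == "irregular":
            # never rises above the abundance floor
            base = float(np.log(rng.uniform(1e3, 8e3)))
            effect *= 0.5
        else:
            base = float(rng.normal(design.base_log_mean, design.base_log_sd))
        records.append(
            {
                "compound_id": cid,
                "compound_class": cls,
                "trend": trend,
                "effect": effect,
                "curvature": curvature,
                "role": role,
                "base_log": base,
                "spectrally_linked": role == "discriminant",
            }
        )
    return pd.DataFrame.from_records(records).set_index("compound_id")


def _gcms_sample_frame(design: RoastDesign) -> pd.DataFrame:
    rows = []
    for origin in design.origins:
        for roast in design.roasts:
            for batch in range(1, design.batch_reps + 1):
                for reading in range(1, design.gcms_readings_per_batch + 1):
                    rows.append(
                        {
                            "sample_id": f"{origin}_{roast}_b{batch}_g{reading}",
                            "origin": origin,
                            "roast": roast,
                            "batch": batch,
                            "reading": reading,
                        }
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def _nir_sample_frame(design: RoastDesign) -> pd.DataFrame:
    rows = []
    for origin in design.origins:
        for roast in design.roasts:
            for batch in range(1, design.batch_reps + 1):
                for reading in range(1, design.nir_readings_per_batch + 1):
                    rows.append(
                        {
                            "sample_id": f"{origin}_{roast}_b{batch}_n{reading}",
                            "origin": origin,
                            "roast": roast,
                            "batch": batch,
                            "reading": reading,
                        }
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_volatile_table(design: RoastDesign) -> VolatileTable:
    """Simulate the GC-MS peak-area table for the full design.

    Log peak area of compound *c* in reading *s* is

        base_c + effect_c * trend_c(roast_s) + origin shift + batch effect
        + lognormal replicate noise with coefficient of variation ``noise_cv``.

    Irregular compounds stay below ``abundance_floor``; sporadic compounds
    are set to zero in a random subset of readings (presence probability
    ``sporadic_presence``).
    """
    truth = ground_truth(design)
    rng = np.random.default_rng([design.seed, 2])
    meta = _gcms_sample_frame(design)
    n_samples, n_compounds = len(meta), design.n_compounds

    roast_index = {roast: i for i, roast in enumerate(design.roasts)}
    trend_vals = np.stack(
        [
            design.trend_profile(t, curvature=g)
            for t, g in zip(truth["trend"], truth["curvature"])
        ],
        axis=1,
    )  # n_roasts x n_compounds

    # origin shifts: first origin is the reference
    origin_shift = {design.origins[0]: np.zeros(n_compounds)}
    for origin in design.origins[1:]:
        origin_shift[origin] = rng.normal(0.0, design.origin_abundance_shift, n_compounds)

    # batch effects per (origin, roast, batch), shared by all readings
    batch_effects: dict[tuple[str, str, int], np.ndarray] = {}
    for origin in design.origins:
        for roast in design.roasts:
            for batch in range(1, design.batch_reps + 1):
                batch_effects[(origin, roast, batch)] = rng.normal(
                    0.0, design.batch_sd, n_compounds
                )

    base = truth["base_log"].to_numpy()
    effect = truth["effect"].to_numpy()
    log_mu = np.empty((n_samples, n_compounds))
    for i, (sid, row) in enumerate(meta.iterrows()):
        ridx = roast_index[row["roast"]]
        log_mu[i] = (
            base
            + effect * trend_vals[ridx]
            + origin_shift[row["origin"]]
            + batch_effects[(row["origin"], row["roast"], row["batch"])]
        )

    if design.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(design.noise_cv**2)))
        noise = rng.normal(0.0, sigma, size=log_mu.shape)
    else:
        noise = np.zeros_like(log_mu)
    areas = np.exp(log_mu + noise)

    # sporadic compounds: present in a fixed fraction of each replicate
    # group's readings (random positions), i.e. never reproducibly detected
    sporadic = truth.index[truth["role"] == "sporadic"]
    groups = meta.groupby(["origin", "roast"], sort=False).groups
    for cid in sporadic:
        j = truth.index.get_loc(cid)
        for _, idx in groups.items():
            rows = np.array([meta.index.get_loc(s) for s in idx])
            n_present = int(round(design.sporadic_presence * len(rows)))
            absent = rng.permutation(rows)[n_present:]
            areas[absent, j] = 0.0

    table = VolatileTable(
        peak_areas=pd.DataFrame(areas, index=meta.index, columns=truth.index),
        compound_class=truth["compound_class"].copy(),
        sample_meta=meta,
    )
    return table


@dataclass
class SpectraTruth:
    """Generator ground truth for one spectra realisation."""

    clean: pd.DataFrame  # artifact-free spectra (sample x wavelength)
    scatter_b: pd.Series  # per-sample multiplicative factor
    baseline_coefs: pd.DataFrame  # per-sample polynomial coefficients c0..ck
    band_matrix: np.ndarray  # wavelength x band Gaussian profiles
    band_weights: pd.DataFrame  # per-sample band weights
    mixing: np.ndarray  # latent -> band-weight mixing (n_bands x rank)
    projection: np.ndarray  # linked-compound -> latent projection (rank x n_linked)
    linked_compounds: list[str]

    def reconstruct(self, wavelengths: np.ndarray) -> pd.DataFrame:
        """Rebuild raw (noise-free) spectra from the stored parameters."""
        lam = rescale_wavelengths(wavelengths)
        basis = np.vander(lam, self.baseline_coefs.shape[1], increasing=True)
        raw = (
            self.scatter_b.to_numpy()[:, None] * self.clean.to_numpy()
            + self.baseline_coefs.to_numpy() @ basis.T
        )
        return pd.DataFrame(raw, index=self.clean.index, columns=self.clean.columns)


def rescale_wavelengths(wavelengths: np.ndarray) -> np.ndarray:
    """Map a wavelength grid onto [-1, 1] (shared polynomial coordinate)."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    lo, hi = wavelengths[0], wavelengths[-1]
    if hi == lo:
        return np.zeros_like(wavelengths)
    return 2.0 * (wavelengths - lo) / (hi - lo) - 1.0


def _band_profiles(
    design: RoastDesign, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed Gaussian band shapes; half the bands sit in 500–1000 nm.

    Returns the profiles and the band centers (the roast signal is
    concentrated in the low-wavelength bands, where the visible and
    third-overtone features that track roast degree live).
    """
    n_low = int(np.ceil(design.n_bands / 2))
    n_high = design.n_bands - n_low
    centers = np.concatenate(
        [
            np.linspace(520.0, 980.0, n_low),
            np.linspace(1150.0, 2400.0, max(n_high, 1))[:n_high],
        ]
    )
    widths = rng.uniform(40.0, 90.0, design.n_bands)
    wl = design.wavelengths[:, None]
    return np.exp(-0.5 * ((wl - centers[None, :]) / widths[None, :]) ** 2), centers


def generate_spectra(
    design: RoastDesign,
    volatiles: VolatileTable,
    return_truth: bool = False,
) -> SpectraSet | tuple[SpectraSet, SpectraTruth]:
    """Simulate NIR spectra for the design, linked to the volatile table.

    For each NIR reading of batch *g*, band weights are
    ``w0 + A @ (L @ d_g) + origin shift`` where ``d_g`` is the batch-mean
    log-abundance deviation of the spectrally linked compounds and ``L`` a
    fixed rank-``latent_rank`` projection; the raw spectrum is
    ``b * (bands @ w) + polynomial baseline + noise``.
    """
    truth_table = ground_truth(design)
    expected = _gcms_sample_frame(design)
    got = volatiles.sample_meta
    expected_groups = set(map(tuple, expected[["origin", "roast", "batch"]].values))
    got_groups = set(map(tuple, got[["origin", "roast", "batch"]].values))
    if expected_groups != got_groups:
        raise ValueError(
            "volatile table sample groups do not match the design "
            f"(missing {sorted(expected_groups - got_groups)}, "
            f"extra {sorted(got_groups - expected_groups)})"
        )

    rng = np.random.default_rng([design.seed, 3])
    meta = _nir_sample_frame(design)
    wl = design.wavelengths
    bands, band_centers = _band_profiles(design, rng)

    linked = list(truth_table.index[truth_table["spectrally_linked"]])
    base_linked = truth_table.loc[linked, "base_log"].to_numpy()

    # batch-mean log-abundance deviations of linked compounds
    areas = volatiles.peak_areas[linked].to_numpy(dtype=float)
    log_areas = np.log(np.clip(areas, 1e-12, None))
    dev_by_batch: dict[tuple[str, str, int], np.ndarray] = {}
    group_cols = volatiles.sample_meta[["origin", "roast", "batch"]]
    for key, idx in group_cols.groupby(list(group_cols.columns)).groups.items():
        rows = [volatiles.peak_areas.index.get_loc(s) for s in idx]
        dev_by_batch[tuple(key)] = log_areas[rows].mean(axis=0) - base_linked

    projection = rng.normal(0.0, 1.0 / np.sqrt(len(linked)), (design.latent_rank, len(linked)))
    mixing = rng.normal(0.0, 0.6, (design.n_bands, design.latent_rank))
    # roast-tracking variance concentrates in the 500-1000 nm bands
    mixing *= np.where(band_centers < 1000.0, 1.5, 0.5)[:, None]
    base_weights = rng.uniform(3.0, 7.0, design.n_bands)
    origin_band_shift = {design.origins[0]: np.zeros(design.n_bands)}
    for origin in design.origins[1:]:
        origin_band_shift[origin] = rng.normal(
            0.0, design.origin_spectral_shift, design.n_bands
        )

    n_samples = len(meta)
    lam = rescale_wavelengths(wl)
    basis = np.vander(lam, design.baseline_order + 1, increasing=True)

    weights = np.empty((n_samples, design.n_bands))
    for i, (sid, row) in enumerate(meta.iterrows()):
        z = projection @ dev_by_batch[(row["origin"], row["roast"], row["batch"])]
        weights[i] = base_weights + mixing @ z + origin_band_shift[row["origin"]]

    clean = weights @ bands.T
    b = np.exp(rng.normal(0.0, design.scatter_sd, n_samples))
    coefs = rng.normal(0.0, design.baseline_sd, (n_samples, design.baseline_order + 1))
    noise = rng.normal(0.0, design.spectral_noise_sd, clean.shape)
    raw = b[:, None] * clean + coefs @ basis.T + noise

    spectra = SpectraSet(
        absorbance=pd.DataFrame(raw, index=meta.index, columns=wl),
        sample_meta=meta,
    )
    if not return_truth:
        return spectra
    truth = SpectraTruth(
        clean=pd.DataFrame(clean, index=meta.index, columns=wl),
        scatter_b=pd.Series(b, index=meta.index, name="b"),
        baseline_coefs=pd.DataFrame(
            coefs, index=meta.index, columns=[f"c{k}" for k in range(design.baseline_order + 1)]
        ),
        band_matrix=bands,
        band_weights=pd.DataFrame(weights, index=meta.index),
        mixing=mixing,
        projection=projection,
        linked_compounds=linked,
    )
    return spectra, truth


#: chemical classes used for the small worked fixture (eight discriminant
#: compounds spanning rising, falling, and peak-at-medium trends)
_FIXTURE_CLASSES: dict[str, tuple[str, float]] = {
    "furan": ("increasing", 1.0),
    "ketone": ("increasing", 1.0),
    "phenol": ("increasing", 1.0),
    "pyridine": ("increasing", 1.0),
    "ester": ("increasing", 1.0),
    "aldehyde": ("decreasing", 1.0),
    "alkane": ("decreasing", 1.0),
    "imidazole": ("peak-at-medium", 1.5),
}

FIXTURE_SEED = 20260

def fixture_design(seed: int = FIXTURE_SEED) -> RoastDesign:
    """Small fixed design: 2 origins x 3 roasts x 3 batches, 12 compounds,
    200 wavelengths."""
    return RoastDesign(
        n_compounds=12,
        class_trend_map=dict(_FIXTURE_CLASSES),
        flat_fraction=2 / 12,
        irregular_fraction=1 / 12,
        sporadic_fraction=1 / 12,
        wavelengths=np.linspace(400.0, 2500.0, 200),
        seed=seed,
    )


def worked_fixture(seed: int = FIXTURE_SEED) -> tuple[SpectraSet, VolatileTable]:
    """The shipped small dataset used throughout tests and docs."""
    design = fixture_design(seed)
    volatiles = generate_volatile_table(design)
    spectra = generate_spectra(design, volatiles)
    return spectra, volatiles
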