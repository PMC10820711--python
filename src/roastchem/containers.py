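"""Data containers: the GC-MS peak-area table and the NIR spectra block.

Both containers pair a numeric matrix (a pandas DataFrame indexed by sample
id) with per-sample metadata (origin, roast, batch replicate, reading).  They
are plain dataclasses — all modelling lives in the other modules — but each
knows how to validate its own invariants and round-trip through delimited
text, which is the interchange format of the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: metadata columns every sample row must carry
META_COLUMNS = ("origin", "roast", "batch", "reading")


def _check_meta(sample_meta: pd.DataFrame, sample_ids: pd.Index) -> None:
    missing = [c for c in META_COLUMNS if c not in sample_meta.columns]
    if missing:
        raise ValueError(f"sample_meta lacks columns: {missing}")
    if not sample_meta.index.equals(sample_ids):
        raise ValueError("sample_meta index does not match the sample ids")


@dataclass
class VolatileTable:
    """Aligned GC-MS peak-area table: samples x compounds.

    Parameters
    ----------
    peak_areas
        Nonnegative peak areas (arbitrary units), NaN for missing peaks.
        Rows are samples, columns compounds.
    compound_class
        Chemical class label per compound (index aligned to the columns).
    sample_meta
        One row per sample with columns ``origin``, ``roast``, ``batch``,
        ``reading``.
    """

    peak_areas: pd.DataFrame
    compound_class: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.peak_areas.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.peak_areas.columns)

    @property
    def n_samples(self) -> int:
        return self.peak_areas.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.peak_areas.shape[1]

    def validate(self) -> None:
        if self.peak_areas.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.peak_areas.columns.has_duplicates:
            raise ValueError("duplicate compound ids")
        values = self.peak_areas.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValueError("peak areas must be >= 0 or missing")
        if not self.compound_class.index.equals(self.peak_areas.columns):
            raise ValueError("compound_class index does not match compound ids")
        _check_meta(self.sample_meta, self.peak_areas.index)

    def subset_compounds(self, keep: list[str]) -> "VolatileTable":
        """New table restricted to ``keep`` (original column order preserved)."""
        keep_set = set(keep)
        cols = [c for c in self.peak_areas.columns if c in keep_set]
        return VolatileTable(
            peak_areas=self.peak_areas[cols].copy(),
            compound_class=self.compound_class.loc[cols].copy(),
            sample_meta=self.sample_meta.copy(),
        )

    def subset_samples(self, keep: list[str]) -> "VolatileTable":
        return VolatileTable(
            peak_areas=self.peak_areas.loc[keep].copy(),
            compound_class=self.compound_class.copy(),
            sample_meta=self.sample_meta.loc[keep].copy(),
        )

    def write(self, directory: str | Path, stem: str = "volatiles") -> None:
        """Write the table as delimited text: matrix + two metadata sidecars."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.peak_areas.to_csv(directory / f"{stem}.tsv", sep="\t", index_label="sample_id")
        self.sample_meta.to_csv(directory / f"{stem}_samples.tsv", sep="\t", index_label="sample_id")
        self.compound_class.rename("compound_class").to_csv(
            directory / f"{stem}_compounds.tsv", sep="\t", index_label="compound_id"
        )

    @classmethod
    def read(cls, directory: str | Path, stem: str = "volatiles") -> "VolatileTable":
        directory = Path(directory)
        areas = pd.read_csv(directory / f"{stem}.tsv", sep="\t", index_col="sample_id")
        meta = pd.read_csv(directory / f"{stem}_samples.tsv", sep="\t", index_col="sample_id")
        classes = pd.read_csv(directory / f"{stem}_compounds.tsv", sep="\t", index_col="compound_id")[
            "compound_class"
        ]
        return cls(peak_areas=areas, compound_class=classes, sample_meta=meta)


@dataclass
class SpectraSet:
    """NIR diffuse-reflectance spectra: samples x wavelengths.

    ``absorbance`` columns are the wavelength grid in nm (strictly
    increasing); ``sample_meta`` mirrors :class:`VolatileTable`.
    """

    absorbance: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        # coerce column labels to float nm once at construction
        self.absorbance.columns = self.absorbance.columns.astype(float)
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.absorbance.index)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.absorbance.columns.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def validate(self) -> None:
        if self.absorbance.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        wl = self.wavelengths
        if wl.size and np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.absorbance.isna().any().any():
            raise ValueError("spectra must not contain missing values")
        _check_meta(self.sample_meta, self.absorbance.index)

    def subset_samples(self, keep: list[str]) -> "SpectraSet":
        return SpectraSet(
            absorbance=self.absorbance.loc[keep].copy(),
            sample_meta=self.sample_meta.loc[keep].copy(),
        )

    def with_absorbance(self, matrix: np.ndarray) -> "SpectraSet":
        """Same samples/grid/metadata, new absorbance values."""
        return SpectraSet(
            absorbance=pd.DataFrame(matrix, index=self.absorbance.index, columns=self.absorbance.columns),
            sample_meta=self.sample_meta.copy(),
        )

    def write(self, directory: str | Path, stem: str = "spectra") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.absorbance.to_csv(directory / f"{stem}.tsv", sep="\t", index_label="sample_id")
        self.sample_meta.to_csv(directory / f"{stem}_samples.tsv", sep="\t", index_label="sample_id")

    @classmethod
    def read(cls, directory: str | Path, stem: str = "spectra") -> "SpectraSet":
        directory = Path(directory)
        absorbance = pd.read_csv(directory / f"{stem}.tsv", sep="\t", index_col="sample_id")
        meta = pd.read_csv(directory / f"{stem}_samples.tsv", sep="\t", index_col="sample_id")
        return cls(absorbance=absorbance, sample_meta=meta)
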