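"""Shared data containers: concentration matrices, spectra and clinical tables.

The central in-memory object is :class:`MetaboliteMatrix`, a samples x
variables concentration table carried as a pandas DataFrame together with
per-sample metadata (patient, timepoint) and per-variable metadata
(platform, chemical class, limit of detection).  Cells can be in one of
three states:

* observed  -- a finite positive number,
* missing   -- NaN in ``values`` with ``censored`` False,
* below LOD -- NaN in ``values`` with ``censored`` True.

Below-LOD cells are an explicit censored state rather than a number so the
QC stage owns the LOD/2 imputation rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: sentinel used for censored cells in CSV round-trips
CENSORED_TOKEN = "<LOD"

SAMPLE_META_COLUMNS = ["patient_id", "timepoint_months"]
VAR_META_COLUMNS = ["platform", "var_class", "lod"]

CLINICAL_COLUMNS = [
    "patient_id",
    "age",
    "menopausal_status",
    "chemo",
    "endocrine",
    "radiation",
    "herceptin",
    "surgery",
    "weight_kg_0",
    "weight_kg_6",
    "weight_kg_12",
    "hba1c",
    "tc",
    "hdl",
    "tg",
]


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical table against its invariants and return it.

    Requires unique patient ids, positive weights where present and
    HDL strictly below total cholesterol.
    """
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(f"clinical table lacks columns: {missing}")
    if table["patient_id"].duplicated().any():
        raise ConfigurationError("clinical table has duplicate patient ids")
    for col in ("weight_kg_0", "weight_kg_6", "weight_kg_12"):
        w = table[col].dropna()
        if (w <= 0).any():
            raise ConfigurationError(f"non-positive weight in column {col}")
    if (table["hdl"] >= table["tc"]).any():
        raise ConfigurationError("HDL must be below total cholesterol")
    return table


@dataclass
class MetaboliteMatrix:
    """Samples x variables concentration table with metadata.

    Parameters
    ----------
    values
        DataFrame of non-negative concentrations; NaN marks missing or
        censored cells.  Index is a plain sample index aligned with
        ``sample_meta``.
    sample_meta
        DataFrame with columns ``patient_id`` and ``timepoint_months``;
        (patient, timepoint) pairs must be unique.
    var_meta
        DataFrame indexed by variable name with columns ``platform``
        (``MRS``/``MS``/``LIPO``), ``var_class`` and ``lod``.
    censored
        Boolean DataFrame aligned with ``values``; True marks below-LOD
        cells.  Defaults to all-False.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    var_meta: pd.DataFrame
    censored: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.censored is None:
            self.censored = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if list(self.sample_meta.index) != list(self.values.index):
            self.sample_meta = self.sample_meta.set_axis(self.values.index)
        if self.values.columns.duplicated().any():
            raise ConfigurationError("duplicate variable names")
        pairs = self.sample_meta[SAMPLE_META_COLUMNS]
        if pairs.duplicated().any():
            raise ConfigurationError("duplicate (patient, timepoint) samples")
        if list(self.var_meta.index) != list(self.values.columns):
            raise ConfigurationError("var_meta index must match value columns")
        lod = self.var_meta["lod"].dropna()
        if (lod < 0).any():
            raise ConfigurationError("negative LOD")
        if self.censored.shape != self.values.shape:
            raise ConfigurationError("censored mask shape mismatch")
        # censored cells must not carry numbers
        bad = self.censored.to_numpy() & np.isfinite(self.values.to_numpy())
        if bad.any():
            raise ConfigurationError("censored cells must hold NaN values")

    # ------------------------------------------------------------------ views
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def select(self, columns: list[str]) -> "MetaboliteMatrix":
        """Column subset, keeping all samples."""
        return MetaboliteMatrix(
            self.values[columns].copy(),
            self.sample_meta.copy(),
            self.var_meta.loc[columns].copy(),
            self.censored[columns].copy(),
        )

    def platform(self, platform: str) -> "MetaboliteMatrix":
        cols = [v for v in self.variables if self.var_meta.loc[v, "platform"] == platform]
        return self.select(cols)

    def at_timepoints(self, timepoints: list[int]) -> "MetaboliteMatrix":
        keep = self.sample_meta["timepoint_months"].isin(timepoints)
        return MetaboliteMatrix(
            self.values.loc[keep].copy(),
            self.sample_meta.loc[keep].copy(),
            self.var_meta.copy(),
            self.censored.loc[keep].copy(),
        )

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            self.values.copy(), self.sample_meta.copy(), self.var_meta.copy(), self.censored.copy()
        )

    # ------------------------------------------------------------------- I/O
    def to_csv(self, prefix: str) -> list[str]:
        """Write ``<prefix>_values.csv`` and ``<prefix>_variables.csv``.

        Censored cells are serialized as ``<LOD`` and missing cells as
        empty fields.
        """
        out = self.values.astype(object).copy()
        out = out.where(~self.censored, CENSORED_TOKEN)
        table = pd.concat([self.sample_meta[SAMPLE_META_COLUMNS].reset_index(drop=True),
                           out.reset_index(drop=True)], axis=1)
        values_path = f"{prefix}_values.csv"
        vars_path = f"{prefix}_variables.csv"
        table.to_csv(values_path, index=False)
        self.var_meta.rename_axis("name").to_csv(vars_path)
        return [values_path, vars_path]

    @classmethod
    def from_csv(cls, prefix: str) -> "MetaboliteMatrix":
        table = pd.read_csv(f"{prefix}_values.csv", dtype={"patient_id": str})
        var_meta = pd.read_csv(f"{prefix}_variables.csv", index_col="name")
        sample_meta = table[SAMPLE_META_COLUMNS].copy()
        raw = table.drop(columns=SAMPLE_META_COLUMNS)
        censored = raw.apply(lambda c: c.astype(str).str.strip() == CENSORED_TOKEN)
        values = raw.mask(censored).apply(pd.to_numeric, errors="coerce")
        return cls(values, sample_meta, var_meta, censored)


@dataclass
class Spectrum:
    """A single frequency-domain 1-D spectrum on a descending ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    applied_shift: float = 0.0
    water_mask: np.ndarray | None = None  # True = excluded point
    normalization_factor: float | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ConfigurationError("ppm and intensity must be 1-D and aligned")
        if not np.all(np.diff(self.ppm) < 0):
            raise ConfigurationError("ppm axis must be strictly decreasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ConfigurationError("intensities must be finite")
        if self.water_mask is None:
            self.water_mask = np.zeros(self.ppm.shape, dtype=bool)

    def replace(self, **kwargs) -> "Spectrum":
        data = {
            "ppm": self.ppm,
            "intensity": self.intensity,
            "applied_shift": self.applied_shift,
            "water_mask": self.water_mask,
            "normalization_factor": self.normalization_factor,
        }
        data.update(kwargs)
        return Spectrum(**data)


@dataclass
class SpectrumSet:
    """A cohort of spectra sharing one ppm axis, with simulation ground truth.

    ``truth`` maps sample position -> ``{"areas": {metabolite: area},
    "shift": ppm_offset}`` for synthetic data; empty for real data.
    """

    ppm: np.ndarray
    intensities: np.ndarray  # (n_samples, n_points)
    sample_meta: pd.DataFrame
    truth: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != self.ppm.size:
            raise ConfigurationError("intensity matrix does not match ppm axis")
        if not np.all(np.diff(self.ppm) < 0):
            raise ConfigurationError("ppm axis must be strictly decreasing")

    def __len__(self) -> int:
        return self.intensities.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.ppm.copy(), self.intensities[i].copy())

    def to_csv(self, prefix: str) -> list[str]:
        ppm_path = f"{prefix}_ppm.csv"
        int_path = f"{prefix}_intensities.csv"
        pd.DataFrame({"ppm": self.ppm}).to_csv(ppm_path, index=False)
        table = pd.concat(
            [
                self.sample_meta[SAMPLE_META_COLUMNS].reset_index(drop=True),
                pd.DataFrame(self.intensities),
            ],
            axis=1,
        )
        table.to_csv(int_path, index=False)
        return [ppm_path, int_path]

    @classmethod
    def from_csv(cls, prefix: str) -> "SpectrumSet":
        ppm = pd.read_csv(f"{prefix}_ppm.csv")["ppm"].to_numpy()
        table = pd.read_csv(f"{prefix}_intensities.csv", dtype={"patient_id": str})
        meta = table[SAMPLE_META_COLUMNS].copy()
        intensities = table.drop(columns=SAMPLE_META_COLUMNS).to_numpy(dtype=float)
        return cls(ppm, intensities, meta)
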