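"""Frequency-domain 1-D serum spectrum preprocessing and region integration.

The preprocessing chain mirrors standard serum NMR practice:

1. :func:`reference_to_alanine` -- shift the ppm axis so the left (higher
   ppm) peak of the alanine doublet sits at 1.47 ppm,
2. :func:`correct_baseline` -- subtract the spectrum minimum,
3. :func:`excise_water` -- flag the residual water region 4.33-5.13 ppm,
4. :func:`normalize_total_area` -- scale the retained 0.29-8.53 ppm area
   to one,
5. :func:`integrate_regions` -- trapezoidal integration of 30 metabolite
   windows, yielding semi-quantified concentrations.

Boundary convention: all windows are closed intervals; a point exactly on
a bound belongs to the window.  Integration is plain trapezoidal on the
normalized intensities -- no lineshape fitting.

The 30-region table ships as editable configuration
(:func:`default_region_table`).  Only the two lipid windows
(lipid1 0.8-0.9 ppm, lipid2 1.55-1.60 ppm) are fixed by convention; the
remaining windows use textbook chemical shifts and may be replaced by a
user CSV for real instruments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MetaboliteMatrix, Spectrum, SpectrumSet
from .errors import (
    ConfigurationError,
    IntegrationError,
    NormalizationError,
    ReferencingError,
)

ALANINE_PPM = 1.47
WATER_WINDOW = (4.33, 5.13)
NORMALIZATION_WINDOW = (0.29, 8.53)
ALANINE_SEARCH_WINDOW = (1.40, 1.55)
#: doublet peak separation accepted by the reference detector (ppm)
DOUBLET_SEPARATION = (0.005, 0.03)

# name, windows [(lo, hi), ...], combine mode ("single" uses the first window)
_DEFAULT_REGIONS: list[tuple[str, list[tuple[float, float]], str]] = [
    ("lipid1", [(0.80, 0.90)], "single"),
    ("leucine", [(0.935, 0.985)], "single"),
    ("isoleucine", [(0.99, 1.03)], "single"),
    ("valine", [(1.045, 1.085)], "single"),
    ("2-methylglutarate", [(1.105, 1.145)], "single"),
    ("3-hydroxybutyrate", [(1.18, 1.22)], "single"),
    ("lactate", [(1.305, 1.36), (4.095, 4.135)], "single"),
    ("alanine", [(1.44, 1.49)], "single"),
    ("lipid2", [(1.55, 1.60)], "single"),
    ("lysine", [(1.70, 1.74)], "single"),
    ("ornithine", [(1.78, 1.82)], "single"),
    ("acetate", [(1.90, 1.94)], "single"),
    ("glutamine+glutamate", [(2.06, 2.10)], "single"),
    ("methionine", [(2.12, 2.16)], "single"),
    ("acetoacetate", [(2.25, 2.29)], "single"),
    ("glutamate", [(2.32, 2.36)], "single"),
    ("pyruvate", [(2.39, 2.43)], "single"),
    ("glutamine", [(2.45, 2.49)], "single"),
    ("citrate", [(2.53, 2.67)], "single"),
    ("unknown", [(2.80, 2.84)], "single"),
    ("creatine", [(3.01, 3.05), (3.91, 3.95)], "mean"),
    ("proline betaine", [(3.09, 3.13)], "single"),
    ("dimethyl sulfone", [(3.15, 3.19)], "single"),
    ("glucose", [(3.38, 3.50)], "single"),
    ("glycine", [(3.54, 3.58)], "single"),
    ("creatinine", [(4.04, 4.08)], "single"),
    ("tyrosine", [(6.88, 6.92)], "single"),
    ("histidine", [(7.05, 7.09)], "single"),
    ("phenylalanine", [(7.33, 7.41)], "single"),
    ("formate", [(8.43, 8.47)], "single"),
]


def default_region_table() -> pd.DataFrame:
    """The default 30-metabolite integration table.

    Columns: ``name``, ``ppm_lo``, ``ppm_hi``, ``window_index``,
    ``combine_mode``.  Metabolites with several resonances occupy several
    rows sharing a name.
    """
    rows = []
    for name, windows, mode in _DEFAULT_REGIONS:
        for k, (lo, hi) in enumerate(windows):
            rows.append(
                {"name": name, "ppm_lo": lo, "ppm_hi": hi, "window_index": k, "combine_mode": mode}
            )
    return validate_region_table(pd.DataFrame(rows))


def validate_region_table(table: pd.DataFrame, require_lipids: bool = True) -> pd.DataFrame:
    lo_ok = (table["ppm_lo"] < table["ppm_hi"]).all()
    inside = (table["ppm_lo"] >= NORMALIZATION_WINDOW[0]).all() and (
        table["ppm_hi"] <= NORMALIZATION_WINDOW[1]
    ).all()
    if not lo_ok:
        raise ConfigurationError("region table: ppm_lo must be < ppm_hi")
    if not inside:
        raise ConfigurationError("region table: windows must lie within 0.29-8.53 ppm")
    if not table["combine_mode"].isin(["mean", "single"]).all():
        raise ConfigurationError("region table: combine_mode must be 'mean' or 'single'")
    if require_lipids:
        for required in ("lipid1", "lipid2"):
            if required not in set(table["name"]):
                raise ConfigurationError(f"region table must include {required}")
    return table


def read_region_table(path: str) -> pd.DataFrame:
    return validate_region_table(pd.read_csv(path))


def write_region_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def reference_to_alanine(
    spectrum: Spectrum, search_window: tuple[float, float] = ALANINE_SEARCH_WINDOW
) -> Spectrum:
    """Shift the ppm axis so the alanine doublet's left peak sits at 1.47 ppm.

    A doublet is two local maxima above ``median + 5 * MAD`` of the window
    intensities, separated by 0.005-0.03 ppm; "left" is the higher-ppm
    peak (conventional display order).  Raises
    :class:`~pmet.errors.ReferencingError` when no such pattern exists.
    """
    lo, hi = min(search_window), max(search_window)
    if spectrum.ppm.min() > lo or spectrum.ppm.max() < hi:
        raise ReferencingError("spectrum does not cover the alanine search window")
    sel = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    ppm_w = spectrum.ppm[sel]
    y = spectrum.intensity[sel]
    if y.size < 5:
        raise ReferencingError("search window too sparse")
    threshold = np.median(y) + 5.0 * _mad(y)
    interior = np.arange(1, y.size - 1)
    is_max = (y[interior] > y[interior - 1]) & (y[interior] > y[interior + 1])
    peaks = interior[is_max & (y[interior] > threshold)]
    if peaks.size < 2:
        raise ReferencingError("no doublet above noise in the search window")
    # best pair by combined height among pairs with plausible separation
    best = None
    for i in range(peaks.size):
        for j in range(i + 1, peaks.size):
            sep = abs(ppm_w[peaks[i]] - ppm_w[peaks[j]])
            if DOUBLET_SEPARATION[0] <= sep <= DOUBLET_SEPARATION[1]:
                height = y[peaks[i]] + y[peaks[j]]
                if best is None or height > best[0]:
                    best = (height, peaks[i], peaks[j])
    if best is None:
        raise ReferencingError("no peak pair with doublet-like separation")
    left_ppm = max(ppm_w[best[1]], ppm_w[best[2]])
    shift = ALANINE_PPM - left_ppm
    return spectrum.replace(
        ppm=spectrum.ppm + shift, applied_shift=spectrum.applied_shift + shift
    )


def correct_baseline(spectrum: Spectrum) -> Spectrum:
    """Set the lowest point of the spectrum to zero (constant offset removal)."""
    if spectrum.intensity.size == 0:
        raise ConfigurationError("empty spectrum")
    return spectrum.replace(intensity=spectrum.intensity - spectrum.intensity.min())


def excise_water(
    spectrum: Spectrum, window: tuple[float, float] = WATER_WINDOW
) -> Spectrum:
    """Flag points in the (closed) residual-water window as excluded.

    Excluded points contribute nothing to any subsequent area.
    """
    lo, hi = min(window), max(window)
    mask = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    return spectrum.replace(water_mask=spectrum.water_mask | mask)


def _segment_area(ppm: np.ndarray, y: np.ndarray, keep: np.ndarray) -> float:
    """Trapezoidal area over retained points, split at excluded gaps.

    The axis is descending; each contiguous retained run is integrated on
    its ascending copy.
    """
    area = 0.0
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        return 0.0
    # split where retained indices are non-contiguous
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        if e > s:
            run = idx[s : e + 1]
            area += np.trapezoid(y[run][::-1], ppm[run][::-1])
    return float(area)


def retained_area(
    spectrum: Spectrum, window: tuple[float, float] = NORMALIZATION_WINDOW
) -> float:
    """Trapezoidal area over the closed window, skipping excluded points."""
    lo, hi = min(window), max(window)
    keep = (spectrum.ppm >= lo) & (spectrum.ppm <= hi) & ~spectrum.water_mask
    return _segment_area(spectrum.ppm, spectrum.intensity, keep)


def normalize_total_area(spectrum: Spectrum) -> Spectrum:
    """Divide intensities by the retained 0.29-8.53 ppm area.

    After this step the retained area equals one.  Raises
    :class:`~pmet.errors.NormalizationError` on a non-positive area.
    """
    area = retained_area(spectrum)
    if not area > 0:
        raise NormalizationError("retained area is not positive")
    return spectrum.replace(
        intensity=spectrum.intensity / area,
        normalization_factor=(spectrum.normalization_factor or 1.0) * area,
    )


def preprocess(spectrum: Spectrum) -> Spectrum:
    """Full chain: reference -> baseline -> water excision -> normalization."""
    s = reference_to_alanine(spectrum)
    s = correct_baseline(s)
    s = excise_water(s)
    return normalize_total_area(s)


def integrate_regions(
    spectrum: Spectrum, regions: pd.DataFrame | None = None
) -> pd.Series:
    """Integrate each metabolite window of a preprocessed spectrum.

    ``combine_mode == "mean"`` averages the window integrals of a
    metabolite; ``"single"`` uses the window with the lowest
    ``window_index`` (the resonance with minimum overlap).  Output order
    follows the region table.
    """
    if regions is None:
        regions = default_region_table()
    regions = validate_region_table(regions, require_lipids=False)
    ppm_min, ppm_max = spectrum.ppm.min(), spectrum.ppm.max()
    out: dict[str, float] = {}
    for name, grp in regions.groupby("name", sort=False):
        grp = grp.sort_values("window_index")
        if grp["combine_mode"].iloc[0] == "single":
            grp = grp.iloc[:1]
        integrals = []
        for _, row in grp.iterrows():
            if row.ppm_lo < ppm_min or row.ppm_hi > ppm_max:
                raise IntegrationError(
                    f"window [{row.ppm_lo}, {row.ppm_hi}] outside spectral axis"
                )
            keep = (
                (spectrum.ppm >= row.ppm_lo)
                & (spectrum.ppm <= row.ppm_hi)
                & ~spectrum.water_mask
            )
            integrals.append(_segment_area(spectrum.ppm, spectrum.intensity, keep))
        out[name] = float(np.mean(integrals))
    return pd.Series(out, name="integral")


def quantify_spectra(
    spectra: SpectrumSet, regions: pd.DataFrame | None = None
) -> MetaboliteMatrix:
    """Preprocess and integrate every spectrum, returning an MRS block."""
    if regions is None:
        regions = default_region_table()
    rows = []
    for i in range(len(spectra)):
        rows.append(integrate_regions(preprocess(spectra.spectrum(i)), regions))
    values = pd.DataFrame(rows).reset_index(drop=True)
    var_meta = pd.DataFrame(
        {"platform": "MRS", "var_class": "mrs_integral", "lod": 0.0},
        index=values.columns,
    )
    return MetaboliteMatrix(values, spectra.sample_meta.reset_index(drop=True), var_meta)
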