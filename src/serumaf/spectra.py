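"""Emission-spectrum container, normalization and tabular I/O.

A :class:`Spectrum` is one emission scan: intensity (arbitrary units)
versus emission wavelength (nm) at fixed excitation, tagged with a
sample id and treatment group.  Before fitting, spectra are peak-
normalized to 100 a.u.; the pre-normalization integrated area over the
analysis window is kept so percentage contributions can later be
rescaled to absolute (really measured) contributions.

Cohorts travel as long-format CSV with columns
``sample_id,group,excitation_nm,wavelength_nm,intensity_au``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "ANALYSIS_WINDOW",
    "normalize",
    "integrated_area",
    "read_spectra",
    "write_spectra",
]

#: default quantification window (nm): the range over which component
#: areas and the measured total area are integrated
ANALYSIS_WINDOW = (390.0, 600.0)

GROUPS = ("sham", "ir_60_60", "ir_60_120", "other")

LONG_COLUMNS = ["sample_id", "group", "excitation_nm", "wavelength_nm", "intensity_au"]


@dataclass(frozen=True)
class Spectrum:
    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation: int
    sample_id: str
    group: str = "other"
    raw_integrated_area: float | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelengths must be a 1-D array of length >= 2")
        if inten.shape != wl.shape:
            raise ValueError("intensities and wavelengths must have equal length")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > 1e-9 * max(1.0, abs(steps[0])):
            raise ValueError("wavelength grid must be uniform")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])


def integrated_area(spectrum: Spectrum, window: tuple[float, float] = ANALYSIS_WINDOW) -> float:
    """Trapezoidal integral of the spectrum over the analysis window."""
    lo, hi = window
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if mask.sum() < 2:
        raise ValueError(f"window [{lo}, {hi}] nm covers < 2 grid points")
    return float(np.trapezoid(spectrum.intensities[mask], spectrum.wavelengths[mask]))


def normalize(spectrum: Spectrum, window: tuple[float, float] = ANALYSIS_WINDOW) -> Spectrum:
    """Peak-normalize to 100 a.u., recording the raw integrated area.

    The maximum intensity is scaled to exactly 100; the trapezoidal
    integral over the analysis window *before* scaling is stored in
    ``raw_integrated_area`` for later absolute-contribution rescaling.
    Already-normalized spectra pass through unchanged (idempotent).
    """
    peak = float(np.max(spectrum.intensities))
    if not (peak > 0):
        raise ValueError(f"{spectrum.sample_id}: spectrum maximum must be > 0")
    raw_area = (spectrum.raw_integrated_area
                if spectrum.raw_integrated_area is not None
                else integrated_area(spectrum, window))
    return replace(
        spectrum,
        intensities=spectrum.intensities * (100.0 / peak),
        raw_integrated_area=raw_area,
    )


def write_spectra(spectra: list[Spectrum], path) -> None:
    """Write a cohort to long-format CSV."""
    frames = []
    for s in spectra:
        frames.append(pd.DataFrame({
            "sample_id": s.sample_id,
            "group": s.group,
            "excitation_nm": s.excitation,
            "wavelength_nm": s.wavelengths,
            "intensity_au": s.intensities,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_spectra(path) -> list[Spectrum]:
    """Read a long-format cohort CSV into spectra.

    Raises ``ValueError`` naming the first offending CSV line on
    malformed rows (non-numeric wavelength/intensity, missing fields).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("excitation_nm", "wavelength_nm", "intensity_au"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (df[col].str.strip() == "")
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
            raise ValueError(
                f"{path}: line {line}: invalid value {df[col].iloc[line - 2]!r} "
                f"in column {col!r}"
            )
        df[col] = converted
    blank = (df["sample_id"].str.strip() == "") | (df["group"].str.strip() == "")
    if blank.any():
        line = int(np.nonzero(blank.to_numpy())[0][0]) + 2
        raise ValueError(f"{path}: line {line}: empty sample_id or group")

    spectra = []
    for (sid, grp, exc), sub in df.groupby(
            ["sample_id", "group", "excitation_nm"], sort=True):
        sub = sub.sort_values("wavelength_nm")
        spectra.append(Spectrum(
            wavelengths=sub["wavelength_nm"].to_numpy(),
            intensities=sub["intensity_au"].to_numpy(),
            excitation=int(exc),
            sample_id=str(sid),
            group=str(grp),
        ))
    return spectra
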