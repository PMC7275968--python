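"""Wavelength-gridded absorbance spectra: containers, CSV I/O, windowing, resampling.

All other modules build on the types here.  Conventions:

* wavelengths are physical nanometres; nothing downstream indexes by raw
  position, so 0.2 nm and 0.4 nm grids interoperate without off-by-one drift;
* grids are closed intervals — both endpoints are grid points;
* absorbance is dimensionless AU, concentrations are always ug/mL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SpectraMatrix",
    "ConcentrationMatrix",
    "ACQUISITION_GRID",
    "MCR_GRID",
    "read_spectra",
    "write_spectra",
    "read_concentrations",
    "write_concentrations",
    "window",
    "resample",
]

#: tolerance (in units of grid step) for deciding a wavelength sits on a grid point
_GRID_TOL = 1e-6


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform closed wavelength grid [start_nm, end_nm] with spacing step_nm."""

    start_nm: float
    end_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if not (self.start_nm < self.end_nm):
            raise ValueError(f"start_nm ({self.start_nm}) must be < end_nm ({self.end_nm})")
        if not (self.step_nm > 0):
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        span = (self.end_nm - self.start_nm) / self.step_nm
        if abs(span - round(span)) > 1e-6:
            raise ValueError(
                f"grid span {self.start_nm}-{self.end_nm} nm is not an integer "
                f"multiple of step {self.step_nm} nm"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def index_of(self, nm: float) -> int:
        """Exact index of a wavelength on this grid; raises if off-grid."""
        pos = (nm - self.start_nm) / self.step_nm
        idx = int(round(pos))
        if abs(pos - idx) > _GRID_TOL * max(1.0, abs(pos)) + 1e-9 or not (0 <= idx < self.n_points):
            raise ValueError(f"{nm} nm is not a point of grid {self}")
        return idx

    def __contains__(self, nm: float) -> bool:
        try:
            self.index_of(nm)
        except ValueError:
            return False
        return True

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.start_nm}-{self.end_nm} nm @ {self.step_nm} nm"


#: default acquisition grid: 200-330 nm at 0.2 nm (651 points)
ACQUISITION_GRID = WavelengthGrid(200.0, 330.0, 0.2)
#: working grid for multivariate resolution: 220-290 nm at 0.4 nm (176 points)
MCR_GRID = WavelengthGrid(220.0, 290.0, 0.4)


def _infer_grid(wl: np.ndarray) -> WavelengthGrid:
    steps = np.diff(wl)
    if len(steps) == 0:
        raise ValueError("need at least two wavelength points")
    if np.any(steps <= 0):
        raise ValueError("wavelengths must be strictly increasing (duplicates not allowed)")
    step = steps[0]
    if not np.allclose(steps, step, rtol=0, atol=1e-6 * step):
        raise ValueError("non-uniform wavelength spacing; resample explicitly if intended")
    return WavelengthGrid(float(wl[0]), float(wl[-1]), float(round(step, 9)))


@dataclass
class Spectrum:
    """Single absorbance spectrum on a uniform grid.

    ``usable`` marks grid points whose value is meaningful for quantitative
    reads; ratio and derivative operators flag points they cannot trust
    (divisor below guard, incomplete smoothing window) as unusable.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    label: str = ""
    usable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (self.grid.n_points,):
            raise ValueError(
                f"absorbance length {self.absorbance.shape} != grid points {self.grid.n_points}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if self.usable is None:
            self.usable = np.ones(self.grid.n_points, dtype=bool)
        else:
            self.usable = np.asarray(self.usable, dtype=bool)
            if self.usable.shape != (self.grid.n_points,):
                raise ValueError("usable mask length mismatch")

    def value_at(self, nm: float, require_usable: bool = True) -> float:
        idx = self.grid.index_of(nm)
        if require_usable and not self.usable[idx]:
            raise ValueError(f"{nm} nm is flagged unusable for {self.label or 'spectrum'}")
        return float(self.absorbance[idx])


@dataclass
class SpectraMatrix:
    """Samples x wavelengths absorbance matrix D on a shared grid."""

    grid: WavelengthGrid
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x wavelengths)")
        if self.values.shape != (len(self.samples), self.grid.n_points):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.samples)} samples x {self.grid.n_points} grid points"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra contain non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def spectrum(self, sample: str | int) -> Spectrum:
        i = sample if isinstance(sample, int) else self.samples.index(sample)
        return Spectrum(self.grid, self.values[i].copy(), label=str(self.samples[i]))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.T, columns=self.samples)
        df.insert(0, "wavelength_nm", self.grid.wavelengths)
        return df


@dataclass
class ConcentrationMatrix:
    """Samples x analytes concentrations (ug/mL); matrix C."""

    samples: list[str]
    analytes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.analytes = list(self.analytes)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.analytes)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.analytes)} analytes"
            )
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    def column(self, analyte: str) -> np.ndarray:
        return self.values[:, self.analytes.index(analyte)]

    def subset(self, sample_indices: list[int]) -> "ConcentrationMatrix":
        return ConcentrationMatrix(
            [self.samples[i] for i in sample_indices],
            self.analytes,
            self.values[sample_indices],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.analytes)
        df.insert(0, "sample_id", self.samples)
        return df


# ---------------------------------------------------------------------------
# CSV I/O.  Canonical on-disk form is wide CSV:
#   spectra:        wavelength_nm,<sample_id>,<sample_id>,...
#   concentrations: sample_id,<analyte>,<analyte>,...
# ---------------------------------------------------------------------------

def read_spectra(path, dialect: str = "wide") -> SpectraMatrix:
    """Read a wide-form spectra CSV into a :class:`SpectraMatrix`.

    The first column must be the monotone wavelength axis (any name containing
    "wavelength" or "nm" is accepted); every remaining column is one sample.
    """
    if dialect != "wide":
        raise ValueError(f"unknown dialect {dialect!r}; only 'wide' is supported")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("spectra CSV needs a wavelength column plus >=1 absorbance column")
    wl_col = df.columns[0]
    if not ("wavelength" in wl_col.lower() or "nm" in wl_col.lower()):
        raise ValueError(f"first column {wl_col!r} does not look like a wavelength axis")
    if df.isna().any().any():
        raise ValueError("spectra CSV contains NaN cells")
    wl = df[wl_col].to_numpy(dtype=float)
    grid = _infer_grid(wl)
    samples = [str(c) for c in df.columns[1:]]
    values = df.iloc[:, 1:].to_numpy(dtype=float).T
    return SpectraMatrix(grid, samples, values)


def write_spectra(s: SpectraMatrix, path) -> None:
    """Write wide-form CSV with 17 significant digits (bit-lossless round-trip)."""
    s.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_concentrations(path) -> ConcentrationMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise ValueError("concentration CSV must start with a 'sample_id' column")
    samples = [str(x) for x in df["sample_id"]]
    analytes = [str(c) for c in df.columns[1:]]
    return ConcentrationMatrix(samples, analytes, df.iloc[:, 1:].to_numpy(dtype=float))


def write_concentrations(c: ConcentrationMatrix, path) -> None:
    c.to_dataframe().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Windowing and resampling
# ---------------------------------------------------------------------------

def window(s: SpectraMatrix, lo: float, hi: float) -> SpectraMatrix:
    """Inclusive wavelength window [lo, hi]; bounds must lie on the grid."""
    if lo > hi:
        raise ValueError("empty window: lo > hi")
    i0 = s.grid.index_of(lo)
    i1 = s.grid.index_of(hi)
    new_grid = WavelengthGrid(lo, hi, s.grid.step_nm)
    return SpectraMatrix(new_grid, list(s.samples), s.values[:, i0 : i1 + 1].copy())


def resample(s: SpectraMatrix, new_step: float, interpolate: bool = False) -> SpectraMatrix:
    """Move spectra onto a coarser (decimation) or arbitrary (linear) grid.

    Decimation takes every k-th point starting at the window start and is
    exact; interpolation must be requested explicitly and is linear.
    """
    ratio = new_step / s.grid.step_nm
    k = int(round(ratio))
    if abs(ratio - k) < 1e-9 and k >= 1:
        if k == 1:
            return SpectraMatrix(s.grid, list(s.samples), s.values.copy())
        idx = np.arange(0, s.grid.n_points, k)
        end = s.grid.start_nm + new_step * (len(idx) - 1)
        new_grid = WavelengthGrid(s.grid.start_nm, end, new_step)
        return SpectraMatrix(new_grid, list(s.samples), s.values[:, idx].copy())
    if not interpolate:
        raise ValueError(
            f"new step {new_step} nm is not an integer multiple of native "
            f"{s.grid.step_nm} nm; pass interpolate=True for linear interpolation"
        )
    n_new = int(np.floor((s.grid.end_nm - s.grid.start_nm) / new_step + 1e-9)) + 1
    end = s.grid.start_nm + new_step * (n_new - 1)
    new_grid = WavelengthGrid(s.grid.start_nm, end, new_step)
    new_vals = np.vstack(
        [np.interp(new_grid.wavelengths, s.grid.wavelengths, row) for row in s.values]
    )
    return SpectraMatrix(new_grid, list(s.samples), new_vals)
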