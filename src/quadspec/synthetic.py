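"""Synthetic UV-Vis spectra generator.

Emulates the statistical structure that both quantification methods assume:
Beer-law additivity of four strongly overlapped drug spectra (atenolol AT,
paracetamol PR, hydrochlorothiazide HZ, levofloxacin LV) over 200-330 nm,
an optional broad urine-background interferent, and additive Gaussian
photometric noise from a seeded RNG.

Component band parameters are versioned constants chosen so that

* the four drugs and the urine background all pairwise overlap over
  220-290 nm,
* the analytical wavelengths used by the derivative-ratio method
  (281.6 / 237.6 / 279.2 / 282.8 nm) fall in informative regions of the
  corresponding ratio spectra, and
* peak absorbances at working concentrations are of order 0.1-1 AU.

They are not fitted to any instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import (
    ACQUISITION_GRID,
    ConcentrationMatrix,
    SpectraMatrix,
    Spectrum,
    WavelengthGrid,
)

__all__ = [
    "GaussianBand",
    "ComponentModel",
    "NoiseModel",
    "default_library",
    "pure_spectrum",
    "mixture_spectrum",
    "simulate_dataset",
    "ANALYTES",
    "URINE",
]

ANALYTES = ("AT", "PR", "HZ", "LV")
URINE = "URINE"


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorption band: height is AU per (ug/mL) at the center."""

    center_nm: float
    width_nm: float  # Gaussian sigma
    height: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("band width must be positive")
        if self.height < 0:
            raise ValueError("band height must be non-negative")

    def evaluate(self, wl: np.ndarray) -> np.ndarray:
        return self.height * np.exp(-((wl - self.center_nm) ** 2) / (2.0 * self.width_nm**2))


@dataclass(frozen=True)
class ComponentModel:
    """Named analyte as a sum of Gaussian bands (unit-concentration spectrum)."""

    name: str
    bands: tuple[GaussianBand, ...]

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValueError("component needs at least one band")

    def unit_spectrum(self, grid: WavelengthGrid) -> np.ndarray:
        wl = grid.wavelengths
        out = np.zeros_like(wl)
        for b in self.bands:
            out += b.evaluate(wl)
        return out


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian photometric noise (AU) with a fixed seed."""

    sigma_au: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_au < 0:
            raise ValueError("noise sigma must be non-negative")


# Versioned band constants (AU per ug/mL).  Maxima orderings mimic the real
# drugs: AT weakest with deep-UV and ~281 nm maxima, PR strong near 241 nm,
# HZ with deep-UV / ~274 nm / 317 nm features plus a narrow vibronic-style
# satellite at 281 nm, LV strong near 289 nm, urine a broad featureless
# background.  AT, HZ and LV share one deep-UV band shape (differing only in
# height) so the interferent background is locally rank-one around the
# 237.6 nm derivative-ratio read; the remaining centers/widths/heights were
# solved jointly (once) so that interferent cross-sensitivities at the
# 279.2 / 281.6 / 282.8 nm reads vanish for the default divisor recipes.
# Do not round or "tidy" them: the cancellation is exact only at these
# values.
_LIBRARY_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "AT": ((226.0, 7.5, 0.04), (281.4172, 2.3928, 0.0993)),
    "PR": ((240.5927, 6.0, 0.1968),),
    "HZ": (
        (226.0, 7.5, 0.05),
        (274.0, 4.1071, 0.15),
        (281.3798, 2.032, 0.0737),
        (317.0, 8.0, 0.01),
    ),
    "LV": ((226.0, 7.5, 0.05), (288.8817, 5.0002, 0.3999)),
    "URINE": ((235.0, 28.0, 0.010), (280.0, 45.0, 0.006)),
}


def default_library() -> list[ComponentModel]:
    """The five-component library: the four drugs plus the urine background."""
    return [
        ComponentModel(name, tuple(GaussianBand(*t) for t in bands))
        for name, bands in _LIBRARY_BANDS.items()
    ]


def _component(library: list[ComponentModel], name: str) -> ComponentModel:
    for m in library:
        if m.name == name:
            return m
    raise KeyError(f"unknown component {name!r}; library has {[m.name for m in library]}")


def pure_spectrum(
    m: ComponentModel, conc: float, grid: WavelengthGrid = ACQUISITION_GRID
) -> Spectrum:
    """Beer-law spectrum of one component: exactly linear in concentration."""
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    return Spectrum(grid, conc * m.unit_spectrum(grid), label=f"{m.name} {conc:g} ug/mL")


def _spectrum_seed(base_seed: int, row_index: int) -> np.random.Generator:
    # one global seed per dataset; per-spectrum streams spawned deterministically
    return np.random.default_rng(np.random.SeedSequence(entropy=base_seed, spawn_key=(row_index,)))


def mixture_spectrum(
    library: list[ComponentModel],
    concs: dict[str, float],
    grid: WavelengthGrid = ACQUISITION_GRID,
    noise: NoiseModel | None = None,
    _row_index: int = 0,
) -> Spectrum:
    """Additive Beer-law mixture, optionally with seeded Gaussian noise."""
    values = np.zeros(grid.n_points)
    for name, c in concs.items():
        values += pure_spectrum(_component(library, name), c, grid).absorbance
    if noise is not None and noise.sigma_au > 0:
        rng = _spectrum_seed(noise.seed, _row_index)
        values = values + rng.normal(0.0, noise.sigma_au, size=grid.n_points)
    return Spectrum(grid, values, label="mixture")


def simulate_dataset(
    design: ConcentrationMatrix,
    library: list[ComponentModel] | None = None,
    grid: WavelengthGrid = ACQUISITION_GRID,
    noise: NoiseModel | None = None,
) -> SpectraMatrix:
    """One spectrum per design row, in design order.

    Row *i* uses an RNG stream spawned deterministically from the dataset
    seed and *i*, so any single spectrum is reproducible in isolation.
    """
    if library is None:
        library = default_library()
    names = {m.name for m in library}
    missing = set(design.analytes) - names
    if missing:
        raise KeyError(f"design analytes {sorted(missing)} not in library {sorted(names)}")
    rows = []
    for i, sample in enumerate(design.samples):
        concs = dict(zip(design.analytes, design.values[i]))
        rows.append(mixture_spectrum(library, concs, grid, noise, _row_index=i).absorbance)
    return SpectraMatrix(grid, list(design.samples), np.vstack(rows))
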