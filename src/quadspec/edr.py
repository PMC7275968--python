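"""Extended derivative ratio (EDR) spectrophotometry.

One target analyte in a four-component mixture is quantified by dividing the
mixture spectrum by the stored spectrum of a mixture of the other three
components (the *divisor*).  Under Beer-law additivity the interferents'
joint contribution to the ratio spectrum is a wavelength-independent
constant, which differentiation annihilates; the remaining derivative
amplitude at the analytical wavelength is directly proportional to the
target concentration.

The derivative is a Savitzky-Golay smoothed derivative: window length
``round(delta_lambda / step) + 1`` points (e.g. 21 points for delta_lambda =
4 nm on a 0.2 nm grid), polynomial order = derivative order + 1, reported in
per-nm units and then multiplied by the dimensionless scaling factor.
Instrument software leaves its derivative kernel unspecified, so amplitudes
here match an instrument's only up to a kernel constant; calibration and
prediction share the kernel, which is what quantification requires.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import minimum_filter1d
from scipy.signal import savgol_filter
from scipy import stats

from . import metrics
from .spectra import SpectraMatrix, Spectrum, WavelengthGrid
from .synthetic import ComponentModel, default_library, mixture_spectrum

__all__ = [
    "DivisorRecipe",
    "DerivativeSettings",
    "EDRCalibration",
    "DEFAULT_RECIPES",
    "DEFAULT_SETTINGS",
    "DEFAULT_WAVELENGTHS",
    "divisor_from_recipe",
    "ratio_spectrum",
    "derivative",
    "calibrate_edr",
    "predict_edr",
]

#: default guard (AU) below which the divisor is considered unusable
DEFAULT_GUARD_AU = 1e-3


@dataclass(frozen=True)
class DivisorRecipe:
    """Concentrations (ug/mL) of the three interferents in the divisor mixture."""

    target: str
    components: dict[str, float]

    def __post_init__(self) -> None:
        if self.target in self.components:
            raise ValueError("target must not appear in its own divisor")
        if len(self.components) != 3:
            raise ValueError("divisor recipe needs exactly the 3 other analytes")


@dataclass(frozen=True)
class DerivativeSettings:
    """Derivative order (1 or 2), delta-lambda window (nm), scaling factor."""

    order: int
    delta_lambda_nm: float
    scaling_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError("derivative order must be 1 or 2")
        if self.delta_lambda_nm <= 0:
            raise ValueError("delta_lambda must be positive")

    def window_points(self, step_nm: float) -> int:
        n = int(round(self.delta_lambda_nm / step_nm)) + 1
        if n % 2 == 0:
            n += 1
        return n


#: published divisor compositions, one per target analyte
DEFAULT_RECIPES: dict[str, DivisorRecipe] = {
    "AT": DivisorRecipe("AT", {"PR": 7.0, "HZ": 2.0, "LV": 4.0}),
    "PR": DivisorRecipe("PR", {"AT": 15.0, "HZ": 3.0, "LV": 5.0}),
    "HZ": DivisorRecipe("HZ", {"AT": 15.0, "PR": 10.0, "LV": 5.0}),
    "LV": DivisorRecipe("LV", {"AT": 15.0, "PR": 7.0, "HZ": 2.0}),
}

#: published derivative settings per target: (order, delta_lambda nm, scaling)
DEFAULT_SETTINGS: dict[str, DerivativeSettings] = {
    "AT": DerivativeSettings(2, 4.0, 10.0),
    "PR": DerivativeSettings(1, 4.0, 10.0),
    "HZ": DerivativeSettings(1, 2.0, 10.0),
    "LV": DerivativeSettings(2, 4.0, 10.0),
}

#: published analytical wavelengths (nm) per target
DEFAULT_WAVELENGTHS: dict[str, float] = {"AT": 281.6, "PR": 237.6, "HZ": 279.2, "LV": 282.8}


@dataclass
class EDRCalibration:
    """Fitted amplitude-vs-concentration line plus figures of merit."""

    target: str
    divisor: Spectrum
    settings: DerivativeSettings
    analytical_wavelength_nm: float
    slope: float
    intercept: float
    r2: float
    s_slope: float
    s_intercept: float
    lod: float
    loq: float
    conc_range: tuple[float, float]
    recipe: DivisorRecipe | None = None

    def to_json(self, path) -> None:
        payload = {
            "target": self.target,
            "settings": asdict(self.settings),
            "analytical_wavelength_nm": self.analytical_wavelength_nm,
            "regression": {
                "slope": self.slope,
                "intercept": self.intercept,
                "r2": self.r2,
                "s_slope": self.s_slope,
                "s_intercept": self.s_intercept,
            },
            "lod": self.lod,
            "loq": self.loq,
            "conc_range": list(self.conc_range),
            "recipe": asdict(self.recipe) if self.recipe else None,
            "divisor": {
                "grid": {
                    "start_nm": self.divisor.grid.start_nm,
                    "end_nm": self.divisor.grid.end_nm,
                    "step_nm": self.divisor.grid.step_nm,
                },
                "absorbance": self.divisor.absorbance.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "EDRCalibration":
        with open(path) as fh:
            p = json.load(fh)
        g = p["divisor"]["grid"]
        divisor = Spectrum(
            WavelengthGrid(g["start_nm"], g["end_nm"], g["step_nm"]),
            np.array(p["divisor"]["absorbance"]),
            label=f"{p['target']} divisor",
        )
        recipe = DivisorRecipe(**p["recipe"]) if p.get("recipe") else None
        reg = p["regression"]
        return cls(
            target=p["target"],
            divisor=divisor,
            settings=DerivativeSettings(**p["settings"]),
            analytical_wavelength_nm=p["analytical_wavelength_nm"],
            slope=reg["slope"],
            intercept=reg["intercept"],
            r2=reg["r2"],
            s_slope=reg["s_slope"],
            s_intercept=reg["s_intercept"],
            lod=p["lod"],
            loq=p["loq"],
            conc_range=tuple(p["conc_range"]),
            recipe=recipe,
        )


def divisor_from_recipe(
    recipe: DivisorRecipe,
    grid: WavelengthGrid,
    library: list[ComponentModel] | None = None,
    noise=None,
) -> Spectrum:
    """Synthesize the divisor mixture spectrum from its recipe."""
    if library is None:
        library = default_library()
    s = mixture_spectrum(library, dict(recipe.components), grid, noise)
    s.label = f"{recipe.target} divisor"
    return s


def ratio_spectrum(
    sample: Spectrum, divisor: Spectrum, guard: float = DEFAULT_GUARD_AU
) -> Spectrum:
    """Point-wise quotient sample / divisor.

    Grid points where |divisor| < guard are flagged unusable; their quotient
    is computed against the guard-clipped divisor purely to keep downstream
    filters finite, and must not be read quantitatively.
    """
    if sample.grid != divisor.grid:
        raise ValueError("sample and divisor must share a wavelength grid")
    if np.all(np.abs(divisor.absorbance) < guard):
        raise ValueError("divisor is below the guard threshold everywhere")
    ok = np.abs(divisor.absorbance) >= guard
    safe = np.where(ok, divisor.absorbance, np.where(divisor.absorbance >= 0, guard, -guard))
    values = sample.absorbance / safe
    usable = ok & sample.usable & divisor.usable
    return Spectrum(sample.grid, values, label=f"{sample.label}/{divisor.label}", usable=usable)


def derivative(ratio: Spectrum, settings: DerivativeSettings) -> Spectrum:
    """Savitzky-Golay smoothed derivative of a ratio spectrum.

    Output is in per-nm units multiplied by the scaling factor.  Points whose
    smoothing window is incomplete (spectrum edges) or touches an unusable
    input point are flagged unusable.
    """
    step = ratio.grid.step_nm
    win = settings.window_points(step)
    n = ratio.grid.n_points
    if win > n:
        raise ValueError(f"window of {win} points exceeds spectrum length {n}")
    deriv = savgol_filter(
        ratio.absorbance,
        window_length=win,
        polyorder=settings.order + 1,
        deriv=settings.order,
        delta=step,
    )
    deriv *= settings.scaling_factor
    half = win // 2
    usable = minimum_filter1d(ratio.usable.astype(np.uint8), size=win, mode="constant", cval=0)
    usable = usable.astype(bool)
    usable[:half] = False
    usable[n - half :] = False
    return Spectrum(ratio.grid, deriv, label=f"d{settings.order}({ratio.label})", usable=usable)


def _amplitude(
    sample: Spectrum,
    divisor: Spectrum,
    settings: DerivativeSettings,
    wavelength_nm: float,
    guard: float,
) -> float:
    d = derivative(ratio_spectrum(sample, divisor, guard), settings)
    return d.value_at(wavelength_nm)


def calibrate_edr(
    standards: SpectraMatrix,
    concs,
    recipe: DivisorRecipe,
    settings: DerivativeSettings,
    wavelength_nm: float,
    divisor: Spectrum | None = None,
    library: list[ComponentModel] | None = None,
    guard: float = DEFAULT_GUARD_AU,
) -> EDRCalibration:
    """Fit the amplitude-vs-concentration calibration line for one target.

    ``divisor`` may be a measured spectrum; if omitted it is synthesized
    from the recipe on the standards' grid.
    """
    concs = np.asarray(concs, dtype=float)
    if len(concs) != standards.n_samples:
        raise ValueError("one concentration per standard required")
    if len(concs) < 3:
        raise ValueError("need at least 3 calibration standards")
    if divisor is None:
        divisor = divisor_from_recipe(recipe, standards.grid, library)
    amps = np.array(
        [
            _amplitude(standards.spectrum(i), divisor, settings, wavelength_nm, guard)
            for i in range(standards.n_samples)
        ]
    )
    fit = stats.linregress(concs, amps)
    s_slope = float(fit.stderr)
    s_intercept = float(fit.intercept_stderr)
    lod, loq = metrics.lod_loq(s_intercept, fit.slope) if s_intercept > 0 else (0.0, 0.0)
    return EDRCalibration(
        target=recipe.target,
        divisor=divisor,
        settings=settings,
        analytical_wavelength_nm=wavelength_nm,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        s_slope=s_slope,
        s_intercept=s_intercept,
        lod=lod,
        loq=loq,
        conc_range=(float(np.min(concs)), float(np.max(concs))),
        recipe=recipe,
    )


def predict_edr(
    cal: EDRCalibration, sample: Spectrum, guard: float = DEFAULT_GUARD_AU
) -> float:
    """Invert the calibration line at the analytical wavelength.

    Negative predictions are returned as-is with a warning; truncation is
    the caller's reporting policy.
    """
    amp = _amplitude(sample, cal.divisor, cal.settings, cal.analytical_wavelength_nm, guard)
    conc = (amp - cal.intercept) / cal.slope
    if conc < 0:
        warnings.warn(
            f"negative predicted concentration {conc:.4g} ug/mL for {cal.target}",
            stacklevel=2,
        )
    return float(conc)
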