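"""quadspec: quantification of four severely overlapped UV-Vis components.

Two complementary methods for the simultaneous determination of atenolol,
paracetamol, hydrochlorothiazide, and levofloxacin from a single UV-Vis
scan: the univariate extended derivative ratio (EDR) and correlation-
constrained multivariate curve resolution (MCR-ALS), together with the
multilevel calibration design, ICH validation statistics, greenness
scoring, and a synthetic spectra generator.
"""

from importlib import resources as _resources

import pandas as _pd

from .spectra import (
    ACQUISITION_GRID,
    MCR_GRID,
    ConcentrationMatrix,
    SpectraMatrix,
    Spectrum,
    WavelengthGrid,
    read_concentrations,
    read_spectra,
    resample,
    window,
    write_concentrations,
    write_spectra,
)
from .synthetic import (
    ANALYTES,
    URINE,
    ComponentModel,
    GaussianBand,
    NoiseModel,
    default_library,
    mixture_spectrum,
    pure_spectrum,
    simulate_dataset,
)
from .design import (
    DEFAULT_LEVELS,
    DEFAULT_VALIDATION_ROWS,
    DesignSpec,
    multilevel_design,
    scale_design,
    split_calibration_validation,
)
from .edr import (
    DEFAULT_RECIPES,
    DEFAULT_SETTINGS,
    DEFAULT_WAVELENGTHS,
    DerivativeSettings,
    DivisorRecipe,
    EDRCalibration,
    calibrate_edr,
    derivative,
    divisor_from_recipe,
    predict_edr,
    ratio_spectrum,
)
from .mcr import (
    MCRModel,
    MCRSettings,
    als_fit,
    correlation_constraint,
    explained_variance,
    lack_of_fit,
    predict_mcr,
    simplisma_init,
)
from .metrics import (
    FiguresOfMerit,
    RegressionFOM,
    ValidationReport,
    compare_methods,
    lod_loq,
    prediction_fom,
    recovery_stats,
    rsd_pct,
    urinary_excretion,
    validation_report,
)
from .greenness import (
    EcoScaleItem,
    EcoScaleSheet,
    NemiProfile,
    eco_scale,
    method_sheet_items,
    nemi,
)

__version__ = "0.1.0"


def published_design(with_flags: bool = False):
    """The published 25-run concentration matrix, shipped verbatim.

    Returns a :class:`ConcentrationMatrix`; with ``with_flags=True`` also
    returns the set of 1-based validation run indices.
    """
    text = _resources.files("quadspec.data").joinpath("published_design.csv")
    with text.open() as fh:
        df = _pd.read_csv(fh)
    cm = ConcentrationMatrix(
        [str(s) for s in df["sample_id"]],
        ["AT", "PR", "HZ", "LV"],
        df[["AT", "PR", "HZ", "LV"]].to_numpy(dtype=float),
    )
    if with_flags:
        flags = frozenset(int(i) + 1 for i in df.index[df["validation"] == 1])
        return cm, flags
    return cm
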