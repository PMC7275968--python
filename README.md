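# quadspec

Simultaneous quantification of four strongly overlapped UV-Vis absorbers —
atenolol (AT), paracetamol (PR), hydrochlorothiazide (HZ), and levofloxacin
(LV) — from a single 200–330 nm absorbance scan, for analysts who want a
green, cuvette-only alternative to chromatographic separation (e.g. for
tablet assays and urinary-excretion work).  The package implements two
complementary methods plus everything around them: the calibration
experimental design, ICH-style validation statistics, greenness scoring,
and a synthetic spectra generator that stands in for instrument data.

**Extended derivative ratio (EDR).**  By Beer-law additivity a mixture
spectrum is `A(λ) = Σⱼ εⱼ(λ)·Cⱼ`.  Dividing by the stored spectrum of a
mixture of the three interferents (the *divisor*) gives

```
A(λ)/A°(λ) = εW(λ)·CW / Σⱼ≠W εⱼ(λ)·C°ⱼ  +  K,
```

where the interferents' joint term `K` is (approximately) constant in λ;
the derivative `d/dλ` annihilates `K`, and the smoothed-derivative
amplitude at a fixed analytical wavelength is directly proportional to
`CW`.  Amplitudes are read at 281.6 / 237.6 / 279.2 / 282.8 nm for
AT / PR / HZ / LV with Δλ = 4 / 4 / 2 / 4 nm and a ×10 scaling factor.

**MCR-ALS.**  The bilinear model `D = C·Sᵀ + E` is refined by alternating
non-negative least squares from SIMPLISMA initial estimates, with a
correlation constraint that regresses each analyte's resolved
concentrations onto known calibration references every iteration — five
components: the four drugs plus one free component that soaks up
uncalibrated background (urine).  Quality is tracked by the lack of fit
`lof% = 100·√(Σe²/Σd²)` and explained variance `R²% = 100 − lof²/100`.
Calibration uses a five-level four-factor design (25 mixtures, 18/7
calibration/validation split) on the 220–290 nm, 0.4 nm working grid.

See `docs/methods.md` for assumptions, parameter defaults, and what the
synthetic generator does and does not emulate.

## Worked example

Run the end-to-end demo pipeline (design → simulate at σ = 0.002 AU →
MCR-ALS fit on the 18 calibration mixtures → predict the 7 held-out
mixtures → validate → greenness):

```sh
quadspec demo --outdir demo --seed 17
cat demo/report.json
```

prints (abridged):

```json
{
  "mcr": {"lof_pct": 0.1366, "explained_var_pct": 99.9998,
          "iterations": 39, "converged": true},
  "fom": {"AT": {"RMSEP": 0.0080, "RE_pct": 0.062, "r2": 0.999997},
          "PR": {"RMSEP": 0.0032, "RE_pct": 0.048, "r2": 0.999999}},
  "eco_scale_score": 95.0,
  "seed": 17
}
```

A lack of fit of 0.14% means the five-component bilinear model reproduces
the noisy spectra to about one part in 700; RMSEP ≈ 0.008 ug/mL and
RE% ≈ 0.06 for AT mean the held-out mixtures are predicted to well under a
percent of their 5–25 ug/mL range; the Eco-Scale score of 95 (water 1×0 +
ethanol 1×2 reagent points + 3 waste points deducted from 100) classifies
the method as green.  Rerunning with the same seed reproduces every
artifact byte for byte.

The same workflow is available as a library.  EDR, end to end:

```python
import numpy as np
import quadspec as q

lib = q.default_library()                       # AT, PR, HZ, LV + urine bands
concs = np.linspace(1, 25, 7)                   # PR standards, ug/mL
standards = q.SpectraMatrix(
    q.ACQUISITION_GRID, [f"s{i}" for i in range(7)],
    np.vstack([q.mixture_spectrum(lib, {"PR": float(c)}).absorbance for c in concs]),
)
cal = q.calibrate_edr(standards, concs, q.DEFAULT_RECIPES["PR"],
                      q.DEFAULT_SETTINGS["PR"], q.DEFAULT_WAVELENGTHS["PR"])
mix = q.mixture_spectrum(lib, {"PR": 8.0, "AT": 15.0, "HZ": 3.0, "LV": 5.0})
print(round(q.predict_edr(cal, mix), 3))        # -> 8.0
```

Other CLI subcommands: `design`, `simulate`, `edr calibrate/predict`,
`mcr fit/predict`, `validate`, `greenness` (all with `--help`).

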