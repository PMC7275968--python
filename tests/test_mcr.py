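import numpy as np
import pytest

import quadspec
from quadspec import (
    ConcentrationMatrix,
    MCRSettings,
    MCR_GRID,
    NoiseModel,
    SpectraMatrix,
    als_fit,
    correlation_constraint,
    default_library,
    explained_variance,
    lack_of_fit,
    mixture_spectrum,
    predict_mcr,
    resample,
    simplisma_init,
    simulate_dataset,
    window,
)
from quadspec.design import DEFAULT_VALIDATION_ROWS, split_calibration_validation


def brute_force_simplisma(X, k, noise_pct):
    """Independent re-implementation: recompute weighted purity over all
    wavelengths at each pick using explicit determinants."""
    n, m = X.shape
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    offset = noise_pct / 100.0 * mu.max()
    alpha = mu + offset
    length = np.sqrt(sigma**2 + alpha**2)
    Y = X / length
    COO = Y.T @ Y / n
    picked = []
    for _ in range(k):
        best, best_p = None, -np.inf
        for j in range(m):
            if j in picked:
                continue
            idx = [j] + picked
            w = np.linalg.det(COO[np.ix_(idx, idx)])
            pj = w * sigma[j] / alpha[j]
            if pj > best_p:
                best, best_p = j, pj
        picked.append(best)
    return picked


def working_grid(spectra):
    return resample(window(spectra, MCR_GRID.start_nm, MCR_GRID.end_nm), MCR_GRID.step_nm)


def five_component_dataset(sigma=0.0, seed=23):
    """Published 25-run design + random urine background, on the working grid."""
    design = quadspec.published_design()
    rng = np.random.default_rng(seed)
    urine = rng.uniform(0.5, 2.0, 25)
    full = ConcentrationMatrix(
        design.samples, design.analytes + ["URINE"],
        np.column_stack([design.values, urine]),
    )
    noise = NoiseModel(sigma, seed) if sigma > 0 else None
    data = working_grid(simulate_dataset(full, noise=noise))
    return design, full, data


class TestSimplisma:
    def test_disjoint_bands_pick_band_centers(self):
        """Two samples of two non-overlapping bands: purest variables sit at
        the band centers (+- 1 grid point)."""
        wl = np.arange(100.0)
        b1 = np.exp(-((wl - 25) ** 2) / 18.0)
        b2 = np.exp(-((wl - 75) ** 2) / 18.0)
        X = np.vstack([2 * b1 + 0.3 * b2, 0.5 * b1 + 1.5 * b2])
        _, picked = simplisma_init(X, 2, noise_pct=5)
        assert sorted(min(abs(p - c) for c in (25, 75)) for p in picked) <= [1, 1]
        assert {min((25, 75), key=lambda c: abs(p - c)) for p in picked} == {25, 75}

    def test_deflation_never_repeats_a_variable(self):
        rng = np.random.default_rng(0)
        X = np.abs(rng.normal(1.0, 0.3, size=(6, 30)))
        _, picked = simplisma_init(X, 4, noise_pct=5)
        assert len(set(picked)) == 4

    def test_purity_ranking_matches_exhaustive_oracle(self):
        """Pick sequence equals a brute-force re-computation on a 20-wavelength toy."""
        rng = np.random.default_rng(1)
        C = np.abs(rng.normal(1.0, 0.5, size=(8, 3)))
        S = np.abs(rng.normal(0.5, 0.3, size=(3, 20)))
        X = C @ S
        _, picked = simplisma_init(X, 3, noise_pct=5)
        assert picked == brute_force_simplisma(X, 3, 5)

    def test_k_exceeding_dimensions_rejected(self):
        with pytest.raises(ValueError):
            simplisma_init(np.ones((3, 10)), 4)


class TestFitMetrics:
    def test_perfect_model_zero_lof_full_variance(self):
        D = np.array([[1.0, 2.0], [3.0, 4.0]])
        C = np.array([[1.0], [2.0]])
        S = np.array([[1.0, 2.0]])
        D = C @ S
        assert lack_of_fit(D, C, S) == 0.0
        assert explained_variance(D, C, S) == 100.0

    def test_zero_model_is_100pct_lof(self):
        D = np.eye(2)
        C = np.zeros((2, 1))
        S = np.zeros((1, 2))
        assert lack_of_fit(D, C, S) == 100.0

    def test_hand_computed_example(self):
        D = np.eye(2)
        C = np.eye(2)
        S = 0.9 * np.eye(2)
        assert lack_of_fit(D, C, S) == pytest.approx(10.0, rel=1e-12)
        assert explained_variance(D, C, S) == pytest.approx(99.0, rel=1e-12)

    def test_lof_variance_identity(self):
        rng = np.random.default_rng(3)
        D = np.abs(rng.normal(1, 0.5, (6, 12)))
        C = np.abs(rng.normal(1, 0.5, (6, 2)))
        S = np.abs(rng.normal(1, 0.5, (2, 12)))
        lof = lack_of_fit(D, C, S)
        ev = explained_variance(D, C, S)
        assert ev == pytest.approx(100.0 - lof**2 / 100.0, abs=1e-10)


class TestCorrelationConstraint:
    def test_identity_when_resolved_equals_refs(self):
        refs = np.array([1.0, 2.0, 3.0, 4.0])
        corrected, slope, intercept = correlation_constraint(refs.copy(), refs)
        assert slope == pytest.approx(1.0) and intercept == pytest.approx(0.0)
        np.testing.assert_allclose(corrected, refs)

    def test_affine_map_recovered(self):
        refs = np.array([1.0, 2.0, 3.0, 5.0])
        resolved = 2.0 * refs + 3.0
        corrected, slope, intercept = correlation_constraint(resolved, refs)
        assert slope == pytest.approx(2.0) and intercept == pytest.approx(3.0)
        np.testing.assert_allclose(corrected, resolved)

    def test_unknown_row_maps_to_midway_concentration(self):
        # calibration rows 0,1 with refs 2 and 4; unknown row resolved midway
        col = np.array([7.0, 11.0, 9.0])
        refs = np.array([2.0, 4.0])
        corrected, slope, intercept = correlation_constraint(col, refs, cal_rows=[0, 1])
        conc_unknown = (col[2] - intercept) / slope
        assert conc_unknown == pytest.approx(3.0)

    def test_zero_variance_resolved_rejected(self):
        with pytest.raises(ValueError):
            correlation_constraint(np.ones(3), np.array([1.0, 2.0, 3.0]))


class TestALS:
    def test_noiseless_truth_init_is_fixed_point(self):
        """Starting at the true spectra of noiseless bilinear data, lack of
        fit is ~0 immediately."""
        design, full, data = five_component_dataset(sigma=0.0)
        lib = default_library()
        S_true = np.vstack([m.unit_spectrum(data.grid) for m in lib])
        model = als_fit(data, MCRSettings(), design, S_T_init=S_true)
        assert model.lof_pct < 1e-6
        assert model.explained_var_pct == pytest.approx(100.0, abs=1e-8)

    def test_noiseless_simplisma_fit_resolves_truth(self):
        """SIMPLISMA-initialized ALS on noiseless 5-component data reaches
        lof < 0.1% and spectral correlation > 0.999 per matched component."""
        design, full, data = five_component_dataset(sigma=0.0)
        model = als_fit(data, MCRSettings(), design)
        assert model.lof_pct < 0.1
        lib = {m.name: m.unit_spectrum(data.grid) for m in default_library()}
        for name in ("AT", "PR", "HZ", "LV"):
            j = model.regressions[name][0]
            r = np.corrcoef(lib[name], model.S_T[j])[0, 1]
            assert r > 0.999, f"{name} spectral correlation {r}"

    def test_nonnegativity_of_profiles(self):
        design, full, data = five_component_dataset(sigma=0.002)
        model = als_fit(data, MCRSettings(), design)
        assert np.all(model.C >= 0)
        assert np.all(model.S_T >= 0)

    def test_lof_explained_variance_identity_on_fit(self):
        design, full, data = five_component_dataset(sigma=0.002)
        model = als_fit(data, MCRSettings(), design)
        assert model.explained_var_pct == pytest.approx(
            100.0 - model.lof_pct**2 / 100.0, abs=1e-9
        )

    def test_monotone_lof_over_accepted_iterations(self):
        """The reconstruction error of accepted iterates never increases:
        the returned model attains the minimum lack of fit seen, and the
        accepted subsequence is the running minimum of the raw sequence."""
        from quadspec import mcr as mcr_mod

        design, full, data = five_component_dataset(sigma=0.002)
        lofs = []
        orig = mcr_mod.lack_of_fit

        def spy(D, C, S_T):
            v = orig(D, C, S_T)
            lofs.append(v)
            return v

        mcr_mod.lack_of_fit = spy
        try:
            model = als_fit(data, MCRSettings(), design)
        finally:
            mcr_mod.lack_of_fit = orig
        iter_lofs = lofs
        assert model.lof_pct == pytest.approx(min(iter_lofs), abs=1e-12)
        accepted = np.minimum.accumulate(iter_lofs)
        assert np.all(np.diff(accepted) <= 0.0 + 1e-15)
        assert iter_lofs[-1] < iter_lofs[0]  # ALS actually improved the fit


class TestPredict:
    def test_in_sample_consistency(self):
        design, full, data = five_component_dataset(sigma=0.0)
        model = als_fit(data, MCRSettings(), design)
        preds = predict_mcr(model, data)
        for name in ("AT", "PR", "HZ", "LV"):
            np.testing.assert_allclose(
                preds.column(name), design.column(name), rtol=5e-3
            )

    def test_interferent_absent_from_model_grid_mismatch(self):
        design, full, data = five_component_dataset(sigma=0.0)
        model = als_fit(data, MCRSettings(), design)
        bad = SpectraMatrix(
            quadspec.ACQUISITION_GRID, ["x"], np.zeros((1, 651)) + 0.1
        )
        with pytest.raises(ValueError, match="grid"):
            predict_mcr(model, bad)

    def test_uncalibrated_interferent_still_recovers_analytes(self):
        """The interferent is absent from the calibration references (only
        the four drugs are calibrated); unknowns carrying a background level
        outside the calibration's range still recover within 5%."""
        design, full, data = five_component_dataset(sigma=0.002, seed=77)
        model = als_fit(data, MCRSettings(), design)  # refs: four drugs only
        lib = default_library()
        unknown_concs = {"AT": 12.0, "PR": 6.0, "HZ": 4.0, "LV": 3.0, "URINE": 2.8}
        s = mixture_spectrum(lib, unknown_concs, quadspec.ACQUISITION_GRID,
                             NoiseModel(0.002, seed=78))
        row = working_grid(
            SpectraMatrix(quadspec.ACQUISITION_GRID, ["u"], s.absorbance[None, :])
        )
        preds = predict_mcr(model, row)
        for name in ("AT", "PR", "HZ", "LV"):
            rec = 100.0 * preds.column(name)[0] / unknown_concs[name]
            assert 95.0 < rec < 105.0, f"{name}: {rec:.2f}%"

    def test_validation_rows_recovered_noiseless(self):
        """Model fitted on the 18 calibration rows predicts the 7 held-out
        rows to < 0.5% relative error (noiseless)."""
        design, full, data = five_component_dataset(sigma=0.0)
        cal_refs, val_refs = split_calibration_validation(design, DEFAULT_VALIDATION_ROWS)
        cal_idx = [design.samples.index(s) for s in cal_refs.samples]
        val_idx = [design.samples.index(s) for s in val_refs.samples]
        cal = SpectraMatrix(data.grid, [data.samples[i] for i in cal_idx], data.values[cal_idx])
        val = SpectraMatrix(data.grid, [data.samples[i] for i in val_idx], data.values[val_idx])
        model = als_fit(cal, MCRSettings(), cal_refs)
        preds = predict_mcr(model, val)
        for name in ("AT", "PR", "HZ", "LV"):
            rel = np.abs(preds.column(name) - val_refs.column(name)) / val_refs.column(name)
            assert np.max(rel) < 0.005, f"{name}: {rel}"
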