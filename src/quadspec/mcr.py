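"""Multivariate curve resolution by alternating least squares (MCR-ALS).

Bilinear model D = C St + E for a samples x wavelengths absorbance matrix D:
C holds concentration profiles, St spectral profiles, E residuals.  Starting
from SIMPLISMA initial estimates, ALS alternates non-negative least-squares
updates of C and St.  A correlation constraint regresses each resolved
concentration column onto known reference concentrations of the calibration
samples every iteration, anchoring that component in real concentration
units and letting the model quantify analytes in the presence of
uncalibrated interferents (extra free components, e.g. a urine background).

Model quality follows the standard lack-of-fit / explained-variance pair:
lof% = 100*sqrt(sum e^2 / sum d^2), R2% = 100*(sum d^2 - sum e^2)/sum d^2,
related by R2% = 100 - lof%^2/100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from .spectra import ConcentrationMatrix, SpectraMatrix

__all__ = [
    "MCRSettings",
    "MCRModel",
    "simplisma_init",
    "als_fit",
    "correlation_constraint",
    "lack_of_fit",
    "explained_variance",
    "predict_mcr",
]


@dataclass
class MCRSettings:
    """ALS configuration; defaults follow the five-component working setup."""

    n_components: int = 5
    max_iter: int = 100
    tol_lof_rel: float = 1e-4  # relative lack-of-fit change, i.e. 0.01%
    nonneg_spectra: bool = True
    nonneg_conc: bool = True
    constrained_analytes: tuple[str, ...] = ("AT", "PR", "HZ", "LV")
    simplisma_noise_pct: float = 5.0
    warmup_iter: int = 0  # optional unconstrained ALS cycles before constraints engage
    # Through-origin regression in the correlation constraint: a component's
    # contribution must vanish at zero concentration, and a free intercept
    # lets weak components swap baseline with the unconstrained background.
    constraint_through_origin: bool = True

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("need at least one component")


@dataclass
class MCRModel:
    """Fitted bilinear decomposition with constraint regressions."""

    C: np.ndarray  # samples x components
    S_T: np.ndarray  # components x wavelengths
    E: np.ndarray  # residuals, samples x wavelengths
    lof_pct: float
    explained_var_pct: float
    iterations: int
    converged: bool
    component_labels: list[str]
    # analyte -> (component index, slope, intercept) of resolved ~ reference
    regressions: dict[str, tuple[int, float, float]]
    wavelengths: np.ndarray


def lack_of_fit(D: np.ndarray, C: np.ndarray, S_T: np.ndarray) -> float:
    """lof% = 100 * sqrt(sum residual^2 / sum data^2)."""
    D = np.asarray(D, dtype=float)
    denom = np.sum(D**2)
    if denom == 0:
        raise ValueError("all-zero data matrix")
    E = D - C @ S_T
    return float(100.0 * np.sqrt(np.sum(E**2) / denom))


def explained_variance(D: np.ndarray, C: np.ndarray, S_T: np.ndarray) -> float:
    """R2% = 100 * (sum d^2 - sum e^2) / sum d^2."""
    D = np.asarray(D, dtype=float)
    denom = np.sum(D**2)
    if denom == 0:
        raise ValueError("all-zero data matrix")
    E = D - C @ S_T
    return float(100.0 * (denom - np.sum(E**2)) / denom)


# ---------------------------------------------------------------------------
# SIMPLISMA
# ---------------------------------------------------------------------------

def simplisma_init(
    D: SpectraMatrix | np.ndarray, k: int, noise_pct: float = 5.0
) -> tuple[np.ndarray, list[int]]:
    """Purest-variable initial spectral estimates (Windig's SIMPLISMA).

    For each wavelength j with column mean mu_j and standard deviation
    sigma_j, purity is p_j = w_j * sigma_j / (mu_j + offset) with
    offset = noise_pct/100 * max(mu).  The determinant weight w_j, computed
    from the correlation-around-origin matrix of length-scaled columns,
    deflates wavelengths correlated with already-picked ones.  The initial
    spectra are the least-squares solution of D = C0 St using the picked
    columns of D as C0, clipped at zero.

    Returns (S_T_init of shape k x m, picked wavelength indices).
    """
    X = D.values if isinstance(D, SpectraMatrix) else np.asarray(D, dtype=float)
    n, m = X.shape
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds matrix dimensions {X.shape}")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)  # population SD, as in the original formulation
    offset = noise_pct / 100.0 * mu.max()
    alpha = mu + offset
    length = np.sqrt(sigma**2 + alpha**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        Y = X / length
    Y[:, length == 0] = 0.0
    COO = (Y.T @ Y) / n

    picked: list[int] = []
    for _ in range(k):
        weights = np.empty(m)
        for j in range(m):
            idx = [j] + picked
            weights[j] = np.linalg.det(COO[np.ix_(idx, idx)])
        purity = weights * sigma / alpha
        purity[picked] = -np.inf
        picked.append(int(np.argmax(purity)))

    C0 = X[:, picked]  # n x k concentration-like profiles
    S_T, *_ = np.linalg.lstsq(C0, X, rcond=None)
    return np.clip(S_T, 0.0, None), picked


# ---------------------------------------------------------------------------
# constrained ALS
# ---------------------------------------------------------------------------

def _nnls_rows(A: np.ndarray, B: np.ndarray, nonneg: bool) -> np.ndarray:
    """Solve min ||A x_i - b_i|| for each column b_i of B; returns k x p."""
    if not nonneg:
        X, *_ = np.linalg.lstsq(A, B, rcond=None)
        return X
    k = A.shape[1]
    out = np.empty((k, B.shape[1]))
    for i in range(B.shape[1]):
        out[:, i], _ = nnls(A, B[:, i])
    return out


def correlation_constraint(
    C_col: np.ndarray,
    refs_col: np.ndarray,
    cal_rows: np.ndarray | None = None,
    through_origin: bool = False,
) -> tuple[np.ndarray, float, float]:
    """Regress resolved concentrations onto references and re-map.

    OLS fit resolved = slope*ref + intercept over the calibration rows;
    those entries are replaced by the fitted values (keeping the column in
    the resolved scale consistent with St), other rows are left as resolved.
    The inverse map (resolved - intercept)/slope converts any resolved value
    to concentration units; the regression is returned for that purpose.

    With ``through_origin`` the intercept is fixed at zero, which pins the
    component's contribution to vanish at zero concentration and prevents
    baseline exchange with unconstrained components.
    """
    C_col = np.asarray(C_col, dtype=float)
    refs_col = np.asarray(refs_col, dtype=float)
    if cal_rows is None:
        cal_rows = np.arange(len(refs_col))
    cal_rows = np.asarray(cal_rows)
    if len(cal_rows) < 2:
        raise ValueError("need at least 2 calibration rows")
    resolved = C_col[cal_rows]
    refs = refs_col if len(refs_col) == len(cal_rows) else refs_col[cal_rows]
    if np.ptp(resolved) == 0:
        raise ValueError("zero-variance resolved column under correlation constraint")
    if through_origin:
        slope = float(np.dot(refs, resolved) / np.dot(refs, refs))
        intercept = 0.0
    else:
        ref_c = refs - refs.mean()
        slope = float(np.dot(ref_c, resolved - resolved.mean()) / np.dot(ref_c, ref_c))
        intercept = float(resolved.mean() - slope * refs.mean())
    corrected = C_col.copy()
    corrected[cal_rows] = slope * refs + intercept
    return corrected, slope, intercept


def _assign_components(
    C: np.ndarray, refs: ConcentrationMatrix, analytes: tuple[str, ...]
) -> dict[str, int]:
    """Match constrained analytes to components by maximal |correlation|."""
    n_comp = C.shape[1]
    corr = np.zeros((len(analytes), n_comp))
    for a, name in enumerate(analytes):
        ref = refs.column(name)
        for j in range(n_comp):
            col = C[: len(ref), j]
            if np.ptp(col) == 0 or np.ptp(ref) == 0:
                continue
            corr[a, j] = abs(np.corrcoef(ref, col)[0, 1])
    rows, cols = linear_sum_assignment(-corr)
    return {analytes[a]: int(j) for a, j in zip(rows, cols)}


def als_fit(
    D: SpectraMatrix,
    settings: MCRSettings,
    refs: ConcentrationMatrix,
    S_T_init: np.ndarray | None = None,
) -> MCRModel:
    """Alternating least squares with non-negativity and correlation constraints.

    ``refs`` supplies reference concentrations for the calibration rows of
    ``D`` (matched by position: row i of refs corresponds to sample i of D).
    Components are assigned to constrained analytes at the first
    constrained C update by maximal correlation (one-to-one); unconstrained
    components remain free to soak up interferent signal, and are re-solved
    against the residual after each constraint application so they cannot
    stall.  Constraints engage from the first cycle by default: an
    unconstrained warm-up can merge spectrally similar components and
    derail the assignment.

    Constraint projections can transiently raise the residual, so each
    iterate is accepted only if it improves the lack of fit; the returned
    model is the best accepted iterate and the accepted-lof sequence is
    therefore non-increasing.
    """
    X = D.values
    n, m = X.shape
    k = settings.n_components
    missing = [a for a in settings.constrained_analytes if a not in refs.analytes]
    if missing:
        raise ValueError(f"constrained analytes {missing} not present in refs")
    if len(refs.samples) > n:
        raise ValueError("refs cover more rows than D has")
    cal_rows = np.arange(len(refs.samples))

    if S_T_init is None:
        _, picked = simplisma_init(X, k, settings.simplisma_noise_pct)
        S_T = _nnls_rows(X[:, picked], X, settings.nonneg_spectra)
    else:
        S_T = np.asarray(S_T_init, dtype=float).copy()
        if S_T.shape != (k, m):
            raise ValueError(f"S_T_init shape {S_T.shape} != ({k}, {m})")

    # warm-up: plain NNLS-ALS to settle the subspace before constraining
    for _ in range(settings.warmup_iter):
        C = _nnls_rows(S_T.T, X.T, settings.nonneg_conc).T
        S_T = _nnls_rows(C, X, settings.nonneg_spectra)

    assignment: dict[str, int] | None = None
    regressions: dict[str, tuple[int, float, float]] = {}
    lof_prev = np.inf
    converged = False
    best: tuple[float, np.ndarray, np.ndarray, dict] | None = None
    it = 0
    for it in range(1, settings.max_iter + 1):
        # C update: rows solved independently
        C = _nnls_rows(S_T.T, X.T, settings.nonneg_conc).T
        dead = np.all(C <= 0, axis=0)
        if np.any(dead):
            raise RuntimeError(
                f"degenerate all-zero component(s) {np.where(dead)[0].tolist()} in C update"
            )
        if assignment is None:
            assignment = _assign_components(C, refs, settings.constrained_analytes)
        for name, j in assignment.items():
            corrected, slope, intercept = correlation_constraint(
                C[:, j], refs.column(name), cal_rows,
                through_origin=settings.constraint_through_origin,
            )
            C[:, j] = np.clip(corrected, 0.0, None) if settings.nonneg_conc else corrected
            regressions[name] = (j, slope, intercept)
        # free components re-fit the residual left by the constrained ones
        cons = [j for j in assignment.values()]
        free = [j for j in range(k) if j not in cons]
        if free:
            resid = X - C[:, cons] @ S_T[cons]
            C[:, free] = _nnls_rows(S_T[free].T, resid.T, settings.nonneg_conc).T
        # St update: columns solved independently
        S_T = _nnls_rows(C, X, settings.nonneg_spectra)
        lof = lack_of_fit(X, C, S_T)
        if best is None or lof < best[0]:
            best = (lof, C.copy(), S_T.copy(), dict(regressions))
        if np.isfinite(lof_prev) and abs(lof_prev - lof) / max(lof, 1e-12) < settings.tol_lof_rel:
            converged = True
            break
        lof_prev = lof

    lof, C, S_T, regressions = best
    labels = [f"component_{j}" for j in range(k)]
    for name, (j, _, _) in regressions.items():
        labels[j] = name
    free = [j for j in range(k) if labels[j].startswith("component_")]
    for i, j in enumerate(free, start=1):
        labels[j] = f"interferent_{i}"
    E = X - C @ S_T
    return MCRModel(
        C=C,
        S_T=S_T,
        E=E,
        lof_pct=lof,
        explained_var_pct=explained_variance(X, C, S_T),
        iterations=it,
        converged=converged,
        component_labels=labels,
        regressions=regressions,
        wavelengths=D.grid.wavelengths,
    )


def predict_mcr(model: MCRModel, unknowns: SpectraMatrix) -> ConcentrationMatrix:
    """Quantify constrained analytes in new samples with St fixed.

    Each unknown row is solved by non-negative least squares against the
    model's spectral profiles, then mapped through the stored correlation
    regressions into ug/mL.  Mapped values are clipped at zero (slightly
    negative values can occur for samples near zero concentration).
    """
    if not np.array_equal(model.wavelengths, unknowns.grid.wavelengths):
        raise ValueError("unknowns are not on the model's wavelength grid")
    C_u = _nnls_rows(model.S_T.T, unknowns.values.T, nonneg=True).T
    analytes = list(model.regressions.keys())
    out = np.empty((unknowns.n_samples, len(analytes)))
    for a, name in enumerate(analytes):
        j, slope, intercept = model.regressions[name]
        out[:, a] = (C_u[:, j] - intercept) / slope
    return ConcentrationMatrix(list(unknowns.samples), analytes, np.clip(out, 0.0, None))
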