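"""SVD-based multi-state melting analysis of spectroscopic matrices.

The analysis factorizes a melting matrix A (spectral variable x
temperature) as A = U S V^T, keeps the leading components whose
temperature profiles (columns of V) are smooth by the first-order
autocorrelation criterion, and globally fits the retained profiles with a
sequential unfolding scheme

    N <-> I1 <-> ... <-> U,

where each step i is a two-state van't Hoff equilibrium with enthalpy
dH_i and midpoint Tm_i, so the step constant is

    K_i(T) = exp[(|dH_i| / R) * (1 / Tm_i - 1 / T)]   (temperatures in K).

Species populations follow from the cumulative products of the K_i, and
the species spectra are recovered by mapping the fitted populations back
through the SVD factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .spectra_io import MeltingMatrix, Probe, ValidationError

__all__ = [
    "R_KCAL",
    "SequentialModelParams",
    "SVDResult",
    "GlobalFitResult",
    "sequential_populations",
    "svd_decompose",
    "autocorrelation",
    "select_significant_species",
    "global_fit_sequential",
    "reconstruct_species_spectra",
    "melting_derivative_screen",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987e-3

#: Offset between Celsius and Kelvin.
T0_K = 273.15


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails; carries best-so-far diagnostics."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class SequentialModelParams:
    """Per-step van't Hoff parameters of a sequential unfolding scheme.

    ``dH`` in kcal/mol (the reported sign is echoed; transition sharpness
    is governed by |dH|), ``Tm`` in deg C.  ``steps`` transitions imply
    ``steps + 1`` species.
    """

    dH: tuple[float, ...]
    Tm: tuple[float, ...]
    dH_err: tuple[float, ...] | None = None
    Tm_err: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "dH", tuple(float(x) for x in self.dH))
        object.__setattr__(self, "Tm", tuple(float(x) for x in self.Tm))
        if len(self.dH) != len(self.Tm) or len(self.dH) < 1:
            raise ValidationError("dH and Tm must have equal length >= 1")
        if any(x == 0 or not np.isfinite(x) for x in self.dH):
            raise ValidationError("|dH| must be finite and nonzero")
        if any(not np.isfinite(x) for x in self.Tm):
            raise ValidationError("Tm must be finite")

    @property
    def steps(self) -> int:
        return len(self.dH)

    @property
    def n_species(self) -> int:
        return len(self.dH) + 1


def sequential_populations(
    params: SequentialModelParams, T: float | np.ndarray
) -> np.ndarray:
    """Species fractions (f_N, f_I1, ..., f_U) of the sequential scheme.

    Computed in log space (log-sum-exp) so that extreme temperatures or
    very sharp steps never overflow.  For array ``T`` of length n the
    result has shape (n, steps + 1); fractions sum to 1 along the last
    axis.
    """
    T = np.asarray(T, dtype=float)
    scalar = T.ndim == 0
    T_K = np.atleast_1d(T) + T0_K
    dH = np.abs(np.asarray(params.dH))
    Tm_K = np.asarray(params.Tm) + T0_K
    # log K_i(T), shape (nT, m)
    logK = (dH / R_KCAL)[np.newaxis, :] * (1.0 / Tm_K[np.newaxis, :] - 1.0 / T_K[:, np.newaxis])
    # log weights: w_0 = 1, w_k = prod_{i<=k} K_i
    logw = np.concatenate(
        [np.zeros((T_K.size, 1)), np.cumsum(logK, axis=1)], axis=1
    )
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    f = w / w.sum(axis=1, keepdims=True)
    return f[0] if scalar else f


@dataclass(frozen=True)
class SVDResult:
    """SVD factors of a melting matrix plus component diagnostics.

    Columns of ``basis`` are linear combinations of the species spectra;
    ``profiles`` columns are the corresponding temperature profiles;
    ``singular_values`` weight each component.  ``autocorr_U`` /
    ``autocorr_V`` hold the first-order autocorrelation of every column
    of each factor; smooth (signal-like) columns score near 1, noise
    scores near 0.
    """

    basis: np.ndarray
    singular_values: np.ndarray
    profiles: np.ndarray
    autocorr_U: np.ndarray
    autocorr_V: np.ndarray
    temperatures: np.ndarray
    axis: np.ndarray
    probe: Probe
    rank_selected: int | None = None
    variance_explained: float | None = None

    def reconstruct(self, rank: int | None = None) -> np.ndarray:
        """A (truncated) reconstruction basis @ diag(s) @ profiles^T."""
        r = self.singular_values.size if rank is None else rank
        return (self.basis[:, :r] * self.singular_values[:r]) @ self.profiles[:, :r].T


def autocorrelation(v: np.ndarray) -> float:
    """First-order autocorrelation C(v) = sum_i v_i v_{i+1} of a vector.

    The vector is unit-normalized first; smooth vectors score close to 1,
    sign-alternating noise close to -1.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValidationError("autocorrelation needs at least 2 points")
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValidationError("autocorrelation of a zero vector is undefined")
    u = v / norm
    return float(np.dot(u[:-1], u[1:]))


def svd_decompose(m: MeltingMatrix) -> SVDResult:
    """Full (economy) SVD of a melting matrix with autocorrelations."""
    U, s, Vt = np.linalg.svd(m.values, full_matrices=False)
    V = Vt.T
    return SVDResult(
        basis=U,
        singular_values=s,
        profiles=V,
        autocorr_U=np.array([autocorrelation(U[:, k]) for k in range(U.shape[1])]),
        autocorr_V=np.array([autocorrelation(V[:, k]) for k in range(V.shape[1])]),
        temperatures=m.temperatures,
        axis=m.axis,
        probe=m.probe,
    )


def select_significant_species(
    svd: SVDResult, cutoff: float = 0.8
) -> tuple[int, float]:
    """Count significant species by the V-profile autocorrelation cutoff.

    Components are scanned in singular-value order; the selected rank is
    the leading contiguous block whose V-column autocorrelation is >=
    ``cutoff`` (counting stops at the first failure).  Returns the rank
    and the percentage of total variance (sum of squared singular values)
    it explains.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValidationError("cutoff must be in (0, 1)")
    rank = 0
    for c in svd.autocorr_V:
        if c >= cutoff:
            rank += 1
        else:
            break
    total = float(np.sum(svd.singular_values**2))
    var = 100.0 * float(np.sum(svd.singular_values[:rank] ** 2)) / total if total else 0.0
    if rank == 0:
        warnings.warn(
            "no V profile passes the autocorrelation cutoff; the matrix "
            "looks like pure noise at this cutoff",
            stacklevel=2,
        )
    return rank, var


@dataclass(frozen=True)
class GlobalFitResult:
    """Result of the sequential-model global fit of SVD temperature profiles."""

    params: SequentialModelParams
    coefficients: np.ndarray  # C, (n_species, rank): profiles ~ populations @ C
    populations: np.ndarray  # (nT, n_species)
    species_spectra: np.ndarray  # (n_axis, n_species)
    chi2_reduced: float
    probe: Probe
    temperatures: np.ndarray
    axis: np.ndarray
    residual_norm: float = 0.0
    diagnostics: dict = field(default_factory=dict)


def _theta_to_params(theta: np.ndarray, m: int) -> SequentialModelParams:
    dH = theta[:m]
    tm1 = theta[m]
    incr = theta[m + 1 :]
    Tm = tm1 + np.concatenate([[0.0], np.cumsum(incr)])
    return SequentialModelParams(dH=tuple(dH), Tm=tuple(Tm))


def _auto_init(
    svd: SVDResult, steps: int, dH0: float = 40.0
) -> SequentialModelParams:
    """Spread initial midpoints from inflections of the 2nd V profile.

    Falls back to an even spread over the interior of the temperature
    range when fewer inflections than steps are found.
    """
    T = svd.temperatures
    cand: list[float] = []
    if svd.profiles.shape[1] >= 2:
        prof = svd.profiles[:, 1]
        d = np.gradient(prof, T)
        mag = np.abs(d)
        if mag.max() > 0:
            peaks, _ = find_peaks(mag, height=0.2 * mag.max())
            cand = sorted(float(T[p]) for p in peaks)
    if len(cand) < steps:
        lo, hi = T[0], T[-1]
        cand = list(np.linspace(lo + 0.15 * (hi - lo), hi - 0.1 * (hi - lo), steps))
    else:
        cand = cand[:steps]
    return SequentialModelParams(dH=(dH0,) * steps, Tm=tuple(sorted(cand)))


def global_fit_sequential(
    svd: SVDResult,
    rank: int,
    steps: int,
    init: SequentialModelParams | str = "auto",
    min_increment: float = 0.5,
    weight_by_singular_values: bool = True,
) -> GlobalFitResult:
    """Globally fit the leading V profiles with the sequential scheme.

    The model is V[:, :rank] ~ F(theta) @ C where F holds the species
    populations at the matrix temperatures and C is a free linear map.
    C is solved exactly by linear least squares at every step of the
    nonlinear optimization (variable projection), so only the shared
    thermodynamic parameters theta = (|dH_i|, Tm_i) are iterated.  Tm's
    are kept ascending by optimizing (Tm_1, positive increments), which
    removes label switching.

    With ``weight_by_singular_values`` (default) each profile's residual
    is scaled by its singular value, i.e. the fit minimizes the
    Frobenius reconstruction error of the rank-truncated data matrix.
    Under iid spectral noise the noise in profile j scales as 1/s_j, so
    this weighting is the maximum-likelihood estimator; unweighted
    profile residuals are available for comparison.

    Requires rank == steps + 1 (one linear map column per species); a
    rank-deficient request is a precondition error.
    """
    m = steps
    if m < 1:
        raise ValidationError("steps must be >= 1")
    if rank != m + 1:
        raise ValidationError(
            f"rank ({rank}) must equal steps + 1 ({m + 1}); re-run rank "
            "selection or change the number of steps"
        )
    if rank > svd.profiles.shape[1]:
        raise ValidationError("rank exceeds the number of SVD components")

    T = svd.temperatures
    V_r = svd.profiles[:, :rank]  # (nT, rank)
    col_w = svd.singular_values[:rank] if weight_by_singular_values else np.ones(rank)
    Y = V_r * col_w  # fit target; C on the V scale is C_Y / col_w

    if isinstance(init, str):
        p0 = _auto_init(svd, steps)
    else:
        if init.steps != steps:
            raise ValidationError("init has the wrong number of steps")
        p0 = init

    tm = np.array(sorted(p0.Tm))
    theta0 = np.concatenate(
        [np.abs(p0.dH), [tm[0]], np.maximum(np.diff(tm), min_increment)]
    )
    lb = np.concatenate([[1.0] * m, [T[0] - 50.0], [min_increment] * (m - 1)])
    ub = np.concatenate([[500.0] * m, [T[-1] + 50.0], [T[-1] - T[0]] * (m - 1)])
    theta0 = np.clip(theta0, lb, ub)

    def solve_C(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        F = sequential_populations(_theta_to_params(theta, m), T)  # (nT, m+1)
        C, *_ = np.linalg.lstsq(F, Y, rcond=None)
        return F, C

    def resid(theta: np.ndarray) -> np.ndarray:
        F, C = solve_C(theta)
        return (Y - F @ C).ravel()

    sol = least_squares(resid, theta0, bounds=(lb, ub), method="trf", x_scale="jac")
    if not sol.success:
        raise FitError(
            f"sequential global fit did not converge: {sol.message}",
            best=_theta_to_params(sol.x, m),
        )

    # asymptotic standard errors from the Jacobian at the solution
    dof = max(sol.fun.size - sol.x.size, 1)
    chi2_red = float(2.0 * sol.cost / dof)
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J) * chi2_red
        perr = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        cov = None
        perr = np.full(sol.x.size, np.nan)

    fitted = _theta_to_params(sol.x, m)
    # error on Tm_k: Tm_k = tm1 + sum of increments -> propagate the
    # covariance of (tm1, incr...) through the cumulative sum
    tm_err = []
    if cov is not None:
        for k in range(m):
            idx = [m] + list(range(m + 1, m + 1 + k))
            sub = cov[np.ix_(idx, idx)]
            tm_err.append(float(np.sqrt(max(sub.sum(), 0.0))))
    else:
        tm_err = [np.nan] * m
    fitted = SequentialModelParams(
        dH=fitted.dH,
        Tm=fitted.Tm,
        dH_err=tuple(float(e) for e in perr[:m]),
        Tm_err=tuple(tm_err),
    )

    F, C_Y = solve_C(sol.x)
    C = C_Y / col_w  # back on the unit-norm V scale
    spectra = reconstruct_species_spectra_from_factors(svd, rank, C)
    return GlobalFitResult(
        params=fitted,
        coefficients=C,
        populations=F,
        species_spectra=spectra,
        chi2_reduced=chi2_red,
        probe=svd.probe,
        temperatures=T,
        axis=svd.axis,
        residual_norm=float(np.linalg.norm(sol.fun)),
        diagnostics={"nfev": sol.nfev, "message": sol.message, "init": p0},
    )


def reconstruct_species_spectra_from_factors(
    svd: SVDResult, rank: int, C: np.ndarray
) -> np.ndarray:
    """Species spectra E = U_r S_r C^T so that A ~ E @ F^T.

    With V_r ~ F C, the truncated reconstruction U_r S_r V_r^T factors as
    (U_r S_r C^T)(F^T).  A nearly singular C means the species spectra
    are poorly determined (two species share a profile shape); this is
    flagged with a warning, not an error.
    """
    U_r = svd.basis[:, :rank]
    s_r = svd.singular_values[:rank]
    if C.shape[0] == C.shape[1] and np.linalg.cond(C) > 1e12:
        warnings.warn(
            "coefficient matrix nearly singular; species spectra are "
            "poorly determined",
            stacklevel=2,
        )
    return (U_r * s_r) @ C.T


def reconstruct_species_spectra(svd: SVDResult, fit: GlobalFitResult) -> np.ndarray:
    """Species spectra implied by a completed global fit (see above)."""
    rank = fit.coefficients.shape[1]
    return reconstruct_species_spectra_from_factors(svd, rank, fit.coefficients)


def melting_derivative_screen(
    m: MeltingMatrix,
    wavelengths: list[float],
    smooth_window: int = 3,
    min_rel_height: float = 0.2,
) -> list[tuple[float, list[float]]]:
    """Candidate transition temperatures from single-wavelength profiles.

    For each requested spectral position (snapped to the nearest axis
    point), the melting profile's central-difference derivative is
    lightly smoothed with a moving average and its local extrema above
    ``min_rel_height`` of the derivative maximum are returned as
    candidate midpoints — the usual initializer for the global fit.
    """
    T = m.temperatures
    if T.size < 5:
        raise ValidationError("need at least 5 temperatures for a derivative screen")
    out: list[tuple[float, list[float]]] = []
    for wl in wavelengths:
        snapped, y = m.profile(wl)
        d = np.gradient(y, T)
        if smooth_window > 1:
            kernel = np.ones(smooth_window) / smooth_window
            d = np.convolve(d, kernel, mode="same")
        mag = np.abs(d)
        if mag.max() <= 0:
            out.append((snapped, []))
            continue
        peaks, _ = find_peaks(mag, height=min_rel_height * mag.max())
        out.append((snapped, [float(T[p]) for p in peaks]))
    return out
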