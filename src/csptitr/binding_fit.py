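"""Dimensionless two-state binding model and the global K_D fit.

The titration is described with a normalized ligand concentration
``alpha = [L]/[P]`` and a normalized dissociation constant
``beta_D = K_D/[P]``. Under two-state fast exchange the fractional chemical
shift of every reporter equals the bound protein fraction,

    f(alpha, beta_D) = ((alpha + 1 + beta_D)
                        - sqrt((alpha + 1 + beta_D)^2 - 4*alpha)) / 2,

the physical root of the mass-action quadratic beta_D*f = (1 - f)(alpha - f).
The conjugate form 2*alpha / (s + sqrt(s^2 - 4*alpha)) with
s = alpha + 1 + beta_D is used throughout: it avoids catastrophic
cancellation for small f and extends smoothly to slightly negative alpha,
which the optimizer may visit while the calibration line is free.

alpha itself is not pipetted but inferred from the intensity of the TSP
internal standard, alpha = slope * I_TSP + intercept, and the global fit
treats (beta_D, slope, intercept) as the free parameters, exactly mirroring
an automated titration in which the mixing ratio is read off the 1D spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateCalibrationError,
    InsufficientDataError,
    InvalidParameterError,
    SingularCovarianceError,
)


def _fractional_shift_raw(alpha, beta_D):
    """Two-state bound fraction; no domain checks, smooth for alpha < 0."""
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta_D, dtype=float)
    s = a + 1.0 + b
    disc = s * s - 4.0 * a  # = (1-a)^2 + b^2 + 2b(1+a) > 0 for b > 0
    return 2.0 * a / (s + np.sqrt(disc))


def fractional_shift(alpha, beta_D):
    """Bound protein fraction f in [0, 1] under two-state mass action.

    Parameters
    ----------
    alpha : array_like
        Normalized ligand concentration [L]/[P], >= 0.
    beta_D : array_like
        Normalized dissociation constant K_D/[P], > 0.
    """
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta_D, dtype=float)
    if np.any(a < 0):
        raise InvalidParameterError("alpha must be >= 0")
    if np.any(b <= 0):
        raise InvalidParameterError("beta_D must be > 0")
    out = _fractional_shift_raw(a, b)
    if np.isscalar(alpha) and np.isscalar(beta_D):
        return float(out)
    return out


def alpha_from_tsp(i_tsp, cal_slope: float, cal_intercept: float):
    """Normalized ligand concentration from the TSP intensity (linear calibration)."""
    return cal_slope * np.asarray(i_tsp, dtype=float) + cal_intercept


def calibration_from_endpoints(i_a: float, i_b: float, alpha_max: float) -> tuple[float, float]:
    """Convert the endpoint parameterization alpha = alpha_max*(I - I_A)/(I_B - I_A)
    to (slope, intercept)."""
    if i_a == i_b:
        raise DegenerateCalibrationError("I_A == I_B: calibration line undefined")
    slope = alpha_max / (i_b - i_a)
    return slope, -slope * i_a


@dataclass
class BindingParams:
    """Point estimates of the free fit parameters (plus optional endpoints)."""

    beta_D: float
    cal_slope: float
    cal_intercept: float
    alpha_max: float | None = None
    I_A: float | None = None
    I_B: float | None = None

    def __post_init__(self):
        if self.beta_D <= 0:
            raise InvalidParameterError("beta_D must be > 0")
        if self.alpha_max is not None and self.alpha_max <= 1:
            raise InvalidParameterError(
                "alpha_max must exceed 1 (the saturating solution carries a molar excess)"
            )


@dataclass
class BindingFitResult:
    params: BindingParams
    K_D: float
    protein_conc: float
    covariance: np.ndarray | None  # over (beta_D, cal_slope, cal_intercept)
    ci95: dict[str, tuple[float, float]] | None
    residuals: dict[tuple[str, int], float]
    n_points: int
    dof: int
    sse: float
    converged: bool
    message: str = ""
    labels_used: list[str] = field(default_factory=list)
    shared_scale: float | None = None


_PARAM_NAMES = ("beta_D", "cal_slope", "cal_intercept")


def _model_matrix(theta, i_tsp, k_sat, fit_shared_scale):
    """Fractional-shift model per step, normalized at the saturated step."""
    log_beta, slope, intercept = theta[:3]
    beta = np.exp(log_beta)
    alpha = slope * i_tsp + intercept
    f = _fractional_shift_raw(alpha, beta)
    f_sat = f[k_sat]
    if f_sat == 0:
        f_sat = np.finfo(float).tiny
    m = f / f_sat
    if fit_shared_scale:
        m = theta[3] * m
    return m


def global_fit(
    csp,
    series,
    protein_conc: float,
    init: tuple[float, float, float] | None = None,
    exclude: set[str] | frozenset[str] = frozenset(),
    include_overlap: bool = False,
    alpha_max_guess: float | None = None,
    fit_shared_scale: bool = False,
    ci_method: str = "covariance",
    ci_level: float = 0.95,
    n_bootstrap: int = 200,
    rng: np.random.Generator | None = None,
) -> BindingFitResult:
    """Global Levenberg–Marquardt fit of the binding isotherm.

    Minimizes, over the significant residues and all titration steps,

        sum_{i,k} [ dd_ik/ddmax_i - f(slope*I_k + intercept, beta_D)
                                    / f(slope*I_K + intercept, beta_D) ]^2

    where K is the saturated step. The model-side normalization matches the
    data-side normalization by the observed saturated CSP, so the estimator
    is unbiased even when the final step is not fully saturated; when it is,
    f(alpha_K, beta_D) -> 1 and the expression reduces to the plain
    fractional-shift model. beta_D is fitted on a log scale to enforce
    positivity. Overlap-flagged residues are excluded by default.

    Parameters
    ----------
    csp : CSPTable
        Output of :func:`csp_analysis.build_csp_table`.
    series : TitrationSeries
        Supplies per-step TSP intensities.
    protein_conc : float
        Total protein concentration in μM; K_D = beta_D * protein_conc.
    """
    if protein_conc <= 0:
        raise InvalidParameterError("protein_conc must be > 0")
    df = csp.data
    mask = df["significant"] & (df["dd_max"] > 0) & ~df.index.isin(exclude)
    if not include_overlap:
        mask &= ~df["overlap"]
    dropped_zero = df.index[df["significant"] & (df["dd_max"] <= 0)].tolist()
    if dropped_zero:
        warnings.warn(
            f"excluding significant residues with zero saturated CSP: {dropped_zero}",
            stacklevel=2,
        )
    labels = df.index[mask].tolist()
    if len(labels) < 1:
        raise InsufficientDataError("no significant residues left to fit")
    n_steps = series.n_steps
    if n_steps < 4:
        raise InsufficientDataError("need >= 4 titration steps for a 3-parameter fit")

    i_tsp = np.asarray(series.i_tsp, dtype=float)
    k_sat = csp.saturated_step_position
    dd = df.loc[labels, csp.step_columns].to_numpy(dtype=float)
    dd_max = df.loc[labels, "dd_max"].to_numpy(dtype=float)
    y = dd / dd_max[:, None]  # fractional shifts, one row per residue

    # residuals at the saturated step are identically zero by construction
    keep = np.arange(n_steps) != k_sat
    step_ids = [s.index for s in series.steps]

    def residual_vec(theta, ymat):
        m = _model_matrix(theta, i_tsp, k_sat, fit_shared_scale)
        return (ymat[:, keep] - m[None, keep]).ravel()

    x0_list = _initial_guesses(init, i_tsp, k_sat, series, alpha_max_guess, fit_shared_scale)
    best = None
    for x0 in x0_list:
        try:
            res = optimize.least_squares(residual_vec, x0, args=(y,), method="lm", xtol=1e-14)
        except Exception:  # singular start etc.; try the next one
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise InsufficientDataError("all optimizer starts failed")
    res = best

    log_beta, slope, intercept = res.x[:3]
    beta = float(np.exp(log_beta))
    scale = float(res.x[3]) if fit_shared_scale else None
    n_params = res.x.size
    n_points = y[:, keep].size
    dof = max(n_points - n_params, 1)
    sse = float(2.0 * res.cost)

    cov = _covariance(res, beta, sse, n_points, n_params)

    params = BindingParams(beta_D=beta, cal_slope=float(slope), cal_intercept=float(intercept))
    resid = res.fun
    residuals = {}
    kept_steps = [sid for j, sid in enumerate(step_ids) if keep[j]]
    for i, lab in enumerate(labels):
        for j, sid in enumerate(kept_steps):
            residuals[(lab, sid)] = float(resid[i * len(kept_steps) + j])

    result = BindingFitResult(
        params=params,
        K_D=beta * protein_conc,
        protein_conc=protein_conc,
        covariance=cov,
        ci95=None,
        residuals=residuals,
        n_points=n_points,
        dof=dof,
        sse=sse,
        converged=bool(res.success and np.isfinite(beta)),
        message=res.message,
        labels_used=labels,
        shared_scale=scale,
    )
    if ci_method == "covariance":
        try:
            result.ci95 = confidence_intervals(result, level=ci_level)
        except SingularCovarianceError:
            result.ci95 = None
    elif ci_method == "bootstrap":
        result.ci95 = _bootstrap_ci(
            y, i_tsp, k_sat, keep, res.x, fit_shared_scale, protein_conc,
            level=ci_level, n_bootstrap=n_bootstrap,
            rng=rng or np.random.default_rng(0),
        )
    else:
        raise InvalidParameterError(f"unknown ci_method {ci_method!r}")
    return result


def _initial_guesses(init, i_tsp, k_sat, series, alpha_max_guess, fit_shared_scale):
    """Starting points: user-supplied, else endpoint calibration + log-grid scan of beta."""
    if init is not None:
        beta0, slope0, int0 = init
        x0 = [np.log(beta0), slope0, int0]
        if fit_shared_scale:
            x0.append(1.0)
        return [np.asarray(x0, dtype=float)]
    if alpha_max_guess is None:
        alpha_max_guess = float(series.metadata.get("alpha_max", 5.0))
    i0, ik = i_tsp[0], i_tsp[k_sat]
    if ik == i0:
        raise DegenerateCalibrationError("TSP intensity identical at first and saturated steps")
    # nominal endpoints: alpha = 0 at step 0, ~= alpha_max at the saturated step
    slope0 = alpha_max_guess / (ik - i0)
    int0 = -slope0 * i0
    guesses = []
    for beta0 in np.logspace(-3, 1, 9):
        x0 = [np.log(beta0), slope0, int0]
        if fit_shared_scale:
            x0.append(1.0)
        guesses.append(np.asarray(x0, dtype=float))
    return guesses


def _covariance(res, beta, sse, n_points, n_params):
    """Covariance over (beta_D, slope, intercept[, scale]) from the LM Jacobian."""
    J = res.jac
    JTJ = J.T @ J
    try:
        cov_x = np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        return None
    s2 = sse / max(n_points - n_params, 1)
    cov_x = cov_x * s2
    # delta method: first coordinate is log(beta_D)
    g = np.eye(n_params)
    g[0, 0] = beta
    return g @ cov_x @ g.T


def confidence_intervals(fit: BindingFitResult, level: float = 0.95) -> dict:
    """Per-parameter t-based confidence intervals from the fit covariance.

    The K_D interval is the beta_D interval scaled by the protein
    concentration. ``level=0`` collapses every interval onto the estimate.
    """
    if fit.covariance is None:
        raise SingularCovarianceError("no covariance available")
    var = np.diag(fit.covariance)
    if np.any(~np.isfinite(var)) or np.any(var < 0):
        raise SingularCovarianceError("covariance not positive semi-definite")
    tq = float(stats.t.ppf(0.5 + level / 2.0, fit.dof))
    est = [fit.params.beta_D, fit.params.cal_slope, fit.params.cal_intercept]
    names = list(_PARAM_NAMES)
    if fit.shared_scale is not None:
        est.append(fit.shared_scale)
        names.append("shared_scale")
    out = {}
    for name, e, v in zip(names, est, var):
        half = tq * float(np.sqrt(v))
        out[name] = (e - half, e + half)
    lo, hi = out["beta_D"]
    out["K_D"] = (lo * fit.protein_conc, hi * fit.protein_conc)
    return out


def _bootstrap_ci(y, i_tsp, k_sat, keep, x_hat, fit_shared_scale, protein_conc,
                  level, n_bootstrap, rng):
    """Case-resampling bootstrap over residues; percentile intervals."""
    n_res = y.shape[0]
    betas, slopes, intercepts = [], [], []

    def residual_vec(theta, ymat):
        m = _model_matrix(theta, i_tsp, k_sat, fit_shared_scale)
        return (ymat[:, keep] - m[None, keep]).ravel()

    for _ in range(n_bootstrap):
        rows = rng.integers(0, n_res, size=n_res)
        try:
            res = optimize.least_squares(residual_vec, x_hat, args=(y[rows],), method="lm")
        except Exception:
            continue
        betas.append(np.exp(res.x[0]))
        slopes.append(res.x[1])
        intercepts.append(res.x[2])
    if not betas:
        return None
    q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
    out = {
        "beta_D": tuple(np.percentile(betas, q)),
        "cal_slope": tuple(np.percentile(slopes, q)),
        "cal_intercept": tuple(np.percentile(intercepts, q)),
    }
    out["K_D"] = (out["beta_D"][0] * protein_conc, out["beta_D"][1] * protein_conc)
    return out
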